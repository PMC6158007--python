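"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they are used to check:
brute-force dense evaluation, forward-Euler ODE integration, enumeration,
and numerical CDF inversion.
"""

import numpy as np


def euler_stp(P0, tau_r0_s, tau_FDR_ms, a_FDR, spike_times_ms, dt_ms=1e-3):
    """Forward-Euler integration of the depletion + use-dependent
    replenishment ODEs; returns normalized per-spike amplitudes."""
    tau_r0 = tau_r0_s * 1000.0
    n, tau_r = 1.0, tau_r0
    t = spike_times_ms[0]
    w = []
    for tk in spike_times_ms:
        steps = int(round((tk - t) / dt_ms))
        for _ in range(steps):
            n += dt_ms * (1.0 - n) / tau_r
            tau_r += dt_ms * (tau_r0 - tau_r) / tau_FDR_ms
        w.append(n * P0)
        n *= (1.0 - P0)
        tau_r *= (1.0 - a_FDR)
        t = tk
    w = np.asarray(w)
    return w / w[0]


def dense_kernel_argmax(tau_r, tau_d, t_max=60.0, dt=1e-3):
    """Peak time of (1-e^{-t/tau_r})^2 e^{-t/tau_d} by 1 us dense scan."""
    t = np.arange(0.0, t_max, dt)
    y = (1.0 - np.exp(-t / tau_r)) ** 2 * np.exp(-t / tau_d)
    return t[np.argmax(y)]


def fisher_two_sided_enum(table):
    """Exact two-sided Fisher p by full enumeration of tables with the
    observed margins (probability-mass definition)."""
    from math import comb
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(0, min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-12))


def beta_quantile_numeric(q, a, b, grid_n=2_000_001):
    """Beta quantile via trapezoidal CDF on a dense grid (no scipy.stats)."""
    from math import lgamma, exp
    x = np.linspace(1e-12, 1 - 1e-12, grid_n)
    logpdf = ((a - 1) * np.log(x) + (b - 1) * np.log1p(-x)
              + lgamma(a + b) - lgamma(a) - lgamma(b))
    pdf = np.exp(logpdf)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                           * np.diff(x))])
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, x))


def product_cv(binom_n, binom_p, gain_mean, gain_sd):
    """Analytic CV of Bin(n,p) x N(m,s) from product moments."""
    ex = binom_n * binom_p
    ex2 = binom_n * binom_p * (1 - binom_p) + ex ** 2
    ey = gain_mean
    ey2 = gain_sd ** 2 + gain_mean ** 2
    mean = ex * ey
    return np.sqrt(ex2 * ey2 - mean ** 2) / mean
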