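"""Short-term depression with use-dependent replenishment.

The model tracks a releasable vesicle fraction ``n`` and a recovery time
constant ``tau_r`` that itself accelerates with presynaptic activity
(use-dependent, or "facilitated", replenishment):

    dn/dt     = (1 - n) / tau_r      - P0 * n * delta(t - t_k)
    dtau_r/dt = (tau_r0 - tau_r) / tau_FDR - a_FDR * tau_r * delta(t - t_k)

The response to spike k is w_k = A * n_k * P0, read out with the pre-spike
state. Between spikes both equations have closed-form solutions, so the
event-driven simulation is exact (no numerical integration):

    tau_r(t) = tau_r0 + (tau_r(0) - tau_r0) * exp(-t / tau_FDR)

and the depleted fraction decays by exp(-I(T)) with

    I(T) = int_0^T dt / (a + b e^{-t/c})
         = (c/a) * [T/c + ln(a + b e^{-T/c}) - ln(a + b)]

where a = tau_r0, b = tau_r(0) - tau_r0, c = tau_FDR.

Units: ``tau_r0`` is expressed in seconds (matching how recovery constants
are conventionally reported), ``tau_FDR`` in ms; all spike times in ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import lmfit
import numpy as np

__all__ = [
    "STPParams",
    "STPFitResult",
    "simulate",
    "steady_state_normalized",
    "fit",
    "param_zscore",
    "FitFailure",
]


class FitFailure(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class STPParams:
    """Dynamic parameters of one connection class.

    P0       : initial release probability, (0, 1)
    tau_r0   : baseline vesicle recovery time constant, seconds
    tau_FDR  : time constant of use-dependent replenishment, ms
    a_FDR    : fractional reduction of tau_r per spike, (0, 1)
    A        : connection strength scale, mV (drops out of normalized fits)
    se       : standard error per parameter, from the fit covariance
    """

    P0: float
    tau_r0: float
    tau_FDR: float
    a_FDR: float
    A: float = 1.0
    se: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.P0 < 1.0):
            raise ValueError("P0 must be in (0, 1)")
        if not (0.0 < self.a_FDR < 1.0):
            raise ValueError("a_FDR must be in (0, 1)")
        if self.tau_r0 <= 0 or self.tau_FDR <= 0:
            raise ValueError("time constants must be positive")


def _depletion_integral(T: float, tau_rk: float, tau_r0: float,
                        tau_fdr: float) -> float:
    # int_0^T dt / (a + b e^{-t/c}), written overflow-safe for large T/c
    a, b, c = tau_r0, tau_rk - tau_r0, tau_fdr
    if abs(b) < 1e-15 * a:
        return T / a
    return (c / a) * (T / c + np.log(a + b * np.exp(-T / c)) - np.log(a + b))


def simulate(params: STPParams,
             spike_times: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Event-driven simulation of per-spike response amplitudes.

    Returns ``(w, w_normalized)`` where ``w[k] = A * n_k * P0`` uses the
    pre-spike state and ``w_normalized = w / w[0]``.
    """
    times = np.asarray(spike_times, dtype=float)
    if times.size == 0:
        return np.array([]), np.array([])
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing")

    tau_r0_ms = params.tau_r0 * 1000.0
    n = 1.0
    tau_r = tau_r0_ms
    t_prev = times[0]
    w = np.empty(times.size)
    for k, t in enumerate(times):
        dt = t - t_prev
        if dt > 0:
            # relax tau_r toward baseline, recover n along the tau_r(t) path
            integral = _depletion_integral(dt, tau_r, tau_r0_ms,
                                           params.tau_FDR)
            n = 1.0 - (1.0 - n) * np.exp(-integral)
            tau_r = tau_r0_ms + (tau_r - tau_r0_ms) * np.exp(
                -dt / params.tau_FDR)
        w[k] = params.A * n * params.P0
        n *= (1.0 - params.P0)
        tau_r *= (1.0 - params.a_FDR)
        assert 0.0 < n <= 1.0 and tau_r > 0.0
        t_prev = t
    return w, w / w[0]


def steady_state_normalized(P0: float, tau_r0: float,
                            frequency: float) -> float:
    """Fixed-point normalized amplitude of a periodic train when a_FDR = 0.

    With inter-spike interval D = 1000/frequency ms and fixed recovery
    constant tau_r0 (seconds), the pre-spike vesicle fraction converges to

        n_ss = (1 - e^{-D/tau}) / (1 - (1 - P0) e^{-D/tau})
    """
    decay = np.exp(-(1000.0 / frequency) / (tau_r0 * 1000.0))
    return (1.0 - decay) / (1.0 - (1.0 - P0) * decay)


def _curve_residuals(p: lmfit.Parameters,
                     curves: Mapping[Tuple[float, float], np.ndarray],
                     spike_table: Mapping[Tuple[float, float], np.ndarray],
                     ) -> np.ndarray:
    params = STPParams(P0=p["P0"].value, tau_r0=p["tau_r0"].value,
                       tau_FDR=p["tau_FDR"].value, a_FDR=p["a_FDR"].value)
    res = []
    for key, observed in curves.items():
        _, norm = simulate(params, spike_table[key])
        res.append(norm[:len(observed)] - observed)
    return np.concatenate(res)


def fit(curves: Mapping[Tuple[float, float], Sequence[float]],
        spike_times: Optional[Mapping[Tuple[float, float],
                                      Sequence[float]]] = None,
        init: Optional[STPParams] = None,
        multi_start: bool = True) -> "STPFitResult":
    """Joint least-squares fit of normalized per-pulse amplitude curves.

    Parameters
    ----------
    curves:
        Mapping ``(frequency_hz, recovery_delay_ms) -> normalized per-pulse
        amplitudes`` (first pulse = 1). Identifiability requires at least
        two distinct frequencies or two recovery delays.
    spike_times:
        Optional explicit spike-time lists per curve; by default the
        standard 8 induction + 4 recovery train is reconstructed from the
        key.
    init:
        Optional single starting point; otherwise a default start is used.
    multi_start:
        When true, a 3x3 grid over (P0, tau_r0) of starts is tried and the
        best (lowest residual) solution returned.
    """
    curves = {k: np.asarray(v, dtype=float) for k, v in curves.items()}
    if not curves:
        raise ValueError("no curves provided")
    freqs = {k[0] for k in curves}
    delays = {k[1] for k in curves}
    if len(freqs) < 2 and len(delays) < 2:
        raise ValueError("need >=2 frequencies or >=2 recovery delays "
                         "for identifiability")
    if spike_times is None:
        from .synthgen import make_protocol
        spike_table = {k: make_protocol(k[0], k[1]).spike_times
                       for k in curves}
    else:
        spike_table = {k: np.asarray(v, dtype=float)
                       for k, v in spike_times.items()}

    def make_params(p0, tr0, tfdr, afdr):
        p = lmfit.Parameters()
        p.add("P0", value=p0, min=0.01, max=0.99)
        p.add("tau_r0", value=tr0, min=0.05, max=20.0)
        p.add("tau_FDR", value=tfdr, min=10.0, max=5000.0)
        p.add("a_FDR", value=afdr, min=0.01, max=0.99)
        return p

    if init is not None:
        starts = [(init.P0, init.tau_r0, init.tau_FDR, init.a_FDR)]
    elif multi_start:
        starts = [(p0, tr0, 250.0, 0.5)
                  for p0 in (0.1, 0.3, 0.6)
                  for tr0 in (0.3, 1.0, 5.0)]
    else:
        starts = [(0.3, 1.0, 250.0, 0.5)]

    best = None
    failures = []
    for start in starts:
        try:
            out = lmfit.minimize(_curve_residuals, make_params(*start),
                                 args=(curves, spike_table),
                                 method="least_squares")
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            failures.append((start, repr(exc)))
            continue
        if not out.success:
            failures.append((start, out.message))
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise FitFailure("all optimizer starts failed",
                         {"starts": failures})

    observed = np.concatenate(list(curves.values()))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - best.chisqr / ss_tot if ss_tot > 0 else float("nan")

    se = {}
    se_reliable = best.covar is not None
    for name in ("P0", "tau_r0", "tau_FDR", "a_FDR"):
        stderr = best.params[name].stderr
        se[name] = float(stderr) if stderr is not None else float("nan")
    if not se_reliable:
        warnings.warn("near-singular covariance; standard errors are "
                      "unreliable", RuntimeWarning)
    # parameters pinned near a bound indicate a degenerate (e.g. flat) input
    at_bounds = []
    for name in ("P0", "tau_r0", "tau_FDR", "a_FDR"):
        par = best.params[name]
        span = par.max - par.min
        if (par.value - par.min) < 0.02 * span \
                or (par.max - par.value) < 0.02 * span:
            at_bounds.append(name)

    params = STPParams(P0=best.params["P0"].value,
                       tau_r0=best.params["tau_r0"].value,
                       tau_FDR=best.params["tau_FDR"].value,
                       a_FDR=best.params["a_FDR"].value,
                       se=se)
    return STPFitResult(params=params, r_squared=r2,
                        se_reliable=se_reliable, at_bounds=at_bounds,
                        chisqr=float(best.chisqr))


@dataclass
class STPFitResult:
    params: STPParams
    r_squared: float
    se_reliable: bool
    at_bounds: list
    chisqr: float

    def to_dict(self) -> dict:
        d = {name: {"value": getattr(self.params, name),
                    "se": self.params.se.get(name)}
             for name in ("P0", "tau_r0", "tau_FDR", "a_FDR")}
        d["r_squared"] = self.r_squared
        d["se_reliable"] = self.se_reliable
        d["at_bounds"] = self.at_bounds
        return d


def param_zscore(x1: float, se1: float, x2: float, se2: float) -> float:
    """Z = |x1 - x2| / sqrt(se1^2 + se2^2) for comparing fitted parameters."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    return abs(x1 - x2) / np.hypot(se1, se2)
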