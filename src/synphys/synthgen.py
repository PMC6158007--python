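"""Synthetic multipatch experiments with known ground truth.

Emulates paired whole-cell recordings: a presynaptic train of evoked spikes
and a postsynaptic trace containing background noise plus stochastic EPSPs.
Every quantity that downstream analysis estimates (per-event amplitudes and
latencies, short-term-plasticity modulation, connectedness) is recorded as
ground truth, so QC, fitting, deconvolution, detection and connectivity
stages are all testable without recorded data.

Amplitude stochasticity is the product of a Binomial(n=24, p=0.2) vesicle
count and a Normal(1, 0.3) gain, scaled to a target mean; EPSP shape follows
the double-exponential kernel

    y(t) = A * (1 - e^{-(t-t0)/tau_r})^2 * e^{-(t-t0)/tau_d},  t >= t0

with tau_r calibrated so that the foot-to-peak rise time matches the
configured value (2 ms by default) and the kernel peak equal to the drawn
amplitude. Event latencies are Normal(2 ms, 0.2 ms). Stimulus trains are
8 induction pulses + 4 recovery pulses at 10/20/50/100 Hz with recovery
delays of 250-4000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .stpmodel import STPParams, simulate as stp_simulate
from .trace import SweepRecording, Trace

__all__ = [
    "StimulusProtocol",
    "SyntheticAmplitudeModel",
    "SyntheticPSPConfig",
    "NoiseModel",
    "GroundTruth",
    "make_protocol",
    "calibrated_tau_r",
    "kernel_peak_time",
    "psp_kernel",
    "sample_amplitudes",
    "make_noise",
    "raw_rms_for_deconvolved",
    "synthesize_pair",
    "synthesize_background_pool",
    "DEFAULT_SAMPLE_RATE_KHZ",
]

DEFAULT_SAMPLE_RATE_KHZ = 50.0


@dataclass
class StimulusProtocol:
    """Induction + recovery pulse train.

    The standard protocol is 8 pulses at ``frequency`` Hz, a recovery delay,
    then 4 more pulses at the same interval; repeated ``n_trials`` times at
    a 15 s inter-trial interval.
    """

    frequency: float             # Hz
    n_induction: int = 8
    n_recovery: int = 4
    recovery_delay: float = 250.0  # ms between 8th and 9th pulses
    n_trials: int = 5
    inter_trial_interval: float = 15.0  # s

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.recovery_delay < 0:
            raise ValueError("recovery delay must be non-negative")
        if min(self.n_induction, self.n_recovery, self.n_trials) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def ipi(self) -> float:
        """Inter-pulse interval, ms."""
        return 1000.0 / self.frequency

    @property
    def spike_times(self) -> np.ndarray:
        """Pulse times within one trial, ms from trial start."""
        ind = np.arange(self.n_induction) * self.ipi
        # the 8th->9th interval IS the recovery delay; later pulses resume
        # the regular inter-pulse interval
        rec = (ind[-1] + self.recovery_delay
               + np.arange(self.n_recovery) * self.ipi)
        return np.concatenate([ind, rec])

    @property
    def n_pulses(self) -> int:
        return self.n_induction + self.n_recovery


def make_protocol(frequency: float, recovery_delay: float = 250.0,
                  n_trials: int = 5, **kwargs) -> StimulusProtocol:
    """Standard 8 + 4 pulse train at ``frequency`` Hz."""
    return StimulusProtocol(frequency=frequency,
                            recovery_delay=recovery_delay,
                            n_trials=n_trials, **kwargs)


@dataclass
class SyntheticAmplitudeModel:
    """Stochastic EPSP amplitude = Binomial release x Normal gain.

    The binomial factor mimics stochastic vesicle release from
    ``binom_n`` sites with probability ``binom_p``; the normal factor
    accounts for vesicle-size / receptor-efficacy variability. All draws
    are scaled by ``target_mean_amplitude / (binom_n * binom_p *
    gain_mean)`` so the distribution mean equals the target. Negative
    products (gain < 0) are rare (~0.04 % at defaults) and deliberately
    kept.
    """

    binom_n: int = 24
    binom_p: float = 0.2
    gain_mean: float = 1.0
    gain_sd: float = 0.3
    target_mean_amplitude: float = 0.5  # mV

    def __post_init__(self) -> None:
        if not (0.0 < self.binom_p <= 1.0):
            raise ValueError("binom_p must be in (0, 1]")
        if self.binom_n < 1:
            raise ValueError("binom_n must be >= 1")
        if self.gain_sd < 0:
            raise ValueError("gain_sd must be non-negative")

    @property
    def scale(self) -> float:
        return self.target_mean_amplitude / (
            self.binom_n * self.binom_p * self.gain_mean)

    def analytic_cv(self) -> float:
        """CV of the product X*Y, X ~ Bin(n, p), Y ~ N(m, s)."""
        ex = self.binom_n * self.binom_p
        ex2 = ex * (1 - self.binom_p) + ex ** 2
        ey = self.gain_mean
        ey2 = self.gain_sd ** 2 + ey ** 2
        mean = ex * ey
        var = ex2 * ey2 - mean ** 2
        return np.sqrt(var) / mean


@dataclass
class SyntheticPSPConfig:
    """Kinetics of simulated EPSPs."""

    rise_time: float = 2.0     # foot-to-peak, ms
    decay_tau: float = 15.0    # ms
    latency_mean: float = 2.0  # ms after presynaptic spike
    latency_sd: float = 0.2    # ms

    def __post_init__(self) -> None:
        if min(self.rise_time, self.decay_tau, self.latency_mean,
               self.latency_sd) <= 0:
            raise ValueError("all kinetic parameters must be positive")


@dataclass
class NoiseModel:
    """Background recording noise: Gaussian, stationary, seed-reproducible.

    ``rms`` is the raw-trace standard deviation in mV. Two spectra are
    available. ``white`` is white noise low-passed at ``cutoff_khz``;
    exponential deconvolution (tau = 15 ms) plus a 1 kHz low-pass amplifies
    it ~37x, so very small raw values give realistic deconvolved
    backgrounds. ``pink-mixed`` (the default) mimics recordings better: a
    dominant low-frequency (1/f, < ~100 Hz) component that sets the raw
    RMS, mixed with a small wide-band component (``white_fraction`` of the
    variance) that dominates after deconvolution. The defaults (raw 0.15
    mV, 1% white variance) produce a deconvolved background RMS of about
    0.6 mV, the typical scale of multipatch recordings;
    :func:`raw_rms_for_deconvolved` calibrates the raw value for any other
    target.
    """

    rms: float = 0.15          # mV, raw trace
    cutoff_khz: float = 2.0
    spectrum: str = "pink-mixed"
    white_fraction: float = 0.01   # variance fraction, pink-mixed only
    pink_cutoff_khz: float = 0.1   # LF band edge

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("rms must be non-negative")
        if self.spectrum not in ("white", "pink-mixed"):
            raise ValueError("spectrum must be 'white' or 'pink-mixed'")
        if not (0.0 <= self.white_fraction <= 1.0):
            raise ValueError("white_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that analysis must estimate."""

    connected: bool
    mean_amplitude: float = 0.0             # mV, target first-pulse mean
    stp_params: Optional[STPParams] = None
    per_event_amplitudes: np.ndarray = field(
        default_factory=lambda: np.array([]))
    per_event_latencies: np.ndarray = field(
        default_factory=lambda: np.array([]))
    stp_normalized: np.ndarray = field(
        default_factory=lambda: np.array([]))   # per-pulse mean modulation


# ---------------------------------------------------------------------------
# kernel

def calibrated_tau_r(rise_time: float, decay_tau: float) -> float:
    """Rise constant giving the requested foot-to-peak rise time.

    The kernel peaks at u* = tau_r * ln(1 + 2 tau_d / tau_r) after onset
    (set the derivative of the shape to zero), so tau_r is the root of
    u*(tau_r) = rise_time. The function is monotone in tau_r.
    """
    f = lambda x: x * np.log1p(2.0 * decay_tau / x) - rise_time
    lo = 1e-6
    hi = rise_time * 2.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-12)


def kernel_peak_time(tau_r: float, tau_d: float) -> float:
    """Foot-to-peak interval of the double-exponential kernel, ms."""
    return tau_r * np.log1p(2.0 * tau_d / tau_r)


def _kernel_shape(u: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    y = np.zeros_like(u)
    pos = u > 0
    up = u[pos]
    y[pos] = (1.0 - np.exp(-up / tau_r)) ** 2 * np.exp(-up / tau_d)
    return y


def psp_kernel(amplitude: float, config: SyntheticPSPConfig, onset: float,
               grid: Trace) -> Trace:
    """Peak-normalized EPSP kernel placed at ``onset`` on ``grid``.

    The returned trace is zero before onset and its maximum equals
    ``amplitude`` exactly (the analytic peak value of the shape is used for
    normalization, so this holds to machine precision on any grid that
    samples the peak).
    """
    if amplitude < 0:
        pass  # negative products from the amplitude model are allowed
    if not (grid.t0 <= onset <= grid.t_end):
        raise ValueError("onset lies outside the trace grid")
    tau_r = calibrated_tau_r(config.rise_time, config.decay_tau)
    u = grid.time_values() - onset
    shape = _kernel_shape(u, tau_r, config.decay_tau)
    peak = _kernel_shape(np.array([kernel_peak_time(tau_r, config.decay_tau)]),
                         tau_r, config.decay_tau)[0]
    return grid.like(amplitude * shape / peak)


# ---------------------------------------------------------------------------
# stochastic draws

def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: adding streams never perturbs earlier ones."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def sample_amplitudes(model: SyntheticAmplitudeModel, n_events: int,
                      seed: int) -> np.ndarray:
    """Draw per-event amplitudes (mV), scaled to the model's target mean."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = _rng(seed, 0xA)
    release = rng.binomial(model.binom_n, model.binom_p, size=n_events)
    gain = rng.normal(model.gain_mean, model.gain_sd, size=n_events)
    return release * gain * model.scale


def _band_limited_white(n: int, dt: float, cutoff_khz: float,
                        rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = 0.5 / dt  # kHz
    if cutoff_khz < nyq:
        b, a = signal.butter(4, cutoff_khz / nyq)
        white = signal.filtfilt(b, a, white)
    return white / white.std()


def _pink_lf(n: int, dt: float, cutoff_khz: float,
             rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise band-limited below ``cutoff_khz``."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=dt)  # kHz
    shape = np.zeros_like(f)
    band = (f > 0) & (f <= cutoff_khz)
    shape[band] = 1.0 / np.sqrt(f[band])
    pink = np.fft.irfft(spec * shape, n)
    return pink / pink.std()


def make_noise(n_samples: int, dt: float, noise: NoiseModel,
               rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with the requested spectrum and raw RMS."""
    if noise.rms == 0:
        return np.zeros(n_samples)
    if noise.spectrum == "white":
        return noise.rms * _band_limited_white(n_samples, dt,
                                               noise.cutoff_khz, rng)
    lf = _pink_lf(n_samples, dt, noise.pink_cutoff_khz, rng)
    wb = _band_limited_white(n_samples, dt, noise.cutoff_khz, rng)
    wf = noise.white_fraction
    mix = np.sqrt(1.0 - wf) * lf + np.sqrt(wf) * wb
    return noise.rms * mix / mix.std()


def raw_rms_for_deconvolved(target_deconvolved_rms: float,
                            dt: float = 1.0 / DEFAULT_SAMPLE_RATE_KHZ,
                            tau: float = 15.0,
                            noise: Optional[NoiseModel] = None,
                            n_samples: int = 2 ** 16,
                            lowpass_khz: float = 1.0) -> float:
    """Raw-trace RMS whose deconvolved (and 1 kHz low-passed) RMS matches.

    Deconvolution D = V + tau dV/dt amplifies high frequencies, so the raw
    RMS producing a given deconvolved background RMS depends on the noise
    spectrum and the sampling grid; this calibrates it empirically on a
    long reference realization.
    """
    from .deconv import deconvolve, lowpass
    ref = noise or NoiseModel(rms=1.0)
    base = NoiseModel(rms=1.0, cutoff_khz=ref.cutoff_khz,
                      spectrum=ref.spectrum,
                      white_fraction=ref.white_fraction,
                      pink_cutoff_khz=ref.pink_cutoff_khz)
    samples = make_noise(n_samples, dt, base, _rng(12345, 0xC))
    d = deconvolve(Trace(samples, dt), tau)
    d = lowpass(d, lowpass_khz * 1000.0)
    return target_deconvolved_rms / d.data.std()


# ---------------------------------------------------------------------------
# sweep synthesis

def _sweep_grid(protocol: StimulusProtocol, dt: float, pre_ms: float,
                post_ms: float) -> Trace:
    span = protocol.spike_times[-1] + post_ms
    n = int(round((span + pre_ms) / dt)) + 1
    return Trace(np.zeros(n), dt, t0=-pre_ms)


def synthesize_pair(protocol: StimulusProtocol,
                    psp_config: SyntheticPSPConfig,
                    amplitude_model: SyntheticAmplitudeModel,
                    stp_params: Optional[STPParams] = None,
                    noise: Optional[NoiseModel] = None,
                    seed: int = 0,
                    connected: bool = True,
                    dt: float = 1.0 / DEFAULT_SAMPLE_RATE_KHZ,
                    pre_ms: float = 100.0,
                    post_ms: float = 200.0,
                    holding: float = -70.0,
                    bias_current: float = 0.0,
                    pair_key: int = 0,
                    ) -> Tuple[List[SweepRecording], GroundTruth]:
    """Generate all sweeps of one probed pair plus its ground truth.

    The postsynaptic trace is noise plus a superposition of stochastic EPSP
    kernels, one per presynaptic pulse. When ``stp_params`` is given, the
    mean of the amplitude draw for pulse k is scaled by the simulated
    normalized response w_k / w_1 (trials start from rest: the 15 s
    inter-trial interval is long relative to recovery). Traces are returned
    baseline-subtracted at 0 mV; ``holding`` is metadata.
    """
    noise = noise or NoiseModel()
    spike_times = protocol.spike_times
    if spike_times[0] < -pre_ms:
        raise ValueError("protocol does not fit the trace grid")
    grid = _sweep_grid(protocol, dt, pre_ms, post_ms)

    if stp_params is not None:
        _, stp_norm = stp_simulate(stp_params, spike_times)
    else:
        stp_norm = np.ones(protocol.n_pulses)

    n_pulses = protocol.n_pulses
    sweeps: List[SweepRecording] = []
    all_amps: List[np.ndarray] = []
    all_lats: List[np.ndarray] = []
    for trial in range(protocol.n_trials):
        rng = _rng(seed, pair_key, trial)
        data = make_noise(grid.n_samples, dt, noise, rng)
        amps = np.zeros(n_pulses)
        lats = np.zeros(n_pulses)
        if connected:
            release = rng.binomial(amplitude_model.binom_n,
                                   amplitude_model.binom_p, size=n_pulses)
            gain = rng.normal(amplitude_model.gain_mean,
                              amplitude_model.gain_sd, size=n_pulses)
            amps = release * gain * amplitude_model.scale * stp_norm
            lats = rng.normal(psp_config.latency_mean, psp_config.latency_sd,
                              size=n_pulses)
            for k in range(n_pulses):
                data += psp_kernel(amps[k], psp_config,
                                   spike_times[k] + lats[k], grid).data
        sweeps.append(SweepRecording(
            trace=grid.like(data), spike_times=spike_times,
            holding_potential=holding, bias_current=bias_current,
            protocol=protocol,
            wall_time=trial * protocol.inter_trial_interval))
        all_amps.append(amps)
        all_lats.append(lats)

    truth = GroundTruth(
        connected=connected,
        mean_amplitude=amplitude_model.target_mean_amplitude
        if connected else 0.0,
        stp_params=stp_params,
        per_event_amplitudes=np.concatenate(all_amps)
        if connected else np.array([]),
        per_event_latencies=np.concatenate(all_lats)
        if connected else np.array([]),
        stp_normalized=stp_norm if connected else np.array([]),
    )
    return sweeps, truth


def synthesize_background_pool(n_pairs: int,
                               protocol: Optional[StimulusProtocol] = None,
                               rms_mean: float = 0.15,
                               rms_sd: float = 0.10,
                               seed: int = 0,
                               dt: float = 1.0 / DEFAULT_SAMPLE_RATE_KHZ,
                               **kwargs) -> List[List[SweepRecording]]:
    """Unconnected sweep sets with heterogeneous noise levels.

    Emulates recordings of background activity taken while no cell was
    stimulated; spike times mark where simulated EPSPs may later be
    injected. Per-pair raw RMS values are drawn from a log-normal with the
    given mean and SD; the defaults correspond to a deconvolved background
    RMS of roughly 0.6 +/- 0.4 mV across pairs.
    """
    protocol = protocol or make_protocol(50.0)
    pool: List[List[SweepRecording]] = []
    psp = SyntheticPSPConfig()
    amp = SyntheticAmplitudeModel()
    meta_rng = _rng(seed, 0xB)
    for i in range(n_pairs):
        if rms_sd > 0:
            sigma2 = np.log1p((rms_sd / rms_mean) ** 2)
            mu = np.log(rms_mean) - sigma2 / 2.0
            rms = float(meta_rng.lognormal(mu, np.sqrt(sigma2)))
        else:
            rms = rms_mean
        sweeps, _ = synthesize_pair(
            protocol, psp, amp, stp_params=None,
            noise=NoiseModel(rms=rms), seed=seed, connected=False,
            dt=dt, pair_key=i + 1, **kwargs)
        pool.append(sweeps)
    return pool
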