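"""Synapse detection: features, classifier, and detection-limit estimation.

A probed pair is summarized by features of its spike-aligned average
response (double-exponential fit parameters and normalized fit error) and
by Kolmogorov-Smirnov comparisons of per-trial deconvolved peak amplitudes
and peak times against matched background windows. A probabilistic binary
classifier on these features separates connected from unconnected pairs.

The detection limit of one recording is estimated by injecting simulated
EPSPs of known mean amplitude into its background sweeps, re-running the
feature + classifier pipeline, and interpolating the amplitude at which the
average classification probability crosses 0.5. Dividing the measured
amplitude histogram by the cohort-average detection probability corrects
the amplitude distribution for synapses that escaped detection.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import pspkit
from .deconv import DEFAULT_TAU, deconvolve, lowpass
from .synthgen import (SyntheticAmplitudeModel, SyntheticPSPConfig, _rng,
                       psp_kernel)
from .trace import SweepRecording, Trace

__all__ = [
    "PairFeatures",
    "DetectionProfile",
    "extract_features",
    "train_classifier",
    "SynapseClassifier",
    "min_detectable_amplitude",
    "corrected_amplitude_distribution",
    "optogenetic_snr",
]

RESPONSE_WINDOW = (1.0, 4.0)     # ms after spike: 3 ms window from +1 ms
BACKGROUND_WINDOW = 10.0         # ms before the stimulus pulse
P_FLOOR = 1e-300                 # KS p-values clipped before log transform
DEFAULT_GRID = np.geomspace(0.01, 2.0, 14)  # mV
DETECTION_FLOOR = 0.1


@dataclass
class PairFeatures:
    amplitude: float         # mV, peak of the fitted average
    latency: float           # ms
    rise_time: float         # ms
    tau_d: float             # ms
    fit_nrmse: float         # baseline-normalized fit residual
    ks_p_amplitude: float    # per-trial deconvolved peaks vs background
    ks_p_time: float         # peak-time distributions vs background
    background_rms: float    # mV, deconvolved

    NAMES = ("amplitude", "latency", "rise_time", "tau_d", "fit_nrmse",
             "log_ks_p_amplitude", "log_ks_p_time", "background_rms")

    def vector(self) -> np.ndarray:
        v = np.array([
            self.amplitude, self.latency, self.rise_time, self.tau_d,
            self.fit_nrmse,
            np.log10(max(self.ks_p_amplitude, P_FLOOR)),
            np.log10(max(self.ks_p_time, P_FLOOR)),
            self.background_rms,
        ])
        # failed fits produce inf/nan components; keep them finite so any
        # estimator backend accepts the vector
        return np.nan_to_num(v, nan=0.0, posinf=1e6, neginf=-1e6)


@dataclass
class DetectionProfile:
    amplitude_grid: np.ndarray
    detection_prob: np.ndarray
    min_detectable_amplitude: float
    censored: bool = False

    def prob_at(self, amplitude: np.ndarray) -> np.ndarray:
        """Detection probability interpolated on log-amplitude."""
        a = np.clip(np.asarray(amplitude, dtype=float),
                    self.amplitude_grid[0], self.amplitude_grid[-1])
        return np.interp(np.log(a), np.log(self.amplitude_grid),
                         self.detection_prob)


def _per_trial_peaks(sweeps: Sequence[SweepRecording], tau: float,
                     ) -> Tuple[np.ndarray, np.ndarray,
                                np.ndarray, np.ndarray, float]:
    """Deconvolved peak amplitude/time per (sweep, spike), response window
    vs matched pre-stimulus background window."""
    fg_amp, fg_t, bg_amp, bg_t = [], [], [], []
    rms = []
    for s in sweeps:
        d = lowpass(deconvolve(s.trace, tau), 1000.0)
        for spike in s.spike_times:
            r = d.time_slice(spike + RESPONSE_WINDOW[0],
                             spike + RESPONSE_WINDOW[1])
            b = d.time_slice(spike - BACKGROUND_WINDOW, spike)
            # scan the background in response-window-sized chunks so the
            # two peak statistics are comparable
            win = RESPONSE_WINDOW[1] - RESPONSE_WINDOW[0]
            n_chunk = max(int(BACKGROUND_WINDOW / win), 1)
            chunk_len = len(b.data) // n_chunk
            i = np.argmax(r.data)
            fg_amp.append(r.data[i])
            fg_t.append(i * d.dt)
            for c in range(n_chunk):
                seg = b.data[c * chunk_len:(c + 1) * chunk_len]
                j = np.argmax(seg)
                bg_amp.append(seg[j])
                bg_t.append(j * d.dt)
        pre = d.time_slice(s.spike_times[0] - BACKGROUND_WINDOW,
                           s.spike_times[0])
        rms.append(pre.data.std())
    return (np.array(fg_amp), np.array(fg_t), np.array(bg_amp),
            np.array(bg_t), float(np.mean(rms)))


def extract_features(sweeps: Sequence[SweepRecording],
                     tau: float = DEFAULT_TAU) -> PairFeatures:
    """Deterministic feature vector for one probed pair.

    Requires at least 5 QC-passed sweeps (the caller applies QC). The
    averaged first-pulse response is curve fit (single-start onset grid is
    enough for features); per-trial deconvolved peaks feed the KS tests.
    """
    if len(sweeps) < 5:
        raise ValueError("need >= 5 QC-passed sweeps")
    avg = pspkit.average_response(sweeps, pulse_index=0,
                                  max_frequency=None)
    try:
        fit = pspkit.fit_psp(avg, spike_time=0.0,
                             t0_starts=(2.0,), tau_d_starts=(15.0,))
        amp, lat, rise = fit.amplitude, fit.latency, fit.rise_time_20_80
        tau_d, nrmse = fit.tau_d, fit.wrmse
    except pspkit.FitError:
        amp = lat = rise = tau_d = 0.0
        nrmse = np.inf

    fg_amp, fg_t, bg_amp, bg_t, rms = _per_trial_peaks(sweeps, tau)
    ks_amp = stats.ks_2samp(fg_amp, bg_amp, method="asymp").pvalue
    ks_t = stats.ks_2samp(fg_t, bg_t, method="asymp").pvalue
    return PairFeatures(amplitude=amp, latency=lat, rise_time=rise,
                        tau_d=tau_d, fit_nrmse=nrmse,
                        ks_p_amplitude=ks_amp, ks_p_time=ks_t,
                        background_rms=rms)


class SynapseClassifier:
    """Margin-based probabilistic classifier over :class:`PairFeatures`.

    The default backend is a standardized logistic regression: a linear
    margin with inherently calibrated probabilities, deterministic given
    the training data, and monotone along each evidence direction. The
    backend is pluggable: any estimator with ``fit``/``predict_proba``
    works (e.g. a calibrated support-vector machine).
    """

    def __init__(self, estimator=None, seed: int = 0):
        self.seed = seed
        self.estimator = estimator or Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(C=1.0, max_iter=1000)),
        ])

    def fit(self, features: Sequence[PairFeatures],
            labels: Sequence[bool]) -> "SynapseClassifier":
        X = np.vstack([f.vector() for f in features])
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.estimator.fit(X, y)
        return self

    def predict_proba(self, features) -> np.ndarray:
        if isinstance(features, PairFeatures):
            features = [features]
        X = np.vstack([f.vector() for f in features])
        return self.estimator.predict_proba(X)[:, 1]

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "seed": self.seed,
                         "estimator": self.estimator}, fh)

    @classmethod
    def load(cls, path: str) -> "SynapseClassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        clf = cls(estimator=blob["estimator"], seed=blob["seed"])
        return clf


def train_classifier(labeled: Sequence[Tuple[PairFeatures, bool]],
                     seed: int = 0) -> SynapseClassifier:
    """Train the default classifier on (features, connected) pairs."""
    features, labels = zip(*labeled)
    return SynapseClassifier(seed=seed).fit(features, labels)


def _inject_psps(sweeps: Sequence[SweepRecording],
                 mean_amplitude: float,
                 psp_config: SyntheticPSPConfig,
                 amplitude_model: SyntheticAmplitudeModel,
                 rng: np.random.Generator) -> List[SweepRecording]:
    """Add one simulated EPSP per presynaptic spike to background sweeps."""
    model = SyntheticAmplitudeModel(
        binom_n=amplitude_model.binom_n, binom_p=amplitude_model.binom_p,
        gain_mean=amplitude_model.gain_mean, gain_sd=amplitude_model.gain_sd,
        target_mean_amplitude=mean_amplitude)
    out = []
    for s in sweeps:
        data = s.trace.data.copy()
        n = len(s.spike_times)
        amps = (rng.binomial(model.binom_n, model.binom_p, n)
                * rng.normal(model.gain_mean, model.gain_sd, n)
                * model.scale)
        lats = rng.normal(psp_config.latency_mean, psp_config.latency_sd, n)
        for spike, a, lat in zip(s.spike_times, amps, lats):
            data += psp_kernel(a, psp_config, spike + lat, s.trace).data
        out.append(SweepRecording(
            trace=s.trace.like(data), spike_times=s.spike_times,
            holding_potential=s.holding_potential,
            bias_current=s.bias_current, protocol=s.protocol,
            wall_time=s.wall_time))
    return out


def min_detectable_amplitude(background: Sequence[SweepRecording],
                             classifier: SynapseClassifier,
                             psp_config: Optional[SyntheticPSPConfig] = None,
                             amplitude_model: Optional[
                                 SyntheticAmplitudeModel] = None,
                             amplitude_grid: Optional[np.ndarray] = None,
                             n_repeats: int = 8,
                             seed: int = 0) -> DetectionProfile:
    """Detection probability vs injected mean EPSP amplitude for one pair.

    For each grid amplitude, simulated EPSPs (one per presynaptic spike,
    with the stochastic amplitude model and Normal(2 ms, 0.2 ms) latencies)
    are injected into the pair's background sweeps; the classification
    probability is averaged over ``n_repeats`` independent injections. Both
    the PSP draws and (implicitly, through fresh draws per repeat) the
    injected event placement vary between repeats. The minimum detectable
    amplitude is the 0.5 crossing, linearly interpolated on log amplitude;
    a profile that never reaches 0.5 is censored at the grid maximum.
    """
    psp_config = psp_config or SyntheticPSPConfig()
    amplitude_model = amplitude_model or SyntheticAmplitudeModel()
    grid = np.asarray(amplitude_grid if amplitude_grid is not None
                      else DEFAULT_GRID, dtype=float)
    probs = np.empty(grid.size)
    for gi, amp in enumerate(grid):
        p = 0.0
        for rep in range(n_repeats):
            # common random numbers across the amplitude grid: each repeat
            # reuses its stochastic draws, so profiles vary monotonically
            rng = _rng(seed, rep)
            injected = _inject_psps(background, amp, psp_config,
                                    amplitude_model, rng)
            p += float(classifier.predict_proba(
                extract_features(injected))[0])
        probs[gi] = p / n_repeats

    crossing = np.where((probs[:-1] < 0.5) & (probs[1:] >= 0.5))[0]
    if probs[0] >= 0.5:
        mda, censored = float(grid[0]), False
    elif crossing.size:
        i = crossing[-1]
        la = np.log(grid)
        f = (0.5 - probs[i]) / (probs[i + 1] - probs[i])
        mda, censored = float(np.exp(la[i] + f * (la[i + 1] - la[i]))), False
    else:
        mda, censored = float(grid[-1]), True
    return DetectionProfile(amplitude_grid=grid, detection_prob=probs,
                            min_detectable_amplitude=mda, censored=censored)


def corrected_amplitude_distribution(
        measured_amps: Sequence[float],
        profiles: Sequence[DetectionProfile],
        bin_width: float = 0.05,
        smoothing_sigma_bins: float = 1.0,
        detection_floor: float = DETECTION_FLOOR) -> Dict[str, np.ndarray]:
    """Detection-corrected amplitude histogram and connectivity inflation.

    The measured histogram (Gaussian-smoothed, sigma = 1 bin) is divided by
    the cohort-average detection probability at each bin center; bins where
    that probability falls below ``detection_floor`` are masked, since the
    correction diverges as detection probability approaches zero.
    ``inflation`` is corrected total / measured total - 1: the fraction of
    connections estimated to have escaped detection.
    """
    amps = np.asarray(measured_amps, dtype=float)
    if amps.size == 0 or not profiles:
        raise ValueError("need measured amplitudes and detection profiles")
    n_bins = int(np.ceil(amps.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist, _ = np.histogram(amps, bins=edges)
    smoothed = gaussian_filter1d(hist.astype(float), smoothing_sigma_bins,
                                 mode="constant")
    p_detect = np.mean([p.prob_at(centers) for p in profiles], axis=0)
    masked = p_detect < detection_floor
    corrected = np.where(masked, np.nan, smoothed / np.maximum(p_detect,
                                                               1e-12))
    measured_total = smoothed[~masked].sum()
    corrected_total = np.nansum(corrected)
    inflation = corrected_total / measured_total - 1.0 \
        if measured_total > 0 else np.nan
    return {"bin_edges": edges, "bin_centers": centers,
            "measured": hist.astype(float), "smoothed": smoothed,
            "detection_prob": p_detect, "corrected": corrected,
            "masked": masked, "inflation": float(inflation)}


# ---------------------------------------------------------------------------
# optogenetic mapping SNR

def _best_10ms_window(region_traces: List[Trace], thresholds: np.ndarray,
                      sub_ms: float = 10.0) -> Tuple[float, float]:
    """Start offset (ms, relative to region start) of the 10 ms sub-window
    containing threshold-crossing events in the most unique trials."""
    dt = region_traces[0].dt
    n = region_traces[0].n_samples
    sub = int(round(sub_ms / dt))
    step = max(1, int(round(0.5 / dt)))  # 0.5 ms scan resolution
    starts = range(0, max(n - sub, 1), step)
    best_start, best_count = 0, -1
    # per-trial boolean arrays of threshold crossings
    crossings = [tr.data > thr for tr, thr in zip(region_traces, thresholds)]
    # cumulative sums let each window be counted in O(trials)
    cums = [np.concatenate([[0], np.cumsum(c)]) for c in crossings]
    for s in starts:
        count = sum(1 for c in cums if c[min(s + sub, n)] - c[s] > 0)
        if count > best_count:
            best_count, best_start = count, s
    return best_start * dt, sub_ms


def optogenetic_snr(trials: Sequence[Trace], stim_onset: float,
                    tau: float = 15.0, lowpass_hz: float = 1000.0,
                    highpass_hz: float = 30.0,
                    threshold_sd: float = 3.0,
                    ratio_threshold: float = 1.5) -> Dict[str, float]:
    """Signal-to-noise scorer for photostimulation mapping trials.

    Pipeline per trial: 1 kHz low-pass, baseline subtraction, exponential
    deconvolution (tau in [10, 40] ms), 30 Hz high-pass. Peaks more than
    3 SD above the pre-stimulus baseline mark events. The signal region is
    a 100 ms window 5-105 ms after stimulus onset; the noise region a
    100 ms window 145-45 ms before onset. Within each region, the 10 ms
    sub-window containing events in the most unique trials is selected, the
    per-trial peak medians are taken, and the mean of the 25 ms window
    preceding each region is subtracted. ``call`` is true when
    signal/noise exceeds 1.5.
    """
    if not (10.0 <= tau <= 40.0):
        raise ValueError("tau should be in [10, 40] ms")
    first = trials[0]
    if first.t0 > stim_onset - 170.0 or first.t_end < stim_onset + 105.0:
        # noise region starts at stim-145 and needs its own 25 ms baseline
        raise ValueError("traces must span [stim-170, stim+105] ms")

    processed: List[Trace] = []
    thresholds = []
    from scipy import signal as sig
    nyq = 0.5 * first.sample_rate_khz * 1000.0
    bh, ah = sig.butter(2, highpass_hz / nyq, btype="high")
    for tr in trials:
        lp = lowpass(tr, lowpass_hz)
        base = lp.time_slice(stim_onset - 145.0, stim_onset).data.mean()
        d = deconvolve(lp.like(lp.data - base), tau)
        hp = d.like(sig.filtfilt(bh, ah, d.data))
        pre = hp.time_slice(stim_onset - 145.0, stim_onset - 45.0)
        thresholds.append(pre.data.mean() + threshold_sd
                          * pre.data.std(ddof=0))
        processed.append(hp)

    def region_value(t_start: float) -> float:
        regions = [p.time_slice(t_start, t_start + 100.0) for p in processed]
        offset, _ = _best_10ms_window(regions, np.asarray(thresholds))
        peaks = [r.time_slice(t_start + offset,
                              t_start + offset + 10.0).data.max()
                 for r in regions]
        pre = [p.time_slice(t_start - 25.0, t_start).data.mean()
               for p in processed]
        return float(np.median(peaks) - np.mean(pre))

    sig_val = region_value(stim_onset + 5.0)
    noise_val = region_value(stim_onset - 145.0)
    if noise_val <= 0:
        ratio = np.inf if sig_val > 0 else 0.0
    else:
        ratio = sig_val / noise_val
    return {"signal": sig_val, "noise": noise_val, "ratio": float(ratio),
            "call": bool(ratio > ratio_threshold)}
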