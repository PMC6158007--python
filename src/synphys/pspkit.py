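"""Sweep quality control, spike-aligned averaging, and PSP curve fitting.

The averaged postsynaptic response is fit with the double-exponential shape

    y(t) = A * (1 - e^{-(t-t0)/tau_r})^2 * e^{-(t-t0)/tau_d},  t >= t0

by weighted nonlinear least squares. The rising phase is weighted most
heavily, baseline and decay intermediately, and the stimulus/crosstalk
window is masked. Reported kinetics: amplitude is the peak of the fitted
curve; latency is the fitted onset t0 relative to the presynaptic maximum
dV/dt; rise time is measured from 20% to 80% of the fitted peak.

The weighted RMS error (WRMSE) is normalized by the pre-stimulus baseline
RMS so that the "< 8" goodness cut used to gate kinetics is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import linregress

from .synthgen import _kernel_shape, kernel_peak_time
from .trace import SweepRecording, Trace

__all__ = [
    "QCResult",
    "PSPFit",
    "FitError",
    "qc_sweep",
    "qc_connection",
    "average_response",
    "fit_psp",
    "kinetics_filter",
    "compute_cv",
    "estimate_rundown",
]

# QC thresholds
MAX_BIAS_PA = 800.0
MAX_DRIFT_MV = 5.0
BASELINE_OUTLIER_SD = 3.0
SPIKE_THRESHOLD_MV = -20.0   # absolute membrane potential
ARTIFACT_LIMIT_MV = 0.030    # 30 uV, on the spike-aligned average
MIN_SWEEPS = 5
WRMSE_KINETICS_CUT = 8.0
STP_HOLDING_MV = -55.0


class FitError(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[list] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class QCResult:
    passed: bool
    reasons: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        assert self.passed == (not self.reasons)

    @classmethod
    def from_reasons(cls, reasons) -> "QCResult":
        reasons = frozenset(reasons)
        return cls(passed=not reasons, reasons=reasons)


@dataclass
class PSPFit:
    """Fitted double-exponential parameters and derived kinetics."""

    A: float                 # shape scale, mV
    t0: float                # onset (foot), ms in trace time
    tau_r: float             # ms
    tau_d: float             # ms
    wrmse: float             # baseline-normalized weighted RMS error
    amplitude: float         # peak of the fitted curve, mV
    rise_time_20_80: float   # ms
    latency: float           # t0 - presynaptic spike time, ms
    success: bool = True
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# quality control

def _baseline(sweep: SweepRecording, pre_ms: float = 10.0) -> np.ndarray:
    stim = float(sweep.spike_times[0])
    if stim - sweep.trace.t0 < pre_ms:
        raise ValueError(f"need >= {pre_ms} ms of pre-stimulus baseline")
    seg = sweep.trace.time_slice(stim - pre_ms, stim)
    return seg.data


def qc_sweep(sweep: SweepRecording, target_holding: float = -70.0,
             baseline_population: Optional[Tuple[float, float]] = None,
             ) -> QCResult:
    """Per-sweep inclusion checks; all failures are reported together.

    Checks, in order of the tags reported: |bias current| < 800 pA;
    baseline within +/-5 mV of the target holding potential; the 10 ms
    pre-stimulus baseline mean within 3 SD of the across-sweep baseline
    mean (only when ``baseline_population = (mean, sd)`` is supplied, since
    a single sweep cannot know the population); no spontaneous postsynaptic
    spike (threshold crossing of -20 mV, evaluated on the trace offset to
    the holding potential if traces are baseline-subtracted).
    """
    reasons = set()
    base = _baseline(sweep)
    if abs(sweep.bias_current) >= MAX_BIAS_PA:
        reasons.add("bias_current")
    # traces may be stored baseline-subtracted (around 0) or absolute
    offset = sweep.holding_potential if abs(base.mean()) < 30.0 else 0.0
    if abs(base.mean() + offset - target_holding) > MAX_DRIFT_MV:
        reasons.add("baseline_drift")
    if baseline_population is not None:
        mu, sd = baseline_population
        if sd > 0 and abs(base.mean() - mu) > BASELINE_OUTLIER_SD * sd:
            reasons.add("baseline_outlier")
    if (sweep.trace.data + offset).max() > SPIKE_THRESHOLD_MV:
        reasons.add("spontaneous_spike")
    return QCResult.from_reasons(reasons)


def _artifact_amplitude(sweeps: Sequence[SweepRecording],
                        half_width: float = 0.5) -> float:
    """Mean deviation inside the stimulus window on the pooled spike-aligned
    average, relative to the preceding 1 ms, in mV."""
    devs = []
    segs_art, segs_pre = [], []
    for s in sweeps:
        for spike in s.spike_times:
            art = s.trace.time_slice(spike - half_width, spike + half_width)
            pre = s.trace.time_slice(spike - half_width - 1.0,
                                     spike - half_width)
            segs_art.append(art.data.mean())
            segs_pre.append(pre.data.mean())
    return abs(float(np.mean(segs_art)) - float(np.mean(segs_pre)))


def qc_connection(sweeps: Sequence[SweepRecording],
                  target_holding: float = -70.0,
                  include_stp_holding: bool = False,
                  check_artifact: bool = True,
                  ) -> Tuple[List[SweepRecording], QCResult]:
    """Connection-level QC: per-sweep filtering plus pooled checks.

    Sweeps failing per-sweep QC are dropped; the connection fails with
    ``min_sweeps`` when fewer than 5 survive. With ``include_stp_holding``
    sweeps held at -55 +/- 5 mV are re-admitted (used for the short-term
    plasticity analysis). Pooled checks on the surviving sweeps: stimulus
    artifact < 30 uV on the spike-aligned average, and positive polarity of
    the averaged response.
    """
    base_means = np.array([_baseline(s).mean() for s in sweeps])
    pop = (float(base_means.mean()), float(base_means.std(ddof=1)))\
        if len(sweeps) > 1 else None

    included = []
    for s in sweeps:
        r = qc_sweep(s, target_holding, baseline_population=pop)
        if r.passed:
            included.append(s)
        elif (include_stp_holding
              and r.reasons == frozenset({"baseline_drift"})):
            alt = qc_sweep(s, STP_HOLDING_MV, baseline_population=pop)
            if alt.passed:
                included.append(s)

    reasons = set()
    if len(included) < MIN_SWEEPS:
        reasons.add("min_sweeps")
    if included and check_artifact:
        if _artifact_amplitude(included) >= ARTIFACT_LIMIT_MV:
            reasons.add("artifact")
    return included, QCResult.from_reasons(reasons)


# ---------------------------------------------------------------------------
# averaging

def average_response(sweeps: Sequence[SweepRecording],
                     pulse_index: int = 0,
                     window: Tuple[float, float] = (-10.0, 50.0),
                     max_frequency: Optional[float] = 50.0) -> Trace:
    """Spike-time-aligned mean of one pulse's response across sweeps.

    Returns a trace on a grid where t = 0 is the presynaptic spike. For
    first-pulse strength/kinetics analysis only trains at <= 50 Hz are
    pooled (``max_frequency``); pass ``None`` to pool everything.
    """
    selected = [s for s in sweeps
                if max_frequency is None or s.frequency is None
                or s.frequency <= max_frequency]
    if not selected:
        raise ValueError("no sweeps to average")
    segs = []
    for s in selected:
        spike = float(s.spike_times[pulse_index])
        seg = s.trace.time_slice(spike + window[0], spike + window[1])
        segs.append(seg.data)
    n = min(len(d) for d in segs)
    data = np.mean([d[:n] for d in segs], axis=0)
    return Trace(data, selected[0].trace.dt, t0=window[0])


# ---------------------------------------------------------------------------
# curve fitting

def _eval_model(t: np.ndarray, A: float, t0: float, tau_r: float,
                tau_d: float) -> np.ndarray:
    return A * _kernel_shape(t - t0, tau_r, tau_d)


def _peak_of_fit(A: float, tau_r: float, tau_d: float) -> float:
    up = kernel_peak_time(tau_r, tau_d)
    return A * _kernel_shape(np.array([up]), tau_r, tau_d)[0]


def _rise_time_20_80(A: float, t0: float, tau_r: float,
                     tau_d: float) -> float:
    up = kernel_peak_time(tau_r, tau_d)
    peak = _peak_of_fit(A, tau_r, tau_d)
    if peak == 0:
        return float("nan")

    def frac(level):
        f = lambda u: _eval_model(np.array([t0 + u]), A, t0, tau_r,
                                  tau_d)[0] - level * peak
        return brentq(f, 1e-9, up)

    return frac(0.8) - frac(0.2)


def _region_weights(t: np.ndarray, spike_time: float, t0_guess: float,
                    rise_weight: float = 30.0, base_weight: float = 3.0,
                    mask_half_width: float = 0.5) -> np.ndarray:
    w = np.full(t.shape, base_weight)
    rise = (t >= t0_guess - 0.5) & (t <= t0_guess + 4.0)
    w[rise] = rise_weight
    mask = np.abs(t - spike_time) <= mask_half_width
    w[mask] = 0.0
    return w


def fit_psp(avg: Trace, spike_time: float = 0.0,
            t0_starts: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
            tau_d_starts: Sequence[float] = (5.0, 15.0, 50.0),
            rise_weight: float = 30.0, base_weight: float = 3.0,
            ) -> PSPFit:
    """Weighted multi-start least-squares fit of the averaged response.

    ``spike_time`` is the presynaptic maximum-dV/dt time on the trace's
    grid. Starts span onsets 1-4 ms post-spike and decay constants
    5/15/50 ms; the solution with the lowest weighted error wins. Bounds:
    t0 in [spike, spike+10] ms, tau_r in [0.05, 20] ms, tau_d in
    [1, 300] ms, A >= 0.
    """
    if spike_time - avg.t0 < 10.0 or avg.t_end - spike_time < 50.0:
        raise ValueError("average must span >=10 ms before and >=50 ms "
                         "after the spike")
    t = avg.time_values()
    y = avg.data - avg.time_slice(spike_time - 10.0, spike_time).data.mean()
    base_rms = float(
        avg.time_slice(spike_time - 10.0, spike_time).data.std(ddof=0))

    amp0 = max(float(np.max(y[t > spike_time])), 1e-3)
    best = None
    best_cost = np.inf
    diagnostics = []
    for t0s in t0_starts:
        for tds in tau_d_starts:
            w = np.sqrt(_region_weights(t, spike_time, spike_time + t0s,
                                        rise_weight, base_weight))

            def resid(p):
                return w * (_eval_model(t, *p) - y)

            x0 = (amp0, spike_time + t0s, 0.5, tds)
            bounds = ([0.0, spike_time, 0.05, 1.0],
                      [np.inf, spike_time + 10.0, 20.0, 300.0])
            try:
                sol = least_squares(resid, x0, bounds=bounds,
                                    method="trf", xtol=1e-10, ftol=1e-10)
            except Exception as exc:  # pragma: no cover
                diagnostics.append((x0, repr(exc)))
                continue
            if not sol.success:
                diagnostics.append((x0, sol.message))
                continue
            if sol.cost < best_cost:
                best_cost, best = sol.cost, sol
    if best is None:
        raise FitError("PSP fit failed on all starts", diagnostics)

    A, t0, tau_r, tau_d = best.x
    # final WRMSE with weights centred on the fitted onset
    wf = _region_weights(t, spike_time, t0, rise_weight, base_weight)
    r = _eval_model(t, *best.x) - y
    wrmse_mv = float(np.sqrt(np.sum(wf * r ** 2) / np.sum(wf)))
    wrmse = wrmse_mv / base_rms if base_rms > 1e-12 else wrmse_mv

    flags = []
    amplitude = _peak_of_fit(A, tau_r, tau_d)
    if amplitude < 1e-3:  # < 1 uV: nothing to fit
        flags.append("degenerate")
    return PSPFit(A=A, t0=t0, tau_r=tau_r, tau_d=tau_d, wrmse=wrmse,
                  amplitude=amplitude,
                  rise_time_20_80=_rise_time_20_80(A, t0, tau_r, tau_d),
                  latency=t0 - spike_time, flags=flags)


def kinetics_filter(fit: PSPFit) -> bool:
    """Gate for reporting kinetics: weighted fit error strictly below 8."""
    return fit.wrmse < WRMSE_KINETICS_CUT


def compute_cv(first_pulse_amplitudes: Sequence[float]) -> float:
    """Coefficient of variation (SD/mean, n-1 denominator) of first-pulse
    response amplitudes; inversely related to release probability."""
    a = np.asarray(first_pulse_amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two amplitudes")
    mean = a.mean()
    if mean == 0:
        raise ZeroDivisionError("mean amplitude is zero; CV undefined")
    return float(a.std(ddof=1) / mean)


def estimate_rundown(first_pulse_fits: Sequence[Tuple[float, float]],
                     holdings: Optional[Sequence[float]] = None,
                     holding_range: Tuple[float, float] = (-75.0, -65.0),
                     ) -> float:
    """EPSP amplitude run-down in percent per minute.

    ``first_pulse_fits`` are (wall_time_s, amplitude_mV) points; when
    ``holdings`` is given, only points with holding potential inside
    ``holding_range`` enter the ordinary least-squares regression of
    amplitude versus time. Positive values mean amplitudes decline.
    """
    pts = np.asarray(first_pulse_fits, dtype=float)
    if holdings is not None:
        holdings = np.asarray(holdings, dtype=float)
        keep = (holdings >= holding_range[0]) & (holdings <= holding_range[1])
        pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("need >= 3 points within the holding window")
    minutes = pts[:, 0] / 60.0
    res = linregress(minutes, pts[:, 1])
    if res.intercept == 0:
        raise ZeroDivisionError("zero intercept; run-down undefined")
    return float(100.0 * (-res.slope) / res.intercept)
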