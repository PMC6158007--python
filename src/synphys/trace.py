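"""Core in-memory containers for uniformly sampled intracellular recordings.

Conventions used throughout the package: voltages in mV, times in ms,
currents in pA. A :class:`Trace` is a uniformly sampled time series with an
explicit start time so that spike-aligned windows can be expressed in
absolute sweep time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["Trace", "SweepRecording"]


@dataclass
class Trace:
    """Uniformly sampled membrane-potential time series.

    Parameters
    ----------
    data:
        Sample values (mV).
    dt:
        Sampling interval in ms (50 kHz acquisition -> ``dt = 0.02``).
    t0:
        Time of the first sample, ms.
    """

    data: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("trace data must be one-dimensional")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def sample_rate_khz(self) -> float:
        return 1.0 / self.dt

    @property
    def t_end(self) -> float:
        """Time of the last sample, ms."""
        return self.t0 + (self.n_samples - 1) * self.dt

    def time_values(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt

    def index_at(self, t: float, clip: bool = False) -> int:
        """Index of the sample nearest to time ``t`` (ms)."""
        i = int(round((t - self.t0) / self.dt))
        if clip:
            return min(max(i, 0), self.n_samples - 1)
        if not (0 <= i < self.n_samples):
            raise ValueError(f"time {t} ms outside trace span "
                             f"[{self.t0}, {self.t_end}] ms")
        return i

    def time_slice(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace covering ``[t_start, t_stop)`` (clipped to the span)."""
        i0 = self.index_at(t_start, clip=True)
        i1 = self.index_at(t_stop, clip=True)
        return Trace(self.data[i0:i1 + 1].copy(), self.dt,
                     self.t0 + i0 * self.dt)

    def copy(self) -> "Trace":
        return replace(self, data=self.data.copy())

    def like(self, data: np.ndarray) -> "Trace":
        """New trace on the same grid with different samples."""
        if len(data) != self.n_samples:
            raise ValueError("data length does not match grid")
        return Trace(np.asarray(data, dtype=float), self.dt, self.t0)


@dataclass
class SweepRecording:
    """One stimulus-train trial: presynaptic spike times plus the
    postsynaptic trace and acquisition metadata.

    ``spike_times`` are the presynaptic maximum-dV/dt times in sweep time
    (ms). ``wall_time`` is seconds since the start of the experiment and is
    used for run-down regression.
    """

    trace: Trace
    spike_times: np.ndarray
    holding_potential: float = -70.0   # mV
    bias_current: float = 0.0          # pA
    protocol: Optional[object] = None  # StimulusProtocol
    wall_time: float = 0.0             # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and (
                self.spike_times.min() < self.trace.t0
                or self.spike_times.max() > self.trace.t_end):
            raise ValueError("spike times fall outside the trace span")
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def frequency(self) -> Optional[float]:
        return getattr(self.protocol, "frequency", None)
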