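"""Connection-probability estimation and comparison.

Connectivity counts (k connections found among n probed pairs) are
summarized as binomial proportions with 95% Jeffreys Bayesian intervals
(quantiles of the Beta(k + 1/2, n - k + 1/2) posterior), profiled against
3D intersomatic distance in 40 um bins, and compared between groups with
Fisher's exact test on (connected, unconnected) tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConnectivityCount",
    "DistanceProfile",
    "connection_probability",
    "jeffreys_interval",
    "distance_profile",
    "compare_connectivity",
    "pairwise_fisher",
    "optogenetic_false_negative",
]

BIN_WIDTH_UM = 40.0


@dataclass
class ConnectivityCount:
    k: int                      # connections found
    n: int                      # pairs probed
    group: str = ""
    distance_filter: Optional[float] = None  # um, inclusive upper bound

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("require 0 <= k <= n")

    @property
    def p_hat(self) -> float:
        if self.n == 0:
            raise ZeroDivisionError("no pairs probed")
        return self.k / self.n


def jeffreys_interval(k: int, n: int,
                      confidence: float = 0.95) -> Tuple[float, float]:
    """Jeffreys Bayesian binomial interval with boundary conventions
    lo = 0 when k = 0 and hi = 1 when k = n."""
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(
        stats.beta.ppf(alpha / 2.0, k + 0.5, n - k + 0.5))
    hi = 1.0 if k == n else float(
        stats.beta.ppf(1.0 - alpha / 2.0, k + 0.5, n - k + 0.5))
    return lo, hi


def connection_probability(c: ConnectivityCount) -> Dict[str, object]:
    """Point estimate and 95% Jeffreys CI; percent rounded to one decimal
    for tabulation."""
    lo, hi = jeffreys_interval(c.k, c.n)
    return {"p_hat": c.p_hat, "ci95": (lo, hi),
            "percent": round(100.0 * c.p_hat, 1)}


@dataclass
class DistanceProfile:
    bin_edges: np.ndarray              # um
    k: np.ndarray
    n: np.ndarray
    p_hat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def distance_profile(pairs: Sequence[Tuple[float, bool]],
                     bin_width: float = BIN_WIDTH_UM) -> DistanceProfile:
    """Connection probability binned by intersomatic distance.

    ``pairs`` are (distance_um, connected) tuples; bins are half-open
    [i*w, (i+1)*w) starting at zero, so the per-bin n values sum to the
    number of input pairs.
    """
    if not len(pairs):
        return DistanceProfile(*(np.array([]) for _ in range(6)))
    dist = np.array([p[0] for p in pairs], dtype=float)
    conn = np.array([p[1] for p in pairs], dtype=bool)
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    n_bins = int(dist.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = (dist // bin_width).astype(int)
    n = np.bincount(idx, minlength=n_bins)
    k = np.bincount(idx, weights=conn.astype(float),
                    minlength=n_bins).astype(int)
    p = np.divide(k, n, out=np.full(n_bins, np.nan), where=n > 0)
    ci = np.array([jeffreys_interval(ki, ni) if ni > 0 else (np.nan, np.nan)
                   for ki, ni in zip(k, n)])
    return DistanceProfile(bin_edges=edges, k=k, n=n, p_hat=p,
                           ci_low=ci[:, 0], ci_high=ci[:, 1])


def compare_connectivity(c1: ConnectivityCount,
                         c2: ConnectivityCount) -> float:
    """Two-sided Fisher exact p on the 2x2 (connected, unconnected) table,
    probability-mass definition (sum over tables at most as probable)."""
    table = [[c1.k, c1.n - c1.k], [c2.k, c2.n - c2.k]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pairwise_fisher(counts: Sequence[ConnectivityCount],
                    bonferroni: bool = False) -> Dict[Tuple[str, str], float]:
    """All pairwise Fisher tests, optionally Bonferroni-adjusted."""
    out = {}
    m = len(counts) * (len(counts) - 1) // 2
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            p = compare_connectivity(counts[i], counts[j])
            if bonferroni:
                p = min(1.0, p * m)
            out[(counts[i].group, counts[j].group)] = p
    return out


def optogenetic_false_negative(photosensitivity: float,
                               prior_p: float) -> float:
    """Expected rate of connections missed because the presynaptic cell
    failed to spike: (1 - photosensitivity) * prior connection probability.
    """
    if not (0.0 <= photosensitivity <= 1.0 and 0.0 <= prior_p <= 1.0):
        raise ValueError("both arguments must lie in [0, 1]")
    return (1.0 - photosensitivity) * prior_p
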