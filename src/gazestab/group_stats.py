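"""Condition-level aggregation and non-parametric comparisons.

Covers circular medians of phases, 95% confidence ellipses of polar response
clouds, median +/- SEM summaries of the compensation error, the three
non-parametric tests (paired signed-rank, rank-sum, Kruskal-Wallis with
Nemenyi post hoc), and the free-flight bout metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .response_metrics import PolarResponse, TrialMetrics

__all__ = [
    "ConditionSummary",
    "EllipseParams",
    "FlightBout",
    "circular_median",
    "confidence_ellipse",
    "summarize_condition",
    "paired_signed_rank",
    "rank_sum",
    "kruskal_nemenyi",
    "flight_metrics",
]


@dataclass(frozen=True)
class EllipseParams:
    """Covariance ellipse of a polar point cloud in Cartesian projection."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # degrees, major axis vs +x, in [0, 180)
    coverage: float = 0.95


@dataclass(frozen=True)
class ConditionSummary:
    n: int
    median_gain: float
    circ_median_phase: float  # NaN when every phase in the group is undefined
    median_epsilon: float
    sem_epsilon: float
    ellipse: EllipseParams | None
    labels: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FlightBout:
    """One free-flight bout: take-off to landing, minus skid/crawl intervals."""

    takeoff: float
    landing: float
    skid_intervals: tuple[tuple[float, float], ...] = ()
    collisions: int = 0

    def __post_init__(self) -> None:
        if self.landing <= self.takeoff:
            raise ValueError("landing must come after takeoff")
        if self.collisions < 0:
            raise ValueError("collisions must be >= 0")
        prev_end = self.takeoff
        for start, end in sorted(self.skid_intervals):
            if start < self.takeoff or end > self.landing or end <= start:
                raise ValueError(f"skid interval ({start}, {end}) outside bout")
            if start < prev_end:
                raise ValueError("skid intervals overlap")
            prev_end = end


def _circ_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal arc distance in degrees."""
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def circular_median(phases: Sequence[float]) -> float:
    """Angle minimizing the summed minimal-arc distance to the samples.

    Candidates are the sample angles themselves; ties break to the smallest
    angle in [0, 360), making the result deterministic.
    """
    a = np.asarray(phases, dtype=float)
    if a.size == 0:
        raise ValueError("circular_median of an empty sample")
    if np.any(np.isnan(a)):
        raise ValueError("NaN phases must be excluded by the caller")
    a = a % 360.0
    candidates = np.unique(a)  # sorted ascending
    costs = _circ_diff(a[None, :], candidates[:, None]).sum(axis=1)
    tol = 1e-9 * max(costs.max(), 1.0)
    return float(candidates[np.flatnonzero(costs <= costs.min() + tol)[0]])


def confidence_ellipse(
    points: Sequence[PolarResponse], coverage: float = 0.95
) -> EllipseParams:
    """Coverage ellipse of polar points projected to (r*cos(theta), r*sin(theta)).

    Sample mean and covariance, scaled by the chi-square(2) quantile at
    ``coverage``.  Requires n >= 3 non-collinear points.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 points for an ellipse, got {len(points)}")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    theta = np.radians([p.theta for p in points])
    r = np.array([p.r for p in points])
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[1], 1e-300) or eigvals[1] <= 0:
        raise ValueError("degenerate (collinear or identical) point cloud")
    scale = stats.chi2.ppf(coverage, df=2)
    semi_minor, semi_major = np.sqrt(eigvals * scale)
    major_vec = eigvecs[:, 1]
    orientation = math.degrees(math.atan2(major_vec[1], major_vec[0])) % 180.0
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        semi_major=float(semi_major),
        semi_minor=float(semi_minor),
        orientation=float(orientation),
        coverage=coverage,
    )


def summarize_condition(
    metrics: Sequence[TrialMetrics],
    labels: dict | None = None,
    se_method: str = "sd",
    n_boot: int = 1000,
    seed: int = 0,
) -> ConditionSummary:
    """Aggregate one condition: medians, phase circular median, epsilon SEM, ellipse.

    Undefined phases (NaN) are excluded from the circular median but their
    trials still contribute to the gain and epsilon summaries.  ``se_method``
    is ``"sd"`` for sd/sqrt(n) (the default pairing with the median) or
    ``"bootstrap"`` for a bootstrap SE of the median.
    """
    if len(metrics) == 0:
        raise ValueError("empty condition")
    gains = np.array([m.gain for m in metrics])
    eps = np.array([m.epsilon for m in metrics])
    phases = np.array([m.phase_xcorr for m in metrics])
    defined = phases[~np.isnan(phases)]

    n = len(metrics)
    if se_method == "sd":
        sem = float(np.std(eps, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.median(rng.choice(eps, size=(n_boot, n), replace=True), axis=1)
        sem = float(np.std(boots, ddof=1)) if n > 1 else 0.0
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    ellipse: EllipseParams | None = None
    if n >= 3:
        points = [
            PolarResponse(m.gain, m.phase_xcorr)
            for m in metrics
            if not math.isnan(m.phase_xcorr)
        ]
        if len(points) >= 3:
            try:
                ellipse = confidence_ellipse(points)
            except ValueError:
                ellipse = None

    return ConditionSummary(
        n=n,
        median_gain=float(np.median(gains)),
        circ_median_phase=circular_median(defined) if defined.size else float("nan"),
        median_epsilon=float(np.median(eps)),
        sem_epsilon=sem,
        ellipse=ellipse,
        labels=dict(labels or {}),
    )


def paired_signed_rank(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    ``method='auto'`` uses the exact null distribution when n <= 25 with no
    zero differences and no tied |differences|, otherwise the tie/zero-handling
    normal approximation.  Returns (statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size == 0:
        raise ValueError("empty samples")
    d = y - x
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: test degenerate")
    if method == "auto":
        nonzero = d[d != 0]
        tie_free = np.unique(np.abs(nonzero)).size == nonzero.size
        method = "exact" if (x.size <= 25 and tie_free and nonzero.size == d.size) else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) for independent groups.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise.  Returns (U statistic of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (tie_free and max(x.size, y.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_nemenyi(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float, np.ndarray]:
    """Kruskal-Wallis H (tie-corrected, chi-square p) plus Nemenyi post hoc.

    The Nemenyi pairwise p values come from the studentized-range distribution
    applied to mean-rank differences:
    ``q_ij = |Rbar_i - Rbar_j| / sqrt(N(N+1)/12 * (1/n_i + 1/n_j) / 2)``,
    ``p_ij = sf_studentized_range(q_ij; k, inf)``.  Returns (H, p, k x k
    symmetric matrix with 1.0 on the diagonal).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    h, p = stats.kruskal(*groups)

    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]

    k = len(groups)
    pmat = np.ones((k, k))
    base_var = n_total * (n_total + 1) / 12.0
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]) / 2.0)
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = float(np.clip(stats.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
            pmat[i, j] = pmat[j, i] = pij
    return float(h), float(p), pmat


def flight_metrics(bout: FlightBout) -> tuple[float, float]:
    """Flight bout duration (s, rounded to nearest second) and collision rate.

    Duration = (landing - takeoff) minus total skid/crawl time, then rounded
    half-up to the nearest whole second; the collision rate divides by the
    rounded duration, reproducing the discretized rates of low-frame-rate
    scoring.
    """
    raw = (bout.landing - bout.takeoff) - sum(e - s for s, e in bout.skid_intervals)
    if raw <= 0:
        raise ValueError(f"non-positive flight duration ({raw:.3g} s) after skid subtraction")
    duration = math.floor(raw + 0.5)
    if duration <= 0:
        raise ValueError(f"flight duration rounds to 0 s (raw {raw:.3g} s)")
    return float(duration), bout.collisions / duration
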