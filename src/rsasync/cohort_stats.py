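"""Cohort-level analysis: age grouping, median/IQR tables, paired
Wilcoxon signed-rank test with the Hodges-Lehmann median difference and its
distribution-free confidence interval, and the data-driven compliance
threshold.

The signed-rank null distribution is computed exactly (dynamic programming
over doubled midranks, so ties are handled) for n <= 25 pairs, and by normal
approximation with tie and continuity corrections beyond that.  The
Hodges-Lehmann estimate is the median of the Walsh averages of the paired
differences; the confidence interval takes order statistics of the sorted
Walsh averages at the exact (or approximate) signed-rank critical counts, as
in the classical distribution-free construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .rsa_metrics import ParticipantSummary
from .synth_ppg import AGE_GROUPS

__all__ = [
    "GroupStats",
    "PairedTestResult",
    "group_by_age",
    "median_iqr",
    "signed_rank_statistic",
    "wilcoxon_hl",
    "derive_threshold",
]


@dataclass(frozen=True)
class GroupStats:
    """Five-number-ish summary: n, median, quartiles, extremes."""

    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min <= self.q1 <= self.median <= self.q3 <= self.max:
            raise ValueError("quantile ordering violated")

    def format_median_iqr(self, nd: int = 2) -> str:
        return f"{self.median:.{nd}f}({self.q1:.{nd}f}-{self.q3:.{nd}f})"


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank test with Hodges-Lehmann location estimate."""

    n_pairs: int
    statistic: float        # W+ (sum of positive-difference ranks)
    p_value: float
    median_diff: float      # Hodges-Lehmann pseudo-median of differences
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median_diff <= self.ci_high:
            raise ValueError("CI must bracket the median difference")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be a probability")


def group_by_age(summaries: list[ParticipantSummary],
                 ages: dict[str, int] | None = None
                 ) -> dict[str, list[ParticipantSummary]]:
    """Partition participant summaries into the four study age groups.

    Ages come from the summaries themselves unless an explicit id->age map
    is given.  Ages outside 5-17 are rejected with the offending id.
    """
    groups: dict[str, list[ParticipantSummary]] = {g: [] for g in AGE_GROUPS}
    for s in summaries:
        age = ages[s.participant_id] if ages is not None else s.age_years
        if age is None:
            raise ValueError(f"participant {s.participant_id!r} has no age")
        placed = False
        for name, (lo, hi) in AGE_GROUPS.items():
            if lo <= age <= hi:
                groups[name].append(s)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"participant {s.participant_id!r}: age {age} out of the "
                "study range 5-17")
    return groups


def median_iqr(values) -> GroupStats:
    """Median and quartiles by linear interpolation (inclusive, 'type 7')."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty list")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return GroupStats(n=int(x.size), median=float(med), q1=float(q1),
                      q3=float(q3), min=float(x.min()), max=float(x.max()))


# ---------------------------------------------------------------------------
# Signed-rank machinery


def _midranks(absd: np.ndarray) -> np.ndarray:
    return sst.rankdata(absd, method="average")


def signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of midranks of positive differences) and the midranks used.

    Zero differences must already be removed.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = _midranks(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_wplus_pmf(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null pmf of W+ over doubled (integer) midranks.

    Returns (counts over doubled statistic values 0..sum(2r), scale=2);
    counts[w2] = number of sign assignments with 2*W+ == w2.
    """
    r2 = np.rint(2 * np.asarray(ranks)).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r] if r > 0 else counts
    return counts, 2


def _exact_p_two_sided(w: float, ranks: np.ndarray) -> float:
    counts, scale = _exact_wplus_pmf(ranks)
    total = counts.sum()
    w2 = int(round(scale * w))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_p_two_sided(w: float, ranks: np.ndarray) -> float:
    n = ranks.size
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float(((counts ** 3 - counts) / 48.0).sum())
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    # continuity correction toward the mean
    z = (w - mu - 0.5 * np.sign(w - mu)) / sigma
    return float(min(1.0, 2.0 * sst.norm.sf(abs(z))))


def _signrank_cdf_exact(n: int) -> np.ndarray:
    """CDF of W+ under H0 for untied ranks 1..n."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r]
    return np.cumsum(counts) / counts.sum()


def _qsignrank(p: float, n: int) -> int:
    """Smallest q with P(W+ <= q) >= p (exact for n <= 25, else normal)."""
    if n <= 25:
        cdf = _signrank_cdf_exact(n)
        return int(np.searchsorted(cdf, p - 1e-12))
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return max(int(math.floor(mu + sigma * sst.norm.ppf(p))), 0)


def walsh_averages(diffs: np.ndarray) -> np.ndarray:
    """All n(n+1)/2 pairwise means (d_i + d_j)/2, i <= j, sorted."""
    d = np.asarray(diffs, dtype=float)
    i, j = np.triu_indices(d.size)
    return np.sort((d[i] + d[j]) / 2.0)


def wilcoxon_hl(deep, spont, confidence: float = 0.95,
                exact_limit: int = 25) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test with Hodges-Lehmann estimate and CI.

    ``deep`` and ``spont`` are equal-length paired samples (one value per
    participant per mode); differences deep - spont are tested against a
    symmetric-about-zero null.  Zero differences are dropped before ranking
    (classical practice).  Exact null for n <= ``exact_limit`` (ties handled
    via doubled midranks), otherwise normal approximation with tie and
    continuity corrections.  The CI is the distribution-free signed-rank
    interval over Walsh averages at >= the requested coverage.
    """
    deep = np.asarray(deep, dtype=float)
    spont = np.asarray(spont, dtype=float)
    if deep.shape != spont.shape:
        raise ValueError("paired samples must have equal length")
    if deep.size == 0:
        raise ValueError("no pairs supplied")
    d_all = deep - spont
    d = d_all[d_all != 0.0]
    n = d.size
    if n == 0:
        # degenerate: the samples are identical pair-for-pair
        return PairedTestResult(n_pairs=int(deep.size), statistic=0.0,
                                p_value=1.0, median_diff=0.0,
                                ci_low=0.0, ci_high=0.0,
                                confidence=confidence)

    w, ranks = signed_rank_statistic(d)
    if n <= exact_limit:
        p = _exact_p_two_sided(w, ranks)
    else:
        p = _normal_p_two_sided(w, ranks)

    walsh = walsh_averages(d)
    hl = float(np.median(walsh))
    alpha = 1.0 - confidence
    qu = _qsignrank(alpha / 2.0, n)
    if qu == 0:
        qu = 1
    m = n * (n + 1) // 2
    ci_low = float(walsh[qu - 1])       # qu-th smallest (1-indexed)
    ci_high = float(walsh[m - qu])      # qu-th largest
    return PairedTestResult(
        n_pairs=int(deep.size), statistic=w, p_value=p,
        median_diff=hl, ci_low=ci_low, ci_high=ci_high,
        confidence=confidence)


def derive_threshold(deep: GroupStats, spont: GroupStats
                     ) -> tuple[float, bool]:
    """Compliance threshold from the non-overlapping area between modes.

    Midpoint of (spontaneous Q3, deep-breathing Q1), rounded to one decimal
    place.  If the IQRs overlap the midpoint is still returned but flagged
    (second element False means clean separation; True means flagged).
    """
    midpoint = 0.5 * (spont.q3 + deep.q1)
    flagged = not deep.q1 > spont.q3
    return round(midpoint, 1), flagged
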