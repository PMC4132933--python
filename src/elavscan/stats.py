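"""Count and ratio statistics for the study design, from first principles.

Two tests carry the quantitative claims: the exact Wilcoxon matched-pairs
signed-rank test for small replicate sets (RT-PCR isoform ratios, n of
order 3–9), and the Pearson chi-squared test on 2×2 tables of
per-hemisegment apoptosis outcomes. Published figures print percentages,
not counts, so a percentage↔count reconciliation with an explicit
consistency check is part of the module, as is reference-gene (RpL32/Rp49)
normalisation of expression replicates.

The Wilcoxon null distribution is exact: it is the distribution of the
positive-rank sum over all 2^m equiprobable sign assignments, computed by
shift-convolution over the (tie-averaged, doubled-to-integer) ranks, which
enumerates exactly that set. Above ``m = EXACT_THRESHOLD`` pairs a normal
approximation with continuity and tie correction takes over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DegenerateDataError, NormalizationError

EXACT_THRESHOLD = 25  # exact enumeration stays well under a second up to here

SIDEDNESS = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class PairedSample:
    """Matched pairs (x_i, y_i); differences x - y carry the test."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ConfigError("paired sample needs at least one pair")
        arr = np.asarray(self.pairs, dtype=float)
        if not np.isfinite(arr).all():
            raise ConfigError("pairs must be finite")

    @classmethod
    def from_arrays(cls, x, y) -> "PairedSample":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ConfigError(f"length mismatch: {x.shape} vs {y.shape}")
        return cls(tuple(zip(x.tolist(), y.tolist())))

    @property
    def n(self) -> int:
        return len(self.pairs)

    def differences(self) -> np.ndarray:
        arr = np.asarray(self.pairs, dtype=float)
        return arr[:, 0] - arr[:, 1]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are conditions, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ConfigError("counts must be nonnegative integers")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DegenerateDataError("each condition row needs at least one count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_percentages(cls, percent_1: float, n_1: int, percent_2: float, n_2: int) -> "ContingencyTable2x2":
        """Reconstruct outcome counts from two printed (percentage, n) pairs."""
        k1 = counts_from_percent(percent_1, n_1)
        k2 = counts_from_percent(percent_2, n_2)
        return cls(k1, n_1 - k1, k2, n_2 - k2)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ConfigError(f"p-value {self.p_value} outside (0, 1]")


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each value of 2·W over all 2^m sign assignments.

    ``ranks2`` are the doubled ranks (integers even with .5 average ranks);
    index w of the returned array counts assignments with 2·W == w.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(sample: PairedSample, sidedness: str = "two_sided") -> TestResult:
    """Exact Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (standard practice); |d| are ranked with
    average ranks for ties; W is the sum of ranks of positive differences.
    The p-value is exact for m ≤ 25 remaining pairs and a continuity- and
    tie-corrected normal approximation above.
    """
    if sidedness not in SIDEDNESS:
        raise ConfigError(f"sidedness must be one of {SIDEDNESS}")
    d = sample.differences()
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise DegenerateDataError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if m <= EXACT_THRESHOLD:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(ranks2)
        total = dist.sum()  # == 2^m
        w2 = int(round(2 * w))
        p_greater = float(dist[w2:].sum() / total)
        p_less = float(dist[: w2 + 1].sum() / total)
        method = "wilcoxon_signed_rank_exact"
    else:
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        sd = np.sqrt(var)
        p_greater = float(sps.norm.sf((w - 0.5 - mu) / sd))
        p_less = float(sps.norm.cdf((w + 0.5 - mu) / sd))
        method = "wilcoxon_signed_rank_normal_approx"
    if sidedness == "greater":
        p = p_greater
    elif sidedness == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(statistic=w, p_value=max(p, np.finfo(float).tiny), method=method, sidedness=sidedness)


def chi_squared_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-squared test with df=1 on a 2×2 table.

    Yates continuity correction is off by default and exposed as a flag.
    Requires all expected counts positive, i.e. no zero margin.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if c1 == 0 or c2 == 0:
        raise DegenerateDataError("zero column margin: an expected count is 0")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2.0, 0.0)
    stat = n * delta**2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(
        statistic=float(stat),
        p_value=max(p, np.finfo(float).tiny),
        method="chi_squared_2x2_yates" if yates else "chi_squared_2x2",
        sidedness="two_sided",
    )


def counts_from_percent(percent: float, n: int) -> int:
    """Nearest-integer count behind a printed percentage of n.

    Verifies the round trip: the recovered count must reproduce the printed
    percentage to within 0.005 points plus the half-count granularity 50/n;
    an irreconcilable pair raises :class:`ConfigError`.
    """
    if not (0 <= percent <= 100):
        raise ConfigError(f"percent {percent} outside [0, 100]")
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    count = int(round(percent * n / 100.0))
    if abs(100.0 * count / n - percent) > 0.005 + 50.0 / n:
        raise ConfigError(
            f"percentage {percent}% inconsistent with any integer count out of {n}"
        )
    return count


def normalize_expression(target_replicates, reference_replicates) -> list[float]:
    """Element-wise target/reference expression ratios (reference-gene normalisation)."""
    t = np.asarray(target_replicates, dtype=float)
    r = np.asarray(reference_replicates, dtype=float)
    if t.shape != r.shape:
        raise ConfigError(f"replicate count mismatch: {t.shape} vs {r.shape}")
    if (r <= 0).any():
        raise NormalizationError("reference replicates must be positive")
    return (t / r).tolist()


def compare_isoform_levels(
    group_a_ratios,
    group_b_ratios,
    paired: bool = True,
    sidedness: str = "two_sided",
) -> TestResult:
    """Compare normalised isoform levels between two matched replicate groups.

    Dispatches to the exact Wilcoxon signed-rank test on paired ratios. All
    differences zero is reported as non-significant (p = 1) with a warning
    rather than an error. Unpaired comparison is out of scope.
    """
    if not paired:
        raise ConfigError("unpaired comparison is not supported; replicates are matched")
    sample = PairedSample.from_arrays(group_a_ratios, group_b_ratios)
    try:
        return wilcoxon_signed_rank_exact(sample, sidedness=sidedness)
    except DegenerateDataError:
        warnings.warn("all paired differences are zero; reporting p = 1 (non-significant)")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank_degenerate", sidedness)
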