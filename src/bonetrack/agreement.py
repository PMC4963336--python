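"""Inter-rater and inter-method agreement statistics.

Cohen's kappa k = (p0 - pe) / (1 - pe), where p0 is the observed agreement
and pe the agreement expected if the two raters decided independently with
their observed marginal category frequencies. Because unweighted kappa
depends only on the diagonal sum and the marginals, it can be recomputed
exactly from published marginal counts plus a discrepancy count — no full
cross-tabulation needed. Verbal strength labels follow Landis & Koch.

Mann-Whitney U and Spearman's rank correlation are provided for group
comparisons and correlations of uptake values; both delegate to scipy.stats
behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CATEGORIES = ("progressive", "stable", "regressive")

#: Landis & Koch strata: (upper bound inclusive, label), checked in order.
LANDIS_KOCH = (
    (0.0, "poor"),  # handled as k < 0 below
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class RatingVector:
    """Ordered per-lesion 3-category ratings from one rater or method."""

    ids: tuple[str, ...]
    categories: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.categories):
            raise ValueError("ids and categories must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("lesion ids must be unique")
        bad = [c for c in self.categories if c not in CATEGORIES]
        if bad:
            raise ValueError(f"unknown categories {sorted(set(bad))}; expected {CATEGORIES}")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "categories", tuple(self.categories))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 cross-tabulation; rows = rater A, columns = rater B.

    Category order is fixed as (progressive, stable, regressive).
    """

    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.shape != (3, 3):
            raise ValueError("contingency table must be 3x3")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if m.sum() < 1:
            raise ValueError("table must contain at least one rating pair")
        object.__setattr__(self, "counts", tuple(tuple(int(v) for v in row) for row in m))

    @property
    def n(self) -> int:
        return int(np.sum(self.counts))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts)

    def marginals(self) -> "MarginalSummary":
        m = self.array
        return MarginalSummary(
            marginals_a=tuple(int(v) for v in m.sum(axis=1)),
            marginals_b=tuple(int(v) for v in m.sum(axis=0)),
            n_agree=int(np.trace(m)),
            n=self.n,
        )


@dataclass(frozen=True)
class MarginalSummary:
    """Marginal category counts for two raters plus their agreement count.

    This is exactly the information published result tables typically carry
    (per-category totals per method and the number of discrepant lesions),
    and it determines unweighted kappa uniquely.
    """

    marginals_a: tuple[int, int, int]
    marginals_b: tuple[int, int, int]
    n_agree: int
    n: int

    def __post_init__(self) -> None:
        if sum(self.marginals_a) != self.n or sum(self.marginals_b) != self.n:
            raise ValueError(
                f"marginal sums ({sum(self.marginals_a)}, {sum(self.marginals_b)}) "
                f"must both equal n = {self.n}"
            )
        if not (0 <= self.n_agree <= self.n):
            raise ValueError("n_agree must lie in [0, n]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its observed/chance agreement components."""

    kappa: float
    p0: float
    pe: float
    n: int
    label: str


def contingency(a: RatingVector, b: RatingVector) -> ContingencyTable:
    """Cross-tabulate two rating vectors after aligning them by lesion id."""
    if set(a.ids) != set(b.ids):
        diff = sorted(set(a.ids) ^ set(b.ids))
        raise ValueError(f"rating vectors cover different lesions: {diff}")
    b_by_id = dict(zip(b.ids, b.categories))
    m = np.zeros((3, 3), dtype=int)
    for lesion_id, cat_a in zip(a.ids, a.categories):
        m[CATEGORIES.index(cat_a), CATEGORIES.index(b_by_id[lesion_id])] += 1
    return ContingencyTable(tuple(tuple(int(v) for v in row) for row in m))


def _kappa(p0: float, pe: float, n: int) -> KappaResult:
    if pe >= 1.0:
        raise ValueError("degenerate marginals; kappa undefined")
    k = (p0 - pe) / (1.0 - pe)
    return KappaResult(kappa=float(k), p0=float(p0), pe=float(pe), n=n, label=interpret_kappa(k))


def kappa_from_table(table: ContingencyTable) -> KappaResult:
    """Cohen's kappa from a full 3x3 cross-tabulation."""
    m = table.array.astype(float)
    n = table.n
    p0 = np.trace(m) / n
    pe = float(np.sum(m.sum(axis=1) * m.sum(axis=0)) / n**2)
    return _kappa(p0, pe, n)


def kappa_from_marginals(m: MarginalSummary) -> KappaResult:
    """Cohen's kappa from marginal counts and an agreement count.

    Equals :func:`kappa_from_table` for any table with these marginals and
    diagonal sum, since unweighted kappa uses nothing else.
    """
    p0 = m.n_agree / m.n
    pe = sum(ma * mb for ma, mb in zip(m.marginals_a, m.marginals_b)) / m.n**2
    return _kappa(p0, pe, m.n)


def kappa_standard_error(table: ContingencyTable) -> float:
    """Large-sample standard error of kappa under the null (Fleiss et al.)."""
    m = table.array.astype(float)
    n = table.n
    pa = m.sum(axis=1) / n
    pb = m.sum(axis=0) / n
    pe = float(np.sum(pa * pb))
    term = pe + pe**2 - float(np.sum(pa * pb * (pa + pb)))
    return float(np.sqrt(term / (n * (1.0 - pe) ** 2)))


def kappa_p_value(table: ContingencyTable) -> float:
    """Two-sided normal-approximation p-value for kappa != 0."""
    k = kappa_from_table(table).kappa
    se = kappa_standard_error(table)
    z = k / se
    return float(2.0 * stats.norm.sf(abs(z)))


def interpret_kappa(k: float) -> str:
    """Landis-Koch verbal strength of agreement for an (unrounded) kappa."""
    if k > 1.0:
        raise ValueError(f"kappa cannot exceed 1, got {k}")
    if k < 0:
        return "poor"
    for upper, label in LANDIS_KOCH[1:]:
        if k <= upper:
            return label
    raise AssertionError("unreachable")


def discrepancy_count(a: RatingVector, b: RatingVector) -> tuple[int, float]:
    """Number and fraction of lesions rated differently by the two sources."""
    if set(a.ids) != set(b.ids):
        diff = sorted(set(a.ids) ^ set(b.ids))
        raise ValueError(f"rating vectors cover different lesions: {diff}")
    b_by_id = dict(zip(b.ids, b.categories))
    n_diff = sum(1 for i, c in zip(a.ids, a.categories) if b_by_id[i] != c)
    return n_diff, n_diff / len(a)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for x) with a two-sided p-value.

    Uses the exact null distribution when both samples are small (min size
    <= 8) and tie-free; otherwise the normal approximation with midrank tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    small = min(x.size, y.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
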