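"""Genotype-by-litter-size association testing.

Three pieces:

* r x c contingency tests with the classical switch rule — Pearson
  chi-square when every expected cell count is at least 5, otherwise the
  Freeman-Halton generalization of Fisher's exact test (full enumeration of
  tables with the observed margins, two-sided by point-probability
  ordering);
* a cumulative-subset robustness scan: one seeded permutation of the
  cohort is consumed in nested increments, re-running the association test
  at each cumulative size, so an association that holds only in a lucky
  subset is exposed;
* genotype-effect estimation under the reduced one-factor linear model
  (group least-squares means = arithmetic means for first-parity data,
  where year and parity covariates drop out), with pooled-variance Student
  t-tests and exclusion of genotype groups below a minimum size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

from .cohort import GENOTYPES, Cohort
from .errors import (
    EmptyTableError,
    EnumerationCapacityError,
    InsufficientGroupsError,
)

#: relative tie tolerance when comparing table point probabilities: tables
#: whose probability is within (1 + TIE_REL) of the observed one count as
#: "as extreme", guarding against floating-point exclusion of exact ties.
TIE_REL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """r x c phenotype-class by genotype-class counts with labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        t = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", t)
        if t.ndim != 2 or (t < 0).any():
            raise ValueError("counts must be a non-negative 2-D table")
        if t.sum() < 1:
            raise EmptyTableError("contingency table has no observations")
        if t.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match table shape")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        r = self.counts.sum(axis=1, keepdims=True)
        c = self.counts.sum(axis=0, keepdims=True)
        return r * c / self.counts.sum()

    def reduced(self) -> "ContingencyTable":
        """Drop all-zero rows and columns (they carry no information)."""
        t = self.counts
        rkeep = t.sum(axis=1) > 0
        ckeep = t.sum(axis=0) > 0
        if rkeep.all() and ckeep.all():
            return self
        return ContingencyTable(
            t[np.ix_(rkeep, ckeep)],
            tuple(l for l, k in zip(self.row_labels, rkeep) if k),
            tuple(l for l, k in zip(self.col_labels, ckeep) if k),
        )


@dataclass(frozen=True)
class AssociationResult:
    test_used: str  # "chi_square" | "fisher_exact"
    p_value: float
    statistic: float | None = None
    df: int | None = None
    min_expected: float | None = None
    degenerate: bool = False


def build_contingency(
    cohort: Cohort, locus: str, classing: str = "binary"
) -> ContingencyTable:
    """Cross-tabulate litter-size class against genotype at ``locus``.

    ``binary`` classing splits mothers of a single lamb from mothers of
    multiple lambs (litter >= 2); ``per-class`` keeps one row per observed
    litter size. Animals missing genotype or phenotype are excluded.
    """
    cohort.locus(locus)
    pairs = [
        (a.litter_size, a.genotypes.get(locus))
        for a in cohort.animals
        if a.litter_size is not None and a.genotypes.get(locus) is not None
    ]
    if not pairs:
        raise EmptyTableError(f"no animals with complete data at {locus!r}")
    if classing == "binary":
        row_labels = ("litter=1", "litter>=2")
        row_of = lambda y: 0 if y == 1 else 1
    elif classing in ("per-class", "per_class"):
        sizes = sorted({y for y, _ in pairs})
        row_labels = tuple(f"litter={y}" for y in sizes)
        index = {y: i for i, y in enumerate(sizes)}
        row_of = index.__getitem__
    else:
        raise ValueError(f"unknown classing {classing!r}")
    t = np.zeros((len(row_labels), 3), dtype=int)
    gidx = {g: j for j, g in enumerate(GENOTYPES)}
    for y, g in pairs:
        t[row_of(y), gidx[g]] += 1
    return ContingencyTable(t, row_labels, GENOTYPES)


def chi_square_rxc(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    red = table.reduced()
    if red.counts.shape != table.counts.shape:
        warnings.warn(
            "dropped all-zero row(s)/column(s) before chi-square test",
            stacklevel=2,
        )
    r, c = red.counts.shape
    if r < 2 or c < 2:
        return AssociationResult(
            "chi_square", 1.0, statistic=0.0, df=0, degenerate=True
        )
    exp = red.expected()
    stat = float(((red.counts - exp) ** 2 / exp).sum())
    df = (r - 1) * (c - 1)
    p = float(chi2_dist.sf(stat, df)) if stat > 0 else 1.0
    return AssociationResult(
        "chi_square", p, statistic=stat, df=df, min_expected=float(exp.min())
    )


def _enumeration_bound(rows: np.ndarray, cols: np.ndarray) -> float:
    """Upper bound on the number of tables visited by the enumerator."""
    bound = 1.0
    for r in rows[:-1]:
        for c in cols[:-1]:
            bound *= min(int(r), int(c)) + 1
    return bound


def freeman_halton_p(counts, max_tables: float = 1e8) -> float:
    """Two-sided Freeman-Halton exact p-value for an r x c count table.

    Enumerates every table with the observed margins, computes each
    table's multivariate hypergeometric point probability via log-factorial
    accumulation (stable at n > 1000), and sums the probabilities of
    tables no more probable than the observed one (relative tie tolerance
    ``TIE_REL``). Degenerate tables (a single non-zero row or column after
    reduction) return p = 1.

    Rows and columns are enumerated smallest-margin first, with the largest
    row and column determined by the margins, which keeps the visited-table
    count near its combinatorial minimum.
    """
    t = np.asarray(counts, dtype=int)
    if t.ndim != 2 or (t < 0).any() or t.sum() < 1:
        raise ValueError("need a non-negative 2-D table with total >= 1")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0

    # sort margins ascending; the largest row/column is the determined one
    t = t[np.argsort(t.sum(axis=1), kind="stable")]
    t = t[:, np.argsort(t.sum(axis=0), kind="stable")]
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if _enumeration_bound(rows, cols) > max_tables:
        raise EnumerationCapacityError(
            "margin configuration exceeds the exact-enumeration budget; "
            "use the chi-square test or a Monte-Carlo approximation"
        )

    n = int(t.sum())
    lf = gammaln(np.arange(n + 2))  # lf[k+1] = log k!
    const = float(lf[rows + 1].sum() + lf[cols + 1].sum() - lf[n + 1])
    logp_obs = const - float(lf[t + 1].sum())
    threshold = logp_obs + math.log1p(TIE_REL)

    n_rows, n_cols = t.shape
    total = 0.0

    def fill_row(i: int, caps: list[int], acc: float) -> None:
        nonlocal total
        if i == n_rows - 1:  # last row determined by remaining capacities
            logp = const - acc - sum(lf[x + 1] for x in caps)
            if logp <= threshold:
                total += math.exp(logp)
            return
        row_total = int(rows[i])
        cell = [0] * n_cols

        def fill_cell(j: int, rem: int, acc2: float) -> None:
            if j == n_cols - 1:  # last column determined by the row total
                if rem <= caps[j]:
                    cell[j] = rem
                    new_caps = [caps[k] - cell[k] for k in range(n_cols)]
                    fill_row(i + 1, new_caps, acc2 + lf[rem + 1])
                return
            tail_cap = sum(caps[j + 1 :])
            lo = max(0, rem - tail_cap)
            hi = min(rem, caps[j])
            for x in range(lo, hi + 1):
                cell[j] = x
                fill_cell(j + 1, rem - x, acc2 + lf[x + 1])

        fill_cell(0, row_total, acc)

    fill_row(0, [int(c) for c in cols], 0.0)
    return min(total, 1.0)


def fisher_exact_rxc(
    table: ContingencyTable, max_tables: float = 1e8
) -> AssociationResult:
    """Freeman-Halton exact test on a contingency table (see
    :func:`freeman_halton_p`)."""
    red = table.reduced()
    if red.counts.shape[0] < 2 or red.counts.shape[1] < 2:
        return AssociationResult("fisher_exact", 1.0, degenerate=True)
    p = freeman_halton_p(red.counts, max_tables=max_tables)
    return AssociationResult(
        "fisher_exact", p, min_expected=float(red.expected().min())
    )


def select_and_test(table: ContingencyTable, rule: str = "auto") -> AssociationResult:
    """Run the contingency test chosen by the expected-count switch rule.

    ``auto`` uses the exact test whenever the smallest expected cell count
    falls below 5 and the chi-square test otherwise; ``chi`` and ``fisher``
    force the respective test.
    """
    if rule == "chi":
        return chi_square_rxc(table)
    if rule == "fisher":
        return fisher_exact_rxc(table)
    if rule != "auto":
        raise ValueError(f"unknown rule {rule!r}")
    red = table.reduced()
    if red.counts.shape[0] < 2 or red.counts.shape[1] < 2:
        return AssociationResult("chi_square", 1.0, statistic=0.0, df=0, degenerate=True)
    min_expected = float(red.expected().min())
    if min_expected < 5.0:
        result = fisher_exact_rxc(table)
    else:
        result = chi_square_rxc(table)
    return AssociationResult(
        result.test_used,
        result.p_value,
        statistic=result.statistic,
        df=result.df,
        min_expected=min_expected,
        degenerate=result.degenerate,
    )


@dataclass(frozen=True)
class ScanStage:
    n: int
    test_used: str
    p_value: float


def cumulative_scan(
    cohort: Cohort,
    locus: str,
    step: int = 100,
    seed: int = 0,
    classing: str = "binary",
    rule: str = "auto",
) -> list[ScanStage]:
    """Re-test association on nested random subsets grown by ``step``.

    A single seeded permutation of the cohort is drawn and consumed in
    increments, so stage k's animals are a superset of stage k-1's
    ("accumulated" subsets rather than independent draws). The final stage
    uses every animal and therefore reproduces the full-cohort test
    exactly, whatever the seed.
    """
    if step <= 0:
        raise ValueError("step must be a positive integer")
    n = len(cohort.animals)
    if n < step:
        raise ValueError(f"cohort size {n} smaller than step {step}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = list(range(step, n, step))
    if not sizes or sizes[-1] != n:
        sizes.append(n)
    stages = []
    for size in sizes:
        sub = Cohort(cohort.loci, tuple(cohort.animals[i] for i in perm[:size]))
        result = select_and_test(build_contingency(sub, locus, classing), rule)
        stages.append(ScanStage(size, result.test_used, result.p_value))
    return stages


@dataclass(frozen=True)
class GroupStats:
    genotype: str
    n: int
    lsm: float  # least-squares mean = group mean under the reduced model
    se: float


@dataclass(frozen=True)
class PairwiseComparison:
    label: str
    t: float
    df: float
    p_value: float


@dataclass(frozen=True)
class GenotypeEffect:
    groups: tuple[GroupStats, ...]
    comparisons: tuple[PairwiseComparison, ...]
    excluded: tuple[tuple[str, int, str], ...] = field(default_factory=tuple)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided pooled-variance Student t-test; (t, df, p).

    Zero pooled variance with equal means is treated as no evidence of a
    difference (t = 0, p = 1); with unequal means as conclusive (p -> 0).
    """
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if s2 == 0.0:
        return (0.0, df, 1.0) if diff == 0.0 else (math.inf, df, 0.0)
    t = diff / math.sqrt(s2 * (1 / n1 + 1 / n2))
    return t, df, float(2 * t_dist.sf(abs(t), df))


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
    diff = a.mean() - b.mean()
    if v1 + v2 == 0.0:
        return (0.0, n1 + n2 - 2, 1.0) if diff == 0.0 else (math.inf, n1 + n2 - 2, 0.0)
    t = diff / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df, float(2 * t_dist.sf(abs(t), df))


def genotype_effect(
    cohort: Cohort, locus: str, min_n: int = 5, welch: bool = False
) -> GenotypeEffect:
    """Per-genotype litter-size means with pairwise Student t-tests.

    Under the reduced model (first-parity records, so year and parity
    effects are dropped) the least-squares mean of a genotype group is its
    arithmetic mean; SE is the sample SD over sqrt(n). Groups with fewer
    than ``min_n`` animals are excluded from testing and reported as such.
    """
    cohort.locus(locus)
    values: dict[str, list[int]] = {g: [] for g in GENOTYPES}
    for a in cohort.animals:
        g = a.genotypes.get(locus)
        if g is not None and a.litter_size is not None:
            values[g].append(a.litter_size)

    groups, excluded, eligible = [], [], []
    for g in GENOTYPES:
        ys = np.asarray(values[g], dtype=float)
        if len(ys) == 0:
            continue
        if len(ys) < min_n:
            excluded.append((g, len(ys), f"n = {len(ys)} < {min_n}"))
            continue
        se = float(ys.std(ddof=1) / math.sqrt(len(ys))) if len(ys) > 1 else float("nan")
        groups.append(GroupStats(g, len(ys), float(ys.mean()), se))
        eligible.append((g, ys))

    if len(eligible) < 2:
        raise InsufficientGroupsError(
            f"fewer than two genotype groups with n >= {min_n} at {locus!r}"
        )

    test = _welch_t if welch else _pooled_t
    comparisons = []
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            (ga, ya), (gb, yb) = eligible[i], eligible[j]
            t, df, p = test(ya, yb)
            comparisons.append(PairwiseComparison(f"{ga} vs {gb}", t, df, p))

    return GenotypeEffect(tuple(groups), tuple(comparisons), tuple(excluded))
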