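"""Pairwise linkage disequilibrium from unphased two-locus genotypes.

Haplotype frequencies are estimated by expectation-maximization over the
3x3 joint genotype table. Under random mating only the double-heterozygote
cell is phase-ambiguous: an ID x ID animal carries either the coupling pair
(AB, ab) or the repulsion pair (Ab, aB). The E-step splits that cell
between the two configurations in proportion to the current
haplotype-frequency products; the M-step recounts expected haplotypes.
Every other cell contributes fixed haplotype counts, which is why the
marginal allele frequencies are invariant across iterations and equal the
single-locus sample frequencies.

Notation: allele A = insertion at locus 1, B = insertion at locus 2;
haplotypes ordered (AB, Ab, aB, ab).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .cohort import GENOTYPES, Cohort
from .errors import UndefinedLDError

_GIDX = {g: i for i, g in enumerate(GENOTYPES)}

#: haplotype count contribution of each unambiguous genotype cell
#: (row = locus-1 genotype II/ID/DD, col = locus-2 genotype), as counts of
#: (AB, Ab, aB, ab) per animal. The ID x ID cell (None) is phase-ambiguous.
_CELL_HAPLOTYPES = {
    (0, 0): (2, 0, 0, 0),
    (0, 1): (1, 1, 0, 0),
    (0, 2): (0, 2, 0, 0),
    (1, 0): (1, 0, 1, 0),
    (1, 1): None,
    (1, 2): (0, 1, 0, 1),
    (2, 0): (0, 0, 2, 0),
    (2, 1): (0, 0, 1, 1),
    (2, 2): (0, 0, 0, 2),
}


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes; sum to 1."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB


@dataclass(frozen=True)
class LDStats:
    """Classical pairwise LD statistics.

    D = p_AB - p_A p_B; D' = |D| / D_max; r2 = D^2 / (p_A p_a p_B p_b).
    """

    D: float
    D_prime: float
    r2: float


def genotype_cell_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities implied by haplotype frequencies."""
    pAB, pAb, paB, pab = h
    return np.array(
        [
            [pAB**2, 2 * pAB * pAb, pAb**2],
            [2 * pAB * paB, 2 * (pAB * pab + pAb * paB), 2 * pAb * pab],
            [paB**2, 2 * paB * pab, pab**2],
        ]
    )


def log_likelihood(counts: np.ndarray, h: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table (constant dropped)."""
    probs = genotype_cell_probs(np.asarray(h, dtype=float))
    counts = np.asarray(counts)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        terms = counts[mask] * np.log(probs[mask])
    return float(terms.sum()) if np.all(probs[mask] > 0) else -np.inf


def _validate_table(counts) -> np.ndarray:
    t = np.asarray(counts, dtype=int)
    if t.shape != (3, 3) or (t < 0).any() or t.sum() < 1:
        raise ValueError("two-locus counts must be a non-negative 3x3 table with total >= 1")
    # marginal allele counts at each locus
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n_A = 2 * row[0] + row[1]
    n_B = 2 * col[0] + col[1]
    n2 = 2 * t.sum()
    if n_A in (0, n2) or n_B in (0, n2):
        raise UndefinedLDError("monomorphic locus: LD undefined")
    return t


def _em_run(t: np.ndarray, h: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    n2 = 2 * t.sum()
    base = np.zeros(4)
    for (i, j), hap in _CELL_HAPLOTYPES.items():
        if hap is not None:
            base += t[i, j] * np.asarray(hap, dtype=float)
    n_dh = t[1, 1]
    for _ in range(max_iter):
        coupling = h[0] * h[3]
        repulsion = h[1] * h[2]
        denom = coupling + repulsion
        w = 0.5 if denom == 0 else coupling / denom
        exp_counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        h_new = exp_counts / n2
        if np.max(np.abs(h_new - h)) < tol:
            return h_new
        h = h_new
    return h


def em_haplotype_freqs(
    counts,
    tol: float = 1e-10,
    max_iter: int = 1000,
    restart_seed: int = 20240001,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies from a 3x3 genotype table.

    Starts at linkage equilibrium (product of the sample allele
    frequencies) and performs one additional random restart as a guard
    against the rare boundary case where the equilibrium start sits on a
    ridge; the higher-likelihood solution is returned. The log-likelihood
    is non-decreasing within each run.
    """
    t = _validate_table(counts)
    n2 = 2 * t.sum()
    row, col = t.sum(axis=1), t.sum(axis=0)
    p_a = (2 * row[0] + row[1]) / n2
    p_b = (2 * col[0] + col[1]) / n2
    starts = [
        np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    ]
    rng = np.random.default_rng(restart_seed)
    starts.append(rng.dirichlet(np.ones(4)))
    best, best_ll = None, -np.inf
    for h0 in starts:
        h = _em_run(t, h0, tol, max_iter)
        ll = log_likelihood(t, h)
        if ll > best_ll:
            best, best_ll = h, ll
    return HaplotypeFreqs(*map(float, best))


def ld_stats(h: HaplotypeFreqs) -> LDStats:
    """D, D' and r2 from haplotype frequencies.

    D' is defined as 0 at D = 0 (continuity); D_max follows the usual
    sign-dependent normalization.
    """
    p_a, p_b = h.p_A, h.p_B
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        raise UndefinedLDError("marginal allele frequency at 0 or 1: LD undefined")
    d = h.p_AB - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, q_a * q_b)
    else:
        d_max = 1.0  # D' := 0 at D = 0
    return LDStats(
        D=d,
        D_prime=abs(d) / d_max,
        r2=d * d / (p_a * q_a * p_b * q_b),
    )


def two_locus_counts(cohort: Cohort, locus_a: str, locus_b: str) -> np.ndarray:
    """3x3 joint genotype table over animals typed at both loci."""
    for name in (locus_a, locus_b):
        cohort.locus(name)  # raises UnknownLocusError
    t = np.zeros((3, 3), dtype=int)
    for animal in cohort.animals:
        ga = animal.genotypes.get(locus_a)
        gb = animal.genotypes.get(locus_b)
        if ga is not None and gb is not None:
            t[_GIDX[ga], _GIDX[gb]] += 1
    return t


def ld_matrix(cohort: Cohort, loci: list[str] | None = None):
    """Pairwise D' and r2 matrices (pandas DataFrames, NaN where undefined).

    Each pair uses its own set of pairwise-complete observations; a
    monomorphic pair yields NaN without aborting the other pairs.
    """
    import pandas as pd

    names = list(loci) if loci is not None else list(cohort.locus_names)
    if len(names) < 2:
        raise ValueError("need at least two loci for an LD matrix")
    dp = pd.DataFrame(np.nan, index=names, columns=names)
    r2 = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        try:
            stats = ld_stats(em_haplotype_freqs(two_locus_counts(cohort, a, b)))
        except UndefinedLDError:
            continue
        dp.loc[a, b] = dp.loc[b, a] = stats.D_prime
        r2.loc[a, b] = r2.loc[b, a] = stats.r2
    return dp, r2
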