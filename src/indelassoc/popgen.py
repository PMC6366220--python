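"""Per-locus population-genetic parameters and Hardy-Weinberg testing.

All statistics are computed from raw genotype counts, never from rounded
table frequencies, to avoid compounding 3-decimal rounding.

Conventions
-----------
For a biallelic indel with insertion-allele frequency p and deletion-allele
frequency q = 1 - p:

* homozygosity            Ho  = p^2 + q^2
* gene diversity          He  = 1 - Ho
* effective allele number Ne  = 1 / Ho
* Botstein PIC            PIC = He - 2 p^2 q^2

The Hardy-Weinberg chi-square goodness of fit compares observed genotype
counts with (n p^2, 2 n p q, n q^2). The field-standard degrees of freedom
are 1 (three classes, one estimated allele frequency); df=2 is exposed as
an option because some legacy software reports it that way, and the two
conventions can disagree about significance near the 0.05 boundary. An
exact conditional test is provided for loci with a rare homozygote class,
where the chi-square approximation is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist

from .cohort import GenotypeCounts
from .errors import DegenerateLocusError


@dataclass(frozen=True)
class AlleleFreqs:
    """Insertion (p_I) and deletion (p_D) allele frequencies; sum to 1."""

    p_I: float
    p_D: float

    def __post_init__(self):
        if not (0.0 <= self.p_I <= 1.0) or abs(self.p_I + self.p_D - 1.0) > 1e-12:
            raise ValueError(f"invalid allele frequencies ({self.p_I}, {self.p_D})")


@dataclass(frozen=True)
class DiversityStats:
    Ho: float
    He: float
    Ne: float
    PIC: float


@dataclass(frozen=True)
class HweResult:
    method: str  # "chi_square" | "exact"
    statistic: float | None
    df: int | None
    p_value: float
    expected_counts: tuple[float, float, float] | None = None


def allele_frequencies(counts: GenotypeCounts) -> AlleleFreqs:
    """Allele frequencies by gene counting: p_I = (2 n_II + n_ID) / 2n."""
    counts.require_nonempty()
    p = (2 * counts.n_II + counts.n_ID) / (2 * counts.n_total)
    return AlleleFreqs(p_I=p, p_D=1.0 - p)


def genotype_frequencies(counts: GenotypeCounts) -> tuple[float, float, float]:
    counts.require_nonempty()
    n = counts.n_total
    return (counts.n_II / n, counts.n_ID / n, counts.n_DD / n)


def diversity_stats(freqs: AlleleFreqs) -> DiversityStats:
    p, q = freqs.p_I, freqs.p_D
    ho = p * p + q * q
    he = 1.0 - ho
    return DiversityStats(Ho=ho, He=he, Ne=1.0 / ho, PIC=he - 2.0 * p * p * q * q)


def hwe_expected_counts(counts: GenotypeCounts) -> tuple[float, float, float]:
    p = allele_frequencies(counts).p_I
    n = counts.n_total
    return (n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2)


def hwe_chi_square(counts: GenotypeCounts, df: int = 1) -> HweResult:
    """Hardy-Weinberg chi-square goodness of fit.

    ``df`` selects the p-value convention (1 is standard; see module notes).
    Monomorphic loci trivially satisfy the equilibrium (statistic 0, p 1).
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    counts.require_nonempty()
    expected = hwe_expected_counts(counts)
    observed = counts.as_tuple()
    stat = 0.0
    for o, e in zip(observed, expected):
        if e == 0.0:
            if o:  # impossible under the estimated frequencies
                raise DegenerateLocusError(
                    "observed genotypes with zero expected count"
                )
            continue
        stat += (o - e) ** 2 / e
    p_value = float(chi2_dist.sf(stat, df)) if stat > 0 else 1.0
    return HweResult("chi_square", stat, df, p_value, expected)


def _log_het_prob(n_het: np.ndarray, n: int, n_rare: int) -> np.ndarray:
    """Log conditional probability of each heterozygote count given allele counts.

    P(n_het | n, n_rare) for the exact Hardy-Weinberg test: all 2n alleles
    fixed, n_rare copies of the rarer allele; probability of observing
    n_het heterozygotes under random union of gametes.
    """
    n_het = np.asarray(n_het)
    n_aa = (n_rare - n_het) // 2
    n_AA = n - n_het - n_aa
    lf = gammaln  # gammaln(k+1) = log k!
    return (
        lf(n + 1)
        - lf(n_AA + 1)
        - lf(n_het + 1)
        - lf(n_aa + 1)
        + n_het * np.log(2.0)
        + lf(n_rare + 1)
        + lf(2 * n - n_rare + 1)
        - lf(2 * n + 1)
    )


def hwe_exact(counts: GenotypeCounts) -> HweResult:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    Conditions on the observed allele counts, enumerates every compatible
    heterozygote count, and sums the probabilities of all outcomes no more
    probable than the observed one (two-sided, point-probability ordering).
    """
    counts.require_nonempty()
    n = counts.n_total
    n_rare = min(2 * counts.n_II + counts.n_ID, 2 * counts.n_DD + counts.n_ID)
    if n_rare == 0:  # monomorphic: single possible configuration
        return HweResult("exact", None, None, 1.0)
    support = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = _log_het_prob(support, n, n_rare)
    logp_obs = logp[support == counts.n_ID][0]
    keep = logp <= logp_obs + 1e-12
    p = float(np.exp(logsumexp(logp[keep])))
    return HweResult("exact", None, None, min(p, 1.0))
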