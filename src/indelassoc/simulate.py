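"""Seeded generators for synthetic cohorts and Ct tables.

These generators produce data with exactly the statistical structure the
analysis assumes — biallelic loci under Hardy-Weinberg proportions (or
with explicit genotype counts), pairs of loci at a specified level of
linkage disequilibrium, litter-size classes whose probabilities depend on
genotype, and replicate qPCR cycle thresholds with known fold changes — so
every stage of the pipeline can be tested end to end without external
data.

One global integer seed drives a ``numpy.random.SeedSequence`` splitting
scheme: child sequences are spawned in a fixed order (one per locus, then
one for phenotypes), so the same seed always yields a byte-identical
cohort and adding a locus never perturbs the phenotype stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import GENOTYPES, AnimalRecord, Cohort, IndelLocus
from .errors import SimulationSpecError


@dataclass(frozen=True)
class LocusSpec:
    """How to draw genotypes at one locus.

    Either ``p_I`` (Hardy-Weinberg mode: genotype probabilities p^2, 2pq,
    q^2) or ``explicit_counts`` (exact II/ID/DD counts, randomly assigned
    to animals) must be given.
    """

    name: str
    p_I: float | None = None
    explicit_counts: tuple[int, int, int] | None = None

    def __post_init__(self):
        if (self.p_I is None) == (self.explicit_counts is None):
            raise SimulationSpecError(
                f"locus {self.name!r}: give exactly one of p_I or explicit_counts"
            )
        if self.p_I is not None and not (0.0 <= self.p_I <= 1.0):
            raise SimulationSpecError(f"locus {self.name!r}: p_I must lie in [0,1]")
        if self.explicit_counts is not None and min(self.explicit_counts) < 0:
            raise SimulationSpecError(
                f"locus {self.name!r}: explicit counts must be non-negative"
            )


@dataclass(frozen=True)
class EffectSpec:
    """Genotype-conditional litter-size class probabilities.

    ``class_probs`` maps each genotype to probabilities over the litter
    classes ``classes`` (default 1/2/3 lambs). A genotype absent from the
    map falls back to the ``II`` row.
    """

    class_probs: Mapping[str, Sequence[float]]
    classes: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        for g, probs in self.class_probs.items():
            if g not in GENOTYPES:
                raise SimulationSpecError(f"unknown genotype {g!r} in effect spec")
            if len(probs) != len(self.classes) or abs(sum(probs) - 1.0) > 1e-9:
                raise SimulationSpecError(
                    f"genotype {g!r}: class probabilities must sum to 1"
                )

    def probs_for(self, genotype: str) -> np.ndarray:
        row = self.class_probs.get(genotype) or self.class_probs["II"]
        return np.asarray(row, dtype=float)


def null_effect(probs: Sequence[float] = (0.55, 0.43, 0.02)) -> EffectSpec:
    """An effect spec with identical class probabilities for every genotype."""
    return EffectSpec({g: tuple(probs) for g in GENOTYPES})


#: Litter-class probabilities conditional on genotype at a locus with a
#: heterozygote advantage of about +0.16 lambs over the insertion
#: homozygote — the magnitude observed for the goat PDGFRB 10 bp indel.
OBSERVED_LITTER_EFFECT = EffectSpec(
    {
        "II": (0.579, 0.409, 0.012),
        "ID": (0.420, 0.570, 0.010),
        "DD": (0.333, 0.667, 0.000),
    }
)


def _draw_genotypes(spec: LocusSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.explicit_counts is not None:
        if sum(spec.explicit_counts) != n:
            raise SimulationSpecError(
                f"locus {spec.name!r}: explicit counts sum to "
                f"{sum(spec.explicit_counts)}, expected {n}"
            )
        pool = np.repeat(np.arange(3), spec.explicit_counts)
        rng.shuffle(pool)
        return pool
    p = spec.p_I
    probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    return rng.choice(3, size=n, p=probs)


def simulate_cohort(
    n: int,
    loci: Sequence[LocusSpec],
    effect: EffectSpec | None = None,
    effect_locus: str | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a cohort of ``n`` animals.

    Litter sizes are drawn from ``effect``'s genotype-conditional class
    probabilities at ``effect_locus`` (default: the first locus); with
    ``effect=None`` the phenotype is left missing.
    """
    if n < 1:
        raise SimulationSpecError("n must be >= 1")
    if not loci:
        raise SimulationSpecError("at least one locus spec required")
    names = [s.name for s in loci]
    if effect is not None:
        effect_locus = effect_locus or names[0]
        if effect_locus not in names:
            raise SimulationSpecError(f"effect locus {effect_locus!r} not simulated")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(loci) + 1)
    genotypes = {
        s.name: _draw_genotypes(s, n, np.random.default_rng(child))
        for s, child in zip(loci, children[:-1])
    }

    litter: np.ndarray | None = None
    if effect is not None:
        rng = np.random.default_rng(children[-1])
        classes = np.asarray(effect.classes)
        g_eff = genotypes[effect_locus]
        litter = np.empty(n, dtype=int)
        for gi, g in enumerate(GENOTYPES):
            mask = g_eff == gi
            if mask.any():
                litter[mask] = rng.choice(
                    classes, size=int(mask.sum()), p=effect.probs_for(g)
                )

    width = len(str(n))
    animals = tuple(
        AnimalRecord(
            animal_id=f"A{i + 1:0{width}d}",
            genotypes={name: GENOTYPES[genotypes[name][i]] for name in names},
            litter_size=None if litter is None else int(litter[i]),
        )
        for i in range(n)
    )
    return Cohort(tuple(IndelLocus(name) for name in names), animals)


def haplotype_freqs_for(p_a: float, p_b: float, d_prime: float) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) at a target positive D'."""
    if not (0.0 <= d_prime <= 1.0):
        raise SimulationSpecError("d_prime must lie in [0,1]")
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise SimulationSpecError("allele frequencies must lie strictly in (0,1)")
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    d = d_prime * min(p_a * q_b, q_a * p_b)
    h = np.array([p_a * p_b + d, p_a * q_b - d, q_a * p_b - d, q_a * q_b + d])
    if (h < -1e-12).any():
        raise SimulationSpecError(
            f"infeasible (p_A={p_a}, p_B={p_b}, D'={d_prime}) combination"
        )
    return np.clip(h, 0.0, 1.0)


def simulate_linked_pair(
    n: int,
    p_a: float,
    p_b: float,
    d_prime: float,
    seed: int = 0,
    locus_names: tuple[str, str] = ("L1", "L2"),
) -> Cohort:
    """Simulate ``n`` animals at two loci in LD at the target D'.

    2n haplotypes are drawn i.i.d. from the implied haplotype frequencies
    and paired at random; genotypes are emitted unphased, so the EM
    estimator sees exactly the inference problem it is built for.
    """
    if n < 1:
        raise SimulationSpecError("n must be >= 1")
    h = haplotype_freqs_for(p_a, p_b, d_prime)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    haps = rng.choice(4, size=(n, 2), p=h / h.sum())
    # haplotype index: bit 1 = deletion at locus A, bit 0 = deletion at locus B
    a_del = haps // 2  # 0 for A, 1 for a
    b_del = haps % 2
    g_a = a_del.sum(axis=1)  # 0=II, 1=ID, 2=DD
    g_b = b_del.sum(axis=1)
    width = len(str(n))
    animals = tuple(
        AnimalRecord(
            animal_id=f"A{i + 1:0{width}d}",
            genotypes={
                locus_names[0]: GENOTYPES[g_a[i]],
                locus_names[1]: GENOTYPES[g_b[i]],
            },
        )
        for i in range(n)
    )
    return Cohort(tuple(IndelLocus(nm) for nm in locus_names), animals)


def simulate_ct(
    groups: Mapping[str, tuple[int, float, float]],
    target_gene: str = "TARGET",
    reference_gene: str = "REF",
    reference_ct: float = 20.0,
    replicates: int = 3,
    replicate_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a replicate Ct table with known group fold changes.

    ``groups`` maps each group label to ``(n_samples, true mean dCt,
    between-sample SD)``. Reference-gene replicates scatter around
    ``reference_ct``; target-gene replicates around ``reference_ct`` plus
    the sample's dCt. A one-cycle difference in true dCt between groups
    therefore corresponds to a twofold expression difference.
    """
    for g, (n, _, sd) in groups.items():
        if n < 1 or sd < 0:
            raise SimulationSpecError(f"group {g!r}: need n >= 1 and SD >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for g in sorted(groups):
        n, dct_mean, sd = groups[g]
        for i in range(n):
            sample = f"{g}_{i + 1}"
            dct = dct_mean + rng.normal(0.0, sd) if sd > 0 else dct_mean
            for rep in range(1, replicates + 1):
                rows.append(
                    (sample, g, reference_gene, rep,
                     reference_ct + rng.normal(0.0, replicate_sd))
                )
                rows.append(
                    (sample, g, target_gene, rep,
                     reference_ct + dct + rng.normal(0.0, replicate_sd))
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene", "replicate", "ct"]
    )
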