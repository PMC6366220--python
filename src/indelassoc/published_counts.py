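"""Published genotype counts for the goat PDGFRB indel litter-size study.

These are the raw counts reported for two intronic indels of the PDGFRB
gene genotyped in Shaanbei white cashmere goats: a 5 bp indel (in complete
linkage with a 36 bp indel, 501 animals) and a 10 bp indel (1122 animals),
with first-parity litter size recorded for every ewe. Only *counts* are
stored here — never the study's derived statistics — so the reproduction
routine exercises the full pipeline rather than echoing stored answers.

The published summary statistics the pipeline is checked against live in
``EXPECTED`` entries alongside each input, with the comparison tolerance
used by :mod:`indelassoc.reproduce`.
"""

from __future__ import annotations

#: (n_II, n_ID, n_DD) per locus.
GENOTYPE_COUNTS: dict[str, tuple[int, int, int]] = {
    "P2_5bp": (29, 147, 325),
    "P3_10bp": (919, 200, 3),
}

#: Published per-locus parameters (3-decimal precision).
DIVERSITY_EXPECTED: dict[str, dict[str, float]] = {
    "P2_5bp": {"p_I": 0.205, "p_D": 0.795, "Ho": 0.674, "He": 0.326,
               "Ne": 1.484, "PIC": 0.273},
    "P3_10bp": {"p_I": 0.908, "p_D": 0.092, "Ho": 0.833, "He": 0.167,
                "Ne": 1.201, "PIC": 0.153},
}

#: Cumulative-subset association rows for the 5/36 bp indel (chi-square):
#: (subset size, [[single-lamb II,ID,DD], [multi-lamb II,ID,DD]], published p).
BINARY_ROWS_5BP: list[tuple[int, list[list[int]], float]] = [
    (100, [[3, 17, 30], [4, 12, 34]], 0.534),
    (200, [[7, 29, 62], [7, 27, 68]], 0.874),
    (300, [[13, 37, 98], [13, 49, 90]], 0.375),
    (400, [[15, 52, 135], [14, 68, 116]], 0.168),
    (501, [[15, 70, 167], [14, 77, 158]], 0.741),
]

#: Cumulative-subset association rows for the 10 bp indel (exact test):
#: (subset size, counts, published p, note). The n=600 published value
#: equals the one-sided hypergeometric tail, not the two-sided
#: point-probability p (0.0000609, confirmed by two independent
#: implementations); the note flags the discrepancy.
BINARY_ROWS_10BP: list[tuple[int, list[list[int]], float, str | None]] = [
    (100, [[43, 7, 0], [35, 15, 0]], 0.09, None),
    (200, [[93, 7, 0], [78, 22, 0]], 0.004, None),
    (300, [[139, 13, 0], [119, 29, 0]], 0.007, None),
    (400, [[184, 18, 0], [165, 33, 0]], 0.024, None),
    (500, [[231, 21, 0], [212, 36, 0]], 0.035, None),
    (600, [[271, 31, 0], [231, 67, 0]], 3.580e-5,
     "published value equals the one-sided tail; two-sided p is 6.086e-5"),
    (1000, [[445, 57, 1], [380, 115, 2]], 7.699e-7, None),
    (1122, [[532, 84, 1], [387, 116, 2]], 6.030e-5, None),
]

#: Litter-size class (1/2/3 lambs) by genotype for the 10 bp indel.
PER_CLASS_TABLE_10BP: list[list[int]] = [
    [532, 84, 1],
    [376, 114, 2],
    [11, 2, 0],
]
PER_CLASS_EXPECTED_P = 4.447e-4

#: Published genotype-effect estimates for the 10 bp indel (DD excluded, n=3).
EFFECT_EXPECTED = {"II_mean": 1.43, "ID_mean": 1.59, "p": 1.103e-4}

#: Published pairwise LD for the completely linked 5 bp / 36 bp pair.
LINKED_PAIR_EXPECTED = {"D_prime": 1.00, "r2": 1.00}


def litter_sizes_from_per_class(table: list[list[int]]) -> dict[str, list[int]]:
    """Reconstruct per-animal litter sizes per genotype from class counts.

    Row k of ``table`` holds the II/ID/DD counts among mothers of k+1
    lambs, so each cell expands to that many animals with litter size k+1.
    """
    genotypes = ("II", "ID", "DD")
    out: dict[str, list[int]] = {g: [] for g in genotypes}
    for k, row in enumerate(table, start=1):
        for g, count in zip(genotypes, row):
            out[g].extend([k] * count)
    return out
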