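import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from indelassoc import Cohort, IndelLocus, AnimalRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def cohort_from_class_table(table, locus="P3_10bp") -> Cohort:
    """Expand a litter-class (rows) by genotype (cols) count table into a
    per-animal cohort — the reconstruction used to analyse published class
    counts as if the raw records were available."""
    genotypes = ("II", "ID", "DD")
    animals = []
    i = 0
    for k, row in enumerate(np.asarray(table, dtype=int), start=1):
        for g, count in zip(genotypes, row):
            for _ in range(count):
                i += 1
                animals.append(
                    AnimalRecord(f"A{i:05d}", {locus: g}, litter_size=k)
                )
    return Cohort((IndelLocus(locus),), tuple(animals))


@pytest.fixture
def goat_10bp_binary_table():
    """Single-lamb vs multi-lamb genotype counts, full 1122-ewe panel."""
    return np.array([[532, 84, 1], [387, 116, 2]])


@pytest.fixture
def goat_10bp_class_table():
    """Litter-size classes 1/2/3 by genotype, full 1122-ewe panel."""
    return np.array([[532, 84, 1], [376, 114, 2], [11, 2, 0]])
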