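"""Cohort data model and delimited-file I/O.

A cohort is one row per animal: an identifier, a genotype per biallelic
indel locus coded ``II``/``ID``/``DD`` (insertion homozygote, heterozygote,
deletion homozygote), the first-parity litter size as a small positive
integer, and optional covariates that downstream models may ignore.

Missing data are handled per locus: an animal untyped at locus A still
contributes to every statistic at locus B. This matters in practice because
typing panels often differ between loci (e.g. 501 animals at one locus,
1122 at another, within the same study population).
"""

from __future__ import annotations

import csv
import io
import math
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    CohortValidationError,
    EmptyLocusError,
    UnknownLocusError,
)

GENOTYPES = ("II", "ID", "DD")

#: Tokens accepted (case-insensitively) for each normalized genotype code.
#: Lab sheets vary; the canonical coding is II/ID/DD.
DEFAULT_GENOTYPE_ALIASES: dict[str, str | None] = {
    "II": "II",
    "I/I": "II",
    "+/+": "II",
    "ID": "ID",
    "DI": "ID",
    "I/D": "ID",
    "D/I": "ID",
    "+/-": "ID",
    "-/+": "ID",
    "DD": "DD",
    "D/D": "DD",
    "-/-": "DD",
    "NA": None,
    "N/A": None,
    ".": None,
    "": None,
}

MISSING_TOKENS = {"NA", "N/A", ".", "", "NAN", "NONE"}


def normalize_genotype(token: str | None, aliases: Mapping[str, str | None] | None = None) -> str | None:
    """Map a raw genotype token to ``II``/``ID``/``DD`` or ``None`` (missing).

    Raises ``ValueError`` for tokens outside the alias table.
    """
    table = DEFAULT_GENOTYPE_ALIASES if aliases is None else aliases
    if token is None:
        return None
    key = str(token).strip().upper()
    if key in table:
        return table[key]
    if key in MISSING_TOKENS:
        return None
    raise ValueError(f"unrecognized genotype token {token!r}")


@dataclass(frozen=True)
class IndelLocus:
    """A biallelic insertion/deletion locus.

    ``variant_label`` is a free-text HGVS-like description of the variant,
    e.g. ``"NC_030814.1:g.33301-33313delCCCCCACCCC"``.
    """

    name: str
    variant_label: str = ""
    insertion_allele_symbol: str = "I"
    deletion_allele_symbol: str = "D"

    def __post_init__(self):
        if not self.name:
            raise CohortValidationError("locus name must be non-empty")
        if self.insertion_allele_symbol == self.deletion_allele_symbol:
            raise CohortValidationError(
                f"locus {self.name!r}: allele symbols must be distinct"
            )


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: genotypes keyed by locus name, phenotype, covariates.

    ``litter_size`` is the number of lambs at first parity (>= 1) or
    ``None`` when unrecorded. ``covariates`` (lambing year, parity, ...)
    are retained but unused by the default models.
    """

    animal_id: str
    genotypes: Mapping[str, str | None] = field(default_factory=dict)
    litter_size: int | None = None
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.litter_size is not None and self.litter_size < 1:
            raise CohortValidationError(
                f"animal {self.animal_id!r}: litter_size must be >= 1, got {self.litter_size}"
            )
        for locus, g in self.genotypes.items():
            if g is not None and g not in GENOTYPES:
                raise CohortValidationError(
                    f"animal {self.animal_id!r}: invalid genotype {g!r} at {locus!r}"
                )

    def __hash__(self):
        return hash(self.animal_id)


@dataclass(frozen=True)
class Cohort:
    """A typed cohort: declared loci plus one record per animal."""

    loci: tuple[IndelLocus, ...]
    animals: tuple[AnimalRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "animals", tuple(self.animals))
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate locus names in cohort")
        seen: set[str] = set()
        for a in self.animals:
            if a.animal_id in seen:
                raise CohortValidationError(
                    f"duplicate animal_id {a.animal_id!r}"
                )
            seen.add(a.animal_id)
            for locus in a.genotypes:
                if locus not in names:
                    raise CohortValidationError(
                        f"animal {a.animal_id!r} carries genotype for undeclared locus {locus!r}"
                    )

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def locus(self, name: str) -> IndelLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise UnknownLocusError(name)

    def __len__(self) -> int:
        return len(self.animals)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts (II, ID, DD) for one locus."""

    n_II: int
    n_ID: int
    n_DD: int

    def __post_init__(self):
        if min(self.n_II, self.n_ID, self.n_DD) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_II + self.n_ID + self.n_DD

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_II, self.n_ID, self.n_DD)

    def require_nonempty(self) -> "GenotypeCounts":
        if self.n_total == 0:
            raise EmptyLocusError("no non-missing genotypes at this locus")
        return self


#: Required columns of a Ct table (replicate qPCR cycle thresholds).
CT_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Validate a replicate Ct table and return it with canonical dtypes.

    Each row is one replicate measurement: (sample, group label, gene,
    replicate index, Ct in cycles). Ct values must be finite and positive.
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise CohortValidationError(f"Ct table missing columns: {missing}")
    out = ct.loc[:, list(CT_COLUMNS)].copy()
    out["ct"] = pd.to_numeric(out["ct"], errors="coerce")
    bad = out.index[~(out["ct"] > 0) | ~out["ct"].apply(math.isfinite)]
    if len(bad):
        raise CohortValidationError(
            f"Ct table has non-finite or non-positive Ct values at rows {list(bad[:5])}"
        )
    return out


def read_ct_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    return validate_ct_table(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# Delimited cohort I/O


@dataclass(frozen=True)
class CohortDialect:
    """Column-mapping configuration for cohort files.

    ``locus_columns`` maps file column name -> locus name; when ``None``
    every column other than the id/phenotype/covariate columns is treated
    as a locus column named after itself.
    """

    id_column: str = "animal_id"
    litter_column: str = "litter_size"
    locus_columns: Mapping[str, str] | None = None
    covariate_columns: Sequence[str] = ()
    delimiter: str | None = None  # None = auto-detect comma vs tab
    genotype_aliases: Mapping[str, str | None] | None = None


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path: str | Path, dialect: CohortDialect | None = None) -> Cohort:
    """Read a delimited cohort file into a validated :class:`Cohort`.

    Rows with unparseable genotype tokens or invalid phenotypes are
    collected into a single :class:`CohortValidationError` whose
    ``row_errors`` lists every offending (1-based data) row. Missing values
    (``NA``) are preserved as missing, never dropped.
    """
    dialect = dialect or CohortDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect.delimiter or _sniff_delimiter(path)

    with open(path, "r", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file")
        header = [h.strip() for h in reader.fieldnames]
        rows = list(reader)

    if dialect.id_column not in header:
        raise CohortValidationError(
            f"{path}: missing id column {dialect.id_column!r}"
        )
    if dialect.locus_columns is not None:
        locus_map = dict(dialect.locus_columns)
        absent = [c for c in locus_map if c not in header]
        if absent:
            raise CohortValidationError(f"{path}: missing locus columns {absent}")
    else:
        reserved = {dialect.id_column, dialect.litter_column, *dialect.covariate_columns}
        locus_map = {c: c for c in header if c not in reserved}

    has_litter = dialect.litter_column in header

    animals: list[AnimalRecord] = []
    row_errors: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(rows, start=1):
        animal_id = (row.get(dialect.id_column) or "").strip()
        if not animal_id:
            row_errors.append((i, "empty animal_id"))
            continue
        if animal_id in seen_ids:
            row_errors.append((i, f"duplicate animal_id {animal_id!r}"))
            continue
        genotypes: dict[str, str | None] = {}
        ok = True
        for col, locus in locus_map.items():
            try:
                genotypes[locus] = normalize_genotype(
                    row.get(col), dialect.genotype_aliases
                )
            except ValueError as e:
                row_errors.append((i, f"{locus}: {e}"))
                ok = False
        litter: int | None = None
        if has_litter:
            raw = (row.get(dialect.litter_column) or "").strip()
            if raw.upper() not in MISSING_TOKENS:
                try:
                    litter = int(raw)
                    if litter < 1:
                        raise ValueError
                except ValueError:
                    row_errors.append((i, f"invalid litter_size {raw!r}"))
                    ok = False
        if not ok:
            continue
        covariates = {
            c: (row.get(c) or "").strip() for c in dialect.covariate_columns if c in header
        }
        seen_ids.add(animal_id)
        animals.append(
            AnimalRecord(animal_id, genotypes, litter, covariates)
        )

    if row_errors:
        preview = "; ".join(f"row {r}: {m}" for r, m in row_errors[:5])
        raise CohortValidationError(
            f"{path}: {len(row_errors)} invalid row(s): {preview}", row_errors
        )

    loci = tuple(IndelLocus(name) for name in locus_map.values())
    return Cohort(loci=loci, animals=tuple(animals))


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = "\t") -> None:
    """Write a cohort back to a delimited file (``NA`` for missing)."""
    cov_names = sorted({k for a in cohort.animals for k in a.covariates})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["animal_id", *cohort.locus_names, "litter_size", *cov_names])
        for a in cohort.animals:
            row = [a.animal_id]
            row += [a.genotypes.get(l) or "NA" for l in cohort.locus_names]
            row.append("NA" if a.litter_size is None else str(a.litter_size))
            row += [a.covariates.get(c, "") for c in cov_names]
            writer.writerow(row)


def counts_for_locus(cohort: Cohort, locus: str) -> GenotypeCounts:
    """Tally II/ID/DD among animals typed at ``locus`` (missing excluded)."""
    if locus not in cohort.locus_names:
        raise UnknownLocusError(locus)
    tally = {g: 0 for g in GENOTYPES}
    for a in cohort.animals:
        g = a.genotypes.get(locus)
        if g is not None:
            tally[g] += 1
    return GenotypeCounts(tally["II"], tally["ID"], tally["DD"])


# ---------------------------------------------------------------------------
# Report writing


def _format_value(v, precision: int) -> str:
    if isinstance(v, bool) or v is None:
        return str(v)
    if isinstance(v, numbers.Integral):
        return str(int(v))
    if isinstance(v, numbers.Real):
        x = float(v)
        if x != 0 and abs(x) < 10 ** (-precision):
            return f"{x:.{precision}e}"  # keep tiny p-values legible
        return f"{x:.{precision}f}"  # round-half-to-even
    return str(v)


def write_report(
    results: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
    precision: int = 3,
) -> None:
    """Write a result bundle as TSV or a markdown pipe table.

    Column order is the order of keys in the first record (or the frame's
    columns) — deterministic, so repeated writes are byte-identical. Floats
    are rounded half-to-even at ``precision`` decimals; values smaller than
    the precision cutoff switch to scientific notation so exact-test
    p-values stay readable.
    """
    if isinstance(results, pd.DataFrame):
        records = results.to_dict(orient="records")
        columns = list(results.columns)
    else:
        records = [dict(r) for r in results]
        columns = list(records[0].keys()) if records else []

    text = render_report(records, columns, fmt=fmt, precision=precision)
    Path(path).write_text(text)


def render_report(records, columns, fmt="tsv", precision=3) -> str:
    cells = [[_format_value(r.get(c), precision) for c in columns] for r in records]
    if fmt == "tsv":
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(cells)
        return buf.getvalue()
    if fmt == "markdown":
        widths = [
            max(len(c), *(len(row[j]) for row in cells)) if cells else len(c)
            for j, c in enumerate(columns)
        ]
        lines = [
            "| " + " | ".join(c.ljust(w) for c, w in zip(columns, widths)) + " |",
            "| " + " | ".join("-" * w for w in widths) + " |",
        ]
        for row in cells:
            lines.append("| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
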