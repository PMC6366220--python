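"""Relative qPCR quantification by the 2^-ddCt method.

Replicate cycle thresholds are averaged on the Ct scale per (sample, gene);
dCt = Ct_target - Ct_reference removes loading differences via the
endogenous-control gene; ddCt = dCt - mean dCt of the calibrator group; and
the relative quantity RQ = base^-ddCt (base 2 assumes perfect doubling per
cycle and is configurable). Group summaries report mean RQ +/- SE with
two-sided t-tests per pair, tiered at 0.05 / 0.01 to match the usual
one-star/two-star figure convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .cohort import validate_ct_table
from .errors import IndelAssocError


@dataclass(frozen=True)
class RelativeQuantity:
    sample_id: str
    group: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    rq: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_rq: float
    se: float


@dataclass(frozen=True)
class GroupComparison:
    label: str
    t: float
    df: float
    p_value: float
    tier: str  # "", "*", "**"


def relative_quantities(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
    base: float = 2.0,
) -> list[RelativeQuantity]:
    """Per-sample relative expression of ``target_gene`` vs the calibrator.

    Samples lacking a reference-gene Ct are dropped with a warning rather
    than aborting the run. The calibrator is the mean dCt of a designated
    group, so RQ = 1 means "expressed at the calibrator group's level".
    """
    ct = validate_ct_table(ct)
    means = (
        ct.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    wide = means.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    ).reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise IndelAssocError(f"no Ct measurements for gene {gene!r}")
    incomplete = wide[wide[[target_gene, reference_gene]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} sample(s) missing target or "
            f"reference Ct: {sorted(incomplete['sample_id'])}",
            stacklevel=2,
        )
        wide = wide.dropna(subset=[target_gene, reference_gene])
    wide = wide.assign(delta_ct=wide[target_gene] - wide[reference_gene])
    cal = wide.loc[wide["group"] == calibrator_group, "delta_ct"]
    if cal.empty:
        raise IndelAssocError(f"calibrator group {calibrator_group!r} is empty")
    cal_mean = float(cal.mean())
    out = []
    for _, row in wide.iterrows():
        ddct = float(row["delta_ct"] - cal_mean)
        out.append(
            RelativeQuantity(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                gene=target_gene,
                delta_ct=float(row["delta_ct"]),
                delta_delta_ct=ddct,
                rq=float(base**-ddct),
            )
        )
    return out


def _tier(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def group_compare(
    rqs: list[RelativeQuantity],
    grouping: Mapping[str, str] | None = None,
    welch: bool = False,
) -> tuple[list[GroupSummary], list[GroupComparison]]:
    """Mean RQ +/- SE per group plus pairwise two-sided t-tests.

    ``grouping`` optionally relabels each RQ's group (e.g. pooling ages
    into developmental stages) before summarizing. Groups of size 1 are
    summarized but take part in no test.
    """
    if not rqs:
        raise IndelAssocError("no relative quantities to summarize")
    by_group: dict[str, list[float]] = {}
    for r in rqs:
        g = grouping[r.group] if grouping is not None else r.group
        by_group.setdefault(g, []).append(r.rq)

    summaries = []
    for g in sorted(by_group):
        x = np.asarray(by_group[g])
        se = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        summaries.append(GroupSummary(g, len(x), float(x.mean()), se))

    comparisons = []
    testable = [g for g in sorted(by_group) if len(by_group[g]) >= 2]
    for ga, gb in itertools.combinations(testable, 2):
        a, b = np.asarray(by_group[ga]), np.asarray(by_group[gb])
        n1, n2 = len(a), len(b)
        if welch:
            v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
            denom2, df = v1 + v2, None
            if denom2 > 0:
                df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
            s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
            denom2 = s2 * (1 / n1 + 1 / n2)
        diff = float(a.mean() - b.mean())
        if denom2 == 0.0:
            t, p = (0.0, 1.0) if diff == 0.0 else (math.inf, 0.0)
            df = df if df is not None else n1 + n2 - 2
        else:
            t = diff / math.sqrt(denom2)
            p = float(2 * t_dist.sf(abs(t), df))
        comparisons.append(
            GroupComparison(f"{ga} vs {gb}", t, float(df), p, _tier(p))
        )
    return summaries, comparisons


#: Default pooling of testis developmental ages into meiotic phases: the
#: first mitotic weeks of gonocyte proliferation versus the onset of
#: meiosis around 6-8 weeks.
DEFAULT_TESTIS_SCHEME: dict[str, str] = {
    "0d": "mitosis",
    "3d": "mitosis",
    "1w": "mitosis",
    "2w": "mitosis",
    "3w": "mitosis",
    "4w": "mitosis",
    "6w": "meiosis",
    "8w": "meiosis",
}


def stage_grouping(
    ages: list[str], scheme: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Deterministically map sample age labels to developmental stages.

    Every age must appear in the scheme; an unmapped age raises rather than
    silently creating a singleton group.
    """
    scheme = DEFAULT_TESTIS_SCHEME if scheme is None else dict(scheme)
    if not scheme:
        raise IndelAssocError("empty stage-grouping scheme")
    unmapped = sorted({a for a in ages if a not in scheme})
    if unmapped:
        raise IndelAssocError(f"ages not covered by the scheme: {unmapped}")
    return {a: scheme[a] for a in ages}
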