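"""Per-gene carrier association and rare-CNV classification.

The counting unit is the carrier *sample*: a gene's deletion (or
duplication) carrier count in a cohort is the number of distinct samples
with at least one CNV of that type overlapping the gene by >= 1 bp —
multiple qualifying CNVs in one sample still count once.

Every gene touched by at least one deletion anywhere forms the deletion
test universe, likewise for duplications; each (gene, type) pair gets a
two-tailed Fisher exact test of its 2x2 carrier table with the
conditional-MLE odds ratio and exact CI. One pooled Benjamini-Hochberg
correction runs across the union of both universes (deletion tests +
duplication tests together). A (gene, type) pair is *rare* when its
control carrier fraction is strictly below ``rare_control_freq``
(default 0.1%), regardless of its frequency in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exact import ExactTestResult, bh_adjust, exact_rxc_p, fisher_exact_2x2
from .io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "count_gene_carriers",
    "run_association",
    "subgroup_association",
    "SubgroupResult",
]


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), g) for s, e, g in
            zip(grp["start"], grp["end"], grp["gene_id"]))
    return trees


def _carrier_pairs(cnvs: pd.DataFrame, trees: dict[str, IntervalTree]) -> pd.DataFrame:
    """Distinct (gene_id, sample_id, cnv_type) hit pairs, >= 1 bp overlap."""
    hits: set[tuple[str, str, str]] = set()
    for rec in cnvs.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(rec.start, rec.end):
            hits.add((iv.data, rec.sample_id, rec.cnv_type))
    return pd.DataFrame(sorted(hits), columns=["gene_id", "sample_id", "cnv_type"])


def count_gene_carriers(
    cnvs: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    cnv_type: str | None = None,
) -> pd.DataFrame:
    """Per-gene distinct-sample carrier counts, split by cohort and subtype.

    Restricted to one CNV type when ``cnv_type`` is given, otherwise both
    types are counted (one row per gene x type with >= 1 carrier). CNVs
    from samples missing from the manifest are an error.

    Returns columns: gene_id, cnv_type, case_carriers, case_cd, case_uc,
    control_carriers.
    """
    unknown = set(cnvs["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValidationError(f"CNV sample(s) absent from manifest: {sorted(unknown)[:5]}")
    if cnv_type is not None:
        cnvs = cnvs[cnvs["cnv_type"] == cnv_type]
    pairs = _carrier_pairs(cnvs, _gene_trees(genes))
    if pairs.empty:
        return pd.DataFrame(columns=["gene_id", "cnv_type", "case_carriers",
                                     "case_cd", "case_uc", "control_carriers"])
    meta = samples.set_index("sample_id")[["cohort", "subtype"]]
    pairs = pairs.join(meta, on="sample_id")
    grp = pairs.groupby(["gene_id", "cnv_type"])
    out = grp.agg(
        case_carriers=("cohort", lambda c: int((c == "case").sum())),
        control_carriers=("cohort", lambda c: int((c == "control").sum())),
        case_cd=("subtype", lambda s: int((s == "CD").sum())),
        case_uc=("subtype", lambda s: int((s == "UC").sum())),
    ).reset_index()
    return out[["gene_id", "cnv_type", "case_carriers", "case_cd", "case_uc",
                "control_carriers"]]


def run_association(
    cnvs: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    rare_control_freq: float = 0.001,
    p_adj_threshold: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene x CNV-type exact association with pooled FDR control.

    The test universe is every (gene, type) pair carried by at least one
    sample in either cohort; deletion and duplication tests share a single
    BH correction (``m_tests`` = size of the pooled universe). The
    significant-rare report is ``is_rare & (p_adj <= p_adj_threshold)``.
    """
    n_cases = int((samples["cohort"] == "case").sum())
    n_controls = int((samples["cohort"] == "control").sum())
    counts = count_gene_carriers(cnvs, genes, samples)
    if counts.empty:
        logger.warning("association: empty test universe (no gene overlapped by any CNV)")
        from .io import ASSOCIATION_COLUMNS
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)

    results = []
    for rec in counts.itertuples(index=False):
        res: ExactTestResult = fisher_exact_2x2(
            rec.case_carriers, n_cases - rec.case_carriers,
            rec.control_carriers, n_controls - rec.control_carriers,
            alpha=alpha)
        results.append((res.p_two_sided, res.or_cmle, res.or_sample,
                        res.ci_low, res.ci_high))
    stats = pd.DataFrame(results, columns=["p", "or_cmle", "or_sample", "ci_low", "ci_high"])
    out = pd.concat([counts.reset_index(drop=True), stats], axis=1)
    out["n_cases"] = n_cases
    out["n_controls"] = n_controls
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["m_tests"] = len(out)
    out["is_rare"] = out["control_carriers"] / n_controls < rare_control_freq
    out["significant_rare"] = out["is_rare"] & (out["p_adj"] <= p_adj_threshold)
    from .io import ASSOCIATION_COLUMNS
    return out[ASSOCIATION_COLUMNS]


@dataclass(frozen=True)
class SubgroupResult:
    """Carrier-status vs clinical-feature contingency test."""

    p: float
    method: str
    table: pd.DataFrame
    exact: ExactTestResult | None = None


def subgroup_association(carrier_flags: pd.Series, feature: pd.Series) -> SubgroupResult:
    """Test whether rare-CNV carrier status varies across a clinical feature.

    ``carrier_flags`` is a boolean Series indexed by sample; ``feature`` a
    categorical Series over the same samples (e.g. disease subtype, age
    class). Builds the (feature level) x (carrier, non-carrier) table:
    2 levels use the exact 2x2 machinery, more levels the exact r x 2
    enumeration when the table is small, chi-square otherwise. The method
    actually used is recorded in the result.
    """
    carrier = pd.Series(carrier_flags).astype(bool)
    feat = pd.Series(feature).reindex(carrier.index)
    if feat.isna().any():
        raise ValidationError("feature missing for some samples")
    levels = sorted(feat.unique())
    if len(levels) < 2:
        raise ValidationError("feature must have at least two levels")
    table = pd.DataFrame(
        {"carrier": [int((carrier & (feat == lv)).sum()) for lv in levels],
         "non_carrier": [int((~carrier & (feat == lv)).sum()) for lv in levels]},
        index=pd.Index(levels, name="level"))
    if len(levels) == 2:
        a, b = int(table.iloc[0, 0]), int(table.iloc[0, 1])
        c, d = int(table.iloc[1, 0]), int(table.iloc[1, 1])
        res = fisher_exact_2x2(a, b, c, d)
        return SubgroupResult(res.p_two_sided, "fisher-exact", table, res)
    p, method = exact_rxc_p(table.to_numpy())
    return SubgroupResult(p, method, table)
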