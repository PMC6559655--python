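"""CNV burden stratification and group comparison.

Stringent CNVs are cross-classified by type (all / deletion /
duplication), length class and genic status (overlapping >= 1 bp of any
gene). Length classes are half-open upward — [5, 100) kb, [100, 500) kb,
[500 kb, 1 Mb), [1 Mb, inf) — so an event of exactly 100 kb falls in the
100-500 kb class and the classes partition the events.

Each cell compares the observed event counts of two sample groups
(CD vs UC subtypes, or cases vs controls) against the counts expected
from the group sizes alone: with T = obs1 + obs2 events in total,
expected1 = round(T * n1 / (n1 + n2)) (half away from zero, complement by
subtraction so the margin is preserved) and the cell p-value is the
two-tailed Fisher exact test of [[obs1, obs2], [expected1, expected2]].
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exact import fisher_p_two_sided
from .io import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["LENGTH_CLASSES", "classify_cnvs", "observed_vs_expected_test", "burden_table"]

LENGTH_CLASSES = ("5-100kb", "100-500kb", "500kb-1Mb", ">1Mb")
_LENGTH_EDGES = (5_000, 100_000, 500_000, 1_000_000)


def classify_cnvs(cnvs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each CNV with its length class and genic flag.

    Events shorter than 5 kb should not reach this stage (the raw-call
    filter removes them); they are classified into the lowest bin with a
    warning rather than rejected.
    """
    lengths = cnvs["end"].to_numpy() - cnvs["start"].to_numpy()
    if (lengths < _LENGTH_EDGES[0]).any():
        logger.warning("%d CNV(s) shorter than 5 kb reached burden classification",
                       int((lengths < _LENGTH_EDGES[0]).sum()))
    idx = np.searchsorted(_LENGTH_EDGES[1:], lengths, side="right")
    out = cnvs.copy()
    out["length_class"] = np.asarray(LENGTH_CLASSES)[idx]

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]))
    genic = np.zeros(len(cnvs), dtype=bool)
    pos = 0
    for rec in cnvs.itertuples(index=False):
        tree = trees.get(rec.chrom)
        genic[pos] = bool(tree is not None and tree.overlaps(rec.start, rec.end))
        pos += 1
    out["genic"] = genic
    return out


def observed_vs_expected_test(obs1: int, obs2: int, n1: int, n2: int) -> float:
    """Observed-vs-expected two-tailed Fisher comparison of two groups.

    ``n1`` and ``n2`` are the group sample sizes; the expected split of
    the ``obs1 + obs2`` observed events is proportional to them, rounded
    to the nearest integer (half away from zero) with the complement
    defined by subtraction. Zero observed events give p = 1.
    """
    if min(obs1, obs2) < 0 or min(n1, n2) <= 0:
        raise ValidationError("counts must be non-negative and group sizes positive")
    total = obs1 + obs2
    if total == 0:
        return 1.0
    expected1 = int(math.floor(total * n1 / (n1 + n2) + 0.5))
    expected2 = total - expected1
    return fisher_p_two_sided(obs1, obs2, expected1, expected2)


def burden_table(
    cnvs: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    group_by: str = "CD_vs_UC",
) -> pd.DataFrame:
    """Full 3 (type) x 5 (length) x 3 (genic) burden grid with p-values.

    ``group_by`` selects the two groups being compared: ``"CD_vs_UC"``
    restricts to case samples split by subtype; ``"case_vs_control"``
    uses the whole cohort. Marginal cells ("all" type, "any" length,
    "all" genic) are sums of their partition cells by construction.
    """
    if group_by == "CD_vs_UC":
        universe = samples[samples["cohort"] == "case"]
        g1_ids = set(universe.loc[universe["subtype"] == "CD", "sample_id"])
        g2_ids = set(universe.loc[universe["subtype"] == "UC", "sample_id"])
        g1_name, g2_name = "CD", "UC"
    elif group_by == "case_vs_control":
        g1_ids = set(samples.loc[samples["cohort"] == "case", "sample_id"])
        g2_ids = set(samples.loc[samples["cohort"] == "control", "sample_id"])
        g1_name, g2_name = "case", "control"
    else:
        raise ValidationError(f"unknown group_by {group_by!r}")
    n1, n2 = len(g1_ids), len(g2_ids)
    if n1 == 0 or n2 == 0:
        raise ValidationError(f"group with zero samples in {group_by} comparison")

    ann = classify_cnvs(cnvs, genes)
    ann = ann[ann["sample_id"].isin(g1_ids | g2_ids)]
    in_g1 = ann["sample_id"].isin(g1_ids).to_numpy()

    rows = []
    for cnv_type in ("all", "deletion", "duplication"):
        type_mask = np.ones(len(ann), dtype=bool) if cnv_type == "all" \
            else (ann["cnv_type"] == cnv_type).to_numpy()
        for length_class in ("any", *LENGTH_CLASSES):
            len_mask = np.ones(len(ann), dtype=bool) if length_class == "any" \
                else (ann["length_class"] == length_class).to_numpy()
            for genic_class in ("all", "genic", "non-genic"):
                if genic_class == "all":
                    gen_mask = np.ones(len(ann), dtype=bool)
                elif genic_class == "genic":
                    gen_mask = ann["genic"].to_numpy()
                else:
                    gen_mask = ~ann["genic"].to_numpy()
                mask = type_mask & len_mask & gen_mask
                c1 = int((mask & in_g1).sum())
                c2 = int((mask & ~in_g1).sum())
                rows.append({
                    "cnv_type": cnv_type,
                    "length_class": length_class,
                    "genic_class": genic_class,
                    f"count_{g1_name}": c1,
                    f"count_{g2_name}": c2,
                    "n_group1": n1,
                    "n_group2": n2,
                    "p": observed_vs_expected_test(c1, c2, n1, n2),
                })
    return pd.DataFrame(rows)
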