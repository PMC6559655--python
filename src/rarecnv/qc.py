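"""Sample quality control.

Two exclusion stages bracket the CNV pipeline:

1. array-metric QC before any CNV analysis — minimum genotype call rate
   plus per-batch outlier bands (mean +/- k*SD) on the per-sample log R
   ratio and B allele frequency standard deviations;
2. CNV-count QC after consensus merging — samples contributing more
   stringent CNVs than their batch mean + k*SD are dropped (one-sided:
   an unusually *low* CNV count is not an exclusion).

Outlier statistics use the sample standard deviation (n - 1 denominator),
are computed once on the full batch (no iterative re-computation), and do
not depend on sample order. Sex-inconsistency / relatedness removals are
accepted as an external exclusion list, not recomputed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["QcDecision", "array_metric_qc", "cnv_count_qc", "decisions_from_frame"]

QC_REASONS = ("low_call_rate", "lrr_sd_outlier", "baf_sd_outlier", "cnv_count_outlier")


@dataclass(frozen=True)
class QcDecision:
    sample_id: str
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def decisions_from_frame(report: pd.DataFrame) -> list[QcDecision]:
    """Collapse a QC report frame into per-sample decisions."""
    out = []
    for rec in report.itertuples(index=False):
        reasons = tuple(r for r in QC_REASONS if getattr(rec, r, False))
        out.append(QcDecision(rec.sample_id, len(reasons) == 0, reasons))
    return out


def array_metric_qc(
    samples: pd.DataFrame,
    min_call_rate: float = 0.95,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """Array-metric QC: call rate plus per-batch LRR/BAF SD bands.

    A sample fails if its call rate is below ``min_call_rate`` or its
    ``lrr_sd`` (resp. ``baf_sd``) falls outside ``[mean - k_sd*SD,
    mean + k_sd*SD]`` computed over all samples of its batch. Every
    failing reason is recorded. A batch of one sample has no defined SD;
    its sample passes the SD criteria with a logged warning.

    Returns a report frame: one row per sample with metric values, batch
    bands, per-reason booleans and ``passed``.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be non-negative")
    report = samples[["sample_id", "batch", "call_rate", "lrr_sd", "baf_sd"]].copy()
    report["low_call_rate"] = report["call_rate"] < min_call_rate

    for metric in ("lrr_sd", "baf_sd"):
        grp = report.groupby("batch")[metric]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # ddof=1; NaN for singleton batches
        lo, hi = mean - k_sd * sd, mean + k_sd * sd
        # round-off guard: a degenerate band (SD = 0) must not flag values
        # numerically equal to the mean
        tol = 1e-9 * (mean.abs() + 1.0)
        outlier = (report[metric] < lo - tol) | (report[metric] > hi + tol)
        outlier &= sd.notna()
        report[f"{metric}_lo"] = lo
        report[f"{metric}_hi"] = hi
        report[f"{metric}_outlier"] = outlier

    singleton = report.groupby("batch")["sample_id"].transform("size") == 1
    if singleton.any():
        logger.warning("batch(es) of size 1: SD criteria undefined, passing %d sample(s)",
                       int(singleton.sum()))

    report["passed"] = ~(report["low_call_rate"] | report["lrr_sd_outlier"]
                         | report["baf_sd_outlier"])
    reasons = []
    for rec in report.itertuples(index=False):
        reasons.append(",".join(r for r in ("low_call_rate", "lrr_sd_outlier", "baf_sd_outlier")
                                if getattr(rec, r)))
    report["reasons"] = reasons
    return report.reset_index(drop=True)


def cnv_count_qc(
    cnv_counts: Mapping[str, int] | pd.Series,
    batch_of: Mapping[str, str] | pd.Series,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """CNV-count outlier removal after consensus merging.

    ``cnv_counts`` maps every post-merge sample (including zero-CNV
    samples) to its stringent CNV count; a sample fails iff its count
    exceeds ``batch mean + k_sd * SD``. Single pass — the batch statistics
    are not recomputed after exclusions.
    """
    counts = pd.Series(dict(cnv_counts), name="cnv_count")
    if counts.empty:
        raise ValidationError("cnv_count_qc: no samples supplied")
    batches = pd.Series(dict(batch_of))
    missing = counts.index.difference(batches.index)
    if len(missing):
        raise ValidationError(f"cnv_count_qc: no batch for sample(s) {sorted(missing)[:5]}")
    report = pd.DataFrame({
        "sample_id": counts.index.astype(str),
        "batch": batches.reindex(counts.index).astype(str).to_numpy(),
        "cnv_count": counts.to_numpy(dtype=np.int64),
    })
    grp = report.groupby("batch")["cnv_count"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    report["upper_bound"] = mean + k_sd * sd
    report["cnv_count_outlier"] = report["cnv_count"] > report["upper_bound"]
    report["passed"] = ~report["cnv_count_outlier"]
    report["reasons"] = np.where(report["cnv_count_outlier"], "cnv_count_outlier", "")
    return report.sort_values("sample_id", kind="mergesort").reset_index(drop=True)
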