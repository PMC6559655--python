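"""End-to-end stage chaining shared by the CLI, tests and scripts.

Stage order follows the analysis workflow funnel:

1. array-metric sample QC (call rate, LRR/BAF SD bands) + external
   exclusion list;
2. raw-call size/probe/quality filtering per caller;
3. >= 2-caller consensus merging into stringent CNVs;
4. genomic-context region exclusion (centromere/telomere buffers,
   segmental-duplication and immunoglobulin fractions);
5. CNV-count sample QC (counts of surviving stringent CNVs per sample);
6. per-gene carrier association with pooled FDR control and rare
   classification;
7. burden stratification (CD vs UC by default);
8. optional gene-set overrepresentation of associated genes against the
   CNV-overlapped background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .association import run_association
from .burden import burden_table
from .intervals import RegionTrack
from .io import GeneSetLibrary
from .merge import FilterReport, filter_raw_calls, merge_consensus
from .ora import run_ora
from .qc import array_metric_qc, cnv_count_qc
from .regions import apply_region_filters, build_buffer_tracks


@dataclass
class PipelineParams:
    """All thresholds of the pipeline, with the study defaults."""

    min_call_rate: float = 0.95
    qc_k_sd: float = 3.0
    min_size_bp: int = 5000
    min_probes: int = 5
    strict_gt: bool = False
    quality_thresholds: dict = field(default_factory=dict)
    min_callers: int = 2
    min_reciprocal_overlap: float = 0.0
    buffer_bp: int = 100_000
    segdup_max_frac: float = 0.70
    ig_max_frac: float = 0.70
    rare_control_freq: float = 0.001
    p_adj_threshold: float = 0.01
    ora_query_p_adj: float = 0.05
    ora_p_adj_threshold: float = 0.25
    ora_min_overlap: int = 2


@dataclass
class PipelineResult:
    samples_pass: pd.DataFrame
    array_qc: pd.DataFrame
    filter_report: FilterReport
    stringent: pd.DataFrame
    region_removed: pd.DataFrame
    cnv_count_qc: pd.DataFrame
    cnvs: pd.DataFrame                 # stringent CNVs of samples passing all QC
    association: pd.DataFrame
    burden: pd.DataFrame
    ora: pd.DataFrame | None
    funnel: dict[str, int]


def run_pipeline(
    samples: pd.DataFrame,
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    centromeres: RegionTrack,
    chrom_lengths: Mapping[str, int],
    segdups: RegionTrack | None = None,
    immunoglobulin: RegionTrack | None = None,
    gene_set_libraries: Sequence[GeneSetLibrary] = (),
    exclude_samples: Sequence[str] = (),
    params: PipelineParams | None = None,
    burden_group_by: str = "CD_vs_UC",
) -> PipelineResult:
    """Run the whole case-control rare-CNV analysis in memory."""
    p = params or PipelineParams()
    funnel: dict[str, int] = {"samples_in": len(samples), "raw_calls_in": len(calls)}

    qc1 = array_metric_qc(samples, p.min_call_rate, p.qc_k_sd)
    passing = set(qc1.loc[qc1["passed"], "sample_id"]) - set(exclude_samples)
    samples1 = samples[samples["sample_id"].isin(passing)].reset_index(drop=True)
    funnel["samples_after_array_qc"] = len(samples1)

    calls1 = calls[calls["sample_id"].isin(passing)].reset_index(drop=True)
    calls2, filt_report = filter_raw_calls(
        calls1, p.min_size_bp, p.min_probes, p.quality_thresholds, p.strict_gt)
    funnel["raw_calls_after_filter"] = len(calls2)

    stringent = merge_consensus(calls2, samples1, p.min_callers, p.min_reciprocal_overlap)
    funnel["stringent_cnvs"] = len(stringent)

    cen_tel = build_buffer_tracks(centromeres, chrom_lengths, p.buffer_bp)
    kept, removed = apply_region_filters(
        stringent, cen_tel, segdups, immunoglobulin,
        p.segdup_max_frac, p.ig_max_frac)
    funnel["stringent_after_region_filter"] = len(kept)

    counts = kept.groupby("sample_id").size().reindex(
        samples1["sample_id"], fill_value=0)
    batch_of = samples1.set_index("sample_id")["batch"]
    qc2 = cnv_count_qc(counts, batch_of, p.qc_k_sd)
    passing2 = set(qc2.loc[qc2["passed"], "sample_id"])
    samples2 = samples1[samples1["sample_id"].isin(passing2)].reset_index(drop=True)
    cnvs = kept[kept["sample_id"].isin(passing2)].reset_index(drop=True)
    funnel["samples_after_cnv_count_qc"] = len(samples2)
    funnel["stringent_final"] = len(cnvs)

    association = run_association(
        cnvs, genes, samples2, p.rare_control_freq, p.p_adj_threshold)
    funnel["association_tests"] = len(association)

    burden = burden_table(cnvs, genes, samples2, burden_group_by)

    ora = None
    if gene_set_libraries:
        query = set(association.loc[association["p_adj"] <= p.ora_query_p_adj, "gene_id"])
        background = set(association["gene_id"])
        if query and background:
            ora = run_ora(query, background, list(gene_set_libraries),
                          p.ora_p_adj_threshold, p.ora_min_overlap)

    return PipelineResult(samples2, qc1, filt_report, stringent, removed, qc2,
                          cnvs, association, burden, ora, funnel)
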