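"""Seeded synthetic case-control CNV studies with known ground truth.

The generator emulates the statistical structure of a SNP-array rare-CNV
case-control study: a cohort of ~243 cases (CD/UC subtypes) against
~2,988 controls, three CNV callers observing the same underlying events
with per-caller dropout and breakpoint jitter plus caller-specific false
positives, an event length distribution dominated by sub-100 kb CNVs
(~88%) with a deletion excess (~65%), and — optionally — *planted*
rare case-enriched CNVs at designated genes with exact carrier counts.

Design properties the pipeline tests rely on:

* truth CNVs of the same sample and type never overlap (after jitter), so
  the consensus of a noiseless study reproduces the truth set exactly;
* false positives are single-caller by construction — they are placed so
  that no same-sample same-type call from another caller overlaps them —
  and must therefore be removed by the >= 2-caller consensus rule;
* background events and false positives avoid the planted genes entirely,
  and planted CNVs always reach >= 2 callers, so post-pipeline carrier
  counts at planted genes equal the configured counts;
* byte-identical outputs for identical (config, seed): each stochastic
  component (placement, lengths, emission, jitter, false positives,
  manifest metrics) draws from its own child stream of the master seed.

Probe positions are implicit: a uniform probe density converts lengths to
probe counts (``n_probes = floor(length * density)``).
"""

from __future__ import annotations

import bisect
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .intervals import RegionTrack

__all__ = [
    "PlantedSignal",
    "SimulationConfig",
    "SyntheticStudy",
    "default_planted_signals",
    "generate_study",
    "generate_qc_outliers",
    "write_study",
]

#: carrier profile (type, case carriers, control carriers) of the rare
#: disease-associated genes used as the default planted-signal panel
DEFAULT_PLANTED_PROFILE: tuple[tuple[str, int, int], ...] = (
    ("deletion", 12, 1),
    ("deletion", 4, 0),
    ("deletion", 4, 0),
    ("duplication", 5, 2),
    ("duplication", 5, 2),
    ("duplication", 4, 0),
    ("duplication", 4, 0),
    ("duplication", 5, 0),
    ("duplication", 4, 0),
    ("duplication", 4, 0),
    ("duplication", 4, 0),
    ("duplication", 4, 0),
)


@dataclass(frozen=True)
class PlantedSignal:
    """A case-enriched CNV signal planted at one gene with exact counts."""

    gene_id: str | None
    cnv_type: str
    n_case_carriers: int
    n_control_carriers: int


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target study design: 243 cases (120 CD / 123 UC)
    vs 2,988 controls, ~18 consensus-detectable CNVs per sample, 88% of
    events below 100 kb, 65% deletions, three callers of slightly
    different sensitivity with a few hundred bp of breakpoint jitter and
    roughly one spurious single-caller call per sample per caller.
    """

    seed: int = 0
    n_cases: int = 243
    n_controls: int = 2988
    n_cd: int | None = 120
    n_chromosomes: int = 8
    chrom_length_bp: int = 25_000_000
    n_genes: int = 640
    background_cnv_rate_per_sample: float = 18.1
    length_class_weights: tuple[float, ...] = (0.881, 0.108, 0.0075, 0.0035)
    length_class_bounds: tuple[tuple[int, int], ...] = (
        (5_000, 100_000), (100_000, 500_000), (500_000, 1_000_000),
        (1_000_000, 3_000_000))
    deletion_fraction: float = 0.65
    caller_sensitivity: Mapping[str, float] = field(default_factory=lambda: {
        "caller_A": 0.95, "caller_B": 0.93, "caller_C": 0.90})
    breakpoint_jitter_sd_bp: float = 300.0
    caller_fp_rate: float = 1.0
    probe_density_per_bp: float = 1.0 / 1000.0
    n_batches: int = 4
    planted_signals: tuple[PlantedSignal, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.background_cnv_rate_per_sample < 0 or self.caller_fp_rate < 0:
            raise ValueError("rates must be non-negative")
        for caller, s in self.caller_sensitivity.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"sensitivity for {caller} must be in (0, 1]")
        for sig in self.planted_signals:
            if sig.n_case_carriers > self.n_cases or \
                    sig.n_control_carriers > self.n_controls:
                raise ValueError(f"planted signal {sig.gene_id}: more carriers than samples")


@dataclass
class SyntheticStudy:
    """All generated inputs plus the ground truth."""

    config: SimulationConfig
    samples: pd.DataFrame
    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    centromeres: RegionTrack
    segdups: RegionTrack
    immunoglobulin: RegionTrack
    calls: pd.DataFrame          # CALL_COLUMNS + is_fp + truth_id
    truth: pd.DataFrame          # truth_id, sample_id, chrom, start, end, cnv_type, planted_gene
    planted_counts: pd.DataFrame
    qc_truth: dict[str, list[str]] = field(default_factory=dict)


def default_planted_signals(n: int | None = None) -> tuple[PlantedSignal, ...]:
    """The default planted panel (gene assignment left to the generator)."""
    profile = DEFAULT_PLANTED_PROFILE if n is None else DEFAULT_PLANTED_PROFILE[:n]
    return tuple(PlantedSignal(None, t, a, c) for t, a, c in profile)


# -- internal helpers --------------------------------------------------

_PLANT_LEN_RANGE = (10_000, 110_000)   # planted CNV lengths (log-uniform)
_PLANT_MIN_OVERLAP = 2_000             # bp of gene overlap preserved pre-jitter
_FP_LEN_RANGE = (5_000, 80_000)
_GENE_LEN_RANGE = (10_000, 100_000)
_EXCLUSION_MARGIN = 150_000            # genes are kept this far from excluded regions


class _Occupancy:
    """Sorted non-overlapping occupied intervals per (sample, chrom, type)."""

    def __init__(self) -> None:
        self._d: dict[tuple[str, str, str], tuple[list[int], list[int]]] = {}

    def overlaps(self, key, start: int, end: int) -> bool:
        entry = self._d.get(key)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start

    def add(self, key, start: int, end: int) -> None:
        starts, ends = self._d.setdefault(key, ([], []))
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _mixture_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    comp = rng.choice(len(cfg.length_class_weights), size=n,
                      p=np.asarray(cfg.length_class_weights)
                      / sum(cfg.length_class_weights))
    u = rng.random(n)
    lo = np.array([b[0] for b in cfg.length_class_bounds], dtype=float)
    hi = np.array([b[1] for b in cfg.length_class_bounds], dtype=float)
    return np.exp(np.log(lo[comp]) + u * (np.log(hi[comp]) - np.log(lo[comp]))).astype(np.int64)


def _build_genome(cfg: SimulationConfig, rng: np.random.Generator):
    L = cfg.chrom_length_bp
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    lengths = {c: L for c in chroms}
    centromeres = RegionTrack.from_records(
        "centromere", [(c, L // 2 - 250_000, L // 2 + 250_000) for c in chroms])
    segdup_recs = []
    for c in chroms:
        for frac in (0.18, 0.62, 0.86):
            s = int(L * frac) + int(rng.integers(-200_000, 200_000))
            segdup_recs.append((c, s, s + int(rng.integers(50_000, 200_000))))
    segdups = RegionTrack.from_records("segdup", segdup_recs)
    ig = RegionTrack.from_records(
        "immunoglobulin", [(chroms[-1], int(L * 0.75), int(L * 0.75) + 300_000)])
    return chroms, lengths, centromeres, segdups, ig


def _place_genes(cfg: SimulationConfig, chroms, lengths, excluded: RegionTrack,
                 rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = math.ceil(cfg.n_genes / len(chroms))
    rows = []
    gene_no = 0
    for chrom in chroms:
        L = lengths[chrom]
        spacing = L // (per_chrom + 1)
        for slot in range(1, per_chrom + 1):
            if gene_no >= cfg.n_genes:
                break
            center = slot * spacing
            glen = int(rng.integers(*_GENE_LEN_RANGE))
            start = center - glen // 2
            end = start + glen
            if start < 0 or end > L:
                continue
            if excluded.overlaps_any(chrom, [start - _EXCLUSION_MARGIN],
                                     [end + _EXCLUSION_MARGIN])[0]:
                continue  # slot too close to an excluded region: skip it
            gene_no += 1
            rows.append((f"G{gene_no:04d}", chrom, start, end))
    if gene_no < len(cfg.planted_signals):
        raise ValueError("not enough placeable genes for the planted signals")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _build_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases + cfg.n_controls
    ids = [f"case_{i + 1:04d}" for i in range(cfg.n_cases)] + \
        [f"ctrl_{i + 1:04d}" for i in range(cfg.n_controls)]
    n_cd = cfg.n_cd if cfg.n_cd is not None else round(cfg.n_cases * 120 / 243)
    n_cd = min(n_cd, cfg.n_cases)
    subtype = ["CD"] * n_cd + ["UC"] * (cfg.n_cases - n_cd) + ["none"] * cfg.n_controls
    batches = np.array([f"B{(i % cfg.n_batches) + 1}" for i in range(n)])
    batches = batches[rng.permutation(n)]
    return pd.DataFrame({
        "sample_id": ids,
        "cohort": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
        "subtype": subtype,
        "batch": batches,
        "call_rate": np.clip(rng.normal(0.995, 0.002, n), 0.90, 1.0),
        "lrr_sd": np.clip(rng.normal(0.12, 0.02, n), 0.01, None),
        "baf_sd": np.clip(rng.normal(0.04, 0.008, n), 0.005, None),
    })


def _resolve_planted(cfg: SimulationConfig, genes: pd.DataFrame) -> list[PlantedSignal]:
    """Assign unassigned planted signals to evenly spaced genes."""
    signals = list(cfg.planted_signals)
    taken = {s.gene_id for s in signals if s.gene_id is not None}
    unknown = taken - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"planted gene(s) not in the gene panel: {sorted(unknown)}")
    free = [g for g in genes["gene_id"] if g not in taken]
    need = sum(1 for s in signals if s.gene_id is None)
    if need:
        step = max(1, len(free) // (need + 1))
        picks = [free[(i + 1) * step - 1] for i in range(need)]
        it = iter(picks)
        signals = [dataclasses.replace(s, gene_id=next(it)) if s.gene_id is None else s
                   for s in signals]
    return signals


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study (see module docstring)."""
    ss = np.random.SeedSequence(config.seed)
    (seq_genome, seq_manifest, seq_place, seq_len, seq_plant,
     seq_emit, seq_jitter, seq_fp, seq_qual, _seq_qc) = ss.spawn(10)
    rng_genome = np.random.default_rng(seq_genome)
    chroms, lengths, centromeres, segdups, ig = _build_genome(config, rng_genome)

    from .regions import build_buffer_tracks
    cen_tel = build_buffer_tracks(centromeres, lengths, 100_000)
    excluded = RegionTrack.from_records("excluded", [
        *cen_tel.to_records(), *segdups.to_records(), *ig.to_records()])

    genes = _place_genes(config, chroms, lengths, excluded, rng_genome)
    samples = _build_manifest(config, np.random.default_rng(seq_manifest))
    signals = _resolve_planted(config, genes)

    gene_ix = genes.set_index("gene_id")
    jitter_sd = config.breakpoint_jitter_sd_bp
    margin = int(4 * jitter_sd) + 2  # truth events stay this far apart

    planted_zone = RegionTrack.from_records("planted_zone", [
        (gene_ix.loc[s.gene_id, "chrom"],
         max(0, int(gene_ix.loc[s.gene_id, "start"]) - _PLANT_LEN_RANGE[1] - margin),
         int(gene_ix.loc[s.gene_id, "end"]) + _PLANT_LEN_RANGE[1] + margin)
        for s in signals]) if signals else RegionTrack("planted_zone")

    occupancy = _Occupancy()
    truth_rows: list[dict] = []

    # planted case-enriched events: exact carrier counts at target genes
    rng_plant = np.random.default_rng(seq_plant)
    case_ids = samples.loc[samples["cohort"] == "case", "sample_id"].to_numpy()
    ctrl_ids = samples.loc[samples["cohort"] == "control", "sample_id"].to_numpy()
    planted_carriers: set[str] = set()
    for sig in signals:
        g = gene_ix.loc[sig.gene_id]
        carriers = list(rng_plant.choice(case_ids, sig.n_case_carriers, replace=False)) + \
            list(rng_plant.choice(ctrl_ids, sig.n_control_carriers, replace=False))
        planted_carriers.update(carriers)
        for sample in carriers:
            length = int(np.exp(rng_plant.uniform(*np.log(_PLANT_LEN_RANGE))))
            lo = int(g["start"]) - (length - _PLANT_MIN_OVERLAP)
            hi = int(g["end"]) - _PLANT_MIN_OVERLAP
            start = int(rng_plant.integers(min(lo, hi), max(lo, hi) + 1))
            start = max(0, start)
            end = start + length
            truth_rows.append({
                "sample_id": sample, "chrom": g["chrom"], "start": start,
                "end": end, "cnv_type": sig.cnv_type, "planted_gene": sig.gene_id})
            occupancy.add((sample, g["chrom"], sig.cnv_type),
                          start - margin, end + margin)

    # Planted carrier counts define the *analyzed* cohort: carrier samples
    # get nominal array metrics and a nominal background CNV load so that
    # sample QC never erodes the configured counts.
    if planted_carriers:
        is_carrier = samples["sample_id"].isin(planted_carriers)
        samples.loc[is_carrier, "call_rate"] = 0.996
        samples.loc[is_carrier, "lrr_sd"] = 0.12
        samples.loc[is_carrier, "baf_sd"] = 0.04

    # background events: uniform placement avoiding planted loci
    rng_place = np.random.default_rng(seq_place)
    rng_len = np.random.default_rng(seq_len)
    n_samples_total = len(samples)
    bg_counts = rng_place.poisson(config.background_cnv_rate_per_sample, n_samples_total)
    if planted_carriers:
        bg_counts[samples["sample_id"].isin(planted_carriers).to_numpy()] = \
            int(round(config.background_cnv_rate_per_sample))
    n_bg = int(bg_counts.sum())
    bg_samples = np.repeat(samples["sample_id"].to_numpy(), bg_counts)
    bg_chrom = np.asarray(chroms)[rng_place.integers(0, len(chroms), n_bg)]
    bg_len = _mixture_lengths(rng_len, n_bg, config)
    bg_type = np.where(rng_place.random(n_bg) < config.deletion_fraction,
                       "deletion", "duplication")
    L = config.chrom_length_bp
    for i in range(n_bg):
        sample, chrom, length, cnv_type = bg_samples[i], bg_chrom[i], int(bg_len[i]), bg_type[i]
        length = min(length, L - 2)
        key = (sample, chrom, cnv_type)
        for _attempt in range(1000):
            start = int(rng_place.integers(0, L - length))
            end = start + length
            if planted_zone.overlaps_any(chrom, [start], [end])[0]:
                continue
            if occupancy.overlaps(key, start - margin, end + margin):
                continue
            break
        else:
            continue  # genome too crowded for this event; drop it
        truth_rows.append({"sample_id": sample, "chrom": chrom, "start": start,
                           "end": end, "cnv_type": cnv_type, "planted_gene": ""})
        occupancy.add(key, start - margin, end + margin)

    truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "chrom", "start", "end", "cnv_type", "planted_gene"])
    truth.insert(0, "truth_id", np.arange(len(truth)))

    calls = _emit_calls(config, truth, gene_ix, lengths,
                        np.random.default_rng(seq_emit),
                        np.random.default_rng(seq_jitter),
                        np.random.default_rng(seq_qual))
    fps = _emit_false_positives(config, samples, chroms, planted_zone, occupancy,
                                np.random.default_rng(seq_fp))
    if len(fps):
        calls = pd.concat([calls, fps], ignore_index=True)
    calls = calls.sort_values(["caller", "sample_id", "chrom", "start", "end"],
                              kind="mergesort").reset_index(drop=True)

    planted_counts = pd.DataFrame(
        [(s.gene_id, s.cnv_type, s.n_case_carriers, s.n_control_carriers)
         for s in signals],
        columns=["gene_id", "cnv_type", "n_case_carriers", "n_control_carriers"])
    return SyntheticStudy(config, samples, lengths, genes, centromeres, segdups,
                          ig, calls, truth, planted_counts)


def _emit_calls(cfg, truth, gene_ix, chrom_lengths, rng_emit, rng_jitter, rng_qual):
    """Per-caller emission of truth events with dropout and jitter."""
    callers = list(rio.CALLERS)
    sens = np.array([cfg.caller_sensitivity.get(c, 1.0) for c in callers])
    n = len(truth)
    present = rng_emit.random((n, len(callers))) < sens[None, :]
    planted = (truth["planted_gene"].to_numpy() != "")
    # planted events always reach the 2-caller consensus: redraw thin emissions
    short = planted & (present.sum(axis=1) < 2)
    for i in np.flatnonzero(short):
        pick = rng_emit.choice(len(callers), 2, replace=False)
        present[i, :] = False
        present[i, pick] = True

    sd = cfg.breakpoint_jitter_sd_bp
    rows = []
    g_start = np.full(n, -1, dtype=np.int64)
    g_end = np.full(n, -1, dtype=np.int64)
    has_gene = planted
    if has_gene.any():
        pg = truth.loc[has_gene, "planted_gene"]
        g_start[has_gene] = gene_ix.loc[pg, "start"].to_numpy()
        g_end[has_gene] = gene_ix.loc[pg, "end"].to_numpy()

    t_sample = truth["sample_id"].to_numpy()
    t_chrom = truth["chrom"].to_numpy()
    t_start = truth["start"].to_numpy()
    t_end = truth["end"].to_numpy()
    t_type = truth["cnv_type"].to_numpy()
    t_id = truth["truth_id"].to_numpy()
    for ci, caller in enumerate(callers):
        idx = np.flatnonzero(present[:, ci])
        m = idx.size
        if sd > 0:
            js = np.rint(np.clip(rng_jitter.normal(0, sd, m), -4 * sd, 4 * sd)).astype(np.int64)
            je = np.rint(np.clip(rng_jitter.normal(0, sd, m), -4 * sd, 4 * sd)).astype(np.int64)
        else:
            js = je = np.zeros(m, dtype=np.int64)
        s = t_start[idx] + js
        e = t_end[idx] + je
        Ls = np.array([chrom_lengths[c] for c in t_chrom[idx]], dtype=np.int64)
        s = np.clip(s, 0, None)
        e = np.minimum(e, Ls)
        # planted calls keep >= 1 bp of gene overlap
        gm = has_gene[idx]
        s[gm] = np.minimum(s[gm], g_end[idx][gm] - 1)
        e[gm] = np.maximum(e[gm], g_start[idx][gm] + 1)
        # enforce minimum size so emitted calls survive the raw-call filter
        shorty = (e - s) < 5000
        e[shorty] = np.minimum(s[shorty] + 5000, Ls[shorty])
        s[shorty] = e[shorty] - 5000
        probes = np.maximum(1, np.floor((e - s) * cfg.probe_density_per_bp)).astype(np.int64)
        rows.append(pd.DataFrame({
            "sample_id": t_sample[idx], "chrom": t_chrom[idx],
            "start": s, "end": e, "cnv_type": t_type[idx],
            "n_probes": probes,
            "quality": np.round(rng_qual.lognormal(3.0, 0.5, m), 3),
            "caller": caller, "is_fp": False, "truth_id": t_id[idx]}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=rio.CALL_COLUMNS + ["is_fp", "truth_id"])


def _emit_false_positives(cfg, samples, chroms, planted_zone, occupancy, rng):
    """Caller-specific spurious calls, guaranteed single-caller."""
    rows = []
    L = cfg.chrom_length_bp
    sample_ids = samples["sample_id"].to_numpy()
    for caller in rio.CALLERS:
        counts = rng.poisson(cfg.caller_fp_rate, len(sample_ids))
        for sample, k in zip(sample_ids, counts):
            for _ in range(int(k)):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                length = int(np.exp(rng.uniform(*np.log(_FP_LEN_RANGE))))
                cnv_type = "deletion" if rng.random() < cfg.deletion_fraction \
                    else "duplication"
                key = (sample, chrom, cnv_type)
                for _attempt in range(1000):
                    start = int(rng.integers(0, L - length))
                    end = start + length
                    if planted_zone.overlaps_any(chrom, [start], [end])[0]:
                        continue
                    if occupancy.overlaps(key, start, end):
                        continue
                    break
                else:
                    continue
                occupancy.add(key, start, end)
                rows.append({
                    "sample_id": sample, "chrom": chrom, "start": start,
                    "end": end, "cnv_type": cnv_type,
                    "n_probes": max(1, int(length * cfg.probe_density_per_bp)),
                    "quality": round(float(rng.lognormal(3.0, 0.5)), 3),
                    "caller": caller, "is_fp": True, "truth_id": -1})
    return pd.DataFrame(rows, columns=rio.CALL_COLUMNS + ["is_fp", "truth_id"])


def generate_qc_outliers(
    config: SimulationConfig,
    n_cnv_outliers: int = 3,
    n_low_call_rate: int = 2,
    extra_cnvs: int = 80,
) -> SyntheticStudy:
    """A study with planted QC failures recorded in ``qc_truth``.

    ``n_low_call_rate`` case samples get a 90% genotype call rate (below
    the 95% threshold); ``n_cnv_outliers`` other case samples each gain
    ``extra_cnvs`` additional consensus-detectable CNVs, pushing their
    counts far (>> 3 SD) above the batch mean.
    """
    study = generate_study(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(10)[9])
    cases = study.samples.loc[study.samples["cohort"] == "case", "sample_id"].to_numpy()
    if n_low_call_rate + n_cnv_outliers > cases.size:
        raise ValueError("more planted QC outliers than case samples")
    picked = rng.choice(cases, n_low_call_rate + n_cnv_outliers, replace=False)
    low_cr = sorted(picked[:n_low_call_rate])
    high_cnv = sorted(picked[n_low_call_rate:])

    study.samples.loc[study.samples["sample_id"].isin(low_cr), "call_rate"] = 0.90

    chroms = sorted(study.chrom_lengths)
    occupancy = _Occupancy()
    for rec in study.truth.itertuples(index=False):
        occupancy.add((rec.sample_id, rec.chrom, rec.cnv_type), rec.start, rec.end)
    planted_zone = RegionTrack.from_records("planted_zone", [
        (study.genes.set_index("gene_id").loc[g, "chrom"],
         max(0, int(study.genes.set_index("gene_id").loc[g, "start"]) - 200_000),
         int(study.genes.set_index("gene_id").loc[g, "end"]) + 200_000)
        for g in study.planted_counts["gene_id"]]) if len(study.planted_counts) \
        else RegionTrack("planted_zone")

    new_truth, new_calls = [], []
    next_id = int(study.truth["truth_id"].max()) + 1 if len(study.truth) else 0
    L = config.chrom_length_bp
    for sample in high_cnv:
        for _ in range(extra_cnvs):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(6_000, 40_000))
            cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
            key = (sample, chrom, cnv_type)
            for _attempt in range(1000):
                start = int(rng.integers(0, L - length))
                end = start + length
                if planted_zone.overlaps_any(chrom, [start], [end])[0]:
                    continue
                if occupancy.overlaps(key, start - 2, end + 2):
                    continue
                break
            else:
                continue
            occupancy.add(key, start, end)
            new_truth.append({"truth_id": next_id, "sample_id": sample, "chrom": chrom,
                              "start": start, "end": end, "cnv_type": cnv_type,
                              "planted_gene": ""})
            for caller in rio.CALLERS:  # emitted by all callers: survives consensus
                new_calls.append({
                    "sample_id": sample, "chrom": chrom, "start": start, "end": end,
                    "cnv_type": cnv_type,
                    "n_probes": max(1, int(length * config.probe_density_per_bp)),
                    "quality": round(float(rng.lognormal(3.0, 0.5)), 3),
                    "caller": caller, "is_fp": False, "truth_id": next_id})
            next_id += 1
    if new_truth:
        study.truth = pd.concat([study.truth, pd.DataFrame(new_truth)], ignore_index=True)
        study.calls = pd.concat([study.calls, pd.DataFrame(new_calls)], ignore_index=True)
        study.calls = study.calls.sort_values(
            ["caller", "sample_id", "chrom", "start", "end"],
            kind="mergesort").reset_index(drop=True)
    study.qc_truth = {"low_call_rate": list(low_cr), "cnv_count_outlier": list(high_cnv)}
    return study


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Serialize a study to the pipeline's on-disk input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["manifest"] = outdir / "manifest.tsv"
    rio.write_samples(study.samples, paths["manifest"])
    paths["genes"] = outdir / "genes.bed"
    rio.write_genes(study.genes, paths["genes"])
    paths["chrom_lengths"] = outdir / "chrom_lengths.tsv"
    rio.write_chrom_lengths(study.chrom_lengths, paths["chrom_lengths"])
    for name, track in (("centromeres", study.centromeres),
                        ("segdups", study.segdups),
                        ("immunoglobulin", study.immunoglobulin)):
        paths[name] = outdir / f"{name}.bed"
        rio.write_regions(track, paths[name])
    for caller in rio.CALLERS:
        sub = study.calls[study.calls["caller"] == caller]
        paths[f"calls_{caller}"] = outdir / f"calls_{caller}.tsv"
        rio.write_caller_calls(sub, paths[f"calls_{caller}"])
    paths["truth"] = outdir / "truth.tsv"
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["truth_summary"] = outdir / "truth_summary.json"
    with open(paths["truth_summary"], "w") as fh:
        json.dump({
            "n_true_cnvs": int(len(study.truth)),
            "n_planted": int((study.truth["planted_gene"] != "").sum()),
            "planted_counts": study.planted_counts.to_dict("records"),
            "qc_truth": study.qc_truth,
        }, fh, indent=2)
    paths["config"] = outdir / "config.yaml"
    cfg = dataclasses.asdict(study.config)
    cfg["caller_sensitivity"] = dict(cfg["caller_sensitivity"])
    cfg["planted_signals"] = [dataclasses.asdict(s) for s in study.config.planted_signals]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths
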