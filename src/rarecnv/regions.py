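"""Genomic-context exclusion of stringent CNVs.

Array CNV calls concentrate artifacts near centromeres, telomeres,
segmental duplications and the somatically rearranging immunoglobulin
loci. Three rules remove them:

* any (>= 1 bp) overlap with a buffered centromere/telomere window
  (100 kb on either side of a centromere, the first and last 100 kb of a
  chromosome),
* more than 70% of the CNV's length inside segmental duplications,
* more than 70% inside immunoglobulin regions.

The fractional rules use strict ``>`` comparisons; a CNV at exactly the
threshold fraction is kept. Fractions are computed against the merged
(union) track, so how a track is split into sub-intervals is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import RegionTrack
from .io import ConfigError, ValidationError

__all__ = [
    "ExclusionRule",
    "overlap_fraction",
    "build_buffer_tracks",
    "apply_region_filters",
]

RULE_CENTROMERE_TELOMERE = "centromere_telomere"
RULE_SEGDUP = "segdup_fraction"
RULE_IG = "ig_fraction"


@dataclass(frozen=True)
class ExclusionRule:
    """One exclusion rule with its parameter (buffer bp or fraction)."""

    rule_id: str
    parameter: float

    def __post_init__(self) -> None:
        if self.rule_id in (RULE_SEGDUP, RULE_IG):
            if not 0.0 < self.parameter <= 1.0:
                raise ConfigError(f"{self.rule_id}: fraction must be in (0, 1]")
        elif self.parameter <= 0:
            raise ConfigError(f"{self.rule_id}: buffer must be positive")


def overlap_fraction(start: int, end: int, chrom: str, track: RegionTrack) -> float:
    """Fraction of a CNV's length covered by the (merged) track."""
    if end <= start:
        raise ValidationError("zero-length CNV has no overlap fraction")
    covered = track.intersect_lengths(chrom, [start], [end])[0]
    return float(covered) / float(end - start)


def build_buffer_tracks(
    centromeres: RegionTrack,
    chrom_lengths: Mapping[str, int],
    buffer_bp: int = 100_000,
) -> RegionTrack:
    """Buffered centromere + telomere exclusion windows.

    Every centromere interval is widened by ``buffer_bp`` on both sides
    (clipped to the chromosome); every chromosome in the length table
    additionally contributes its two terminal ``buffer_bp`` windows. A
    chromosome present in the centromere track but missing from the
    length table is a configuration error.
    """
    if buffer_bp <= 0:
        raise ConfigError("buffer_bp must be positive")
    records: list[tuple[str, int, int]] = []
    missing = [c for c in centromeres.chroms() if c not in chrom_lengths]
    if missing:
        raise ConfigError(f"centromere track has chromosome(s) without a length: {missing}")
    for chrom, length in chrom_lengths.items():
        records.append((chrom, 0, min(buffer_bp, length)))
        records.append((chrom, max(0, length - buffer_bp), length))
        cs, ce = centromeres.intervals(chrom)
        for s, e in zip(cs, ce):
            records.append((chrom, max(0, int(s) - buffer_bp), min(length, int(e) + buffer_bp)))
    return RegionTrack.from_records("centromere_telomere_buffer", records)


def apply_region_filters(
    cnvs: pd.DataFrame,
    cen_tel: RegionTrack,
    segdup: RegionTrack | None = None,
    ig: RegionTrack | None = None,
    segdup_max_frac: float = 0.70,
    ig_max_frac: float = 0.70,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition stringent CNVs into (kept, removed) by genomic context.

    ``cen_tel`` is the pre-buffered centromere/telomere track (see
    :func:`build_buffer_tracks`) and removes on any overlap; ``segdup`` /
    ``ig`` remove on overlap fraction strictly above their thresholds.
    Passing ``None`` for a fractional track disables that rule.

    The removed frame carries ``removed_by`` (first matching rule, in the
    order centromere/telomere, segdup, immunoglobulin) and ``rules`` (all
    matching rules, comma-joined). Every input row lands in exactly one of
    the two outputs.
    """
    if cen_tel is None:
        raise ConfigError("the buffered centromere/telomere track is required")
    for frac, name in ((segdup_max_frac, "segdup_max_frac"), (ig_max_frac, "ig_max_frac")):
        if not 0.0 < frac <= 1.0:
            raise ConfigError(f"{name} must be in (0, 1]")
    if len(cnvs) == 0:
        empty = cnvs.copy()
        removed = cnvs.copy()
        removed["removed_by"] = pd.Series(dtype=str)
        removed["rules"] = pd.Series(dtype=str)
        return empty, removed

    n = len(cnvs)
    hits = {RULE_CENTROMERE_TELOMERE: np.zeros(n, dtype=bool),
            RULE_SEGDUP: np.zeros(n, dtype=bool),
            RULE_IG: np.zeros(n, dtype=bool)}
    lengths = cnvs["end"].to_numpy() - cnvs["start"].to_numpy()
    if (lengths <= 0).any():
        raise ValidationError("zero-length CNV in region filtering")
    for chrom, idx in cnvs.groupby("chrom").indices.items():
        s = cnvs["start"].to_numpy()[idx]
        e = cnvs["end"].to_numpy()[idx]
        hits[RULE_CENTROMERE_TELOMERE][idx] = cen_tel.overlaps_any(chrom, s, e)
        if segdup is not None:
            frac = segdup.intersect_lengths(chrom, s, e) / (e - s)
            hits[RULE_SEGDUP][idx] = frac > segdup_max_frac
        if ig is not None:
            frac = ig.intersect_lengths(chrom, s, e) / (e - s)
            hits[RULE_IG][idx] = frac > ig_max_frac
    any_hit = hits[RULE_CENTROMERE_TELOMERE] | hits[RULE_SEGDUP] | hits[RULE_IG]

    order = (RULE_CENTROMERE_TELOMERE, RULE_SEGDUP, RULE_IG)
    removed_by = []
    all_rules = []
    for i in np.flatnonzero(any_hit):
        matched = [r for r in order if hits[r][i]]
        removed_by.append(matched[0])
        all_rules.append(",".join(matched))
    kept = cnvs.loc[~any_hit].reset_index(drop=True)
    removed = cnvs.loc[any_hit].reset_index(drop=True)
    removed["removed_by"] = removed_by
    removed["rules"] = all_rules
    return kept, removed
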