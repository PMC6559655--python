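"""Raw-call filtering and multi-caller consensus merging.

A "stringent CNV" is an event reported independently by at least two of
the three callers. Within each (sample, chromosome, CNV type) stratum the
filtered raw calls form an interval-overlap graph (edge iff >= 1 bp
shared); each connected component supported by >= 2 distinct callers is
emitted as one consensus CNV spanning the outermost union of its member
calls. Components seen by a single caller — however many calls it made —
are dropped. Deletions and duplications never co-merge.

Size/probe/quality filters apply to *raw* calls, before merging; the
merged union span is not re-filtered (a union can only be longer than its
members).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CALL_COLUMNS, STRINGENT_COLUMNS, ConfigError, ValidationError

__all__ = ["FilterReport", "filter_raw_calls", "merge_consensus"]


@dataclass
class FilterReport:
    """Removal counts per criterion (a call may fail several)."""

    n_input: int = 0
    n_kept: int = 0
    removed_short: int = 0
    removed_few_probes: int = 0
    removed_low_quality: int = 0
    quality_thresholds: dict = field(default_factory=dict)


def filter_raw_calls(
    calls: pd.DataFrame,
    min_size_bp: int = 5000,
    min_probes: int = 5,
    quality_thresholds: Mapping[str, float] | None = None,
    strict_gt: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Size / probe-content / quality filter on raw calls.

    A call is retained iff its length is at least ``min_size_bp`` (strictly
    greater when ``strict_gt``), it spans at least ``min_probes`` array
    probes, and — when a quality threshold is configured for its caller —
    its score meets that threshold. Callers without a configured threshold
    are not quality-filtered.
    """
    if min_size_bp < 0 or min_probes < 0:
        raise ConfigError("size/probe thresholds must be non-negative")
    quality_thresholds = dict(quality_thresholds or {})
    for caller, thr in quality_thresholds.items():
        if thr is not None and thr < 0:
            raise ConfigError(f"negative quality threshold for {caller!r}")

    length = calls["end"].to_numpy() - calls["start"].to_numpy()
    ok_size = length > min_size_bp if strict_gt else length >= min_size_bp
    ok_probes = calls["n_probes"].to_numpy() >= min_probes
    ok_quality = np.ones(len(calls), dtype=bool)
    for caller, thr in quality_thresholds.items():
        if thr is None:
            continue
        mask = calls["caller"].to_numpy() == caller
        ok_quality[mask] = calls["quality"].to_numpy()[mask] >= thr

    keep = ok_size & ok_probes & ok_quality
    report = FilterReport(
        n_input=len(calls),
        n_kept=int(keep.sum()),
        removed_short=int((~ok_size).sum()),
        removed_few_probes=int((~ok_probes).sum()),
        removed_low_quality=int((~ok_quality).sum()),
        quality_thresholds=quality_thresholds,
    )
    return calls.loc[keep].reset_index(drop=True), report


def _components_sweep(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Connected components of the >=1 bp interval-overlap graph.

    Intervals must be sorted by start. With half-open coordinates a new
    component begins exactly where an interval's start reaches the running
    maximum end of its predecessors.
    """
    comp = np.zeros(starts.size, dtype=np.int64)
    if starts.size == 0:
        return comp
    run_max = np.maximum.accumulate(ends)
    new_comp = np.empty(starts.size, dtype=bool)
    new_comp[0] = True
    new_comp[1:] = starts[1:] >= run_max[:-1]
    return np.cumsum(new_comp) - 1


def _components_reciprocal(starts: np.ndarray, ends: np.ndarray, min_frac: float) -> np.ndarray:
    """Union-find components under a reciprocal-overlap edge rule."""
    n = starts.size
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ov = min(ends[i], ends[j]) - max(starts[i], starts[j])
            if ov <= 0:
                continue
            if ov >= min_frac * (ends[i] - starts[i]) and ov >= min_frac * (ends[j] - starts[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def merge_consensus(
    calls: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    min_callers: int = 2,
    min_reciprocal_overlap: float = 0.0,
) -> pd.DataFrame:
    """Merge filtered raw calls into stringent consensus CNVs.

    Parameters
    ----------
    calls
        Filtered raw calls (``CALL_COLUMNS``) from all callers together.
    manifest
        Optional sample manifest; calls from samples absent from it raise
        :class:`ValidationError`.
    min_callers
        Minimum number of *distinct* callers per component (default 2).
    min_reciprocal_overlap
        0 (default) uses the any-overlap rule; a positive fraction
        requires reciprocal overlap of at least that fraction of both
        interval lengths for two calls to be linked (stricter matching;
        transitive closure still applies).

    Returns the stringent CNV frame (``STRINGENT_COLUMNS``), sorted by
    (sample_id, chrom, start, end, cnv_type). The consensus span is the
    outermost union min(start)..max(end) of the component's members;
    ``max_probes`` is the largest member probe count (reporting only).
    """
    if not 0.0 <= min_reciprocal_overlap <= 1.0:
        raise ConfigError("min_reciprocal_overlap must be in [0, 1]")
    if manifest is not None and len(calls):
        known = set(manifest["sample_id"])
        unknown = set(calls["sample_id"]) - known
        if unknown:
            raise ValidationError(f"calls from sample(s) absent from the manifest: "
                                  f"{sorted(unknown)[:5]}")
    if len(calls) == 0:
        return pd.DataFrame(columns=STRINGENT_COLUMNS)

    calls = calls.sort_values(["sample_id", "chrom", "cnv_type", "start", "end"],
                              kind="mergesort")
    rows = []
    for (sample, chrom, cnv_type), grp in calls.groupby(
            ["sample_id", "chrom", "cnv_type"], sort=True):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if min_reciprocal_overlap > 0.0:
            comp = _components_reciprocal(s, e, min_reciprocal_overlap)
        else:
            comp = _components_sweep(s, e)
        callers = grp["caller"].to_numpy()
        probes = grp["n_probes"].to_numpy()
        for cid in np.unique(comp):
            m = comp == cid
            supporting = sorted(set(callers[m]))
            if len(supporting) < min_callers:
                continue
            start, end = int(s[m].min()), int(e[m].max())
            rows.append({
                "sample_id": sample,
                "chrom": chrom,
                "start": start,
                "end": end,
                "cnv_type": cnv_type,
                "length": end - start,
                "n_callers": len(supporting),
                "callers": ",".join(supporting),
                "max_probes": int(probes[m].max()),
            })
    out = pd.DataFrame(rows, columns=STRINGENT_COLUMNS)
    return out.sort_values(["sample_id", "chrom", "start", "end", "cnv_type"],
                           kind="mergesort").reset_index(drop=True)
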