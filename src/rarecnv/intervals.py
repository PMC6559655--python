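"""Genomic-interval arithmetic on plain numpy arrays.

All coordinates are 0-based, half-open: an interval ``[start, end)`` covers
``end - start`` base pairs and two intervals overlap iff they share at least
one base, i.e. ``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["RegionTrack", "merge_intervals"]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of a set of half-open intervals.

    Returns sorted, disjoint intervals covering exactly the union of the
    input. Touching intervals ([0,10) and [10,20)) are coalesced; overlap
    fractions are unaffected either way since no base is double counted.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    # run-end detection: a new run starts where start > running max of ends
    run_max = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_max[:-1]
    idx = np.flatnonzero(new_run)
    out_s = s[idx]
    out_e = np.append(run_max[idx[1:] - 1], run_max[-1])
    return out_s, out_e


class RegionTrack:
    """A named union of genomic intervals, stored merged per chromosome.

    Intervals may be supplied overlapping or unsorted; they are merged on
    construction so that overlap fractions against the track are well
    defined (union semantics).
    """

    def __init__(self, name: str, intervals: Mapping[str, np.ndarray] | None = None):
        self.name = name
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                self._set_chrom(chrom, arr[:, 0], arr[:, 1])

    @classmethod
    def from_records(cls, name: str, records: Iterable[tuple[str, int, int]]) -> "RegionTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        track = cls(name)
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs, dtype=np.int64)
            track._set_chrom(chrom, arr[:, 0], arr[:, 1])
        return track

    def _set_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> None:
        if np.any(starts < 0):
            raise ValueError(f"track {self.name!r}: negative coordinate on {chrom}")
        if np.any(ends <= starts):
            raise ValueError(f"track {self.name!r}: empty or inverted interval on {chrom}")
        s, e = merge_intervals(starts, ends)
        self._starts[chrom] = s
        self._ends[chrom] = e
        self._cum[chrom] = np.concatenate(([0], np.cumsum(e - s)))

    # -- introspection -------------------------------------------------

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    @property
    def n_intervals(self) -> int:
        return sum(s.size for s in self._starts.values())

    @property
    def total_length(self) -> int:
        return int(sum(self._cum[c][-1] for c in self._cum))

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Merged (starts, ends) for one chromosome (empty arrays if absent)."""
        if chrom not in self._starts:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._starts[chrom], self._ends[chrom]

    def to_records(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms():
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield chrom, int(s), int(e)

    # -- queries -------------------------------------------------------

    def intersect_lengths(self, chrom: str, starts, ends) -> np.ndarray:
        """Base pairs of each query interval covered by the track.

        Vectorised: ``starts``/``ends`` are arrays of query intervals on
        ``chrom``; the result has the same shape.
        """
        q_s = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        q_e = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        out = np.zeros(q_s.size, dtype=np.int64)
        if chrom not in self._starts:
            return out
        t_s, t_e, cum = self._starts[chrom], self._ends[chrom], self._cum[chrom]
        # first track interval that could overlap (end > query start) and
        # first that cannot (start >= query end)
        i0 = np.searchsorted(t_e, q_s, side="right")
        i1 = np.searchsorted(t_s, q_e, side="left")
        hit = i1 > i0
        if np.any(hit):
            full = cum[i1[hit]] - cum[i0[hit]]
            left_clip = np.maximum(0, q_s[hit] - t_s[i0[hit]])
            right_clip = np.maximum(0, t_e[i1[hit] - 1] - q_e[hit])
            out[hit] = full - left_clip - right_clip
        return out

    def overlaps_any(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean per query: does it share >= 1 bp with the track?"""
        q_s = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        q_e = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(q_s.size, dtype=bool)
        t_s, t_e = self._starts[chrom], self._ends[chrom]
        i0 = np.searchsorted(t_e, q_s, side="right")
        i1 = np.searchsorted(t_s, q_e, side="left")
        return i1 > i0
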