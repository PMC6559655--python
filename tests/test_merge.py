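"""Raw-call filtering and consensus merging vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from rarecnv.io import CALL_COLUMNS, ConfigError, ValidationError
from rarecnv.merge import filter_raw_calls, merge_consensus

from conftest import make_calls, make_samples


def call(sample="S1", chrom="chr1", start=0, end=10_000, cnv_type="deletion",
         probes=8, quality=30.0, caller="caller_A"):
    return (sample, chrom, start, end, cnv_type, probes, quality, caller)


def random_calls(rng, n, sample="S1", chrom="chr1", cnv_type="deletion"):
    rows = []
    for _ in range(n):
        start = int(rng.integers(0, 500_000))
        length = int(rng.integers(5_000, 60_000))
        rows.append(call(sample, chrom, start, start + length,
                         cnv_type, caller=f"caller_{rng.choice(list('ABC'))}"))
    return make_calls(rows)


def oracle_components(calls: pd.DataFrame):
    """O(n^2) union-find over the >=1 bp pairwise overlap graph."""
    groups = {}
    for (sample, chrom, typ), grp in calls.groupby(["sample_id", "chrom", "cnv_type"]):
        idx = grp.index.to_numpy()
        parent = {i: i for i in idx}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in idx:
            for j in idx:
                if i < j and calls.at[i, "start"] < calls.at[j, "end"] \
                        and calls.at[j, "start"] < calls.at[i, "end"]:
                    parent[find(i)] = find(j)
        comps = {}
        for i in idx:
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            callers = {calls.at[i, "caller"] for i in members}
            if len(callers) >= 2:
                groups.setdefault((sample, chrom, typ), []).append((
                    min(calls.at[i, "start"] for i in members),
                    max(calls.at[i, "end"] for i in members),
                    frozenset(callers)))
    return {k: sorted(v) for k, v in groups.items()}


class TestFilterRawCalls:
    def test_size_boundary(self):
        calls = make_calls([call(end=4_999), call(end=5_000, sample="S2")])
        kept, report = filter_raw_calls(calls)
        assert list(kept["sample_id"]) == ["S2"]  # 4,999 bp removed, 5,000 kept
        assert report.removed_short == 1

    def test_strict_gt_excludes_exact_boundary(self):
        calls = make_calls([call(end=5_000), call(end=5_001, sample="S2")])
        kept, _ = filter_raw_calls(calls, strict_gt=True)
        assert list(kept["sample_id"]) == ["S2"]

    def test_probe_boundary_inclusive(self):
        calls = make_calls([call(probes=5), call(probes=4, sample="S2")])
        kept, report = filter_raw_calls(calls)
        assert list(kept["sample_id"]) == ["S1"]
        assert report.removed_few_probes == 1

    def test_quality_threshold_per_caller(self):
        calls = make_calls([call(quality=10, caller="caller_A"),
                            call(quality=10, caller="caller_B", sample="S2")])
        kept, _ = filter_raw_calls(calls, quality_thresholds={"caller_A": 15.0})
        assert list(kept["sample_id"]) == ["S2"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            filter_raw_calls(make_calls([call()]), quality_thresholds={"caller_A": -1})

    def test_matches_independent_predicate(self):
        rng = np.random.default_rng(2)
        rows = [call(start=int(rng.integers(0, 1000)),
                     end=int(rng.integers(1001, 20_000)),
                     probes=int(rng.integers(1, 12)),
                     quality=float(rng.uniform(0, 50)),
                     caller=f"caller_{rng.choice(list('ABC'))}")
                for _ in range(50)]
        calls = make_calls(rows)
        thr = {"caller_B": 20.0}
        kept, _ = filter_raw_calls(calls, 5000, 5, thr)
        expect = [(e - s >= 5000) and p >= 5 and
                  (c != "caller_B" or q >= 20.0)
                  for s, e, p, q, c in zip(calls["start"], calls["end"],
                                           calls["n_probes"], calls["quality"],
                                           calls["caller"])]
        pd.testing.assert_frame_equal(kept, calls.loc[expect].reset_index(drop=True))


class TestMergeConsensus:
    def test_union_of_two_callers(self):
        calls = make_calls([call(start=100, end=5200, caller="caller_A"),
                            call(start=120, end=5210, caller="caller_B")])
        merged = merge_consensus(calls)
        assert len(merged) == 1
        assert merged.loc[0, "start"] == 100 and merged.loc[0, "end"] == 5210
        assert merged.loc[0, "n_callers"] == 2
        assert merged.loc[0, "callers"] == "caller_A,caller_B"

    def test_single_caller_dropped(self):
        calls = make_calls([call(start=300, end=5400, caller="caller_A")])
        assert len(merge_consensus(calls)) == 0

    def test_same_caller_twice_does_not_qualify(self):
        calls = make_calls([call(start=0, end=6000, caller="caller_A"),
                            call(start=5000, end=11_000, caller="caller_A")])
        assert len(merge_consensus(calls)) == 0

    def test_transitive_chain_merges(self):
        calls = make_calls([
            call(start=0, end=6000, caller="caller_A"),
            call(start=5900, end=12_000, caller="caller_B"),
            call(start=11_900, end=18_000, caller="caller_A"),
        ])
        merged = merge_consensus(calls)
        assert len(merged) == 1
        assert (merged.loc[0, "start"], merged.loc[0, "end"]) == (0, 18_000)
        assert merged.loc[0, "callers"] == "caller_A,caller_B"

    def test_touching_intervals_do_not_merge(self):
        # half-open [0,6000) and [6000,12000) share no base
        calls = make_calls([call(start=0, end=6000, caller="caller_A"),
                            call(start=6000, end=12_000, caller="caller_B")])
        assert len(merge_consensus(calls)) == 0

    def test_types_never_co_merge(self):
        calls = make_calls([call(cnv_type="deletion", caller="caller_A"),
                            call(cnv_type="duplication", caller="caller_B")])
        assert len(merge_consensus(calls)) == 0

    def test_unknown_sample_rejected_against_manifest(self):
        calls = make_calls([call(sample="ghost")])
        with pytest.raises(ValidationError):
            merge_consensus(calls, manifest=make_samples())

    def test_idempotence_of_spans(self):
        rng = np.random.default_rng(9)
        calls = random_calls(rng, 60)
        merged = merge_consensus(calls)
        # merging the consensus spans (tagged with two fake callers each)
        rows = []
        for rec in merged.itertuples(index=False):
            rows.append(call(rec.sample_id, rec.chrom, rec.start, rec.end,
                             rec.cnv_type, caller="caller_A"))
            rows.append(call(rec.sample_id, rec.chrom, rec.start, rec.end,
                             rec.cnv_type, caller="caller_B"))
        again = merge_consensus(make_calls(rows))
        assert list(again["start"]) == list(merged["start"])
        assert list(again["end"]) == list(merged["end"])

    def test_no_same_stratum_overlap_in_output(self):
        rng = np.random.default_rng(12)
        calls = random_calls(rng, 150)
        merged = merge_consensus(calls)
        for _, grp in merged.groupby(["sample_id", "chrom", "cnv_type"]):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert np.all(starts[1:] >= ends[:-1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        frames = [random_calls(rng, int(rng.integers(5, 60)),
                               sample=f"S{k}",
                               cnv_type=rng.choice(["deletion", "duplication"]))
                  for k in range(3)]
        calls = pd.concat(frames, ignore_index=True)
        merged = merge_consensus(calls)
        expected = oracle_components(calls)
        got = {}
        for rec in merged.itertuples(index=False):
            got.setdefault((rec.sample_id, rec.chrom, rec.cnv_type), []).append(
                (rec.start, rec.end, frozenset(rec.callers.split(","))))
        got = {k: sorted(v) for k, v in got.items()}
        assert got == expected

    def test_empty_input(self):
        out = merge_consensus(make_calls([]))
        assert len(out) == 0
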