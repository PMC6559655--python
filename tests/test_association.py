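"""Gene carrier counting, association universe, rarity, subgroup tests."""

import numpy as np
import pandas as pd
import pytest

from rarecnv.association import (count_gene_carriers, run_association,
                                 subgroup_association)
from rarecnv.io import ValidationError

from conftest import make_calls, make_samples


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def cnv_frame(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "cnv_type"])
    df["length"] = df["end"] - df["start"]
    df["n_callers"] = 2
    df["callers"] = "caller_A,caller_B"
    df["max_probes"] = 9
    return df


GENES = gene_frame([("G1", "chr1", 10_000, 30_000), ("G2", "chr1", 100_000, 140_000),
                    ("G3", "chr2", 50_000, 60_000)])


class TestCarrierCounting:
    def test_one_bp_overlap_is_a_carrier(self):
        cnvs = cnv_frame([("case_0001", "chr1", 4_000, 10_001, "deletion")])
        counts = count_gene_carriers(cnvs, GENES, make_samples())
        assert len(counts) == 1
        assert counts.loc[0, "gene_id"] == "G1"
        assert counts.loc[0, "case_carriers"] == 1

    def test_adjacent_cnv_is_not_a_carrier(self):
        cnvs = cnv_frame([("case_0001", "chr1", 4_000, 10_000, "deletion")])
        assert len(count_gene_carriers(cnvs, GENES, make_samples())) == 0

    def test_multiple_cnvs_one_sample_count_once(self):
        cnvs = cnv_frame([
            ("case_0001", "chr1", 9_000, 15_000, "duplication"),
            ("case_0001", "chr1", 20_000, 29_000, "duplication"),
        ])
        counts = count_gene_carriers(cnvs, GENES, make_samples())
        assert counts.loc[0, "case_carriers"] == 1

    def test_subtype_split_sums_to_case_carriers(self):
        cnvs = cnv_frame([
            ("case_0001", "chr1", 9_000, 15_000, "deletion"),   # CD
            ("case_0002", "chr1", 9_000, 15_000, "deletion"),   # UC
            ("ctrl_0001", "chr1", 9_000, 15_000, "deletion"),
        ])
        counts = count_gene_carriers(cnvs, GENES, make_samples())
        row = counts.iloc[0]
        assert row["case_carriers"] == 2 == row["case_cd"] + row["case_uc"]
        assert row["control_carriers"] == 1

    def test_unknown_sample_is_error(self):
        cnvs = cnv_frame([("ghost", "chr1", 9_000, 15_000, "deletion")])
        with pytest.raises(ValidationError):
            count_gene_carriers(cnvs, GENES, make_samples())

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(6)
        samples = make_samples(10, 10)
        ids = list(samples["sample_id"])
        rows = []
        for _ in range(40):
            s = int(rng.integers(0, 150_000))
            rows.append((ids[int(rng.integers(0, len(ids)))], "chr1",
                         s, s + int(rng.integers(1_000, 5_000)),
                         str(rng.choice(["deletion", "duplication"]))))
        cnvs = cnv_frame(rows)
        counts = count_gene_carriers(cnvs, GENES, samples)
        # oracle: per-base coverage scan per (gene, sample, type)
        for rec in GENES.itertuples(index=False):
            if rec.chrom != "chr1":
                continue
            for typ in ("deletion", "duplication"):
                carriers = set()
                for c in cnvs.itertuples(index=False):
                    if c.cnv_type != typ:
                        continue
                    if any(rec.start <= pos < rec.end
                           for pos in range(c.start, c.end, 1)
                           if rec.start <= pos < rec.end):
                        carriers.add(c.sample_id)
                sel = counts[(counts["gene_id"] == rec.gene_id)
                             & (counts["cnv_type"] == typ)]
                got = 0 if sel.empty else int(sel["case_carriers"].iloc[0]
                                              + sel["control_carriers"].iloc[0])
                assert got == len(carriers), (rec.gene_id, typ)


class TestRunAssociation:
    def test_rarity_thresholds(self):
        samples = make_samples(4, 2988)
        rows = []
        for k, gene_pos in [(1, 10_000), (2, 100_000)]:
            for i in range(k):
                rows.append((f"ctrl_{i+1:04d}", "chr1", gene_pos - 1_000,
                             gene_pos + 5_000, "deletion"))
        rows.append(("case_0001", "chr2", 49_000, 55_000, "deletion"))
        for i in range(3):
            rows.append((f"ctrl_{i+1:04d}", "chr2", 49_000, 55_000, "deletion"))
        cnvs = cnv_frame(rows)
        res = run_association(cnvs, GENES, samples).set_index("gene_id")
        assert res.loc["G1", "is_rare"]          # 1 / 2988 < 0.1%
        assert res.loc["G2", "is_rare"]          # 2 / 2988 < 0.1%
        assert not res.loc["G3", "is_rare"]      # 3 / 2988 >= 0.1%

    def test_universe_size_is_sum_of_type_universes(self, small_study, small_result):
        res = small_result.association
        n_del = (res["cnv_type"] == "deletion").sum()
        n_dup = (res["cnv_type"] == "duplication").sum()
        assert len(res) == n_del + n_dup
        assert (res["m_tests"] == len(res)).all()

    def test_pooled_bh_matches_direct_recomputation(self, small_result):
        from rarecnv.exact import bh_adjust

        res = small_result.association
        assert res["p_adj"].to_numpy() == pytest.approx(
            bh_adjust(res["p"].to_numpy()))
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_gene_and_type_in_both_universes_tested_twice(self):
        samples = make_samples(4, 6)
        cnvs = cnv_frame([
            ("case_0001", "chr1", 9_000, 15_000, "deletion"),
            ("case_0002", "chr1", 9_000, 15_000, "duplication"),
        ])
        res = run_association(cnvs, GENES, samples)
        assert len(res) == 2
        assert set(res["cnv_type"]) == {"deletion", "duplication"}
        assert (res["m_tests"] == 2).all()

    def test_empty_universe_warns_and_returns_empty(self):
        res = run_association(cnv_frame([]), GENES, make_samples())
        assert len(res) == 0


class TestSubgroupAssociation:
    def test_cd_uc_split_not_significant(self):
        # 17 of 120 CD vs 23 of 123 UC rare-CNV carriers
        idx = [f"s{i}" for i in range(243)]
        carrier = pd.Series([True] * 17 + [False] * 103 + [True] * 23 + [False] * 100,
                            index=idx)
        feature = pd.Series(["CD"] * 120 + ["UC"] * 123, index=idx)
        res = subgroup_association(carrier, feature)
        assert res.method == "fisher-exact"
        assert res.p > 0.05

    def test_identical_proportions_give_p_one(self):
        idx = [f"s{i}" for i in range(40)]
        carrier = pd.Series(([True] * 5 + [False] * 15) * 2, index=idx)
        feature = pd.Series(["A"] * 20 + ["B"] * 20, index=idx)
        assert subgroup_association(carrier, feature).p == 1.0

    def test_three_level_feature_uses_exact_enumeration(self):
        idx = [f"s{i}" for i in range(30)]
        carrier = pd.Series([True] * 6 + [False] * 24, index=idx)
        feature = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=idx)
        res = subgroup_association(carrier, feature)
        assert res.method == "fisher-exact"
        assert 0 <= res.p <= 1

    def test_single_level_feature_is_error(self):
        idx = ["a", "b"]
        with pytest.raises(ValidationError):
            subgroup_association(pd.Series([True, False], index=idx),
                                 pd.Series(["X", "X"], index=idx))
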