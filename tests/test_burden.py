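"""Burden stratification grid and observed-vs-expected comparison."""

import numpy as np
import pandas as pd
import pytest

from rarecnv.burden import (LENGTH_CLASSES, burden_table, classify_cnvs,
                            observed_vs_expected_test)
from rarecnv.exact import fisher_p_two_sided
from rarecnv.io import ValidationError

from conftest import make_samples


def cnv_frame(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "cnv_type"])
    df["length"] = df["end"] - df["start"]
    df["n_callers"] = 2
    df["callers"] = "caller_A,caller_B"
    df["max_probes"] = 9
    return df


GENES = pd.DataFrame([("G1", "chr1", 50_000, 90_000)],
                     columns=["gene_id", "chrom", "start", "end"])


class TestClassify:
    @pytest.mark.parametrize("length,expected", [
        (5_000, "5-100kb"),
        (99_999, "5-100kb"),
        (100_000, "100-500kb"),       # half-open boundary goes up
        (499_999, "100-500kb"),
        (500_000, "500kb-1Mb"),
        (1_000_000, ">1Mb"),
        (5_000_000, ">1Mb"),
    ])
    def test_length_bins_half_open(self, length, expected):
        cnvs = cnv_frame([("S1", "chr1", 1_000_000, 1_000_000 + length, "deletion")])
        assert classify_cnvs(cnvs, GENES).loc[0, "length_class"] == expected

    def test_one_bp_gene_overlap_is_genic(self):
        cnvs = cnv_frame([("S1", "chr1", 40_000, 50_001, "deletion"),
                          ("S2", "chr1", 40_000, 50_000, "deletion")])
        ann = classify_cnvs(cnvs, GENES)
        assert bool(ann.loc[0, "genic"]) and not bool(ann.loc[1, "genic"])

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(13)
        rows = []
        for i in range(200):
            s = int(rng.integers(0, 2_000_000))
            rows.append((f"S{i}", "chr1", s, s + int(rng.integers(5_000, 2_000_000)),
                         "deletion"))
        cnvs = cnv_frame(rows)
        ann = classify_cnvs(cnvs, GENES)
        edges = [(5_000, 100_000), (100_000, 500_000), (500_000, 1_000_000),
                 (1_000_000, float("inf"))]
        for rec in ann.itertuples(index=False):
            length = rec.end - rec.start
            expected = next(c for c, (lo, hi) in zip(LENGTH_CLASSES, edges)
                            if lo <= length < hi)
            assert rec.length_class == expected
            assert rec.genic == (rec.start < 90_000 and rec.end > 50_000)


class TestObservedVsExpected:
    def test_published_style_construction(self):
        # the construction is: expected split proportional to group sizes,
        # rounded, then a two-tailed Fisher test of observed vs expected
        p = observed_vs_expected_test(2297, 2105, 120, 123)
        total = 2297 + 2105
        e1 = round(total * 120 / 243)
        assert p == pytest.approx(fisher_p_two_sided(2297, 2105, e1, total - e1))

    def test_proportional_counts_give_p_one(self):
        assert observed_vs_expected_test(240, 246, 120, 123) == 1.0

    def test_zero_events_give_p_one(self):
        assert observed_vs_expected_test(0, 0, 120, 123) == 1.0

    def test_symmetric_in_group_swap(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            o1, o2 = (int(x) for x in rng.integers(0, 400, 2))
            p1 = observed_vs_expected_test(o1, o2, 120, 123)
            p2 = observed_vs_expected_test(o2, o1, 123, 120)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_small_counts_match_enumeration_oracle(self):
        import scipy.stats

        for o1, o2, n1, n2 in [(5, 1, 10, 10), (8, 2, 7, 13), (0, 4, 5, 5)]:
            total = o1 + o2
            e1 = int(np.floor(total * n1 / (n1 + n2) + 0.5))
            expected = scipy.stats.fisher_exact([[o1, o2], [e1, total - e1]])[1]
            assert observed_vs_expected_test(o1, o2, n1, n2) == \
                pytest.approx(expected, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            observed_vs_expected_test(-1, 2, 10, 10)


class TestBurdenTable:
    def test_partition_conservation(self, small_study, small_result):
        table = small_result.burden.set_index(
            ["cnv_type", "length_class", "genic_class"])
        g1 = [c for c in table.columns if c.startswith("count_")][0]
        for length in ("any", *LENGTH_CLASSES):
            for genic in ("all", "genic", "non-genic"):
                assert table.loc[("all", length, genic), g1] == \
                    table.loc[("deletion", length, genic), g1] + \
                    table.loc[("duplication", length, genic), g1]
        for typ in ("all", "deletion", "duplication"):
            for genic in ("all", "genic", "non-genic"):
                assert table.loc[(typ, "any", genic), g1] == sum(
                    table.loc[(typ, c, genic), g1] for c in LENGTH_CLASSES)
            for length in ("any", *LENGTH_CLASSES):
                assert table.loc[(typ, length, "all"), g1] == \
                    table.loc[(typ, length, "genic"), g1] + \
                    table.loc[(typ, length, "non-genic"), g1]

    def test_grid_shape(self, small_result):
        assert len(small_result.burden) == 3 * 5 * 3

    def test_zero_sample_group_is_error(self):
        samples = make_samples(2, 0)
        samples["subtype"] = "CD"  # no UC samples at all
        with pytest.raises(ValidationError):
            burden_table(cnv_frame([]), GENES, samples, "CD_vs_UC")

    def test_planted_excess_in_one_group_flagged(self):
        rng = np.random.default_rng(23)
        samples = make_samples(60, 0)
        cd = samples[samples["subtype"] == "CD"]["sample_id"].to_list()
        uc = samples[samples["subtype"] == "UC"]["sample_id"].to_list()
        rows = []
        # equal background in both groups, strong short-deletion excess in CD
        for ids, n_del in ((cd, 300), (uc, 100)):
            for i in range(n_del):
                s = int(rng.integers(100_000, 1_900_000))
                rows.append((ids[i % len(ids)], "chr1", s, s + 20_000, "deletion"))
        table = burden_table(cnv_frame(rows), GENES, samples, "CD_vs_UC")
        cell = table[(table["cnv_type"] == "deletion")
                     & (table["length_class"] == "5-100kb")
                     & (table["genic_class"] == "all")]
        assert cell["p"].iloc[0] < 0.001

    def test_null_calibration_across_replicates(self):
        """Uniform CNV rates: ~5% of informative cells reach p < 0.05."""
        rng = np.random.default_rng(31)
        samples = make_samples(80, 0)
        ids = samples["sample_id"].to_list()
        flagged, informative = 0, 0
        for _rep in range(40):
            rows = []
            for _ in range(400):
                s = int(rng.integers(100_000, 1_900_000))
                rows.append((ids[int(rng.integers(0, len(ids)))], "chr1",
                             s, s + int(rng.integers(5_000, 60_000)),
                             "deletion" if rng.random() < 0.6 else "duplication"))
            table = burden_table(cnv_frame(rows), GENES, samples, "CD_vs_UC")
            counts = table.filter(like="count_").sum(axis=1)
            keep = counts >= 20  # exact test has no power on near-empty cells
            informative += int(keep.sum())
            flagged += int((table.loc[keep, "p"] < 0.05).sum())
        rate = flagged / informative
        se = np.sqrt(0.05 * 0.95 / informative)
        assert rate <= 0.05 + 3 * se
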