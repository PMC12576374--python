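import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbmkit import methylome
from gbmkit.io_formats import CpGRecord
from gbmkit.methylome import (
    MethylationCall,
    call_cpg_levels,
    consolidated_gene_set,
    conversion_efficiency,
    feature_methylation,
    genome_wide_methylation,
    methylation_status,
    region_class_summary,
)


class TestCallCpGLevels:
    @pytest.mark.parametrize(
        "meth,unmeth,expected_level",
        [(3, 2, 60.0), (0, 50, 0.0), (5, 0, 100.0)],
    )
    def test_level_formula(self, meth, unmeth, expected_level):
        (call,) = call_cpg_levels([CpGRecord("c", 1, "+", meth, unmeth)], min_coverage=5)
        assert call.level == pytest.approx(expected_level)
        assert call.coverage == meth + unmeth

    def test_below_coverage_threshold_not_called(self):
        assert call_cpg_levels([CpGRecord("c", 1, "+", 1, 3)], min_coverage=5) == []

    def test_raising_min_coverage_never_adds_calls(self):
        rng = np.random.default_rng(0)
        records = [
            CpGRecord("c", i + 1, "+", int(rng.integers(0, 10)), int(rng.integers(0, 10)))
            for i in range(200)
        ]
        counts = [len(call_cpg_levels(records, mc)) for mc in range(1, 15)]
        assert counts == sorted(counts, reverse=True)


class TestConversionEfficiency:
    @pytest.mark.parametrize(
        "meth,total,expected",
        [(0, 1000, 100.0), (77, 10000, 99.23), (1000, 1000, 0.0)],
    )
    def test_pooled_formula(self, meth, total, expected):
        # spread the counts over several control cytosines
        records = [
            CpGRecord("Lambda", 1, "+", meth, total - meth),
            CpGRecord("Lambda", 11, "+", 0, 0),
        ]
        assert conversion_efficiency(records) == pytest.approx(expected)

    def test_zero_coverage_reported_missing(self):
        assert conversion_efficiency([CpGRecord("Lambda", 1, "+", 0, 0)]) is None


class TestMethylationStatus:
    @pytest.mark.parametrize(
        "level,expected",
        [(9.99, "not methylated"), (10.0, "methylated"), (70.1, "methylated")],
    )
    def test_strict_threshold(self, level, expected):
        assert methylation_status(level) == expected


class TestFeatureMethylation:
    def test_unweighted_mean_of_levels(self):
        calls = [MethylationCall("c", p, lv, 10) for p, lv in [(5, 0), (10, 50), (15, 100)]]
        df = feature_methylation(calls, {"f": [("c", 0, 20)]}, min_cpgs=3)
        assert df.loc["f", "mean_level"] == pytest.approx(50.0)
        assert bool(df.loc["f", "defined"])

    @pytest.mark.parametrize("n_cpgs", [0, 1, 2])
    def test_undefined_below_min_cpgs(self, n_cpgs):
        calls = [MethylationCall("c", 5 * (i + 1), 50.0, 10) for i in range(n_cpgs)]
        df = feature_methylation(calls, {"f": [("c", 0, 100)]}, min_cpgs=3)
        assert not bool(df.loc["f", "defined"])
        assert np.isnan(df.loc["f", "mean_level"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        calls = [
            MethylationCall("c", int(p), float(lv), 10)
            for p, lv in zip(rng.choice(1000, 50, replace=False) + 1, rng.uniform(0, 100, 50))
        ]
        feats = {"f": [("c", 0, 1001)]}
        a = feature_methylation(calls, feats)
        b = feature_methylation(list(reversed(calls)), feats)
        assert a.loc["f", "mean_level"] == pytest.approx(b.loc["f", "mean_level"])

    @given(
        levels=st.lists(st.floats(0, 100), min_size=3, max_size=40),
        cut=st.integers(0, 39),
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_weighted_mean_identity(self, levels, cut):
        """Feature mean equals the CpG-count-weighted mean of part means."""
        cut = min(cut, len(levels))
        calls = [MethylationCall("c", i + 1, lv, 10) for i, lv in enumerate(levels)]
        whole = feature_methylation(calls, {"f": [("c", 0, len(levels) + 1)]}, min_cpgs=1)
        left = levels[:cut]
        right = levels[cut:]
        weighted = (sum(left) + sum(right)) / len(levels)
        assert whole.loc["f", "mean_level"] == pytest.approx(weighted)

    def test_exact_simulation_recovers_truth(self, genome, truth, exact_methylome):
        """With sequencing noise silenced, per-gene means equal the truth."""
        ann, sites = genome
        genomic, _ = methylome.split_control_records(exact_methylome["embryo_1"])
        calls = call_cpg_levels(genomic, 5)
        fm = feature_methylation(calls, methylome.gene_feature_map(ann), 3)
        expected = truth.gene_true_means(ann, sites, "embryo")
        defined = fm.index[fm["defined"]]
        assert len(defined) > 0
        assert np.allclose(fm.loc[defined, "mean_level"], expected.loc[defined])


class TestConsolidatedSet:
    def _table(self, defined_map):
        genes = sorted(defined_map)
        return pd.DataFrame(
            {
                "n_cpgs_covered": [3 if defined_map[g] else 2 for g in genes],
                "mean_level": [10.0] * len(genes),
                "defined": [defined_map[g] for g in genes],
            },
            index=pd.Index(genes, name="feature_id"),
        )

    def test_gene_defined_everywhere_retained(self):
        tables = {f"s{i}": self._table({"g1": True, "g2": True}) for i in range(6)}
        assert consolidated_gene_set(tables) == {"g1", "g2"}

    def test_gene_failing_one_sample_excluded(self):
        tables = {f"s{i}": self._table({"g1": True, "g2": True}) for i in range(5)}
        tables["s5"] = self._table({"g1": True, "g2": False})
        assert consolidated_gene_set(tables) == {"g1"}

    def test_mismatched_universe_rejected(self):
        tables = {
            "a": self._table({"g1": True}),
            "b": self._table({"g1": True, "g2": True}),
        }
        with pytest.raises(ValueError, match="universe"):
            consolidated_gene_set(tables)


class TestRegionSummary:
    def test_hand_built_three_region_toy(self, tmp_path):
        from gbmkit.io_formats import read_annotation

        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##sequence-region chr1 1 300\n"
            "chr1\ts\tgene\t1\t200\t.\t+\t.\tID=g1\n"
            "chr1\ts\texon\t1\t100\t.\t+\t.\tParent=g1\n"
            "chr1\ts\texon\t151\t200\t.\t+\t.\tParent=g1\n"
        )
        ann = read_annotation(gff)
        calls = [
            MethylationCall("chr1", 10, 20.0, 10),  # exon
            MethylationCall("chr1", 50, 40.0, 10),  # exon
            MethylationCall("chr1", 120, 10.0, 10),  # intron
            MethylationCall("chr1", 250, 0.0, 10),  # intergenic
            MethylationCall("chr1", 280, 0.0, 10),  # intergenic
        ]
        df = region_class_summary(calls, ann).set_index("region_class")
        assert df.loc["exon", "mean_level"] == pytest.approx(30.0)
        assert df.loc["intron", "mean_level"] == pytest.approx(10.0)
        assert df.loc["intergenic", "mean_level"] == pytest.approx(0.0)
        assert df["genome_fraction_pct"].sum() == pytest.approx(100.0)
        assert df.loc["exon", "genome_fraction_pct"] == pytest.approx(100 * 150 / 300)

    def test_all_zero_levels_give_zero_means(self, genome, exact_methylome):
        ann, _ = genome
        calls = [
            MethylationCall("chr1", p, 0.0, 10) for p in range(10, 5000, 100)
        ]
        df = region_class_summary(calls, ann).set_index("region_class")
        present = df["n_cpgs"] > 0
        assert (df.loc[present, "mean_level"] == 0).all()


class TestGenomeWide:
    def test_both_definitions(self):
        calls = [MethylationCall("c", i + 1, lv, 10) for i, lv in enumerate([0, 0, 20, 100])]
        gw = genome_wide_methylation(calls, threshold=10)
        assert gw["mean_level"] == pytest.approx(30.0)
        assert gw["fraction_methylated"] == pytest.approx(50.0)
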