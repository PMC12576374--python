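import numpy as np
import pytest

from _oracles import best_split_enum, bh_brute, interval_jaccard
from conftest import records_from_levels
from gbmkit import dmr, methylome
from gbmkit.dmr import (
    bh_adjust,
    build_cpg_matrix,
    call_dmrs,
    dmr_input_filter,
    segment_candidates,
)
from gbmkit.dmr import test_dmrs as run_region_tests
from gbmkit.io_formats import CpGRecord
from gbmkit.synthetic_data import TruthParams, generate_genome, simulate_methylome, simulate_truth

E = ["e1", "e2", "e3"]
A = ["a1", "a2", "a3"]


def paired_records(positions, embryo_levels, adult_levels, coverage=20):
    recs = {}
    for name in E:
        recs[name] = records_from_levels(positions, embryo_levels, coverage)
    for name in A:
        recs[name] = records_from_levels(positions, adult_levels, coverage)
    return recs


class TestInputFilter:
    def make(self, coverages):
        recs = {}
        for name in E + A:
            recs[name] = [
                CpGRecord("chr1", 100 + 10 * i, "+", c // 2, c - c // 2)
                for i, c in enumerate(coverages[name])
            ]
        return recs

    def test_coverage_window_inclusive(self):
        covs = {name: [5, 100, 50] for name in E + A}
        mat = dmr_input_filter(self.make(covs), E, A)
        assert len(mat) == 3  # bounds are inclusive on both sides

    def test_single_replicate_over_max_excludes_site(self):
        covs = {name: [50, 50] for name in E + A}
        covs["a2"] = [101, 50]
        mat = dmr_input_filter(self.make(covs), E, A)
        assert list(mat.index.get_level_values("pos")) == [110]

    def test_empty_group_rejected(self):
        covs = {name: [50] for name in E + A}
        with pytest.raises(ValueError, match="replicate"):
            dmr_input_filter(self.make(covs), [], A)


class TestSegmentation:
    def test_uniform_run_is_single_candidate(self):
        pos = list(range(100, 100 + 15 * 50, 50))
        recs = paired_records(pos, [50.0] * 15, [20.0] * 15)
        mat = build_cpg_matrix(recs, E, A)
        (cand,) = segment_candidates(mat)
        assert len(cand.positions) == 15
        assert cand.mean_diff == pytest.approx(-30.0)

    def test_split_at_boundary_matches_enumeration_oracle(self):
        pos = list(range(100, 100 + 30 * 50, 50))
        embryo = [50.0] * 30
        adult = [20.0] * 15 + [50.0] * 15
        recs = paired_records(pos, embryo, adult)
        mat = build_cpg_matrix(recs, E, A)
        cands = segment_candidates(mat)
        # oracle: exhaustive split of the per-CpG diffs
        diffs = [a - e for e, a in zip(embryo, adult)]
        k, _ = best_split_enum(diffs, 10)
        assert k == 15
        assert len(cands) == 1
        assert cands[0].positions == tuple(pos[:15])
        assert cands[0].mean_diff == pytest.approx(-30.0)

    def test_run_below_min_cpgs_yields_nothing(self):
        pos = list(range(100, 100 + 9 * 50, 50))
        recs = paired_records(pos, [50.0] * 9, [10.0] * 9)
        assert segment_candidates(build_cpg_matrix(recs, E, A)) == []

    def test_gap_breaks_runs(self):
        pos = list(range(100, 100 + 10 * 50, 50)) + list(
            range(5000, 5000 + 10 * 50, 50)
        )
        recs = paired_records(pos, [50.0] * 20, [20.0] * 20)
        cands = segment_candidates(build_cpg_matrix(recs, E, A), max_gap=300)
        assert len(cands) == 2
        assert all(len(c.positions) == 10 for c in cands)


class TestTesting:
    def test_bh_matches_brute_force(self):
        pvals = [0.01, 0.02, 0.04]
        assert np.allclose(bh_adjust(pvals), [0.03, 0.03, 0.04])
        rng = np.random.default_rng(5)
        for _ in range(5):
            ps = rng.uniform(0, 1, size=rng.integers(1, 30)).tolist()
            assert np.allclose(bh_adjust(ps), bh_brute(ps))

    def test_identical_groups_give_no_dmrs(self):
        pos = list(range(100, 100 + 20 * 50, 50))
        recs = paired_records(pos, [50.0] * 20, [50.0] * 20)
        assert call_dmrs(recs, E, A) == []

    def test_constant_data_gets_p_one(self):
        pos = list(range(100, 100 + 15 * 50, 50))
        recs = paired_records(pos, [50.0] * 15, [50.0] * 15)
        mat = build_cpg_matrix(recs, E, A)
        cand = dmr.Candidate("chr1", tuple(pos), 0.0)
        out = run_region_tests([cand], mat, calibrate=False)
        assert out == []  # p = 1 by convention, never significant

    def test_separated_groups_detected_without_calibration(self):
        pos = list(range(100, 100 + 15 * 50, 50))
        rng = np.random.default_rng(2)
        recs = {}
        for name in E:
            recs[name] = records_from_levels(pos, rng.uniform(45, 55, 15))
        for name in A:
            recs[name] = records_from_levels(pos, rng.uniform(15, 25, 15))
        dmrs = call_dmrs(recs, E, A, calibrate=False)
        assert len(dmrs) == 1
        assert dmrs[0].direction == "hypo"
        assert dmrs[0].n_cpgs == 15

    def test_label_swap_flips_direction_not_pvalue(self):
        pos = list(range(100, 100 + 15 * 50, 50))
        rng = np.random.default_rng(3)
        recs = {}
        for name in E:
            recs[name] = records_from_levels(pos, rng.uniform(40, 60, 15))
        for name in A:
            recs[name] = records_from_levels(pos, rng.uniform(10, 30, 15))
        fwd = call_dmrs(recs, E, A, calibrate=False)
        rev = call_dmrs(recs, A, E, calibrate=False)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].mean_diff == pytest.approx(-rev[0].mean_diff)
        assert {fwd[0].direction, rev[0].direction} == {"hypo", "hyper"}
        assert fwd[0].p_raw == pytest.approx(rev[0].p_raw)

    def test_output_always_satisfies_region_criteria(self, genome, noisy_methylome):
        per = {k: methylome.split_control_records(v)[0] for k, v in noisy_methylome.items()}
        dmrs = call_dmrs(per, ["embryo_1", "embryo_2", "embryo_3"],
                         ["adult_1", "adult_2", "adult_3"])
        for d in dmrs:
            assert d.n_cpgs >= 10
            assert abs(d.mean_diff) >= 10
            assert d.q_bh < 0.05
            assert d.direction == ("hypo" if d.mean_diff < 0 else "hyper")


class TestPlantedRecovery:
    def test_planted_dmrs_recovered_with_high_jaccard(self):
        """-30-point 15-CpG regions planted in the adult stage are found."""
        ann, sites = generate_genome(120, seed=21)
        truth = simulate_truth(
            ann, sites, params=TruthParams(dispersion=0.05), seed=22
        )
        assert len(truth.dmrs) > 0
        meth = simulate_methylome(ann, sites, truth, mean_coverage=30, seed=23)
        per = {k: methylome.split_control_records(v)[0] for k, v in meth.items()}
        called = call_dmrs(per, ["embryo_1", "embryo_2", "embryo_3"],
                           ["adult_1", "adult_2", "adult_3"])
        jaccards = [
            max(
                (interval_jaccard((t["start"], t["end"]), (d.start, d.end))
                 for d in called if d.chrom == t["chrom"]),
                default=0.0,
            )
            for t in truth.dmrs
        ]
        assert np.mean(jaccards) >= 0.8


class TestAnnotate:
    def test_feature_classes(self, tmp_path):
        from gbmkit.io_formats import read_annotation

        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##sequence-region chr1 1 10000\n"
            "chr1\ts\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "chr1\ts\texon\t1001\t1400\t.\t+\t.\tParent=g1\n"
            "chr1\ts\texon\t1601\t2000\t.\t+\t.\tParent=g1\n"
        )
        ann = read_annotation(gff)

        def mk(start, end):
            return dmr.DMR("chr1", start, end, 10, -20.0, 0.001, 0.01)

        per_dmr, _counts = dmr.annotate_dmrs(
            [mk(1050, 1200), mk(1350, 1650), mk(1450, 1550), mk(5000, 5200)], ann
        )
        assert list(per_dmr["feature_class"]) == [
            "exon-only", "exon+intron", "intron-only", "intergenic"
        ]
        assert list(per_dmr["genic"]) == [True, True, True, False]
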