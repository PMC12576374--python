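import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import hypergeom_tail_enum
from gbmkit.integration import (
    build_gene_status_table,
    category_stats,
    classify_four_sets,
    dmr_deg_overlap,
    gbm_expression_regression,
    hypergeom_overlap_p,
    methylation_change_profile,
    transition_counts,
)


def status_table(levels, fpkms):
    genes = [f"g{i}" for i in range(len(levels))]
    return build_gene_status_table(
        dict(zip(genes, levels)), dict(zip(genes, fpkms)), genes
    )


class TestClassify:
    @pytest.mark.parametrize(
        "level,fpkm,expected",
        [
            (10.0, 1.01, "methylated/expressed"),  # both boundaries inclusive side
            (9.9, 1.0, "not methylated/not expressed"),
            (50.0, 0.5, "methylated/not expressed"),
            (0.0, 10.0, "not methylated/expressed"),
        ],
    )
    def test_boundary_cross(self, level, fpkm, expected):
        table = status_table([level], [fpkm])
        assert table["category"].iloc[0] == expected

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError):
            classify_four_sets("sort of methylated", "expressed")

    def test_truth_categories_recovered_at_zero_noise(self, genome, truth):
        """The four-way classification of noise-free simulated data equals
        the generator's truth for every gene."""
        from gbmkit import methylome
        from gbmkit.synthetic_data import simulate_expression_and_tracks, simulate_methylome

        ann, sites = genome
        meth = simulate_methylome(ann, sites, truth, n_replicates=1, seed=44, exact=True)
        genomic, _ = methylome.split_control_records(meth["embryo_1"])
        calls = methylome.call_cpg_levels(genomic, 5)
        fm = methylome.feature_methylation(calls, methylome.gene_feature_map(ann), 3)
        expr = simulate_expression_and_tracks(ann, truth, seed=45, noise=False)
        fpkm = expr["fpkm"]["embryo"].mean(axis=1)
        genes = fm.index[fm["defined"]]
        table = build_gene_status_table(
            fm["mean_level"].to_dict(), fpkm.to_dict(), list(genes)
        )
        want = truth.categories("embryo").loc[genes]
        assert (table["category"] == want).all()


class TestTransitions:
    def test_published_scale_accounting(self):
        """From 9,361 embryo-expressed genes, 2,854 activations and 868
        inactivations yield 11,347 adult-expressed and 3,722 changers."""
        n, e_expr, act, inact = 25631, 9361, 2854, 868
        expr_e = np.zeros(n, dtype=bool)
        expr_e[:e_expr] = True
        expr_a = expr_e.copy()
        expr_a[:inact] = False  # inactivate 868 embryo-expressed
        expr_a[e_expr : e_expr + act] = True
        genes = [f"g{i}" for i in range(n)]
        levels = dict(zip(genes, [5.0] * n))
        e = build_gene_status_table(
            levels, dict(zip(genes, np.where(expr_e, 10.0, 0.1))), genes
        )
        a = build_gene_status_table(
            levels, dict(zip(genes, np.where(expr_a, 10.0, 0.1))), genes
        )
        t = transition_counts(e, a)
        assert t.embryo_expressed == 9361
        assert t.adult_expressed == 11347
        assert t.become_active == 2854
        assert t.become_inactive == 868
        assert t.expression_changers == 3722
        pct = t.percentages()
        assert round(pct["embryo_expressed_pct"], 1) == 36.5
        assert round(pct["adult_expressed_pct"], 1) == 44.3

    def test_identical_tables_have_no_changers(self):
        t1 = status_table([5, 50, 5, 50], [0.5, 10, 10, 0.5])
        t = transition_counts(t1, t1)
        assert t.expression_changers == 0
        assert t.gain_methylation == t.lose_methylation == 0
        assert t.maintain_methylation == t.n_genes
        assert int(np.diag(t.flows).sum()) == t.n_genes

    @given(data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_flows_sum_to_n_and_marginals_reconcile(self, data):
        n = data.draw(st.integers(1, 60))
        levels = data.draw(
            st.lists(st.floats(0, 100, allow_nan=False), min_size=n, max_size=n)
        )
        f1 = data.draw(st.lists(st.floats(0, 50, allow_nan=False), min_size=n, max_size=n))
        levels2 = data.draw(
            st.lists(st.floats(0, 100, allow_nan=False), min_size=n, max_size=n)
        )
        f2 = data.draw(st.lists(st.floats(0, 50, allow_nan=False), min_size=n, max_size=n))
        e, a = status_table(levels, f1), status_table(levels2, f2)
        t = transition_counts(e, a)
        assert int(t.flows.to_numpy().sum()) == n
        assert t.adult_expressed == t.embryo_expressed + t.become_active - t.become_inactive
        long = t.long_flows()
        assert int(long["count"].sum()) == n


class TestCategoryStats:
    def test_single_gene_category(self, genome):
        ann, _ = genome
        gids = ann.gene_ids()[:4]
        levels = [50.0, 5.0, 50.0, 5.0]
        fpkms = [10.0, 10.0, 0.1, 0.1]
        table = build_gene_status_table(
            dict(zip(gids, levels)), dict(zip(gids, fpkms)), gids
        )
        stats = category_stats(table, ann).set_index("category")
        g0 = ann.genes[gids[0]]
        assert stats.loc["methylated/expressed", "n_genes"] == 1
        assert stats.loc["methylated/expressed", "mean_length"] == pytest.approx(g0.length)
        assert np.isnan(stats.loc["methylated/expressed", "sd_length"])

    def test_empty_category_reported_missing(self):
        table = status_table([50.0], [10.0])  # only methylated/expressed

        class FakeAnn:
            def gene_lengths(self):
                return {"g0": 1000}

        stats = category_stats(table, FakeAnn()).set_index("category")
        assert stats.loc["not methylated/expressed", "n_genes"] == 0
        assert np.isnan(stats.loc["not methylated/expressed", "mean_length"])


class TestRegression:
    def test_collinear_points_give_r2_one(self):
        levels = np.linspace(20, 60, 30)
        fpkm = 10 ** (0.5 + 0.02 * levels)
        table = status_table(levels, fpkm)
        fit = gbm_expression_regression(table)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(0.02)

    def test_permuted_response_slope_near_zero(self):
        rng = np.random.default_rng(7)
        levels = rng.uniform(15, 70, 2000)
        fpkm = 10 ** rng.normal(1.0, 0.5, 2000)  # independent of level
        fit = gbm_expression_regression(status_table(levels, fpkm))
        assert abs(fit["slope"]) < 0.005
        assert fit["p"] > 1e-4  # no spurious strong association

    def test_generating_slope_recovered(self):
        """OLS on methylated/expressed genes recovers the generator's
        methylation-expression slope within its confidence interval."""
        from gbmkit.synthetic_data import TruthParams, generate_genome, simulate_truth

        ann, sites = generate_genome(400, seed=89)
        truth = simulate_truth(ann, sites, params=TruthParams(), seed=90)
        rows = truth.genes
        me = rows[(rows["level_embryo"] >= 10) & rows["expr_embryo"]]
        table = build_gene_status_table(
            rows["level_embryo"].to_dict(),
            rows["fpkm_embryo"].to_dict(),
            list(rows.index),
        )
        fit = gbm_expression_regression(table)
        se = abs(fit["slope"]) / max(np.sqrt(max(len(me) - 2, 1)), 1)
        # generous CI: +-4 sd of the fitted slope around the true 0.01
        resid_scale = TruthParams().gbm_expr_sd
        level_sd = np.std(me["level_embryo"]) if len(me) > 2 else 1.0
        slope_se = resid_scale / (level_sd * np.sqrt(len(me)))
        assert abs(fit["slope"] - TruthParams().gbm_expr_slope) < 4 * slope_se


class TestOverlap:
    def test_example_five_over_210(self):
        # N=10, |A|=5, |B|=4, overlap 4: p = 5/210
        assert hypergeom_overlap_p(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_overlap_p(10, 5, 4, 0) == 1.0

    def test_a_equals_universe(self):
        assert hypergeom_overlap_p(10, 10, 4, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_universe", [6, 9, 12, 15])
    def test_matches_enumeration_oracle(self, n_universe):
        rng = np.random.default_rng(n_universe)
        for _ in range(8):
            n_a = int(rng.integers(0, n_universe + 1))
            n_b = int(rng.integers(0, n_universe + 1))
            k = int(rng.integers(0, min(n_a, n_b) + 1))
            assert hypergeom_overlap_p(n_universe, n_a, n_b, k) == pytest.approx(
                hypergeom_tail_enum(n_universe, n_a, n_b, k)
            )

    def test_dmr_deg_table(self):
        universe = {f"g{i}" for i in range(10)}
        dmr_sets = {"hypo": {"g0", "g1", "g2", "g3", "g4"}}
        deg_sets = {"down": {"g0", "g1", "g2", "g3"}}
        df = dmr_deg_overlap(dmr_sets, deg_sets, universe)
        assert df.loc[0, "n_overlap"] == 4
        assert df.loc[0, "p"] == pytest.approx(5 / 210)


class TestChangeProfile:
    def test_identical_stages_give_zero_deltas(self):
        levels = {f"g{i}": float(i) for i in range(100)}
        prof = methylation_change_profile(levels, levels, n_bins=10)
        occupied = prof["n_genes"] > 0
        assert np.allclose(prof.loc[occupied, "mean_delta"], 0.0)

    def test_uniform_shift(self):
        e = {f"g{i}": 20.0 + i for i in range(50)}
        a = {g: v - 10.0 for g, v in e.items()}
        prof = methylation_change_profile(e, a, n_bins=5)
        occupied = prof["n_genes"] > 0
        assert np.allclose(prof.loc[occupied, "mean_delta"], -10.0)
        assert int(prof["n_genes"].sum()) == 50

    def test_regression_to_baseline_truth_shows_negative_trend(self, genome):
        """Highly methylated genes drift down between stages in the
        generator; the binned change profile reproduces the trend."""
        from gbmkit.synthetic_data import simulate_truth

        ann, sites = genome
        truth = simulate_truth(ann, sites, seed=91)
        e = truth.genes["level_embryo"].astype(float).to_dict()
        a = truth.genes["level_adult"].astype(float).to_dict()
        prof = methylation_change_profile(e, a, n_bins=10)
        high = prof[(prof["bin_low"] >= 40) & (prof["n_genes"] > 0)]
        low = prof[(prof["bin_high"] <= 10) & (prof["n_genes"] > 0)]
        assert high["mean_delta"].mean() < -3
        assert abs(low["mean_delta"].mean()) < 3
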