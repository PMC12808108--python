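"""Ground-truth consistency, reproducibility and calibration of the simulators."""

import numpy as np
import pandas as pd
import pytest

from xreact import sc_allelic, synthetic


class TestConfig:
    def test_default_config_is_category_consistent(self, fixture_config):
        fixture_config.validate()  # raises on inconsistency

    def test_out_of_range_p_xi_names_gene(self, fixture_config):
        prof = fixture_config.xi_profile.copy()
        prof.iloc[3, 0] = 0.7
        with pytest.raises(ValueError, match=prof.index[3]):
            synthetic.SimulationConfig(
                n_genes=len(prof), xi_profile=prof,
                category_truth=fixture_config.category_truth, seed=0)

    def test_inconsistent_category_rejected(self, fixture_config):
        truth = fixture_config.category_truth.copy()
        inactive_gene = truth.index[truth == "inactive"][0]
        truth[inactive_gene] = "escape"
        with pytest.raises(ValueError, match="inconsistent"):
            synthetic.SimulationConfig(
                n_genes=fixture_config.n_genes, xi_profile=fixture_config.xi_profile,
                category_truth=truth, seed=0)


class TestBulkSimulator:
    def test_same_seed_identical_outputs(self):
        a = synthetic.simulate_bulk_allelic_counts(synthetic.default_config(50, seed=9))
        b = synthetic.simulate_bulk_allelic_counts(synthetic.default_config(50, seed=9))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_different_seed_differs(self):
        a, _, _ = synthetic.simulate_bulk_allelic_counts(synthetic.default_config(50, seed=9))
        b, _, _ = synthetic.simulate_bulk_allelic_counts(synthetic.default_config(50, seed=10))
        assert not a.equals(b)

    def test_degenerate_p_xi_zero_is_strictly_monoallelic(self):
        genes = ["GA", "GB"]
        prof = pd.DataFrame(0.0, index=genes, columns=["iPSC", "NPC", "neuron"])
        cfg = synthetic.SimulationConfig(
            n_genes=2, xi_profile=prof,
            category_truth=pd.Series("inactive", index=genes), seed=1)
        counts, sites, truth = synthetic.simulate_bulk_allelic_counts(cfg)
        merged = counts.merge(sites[["variant_id", "gene"]]).merge(truth, on="gene")
        on_xa = merged["ref_on_xa"]
        assert (merged.loc[on_xa, "ref_reads"] == merged.loc[on_xa, "total_reads"]).all()
        assert (merged.loc[~on_xa, "ref_reads"] == 0).all()

    def test_balanced_gene_near_half_at_high_depth(self):
        genes = ["GE"]
        prof = pd.DataFrame(0.5, index=genes, columns=["iPSC", "NPC", "neuron"])
        cfg = synthetic.SimulationConfig(
            n_genes=1, xi_profile=prof, category_truth=pd.Series("escape", index=genes),
            depth_mean=10_000.0, depth_dispersion=1e6, variants_per_gene=(1, 1), seed=2)
        counts, _, _ = synthetic.simulate_bulk_allelic_counts(cfg)
        pooled_ref = counts["ref_reads"].sum()
        pooled_total = counts["total_reads"].sum()
        frac = min(pooled_ref / pooled_total, 1 - pooled_ref / pooled_total)
        se = np.sqrt(0.25 / pooled_total)
        assert abs(frac - 0.5) <= 3 * se

    def test_marginal_calibration_at_extreme_depth(self):
        # pooled minor-allele fraction converges to p_Xi: within 1% at 1e5 reads
        genes = ["GX"]
        prof = pd.DataFrame(
            [[0.2, 0.3, 0.4]], index=genes, columns=["iPSC", "NPC", "neuron"])
        cfg = synthetic.SimulationConfig(
            n_genes=1, xi_profile=prof, category_truth=pd.Series("escape", index=genes),
            depth_mean=25_000.0, depth_dispersion=1e6, variants_per_gene=(1, 1), seed=3)
        counts, _, truth = synthetic.simulate_bulk_allelic_counts(cfg)
        for ct, p in zip(("iPSC", "NPC", "neuron"), (0.2, 0.3, 0.4)):
            grp = counts.loc[counts["cell_type"] == ct]
            ratio = grp["ref_reads"].sum() / grp["total_reads"].sum()
            assert min(ratio, 1 - ratio) == pytest.approx(p, abs=0.01)

    def test_phase_shared_between_bulk_and_sc(self):
        cfg = synthetic.default_config(30, seed=4)
        _, _, truth = synthetic.simulate_bulk_allelic_counts(cfg)
        phase = synthetic.gene_phase(cfg)
        assert (truth.set_index("gene")["ref_on_xa"] == phase).all()


class TestAnnotationSimulator:
    def test_two_gene_distance(self):
        from xreact.set_stats import mean_pairwise_distance
        assert mean_pairwise_distance([1000, 2000]) == 1000.0

    def test_clustered_genes_land_in_window(self):
        cfg = synthetic.default_config(100, seed=5)
        ann = synthetic.simulate_annotation(cfg, clustered_fraction=1.0, window=10_000)
        designated = cfg.category_truth.index[cfg.category_truth == "reactivated"]
        tss = ann.set_index("gene").loc[designated, "tss_pos"]
        assert tss.max() - tss.min() <= 10_000

    def test_par_flags_in_terminal_interval(self):
        cfg = synthetic.default_config(50, seed=6)
        ann = synthetic.simulate_annotation(cfg, n_par=5, par_length=2.7e6)
        par = ann.loc[ann["par_flag"]]
        assert len(par) == 5
        assert (par["tss_pos"] <= 2.7e6).all()
        assert (ann.loc[~ann["par_flag"], "tss_pos"] > 2.7e6).all()

    def test_positions_one_based(self):
        cfg = synthetic.default_config(50, seed=7)
        ann = synthetic.simulate_annotation(cfg)
        assert (ann["tss_pos"] >= 1).all()

    def test_invalid_fraction_rejected(self):
        cfg = synthetic.default_config(10, seed=8)
        with pytest.raises(ValueError):
            synthetic.simulate_annotation(cfg, clustered_fraction=1.5)


class TestScSimulator:
    def test_silent_xi_gives_zero_scores(self):
        genes = ["GA", "GB", "GC"]
        prof = pd.DataFrame(0.0, index=genes, columns=["iPSC", "NPC", "neuron"])
        cfg = synthetic.SimulationConfig(
            n_genes=3, xi_profile=prof, category_truth=pd.Series("inactive", index=genes),
            seed=9)
        counts, _ = synthetic.simulate_sc_allele_umis(300, cfg, umi_depth=10.0,
                                                      detection_rate=1.0)
        scores = sc_allelic.score_cells(counts)
        assert np.allclose(scores.biallelic_sum, 0.0)

    def test_reproducible(self):
        cfg = synthetic.default_config(20, seed=10)
        a, ma = synthetic.simulate_sc_allele_umis(100, cfg, umi_depth=3.0)
        b, mb = synthetic.simulate_sc_allele_umis(100, cfg, umi_depth=3.0)
        assert (a.ref != b.ref).nnz == 0 and (a.alt != b.alt).nnz == 0
        pd.testing.assert_frame_equal(ma, mb)

    def test_single_site_balanced_score(self):
        counts = sc_allelic.CellAlleleCounts(
            ref=np.array([[4]]), alt=np.array([[4]]),
            barcodes=np.array(["c"]),
            variants=pd.DataFrame({"variant_id": ["v"], "gene": ["g"], "par_flag": [False]}))
        assert sc_allelic.score_cells(counts).biallelic_sum[0] == pytest.approx(np.log(2))

    def test_reactivation_ramp_monotone_along_pseudotime(self):
        from scipy.stats import spearmanr
        cfg = synthetic.default_config(60, seed=12)
        counts, meta = synthetic.simulate_sc_allele_umis(5000, cfg, umi_depth=6.0,
                                                         detection_rate=0.5)
        scores = sc_allelic.score_cells(counts)
        cats = cfg.category_truth.rename_axis("gene").reset_index()
        out = sc_allelic.category_scores(scores, cats)
        binned = sc_allelic.bin_by_pseudotime(out["reactivation_score"].to_numpy(),
                                              meta["pseudotime"].to_numpy(), 10)
        rho = spearmanr(binned["bin"], binned["mean"]).statistic
        assert rho > 0.9


class TestFlatNull:
    def test_minor_fraction_matches_target(self):
        counts = synthetic.simulate_flat_allelic_counts(500, 0.1, depth_mean=500, seed=0)
        minor = (counts["total_reads"] - counts["ref_reads"]).sum()
        assert minor / counts["total_reads"].sum() == pytest.approx(0.1, abs=0.01)


class TestExpressionSimulator:
    def test_unit_fold_case_cells_match_controls(self):
        expr, _, labels = synthetic.simulate_expression_for_deviation(
            {"control": 5, "case": 5}, {"G0001": ("up", 1.0)}, sigma=0.0, seed=0)
        assert np.allclose(expr.loc[labels == "control"].to_numpy(),
                           expr.loc[labels == "case"].to_numpy())

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            synthetic.simulate_expression_for_deviation(
                {"control": 2, "case": 2}, {"G0001": ("up", -1.0)})
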