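import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from conftest import additive_share_enumeration
from domdev.cohort import (CohortConfig, VariantPanel, genetic_values,
                           simulate_cohort_pair, simulate_genotypes,
                           simulate_phenotype)


class TestVariantPanel:
    def test_zero_maf_rejected(self):
        with pytest.raises(ValueError, match="var1"):
            VariantPanel(["var1"], [0.0], [0.1], [0.0], ["additive"])

    def test_maf_above_half_rejected(self):
        with pytest.raises(ValueError):
            VariantPanel(["v"], [0.6], [0.1], [0.0], ["additive"])

    def test_mode_constraints(self):
        with pytest.raises(ValueError):
            VariantPanel(["v"], [0.2], [0.1], [0.05], ["additive"])
        with pytest.raises(ValueError):
            VariantPanel(["v"], [0.2], [0.1], [0.05], ["dominant"])
        # dominant: heterozygote value equals minor-homozygote value
        p = VariantPanel(["v"], [0.2], [0.1], [0.1], ["dominant"])
        vals = p.genotypic_values()[0]
        assert vals[1] == pytest.approx(vals[2])
        # recessive: heterozygote value equals major-homozygote value
        p = VariantPanel(["v"], [0.2], [0.1], [-0.1], ["recessive"])
        vals = p.genotypic_values()[0]
        assert vals[1] == pytest.approx(vals[0])

    def test_default_size_and_maf_filter(self):
        p = VariantPanel.default()
        assert p.n_variants == 146
        assert (p.maf > 0.03).all() and (p.maf <= 0.5).all()

    def test_file_round_trip(self, tmp_path):
        p = VariantPanel.default(8, "dominant", seed=4)
        path = tmp_path / "panel.tsv"
        p.write(path)
        back = VariantPanel.read(path)
        np.testing.assert_array_equal(back.variant_id, p.variant_id)
        np.testing.assert_allclose(back.maf, p.maf)
        np.testing.assert_allclose(back.gamma_true, p.gamma_true)


class TestSimulateGenotypes:
    def test_deterministic(self, small_panel):
        a = simulate_genotypes(small_panel, 500, seed=3)
        b = simulate_genotypes(small_panel, 500, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_n_must_be_positive(self, small_panel):
        with pytest.raises(ValueError):
            simulate_genotypes(small_panel, 0, seed=1)

    def test_half_maf_mean_count(self):
        panel = VariantPanel(["v"], [0.5], [0.0], [0.0], ["additive"])
        g = simulate_genotypes(panel, 100_000, seed=9)
        assert 0.99 <= g.values.mean() <= 1.01

    def test_hwe_proportions_full_panel(self):
        panel = VariantPanel.default(146, "additive", seed=5)
        g = simulate_genotypes(panel, 75_000, seed=6)
        assert g.values.shape == (75_000, 146)
        n = 75_000
        for j, q in enumerate(panel.maf):
            expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            counts = np.bincount(g.values[:, j], minlength=3)
            se = np.sqrt(n * expected * (1 - expected))
            assert np.all(np.abs(counts - n * expected) <= 4 * se + 1)

    def test_hwe_chisquare_non_rejection(self):
        panel = VariantPanel.default(20, "additive", seed=8)
        g = simulate_genotypes(panel, 10_000, seed=8)
        for j, q in enumerate(panel.maf):
            counts = np.bincount(g.values[:, j], minlength=3)
            expected = 10_000 * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            p = stats.chisquare(counts, expected).pvalue
            assert p > 0.001


class TestSimulatePhenotype:
    def test_zero_r2_is_noise(self, small_panel):
        n = 50_000
        g = simulate_genotypes(small_panel, n, seed=2)
        y = simulate_phenotype(g, small_panel, 0.0, noise_seed=3)
        gv = genetic_values(g, small_panel)
        r = np.corrcoef(gv, y)[0, 1]
        assert abs(r) < 4 / np.sqrt(n)

    def test_single_additive_variant_realized_r2(self):
        panel = VariantPanel(["v"], [0.3], [0.2], [0.0], ["additive"])
        g = simulate_genotypes(panel, 200_000, seed=4)
        y = simulate_phenotype(g, panel, 0.10, noise_seed=5)
        r2 = np.corrcoef(g.values[:, 0], y)[0, 1] ** 2
        assert r2 == pytest.approx(0.10, abs=0.005)

    def test_dominant_additive_variance_share(self):
        # closed form 2(1-p)/(2(1-p)+p) = 0.889 at minor frequency 0.2
        q = 0.2
        panel = VariantPanel(["v"], [q], [0.3], [0.3], ["dominant"])
        share_closed = 2 * (1 - q) / (2 * (1 - q) + q)
        assert share_closed == pytest.approx(0.889, abs=1e-3)
        freqs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        share_enum = additive_share_enumeration(panel.genotypic_values()[0], freqs)
        assert share_enum == pytest.approx(share_closed, abs=1e-12)

        n = 400_000
        g = simulate_genotypes(panel, n, seed=6)
        y = simulate_phenotype(g, panel, 0.10, noise_seed=7)
        gcol = g.values[:, 0].astype(float)
        r2_add = np.corrcoef(gcol, y)[0, 1] ** 2
        gv = genetic_values(g, panel)
        r2_total = np.corrcoef(gv, y)[0, 1] ** 2
        assert r2_add / r2_total == pytest.approx(share_closed, abs=0.02)

    def test_invalid_target_rejected(self, small_panel):
        g = simulate_genotypes(small_panel, 100, seed=1)
        with pytest.raises(ValueError):
            simulate_phenotype(g, small_panel, 1.0, noise_seed=1)

    def test_all_zero_effects_unscalable(self):
        panel = VariantPanel(["v"], [0.2], [0.0], [0.0], ["additive"])
        g = simulate_genotypes(panel, 100, seed=1)
        with pytest.raises(ValueError, match="constant"):
            simulate_phenotype(g, panel, 0.1, noise_seed=1)

    def test_deterministic(self, small_panel):
        g = simulate_genotypes(small_panel, 200, seed=1)
        y1 = simulate_phenotype(g, small_panel, 0.05, noise_seed=9)
        y2 = simulate_phenotype(g, small_panel, 0.05, noise_seed=9)
        np.testing.assert_array_equal(y1, y2)


class TestCohortPair:
    def test_default_sizes_match_target_design(self):
        panel = VariantPanel.default(5, "additive", seed=0)
        cfg = CohortConfig(panel=panel, seed=0)
        assert cfg.n_discovery == 228_423
        assert cfg.n_replication == 73_577
        disc, repl = simulate_cohort_pair(cfg)
        assert disc.n == 228_423
        assert repl.n == 73_577

    def test_structure_and_disjoint_ids(self, small_cohort_pair):
        disc, repl = small_cohort_pair
        assert disc.refractive_error is None and disc.aosw is not None
        assert repl.refractive_error is not None
        assert not set(disc.genotypes.individual_ids) & set(
            repl.genotypes.individual_ids)
        assert not disc.covariates.isna().any().any()
        assert list(disc.covariates.columns)[:4] == [
            "age", "age_squared", "gender", "array"]

    def test_no_signal_link_gives_chance_auc(self):
        panel = VariantPanel.default(4, "additive", seed=2)
        cfg = CohortConfig(panel=panel, n_discovery=4000, n_replication=4000,
                           aosw_slope=0.0, seed=3)
        _, repl = simulate_cohort_pair(cfg)
        keep = ~np.isnan(repl.aosw)
        auc = roc_auc_score(repl.myopia_true[keep], -repl.aosw[keep])
        assert abs(auc - 0.5) < 0.05

    def test_perfect_link_gives_perfect_auc(self):
        panel = VariantPanel.default(4, "additive", seed=2)
        cfg = CohortConfig(panel=panel, n_discovery=3000, n_replication=3000,
                           aosw_noise_sd=0.0, never_wearer_frac=0.0, seed=3)
        _, repl = simulate_cohort_pair(cfg)
        auc = roc_auc_score(repl.myopia_true, -repl.aosw)
        assert auc > 0.999

    def test_deterministic_given_seed(self):
        panel = VariantPanel.default(4, "additive", seed=2)
        cfg = CohortConfig(panel=panel, n_discovery=500, n_replication=400,
                           seed=42)
        d1, r1 = simulate_cohort_pair(cfg)
        d2, r2 = simulate_cohort_pair(cfg)
        np.testing.assert_array_equal(d1.genotypes.values, d2.genotypes.values)
        np.testing.assert_array_equal(r1.refractive_error, r2.refractive_error)
        np.testing.assert_array_equal(d1.aosw, d2.aosw)

    def test_aosw_link_is_monotone_decreasing_in_myopia(self):
        # more myopic (lower refractive error) -> earlier onset on average
        panel = VariantPanel.default(4, "additive", seed=2)
        cfg = CohortConfig(panel=panel, n_discovery=2000, n_replication=6000,
                           seed=5)
        _, repl = simulate_cohort_pair(cfg)
        keep = ~np.isnan(repl.aosw)
        re, ao = repl.refractive_error[keep], repl.aosw[keep]
        myopic = re <= cfg.myopia_cut
        assert ao[myopic].mean() < ao[~myopic].mean()


class TestNullDominanceCalibration:
    def test_type_i_error_of_downstream_test_under_additive_truth(self):
        """Under additive architecture the dominance-deviation coefficient is
        null; its rejection rate at 0.05 stays near nominal over 500 variants."""
        from domdev.assoc import fit_domdev

        panel = VariantPanel.default(500, "additive", seed=21)
        g = simulate_genotypes(panel, 1500, seed=22)
        y = simulate_phenotype(g, panel, 0.0, noise_seed=23)
        pvals = [
            fit_domdev(g.values[:, j], y, model="linear").p_gamma
            for j in range(500)
        ]
        rate = np.mean(np.array(pvals) < 0.05)
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(rate - 0.05) <= 3 * se
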