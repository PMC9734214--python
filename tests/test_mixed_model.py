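import numpy as np
import pytest

from genebankgp.kernels import (
    DesignMatrices,
    allele_content,
    build_design,
    build_kernels,
    centered_design,
    reduced_g,
)
from genebankgp.mixed_model import (
    ModelSpec,
    fit_gblup,
    fit_multikernel,
    fit_rr_family,
    fit_wblup,
    genomic_heritability,
)
from genebankgp.synthetic_data import (
    SimulationConfig,
    TraitArchitecture,
    simulate_genotypes,
    simulate_trait,
)
from conftest import truth_admixture, y_aligned

from oracles import gls_conditional_oracle, henderson_mme_predict


@pytest.fixture(scope="module")
def toy():
    """Tiny panel + trait for exact oracle comparisons."""
    cfg = SimulationConfig(n_samples=10, n_markers=40, k_pops=2,
                           fst_like_divergence=0.3, admixture_concentration=0.2,
                           seed=301)
    g, q = simulate_genotypes(cfg)
    arch = TraitArchitecture(n_additive_qtl=20, heritability=0.6, seed=302)
    blues, _ = simulate_trait(g, q, arch)
    y = y_aligned(blues, g, np.arange(10))
    return g, q, y


class TestFitGblup:
    def test_matches_gls_oracle_fixed_components(self, toy):
        g, _, y = toy
        G = build_kernels(g).G
        tr, te = np.arange(7), np.arange(7, 10)
        vc = {"sigma2_g": 0.4, "sigma2_e": 0.2}
        fit = fit_gblup(y[tr], G, tr, te, var_components=vc)
        oracle = gls_conditional_oracle(
            y[tr], np.ones((10, 1)), [(G, 0.4)], 0.2, tr, te
        )
        np.testing.assert_allclose(fit.predicted_test, oracle, atol=1e-8)

    def test_matches_henderson_mme(self):
        cfg = SimulationConfig(n_samples=6, n_markers=30, k_pops=1,
                               admixture_concentration=1.0, seed=310)
        g, q = simulate_genotypes(cfg)
        arch = TraitArchitecture(n_additive_qtl=15, heritability=0.7, seed=311)
        blues, _ = simulate_trait(g, q, arch)
        y = y_aligned(blues, g, np.arange(6))
        G = build_kernels(g).G + 1e-6 * np.eye(6)  # invertible for the MME
        tr, te = np.arange(4), np.arange(4, 6)
        s2g, s2e = 0.5, 0.25
        fit = fit_gblup(y[tr], G, tr, te,
                        var_components={"sigma2_g": s2g, "sigma2_e": s2e})
        mme = henderson_mme_predict(y[tr], G, s2e / s2g, tr, te)
        np.testing.assert_allclose(fit.predicted_test, mme, atol=1e-8)

    def test_pure_noise_shrinks_to_mean(self):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(n_samples=120, n_markers=200, k_pops=1,
                               admixture_concentration=1.0, seed=312)
        g, _ = simulate_genotypes(cfg)
        G = build_kernels(g).G
        y = rng.standard_normal(100)
        tr, te = np.arange(100), np.arange(100, 120)
        fit = fit_gblup(y, G, tr, te)
        mu = fit.fixed_effects["mu"]
        assert np.abs(fit.predicted_test - mu).max() < 0.15 * y.std()

    def test_h2_recovery_simulated(self):
        ests = []
        for seed in range(5):
            cfg = SimulationConfig(n_samples=400, n_markers=1000, k_pops=1,
                                   admixture_concentration=1.0, seed=seed)
            g, q = simulate_genotypes(cfg)
            arch = TraitArchitecture(n_additive_qtl=200, heritability=0.8,
                                     seed=seed + 100)
            blues, _ = simulate_trait(g, q, arch)
            G = build_kernels(g).G
            idx = np.arange(400)
            fit = fit_gblup(y_aligned(blues, g, idx), G, idx, idx[:1])
            ests.append(genomic_heritability(fit, {"g": G}))
        assert abs(np.mean(ests) - 0.8) < 0.1

    def test_shift_invariance(self, toy):
        g, _, y = toy
        G = build_kernels(g).G
        tr, te = np.arange(7), np.arange(7, 10)
        f1 = fit_gblup(y[tr], G, tr, te)
        f2 = fit_gblup(y[tr] + 100.0, G, tr, te)
        assert f2.fixed_effects["mu"] == pytest.approx(f1.fixed_effects["mu"] + 100.0, abs=1e-6)
        np.testing.assert_allclose(f2.predicted_test, f1.predicted_test + 100.0, atol=1e-6)
        for key in ("sigma2_g", "sigma2_e"):
            assert f2.variance_components[key] == pytest.approx(
                f1.variance_components[key], rel=1e-5
            )

    def test_scaling_equivariance(self, toy):
        g, _, y = toy
        G = build_kernels(g).G
        tr, te = np.arange(7), np.arange(7, 10)
        f1 = fit_gblup(y[tr], G, tr, te)
        f2 = fit_gblup(3.0 * y[tr], G, tr, te)
        for key in ("sigma2_g", "sigma2_e"):
            assert f2.variance_components[key] == pytest.approx(
                9.0 * f1.variance_components[key], rel=1e-4
            )


class TestFitMultikernel:
    def test_matches_gls_oracle_fixed_components(self, toy):
        g, _, y = toy
        kern = build_kernels(g)
        tr, te = np.arange(7), np.arange(7, 10)
        vc = {"sigma2_g": 0.3, "sigma2_g1": 0.2, "sigma2_e": 0.1}
        fit = fit_multikernel(y[tr], [("g", kern.G), ("g1", kern.H)], tr, te,
                              var_components=vc)
        oracle = gls_conditional_oracle(
            y[tr], np.ones((10, 1)), [(kern.G, 0.3), (kern.H, 0.2)], 0.1, tr, te
        )
        np.testing.assert_allclose(fit.predicted_test, oracle, atol=1e-8)

    def test_pinned_epistatic_component_reduces_to_gblup(self, small_panel, additive_trait):
        g, _ = small_panel
        blues, _ = additive_trait
        kern = build_kernels(g)
        tr, te = np.arange(60), np.arange(60, 80)
        y = y_aligned(blues, g, tr)
        f1 = fit_gblup(y, kern.G, tr, te)
        f2 = fit_multikernel(y, [("g", kern.G), ("g1", kern.H)], tr, te,
                             fixed_components={"g1": 0.0})
        np.testing.assert_allclose(f2.predicted_test, f1.predicted_test, atol=1e-6)

    def test_duplicate_kernel_sum_stable(self, small_panel, additive_trait):
        g, _ = small_panel
        blues, _ = additive_trait
        kern = build_kernels(g)
        tr, te = np.arange(60), np.arange(60, 80)
        y = y_aligned(blues, g, tr)
        single = fit_gblup(y, kern.G, tr, te)
        double = fit_multikernel(y, [("g", kern.G), ("g1", kern.G)], tr, te)
        total_single = single.variance_components["sigma2_g"]
        total_double = (double.variance_components["sigma2_g"]
                        + double.variance_components["sigma2_g1"])
        assert total_double == pytest.approx(total_single, rel=1e-3)
        np.testing.assert_allclose(double.predicted_test, single.predicted_test,
                                   atol=1e-5)

    def test_additive_trait_gives_small_epistatic_share(self):
        shares = []
        for seed in range(5):
            cfg = SimulationConfig(n_samples=200, n_markers=400, k_pops=2,
                                   fst_like_divergence=0.25,
                                   admixture_concentration=0.3, seed=seed + 400)
            g, q = simulate_genotypes(cfg)
            arch = TraitArchitecture(n_additive_qtl=100, heritability=0.8,
                                     seed=seed + 500)
            blues, _ = simulate_trait(g, q, arch)
            kern = build_kernels(g)
            idx = np.arange(200)
            y = y_aligned(blues, g, idx)
            fit = fit_multikernel(y, [("g", kern.G), ("g1", kern.H)], idx, idx[:1])
            vg = fit.variance_components["sigma2_g"] * np.diag(kern.G).mean()
            vg1 = fit.variance_components["sigma2_g1"] * np.diag(kern.H).mean()
            shares.append(vg1 / (vg + vg1))
        assert np.median(shares) < 0.2


class TestFitRrFamily:
    def test_k1_hard_equals_rrblup(self, small_panel, additive_trait):
        g, _ = small_panel
        blues, _ = additive_trait
        z = centered_design(g)
        plain = DesignMatrices(Z_A=z, Z_S=None, Z_Sadm=None,
                               sample_ids=list(g.sample_ids), k=0)
        adm = truth_admixture(np.ones((g.n_samples, 1)))
        one_pop = build_design(g, adm, mode="hard", k=1)
        tr, te = np.arange(60), np.arange(60, 80)
        y = y_aligned(blues, g, tr)
        f_rr = fit_rr_family(y, plain, ModelSpec(family="RRBLUP"), tr, te)
        f_gsa = fit_rr_family(y, one_pop, ModelSpec(family="GSA_RRBLUP", k=1), tr, te)
        np.testing.assert_allclose(f_gsa.predicted_test, f_rr.predicted_test,
                                   atol=1e-6)

    def test_rrblup_equals_gblup_predictions(self, small_panel, additive_trait):
        g, _ = small_panel
        blues, _ = additive_trait
        kern = build_kernels(g)
        z = centered_design(g)
        plain = DesignMatrices(Z_A=z, Z_S=None, Z_Sadm=None,
                               sample_ids=list(g.sample_ids), k=0)
        tr, te = np.arange(60), np.arange(60, 80)
        y = y_aligned(blues, g, tr)
        f_rr = fit_rr_family(y, plain, ModelSpec(family="RRBLUP"), tr, te)
        f_g = fit_gblup(y, kern.G, tr, te)
        np.testing.assert_allclose(f_rr.predicted_test, f_g.predicted_test,
                                   atol=1e-6)

    def test_one_hot_admixed_equals_hard(self, structured_panel):
        g, q = structured_panel
        arch = TraitArchitecture(n_additive_qtl=80, subpop_effect_sd=1.0,
                                 heritability=0.8, seed=320)
        blues, _ = simulate_trait(g, q, arch)
        one_hot = np.zeros_like(q)
        one_hot[np.arange(q.shape[0]), q.argmax(axis=1)] = 1.0
        adm = truth_admixture(one_hot)
        hard = build_design(g, adm, mode="hard")
        soft = build_design(g, adm, mode="admixed")
        tr, te = np.arange(120), np.arange(120, 150)
        y = y_aligned(blues, g, tr)
        fh = fit_rr_family(y, hard, ModelSpec(family="GSA_RRBLUP", k=2), tr, te)
        fa = fit_rr_family(y, soft, ModelSpec(family="GSA_RRBLUP", k=2, admixed=True),
                           tr, te)
        np.testing.assert_allclose(fa.predicted_test, fh.predicted_test, atol=1e-6)

    def test_oracle_fixed_components(self, toy):
        g, q, y = toy
        adm = truth_admixture(q)
        design = build_design(g, adm, mode="admixed")
        tr, te = np.arange(7), np.arange(7, 10)
        scale = float(np.trace(design.Z_A @ design.Z_A.T)) / design.Z_A.shape[0]
        vc = {"sigma2_a": 0.3, "sigma2_S1": 0.1, "sigma2_S2": 0.15, "sigma2_e": 0.2}
        fit = fit_rr_family(y[tr], design, ModelSpec(family="GSA_RRBLUP", k=2, admixed=True),
                            tr, te, var_components=vc)
        comps = [(design.Z_A @ design.Z_A.T / scale, 0.3)]
        for c, z in enumerate(design.Z_Sadm):
            comps.append((z @ z.T / scale, vc[f"sigma2_S{c + 1}"]))
        oracle = gls_conditional_oracle(y[tr], np.ones((10, 1)), comps, 0.2, tr, te)
        np.testing.assert_allclose(fit.predicted_test, oracle, atol=1e-8)

    def test_empty_subpopulation_dropped(self, structured_panel, caplog):
        g, q = structured_panel
        arch = TraitArchitecture(n_additive_qtl=50, heritability=0.8, seed=321)
        blues, _ = simulate_trait(g, q, arch)
        labels = q.argmax(axis=1)
        adm = truth_admixture(np.eye(2)[labels])
        design = build_design(g, adm, mode="hard")
        pop0 = np.where(labels == 0)[0]
        tr, te = pop0[:-10], pop0[-10:]  # training set contains only one cluster
        y = y_aligned(blues, g, tr)
        import logging

        with caplog.at_level(logging.WARNING):
            fit = fit_rr_family(y, design, ModelSpec(family="GSA_RRBLUP", k=2), tr, te)
        assert "dropped" in caplog.text
        assert "sigma2_S2" not in fit.variance_components

    def test_marker_effects_reported(self, small_panel, additive_trait):
        g, _ = small_panel
        blues, _ = additive_trait
        z = centered_design(g)
        plain = DesignMatrices(Z_A=z, Z_S=None, Z_Sadm=None,
                               sample_ids=list(g.sample_ids), k=0)
        tr, te = np.arange(60), np.arange(60, 80)
        y = y_aligned(blues, g, tr)
        fit = fit_rr_family(y, plain, ModelSpec(family="RRBLUP"), tr, te)
        assert fit.marker_effects["a"].shape == (z.shape[1],)
        # marker BLUPs reproduce the genetic-value BLUPs: Z a == u
        u = z[tr] @ fit.marker_effects["a"]
        np.testing.assert_allclose(u, fit.random_blups["a"][tr], atol=1e-8)


class TestFitWblup:
    @pytest.fixture(scope="class")
    @staticmethod
    def qtl_panel():
        cfg = SimulationConfig(n_samples=400, n_markers=500, k_pops=1,
                               admixture_concentration=1.0, seed=330)
        g, q = simulate_genotypes(cfg)
        arch = TraitArchitecture(n_additive_qtl=50, n_major_qtl=1,
                                 major_qtl_variance_share=0.5, heritability=0.8,
                                 seed=331)
        blues, truth = simulate_trait(g, q, arch)
        return g, blues, truth

    def test_recovers_planted_effect(self, qtl_panel):
        g, blues, truth = qtl_panel
        j, effect = truth.major_qtl[0]
        marker = g.marker_ids[j]
        tr, te = np.arange(320), np.arange(320, 400)
        y = y_aligned(blues, g, tr)
        fit = fit_wblup(y, reduced_g(g, [marker]), allele_content(g, [marker]), tr, te)
        a_hat = fit.fixed_effects["a_F_0"]
        assert np.sign(a_hat) == np.sign(effect)
        assert abs(a_hat - effect) < 0.25 * abs(effect)

    def test_constant_column_rejected(self, qtl_panel):
        g, blues, _ = qtl_panel
        tr, te = np.arange(320), np.arange(320, 400)
        y = y_aligned(blues, g, tr)
        const = np.full((g.n_samples, 1), 2.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_wblup(y, build_kernels(g).G, const, tr, te)

    def test_duplicate_column_dropped(self, qtl_panel):
        g, blues, truth = qtl_panel
        j, _ = truth.major_qtl[0]
        marker = g.marker_ids[j]
        tr, te = np.arange(320), np.arange(320, 400)
        y = y_aligned(blues, g, tr)
        f = allele_content(g, [marker, marker])
        fit = fit_wblup(y, reduced_g(g, [marker]), f, tr, te)
        assert "a_F_1" not in fit.fixed_effects

    def test_matches_gls_oracle_fixed_components(self, toy):
        g, _, y = toy
        marker = g.marker_ids[5]
        G_r = reduced_g(g, [marker])
        f = allele_content(g, [marker])
        tr, te = np.arange(7), np.arange(7, 10)
        vc = {"sigma2_g": 0.4, "sigma2_e": 0.2}
        fit = fit_wblup(y[tr], G_r, f, tr, te, var_components=vc)
        x_full = np.column_stack([np.ones(10), f])
        oracle = gls_conditional_oracle(y[tr], x_full, [(G_r, 0.4)], 0.2, tr, te)
        np.testing.assert_allclose(fit.predicted_test, oracle, atol=1e-8)

    def test_zero_markers_rejected(self, toy):
        g, _, y = toy
        with pytest.raises(ValueError, match="fall back"):
            fit_wblup(y[:7], build_kernels(g).G, np.empty((10, 0)),
                      np.arange(7), np.arange(7, 10))


class TestModelSpec:
    def test_default_names(self):
        assert ModelSpec(family="GBLUP").name == "G-BLUP"
        assert ModelSpec(family="WBLUP", marker_strategy="S3").name == "W-BLUP_S3"
        assert ModelSpec(family="GSA_RRBLUP", k=5, admixed=True).name == "GSA-RRBLUP_adm_k5"

    def test_rejects_bad_family(self):
        with pytest.raises(ValueError):
            ModelSpec(family="BAYES_B")

    def test_wblup_requires_strategy(self):
        with pytest.raises(ValueError):
            ModelSpec(family="WBLUP")
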