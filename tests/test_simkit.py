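"""Scenario construction and the replicate engine."""

import itertools

import numpy as np
import pytest

from regjoint.hapcore import (
    allele_frequencies,
    haplotype_variance,
    pairwise_ld,
    system_with_r2,
)
from regjoint.simkit import (
    InfeasibleLDError,
    common_variant_scenario,
    extend_with_nuisance,
    generate_fixture_panel,
    panel_window_scenario,
    rare_tagging_scenario,
    run_scenario,
    sample_diplotypes,
    simulate_phenotype,
)

from conftest import PI_A


class TestSampling:
    def test_rows_sum_to_two(self, sys_r2_zero, rng):
        sample = sample_diplotypes(sys_r2_zero, 500, rng)
        assert (sample.D.sum(axis=1) == 2).all()

    def test_determinism(self, sys_r2_zero):
        a = sample_diplotypes(sys_r2_zero, 200, np.random.default_rng(5))
        b = sample_diplotypes(sys_r2_zero, 200, np.random.default_rng(5))
        assert (a.D == b.D).all()

    def test_phenotype_variance_decomposition(self, sys_r2_zero, rng):
        beta = np.array([0.3, -0.1, 0.2, 0.0])
        s = sys_r2_zero.with_beta(beta)
        sample = sample_diplotypes(s, 200_000, rng)
        y = simulate_phenotype(sample, s, rng)
        expect = haplotype_variance(s) + 1.0
        assert y.y.var() == pytest.approx(expect, rel=0.02)

    def test_null_phenotype_pure_noise(self, sys_r2_zero, rng):
        s = sys_r2_zero.with_beta(np.zeros(4))
        sample = sample_diplotypes(s, 50_000, rng)
        y = simulate_phenotype(sample, s, rng)
        assert y.y.var() == pytest.approx(1.0, rel=0.03)


class TestNuisanceExtension:
    def test_independent_nuisance_by_product_measure(self, sys_r2_02):
        s = sys_r2_02.with_beta([0.1, 0.2, 0.0, -0.1])
        ext = extend_with_nuisance(s, 2, 0.0)
        assert ext.m == 4
        for a, b in itertools.combinations(range(4), 2):
            if a >= 2 or b >= 2:
                assert pairwise_ld(ext, a, b)[2] == pytest.approx(0.0, abs=1e-12)
        assert haplotype_variance(ext) == pytest.approx(
            haplotype_variance(s), abs=1e-12
        )

    def test_all_pairs_at_r2_02(self):
        base = system_with_r2(0.40, 0.48, 0.2)
        base = base.with_beta([0.0, 0.1, -0.1, 0.2])
        ext = extend_with_nuisance(base, 2, 0.2)
        for a, b in itertools.combinations(range(4), 2):
            assert pairwise_ld(ext, a, b)[2] == pytest.approx(0.2, abs=1e-6)
        assert haplotype_variance(ext) == pytest.approx(
            haplotype_variance(base), abs=1e-12
        )

    def test_infeasible_target_raises(self):
        base = system_with_r2(0.05, 0.5, 0.0)
        with pytest.raises(InfeasibleLDError):
            extend_with_nuisance(base, 1, 0.9)


class TestRareTagging:
    def test_perfect_tag_geometry(self):
        cfg = rare_tagging_scenario(r2_hap=1.0, variance_explained=0.01)
        s = cfg.system
        # 1-1 haplotype of the common pair has frequency f_rare and always
        # carries the rare allele
        f = 1.0 / 576.0
        carrier = (s.H[:, 0] == 1) & (s.H[:, 1] == 1)
        assert s.pi[carrier].sum() == pytest.approx(f, abs=1e-12)
        assert (s.H[carrier, 2] == 1).all()
        # commons in mutual LE, per-common-SNP r2 with rare = p/(1+p) = 0.04
        assert pairwise_ld(s, 0, 1)[2] == pytest.approx(0.0, abs=1e-12)
        for c in (0, 1):
            assert pairwise_ld(s, c, 2)[2] == pytest.approx(0.04, abs=1e-12)
        d, dprime, _ = pairwise_ld(s, 0, 2)
        assert dprime == pytest.approx(1.0, abs=1e-12)
        assert haplotype_variance(s) == pytest.approx(0.01, abs=1e-12)

    def test_partial_tag_geometry(self):
        cfg = rare_tagging_scenario(f_rare=0.005, r2_hap=0.5, variance_explained=0.005)
        s = cfg.system
        # r2 between the rare allele and the 1-1 haplotype indicator
        f = 0.005
        carrier = (s.H[:, 0] == 1) & (s.H[:, 1] == 1)
        h = s.pi[carrier].sum()
        r2 = (f * (1 - h)) / (h * (1 - f))
        assert r2 == pytest.approx(0.5, abs=1e-10)
        assert haplotype_variance(s) == pytest.approx(0.005, abs=1e-12)

    def test_masking_controls_visible_columns(self):
        masked = rare_tagging_scenario()
        assert list(masked.visible_snps) == [0, 1]
        typed = rare_tagging_scenario(mask_rare=False)
        assert list(typed.visible_snps) == [0, 1, 2]

    def test_nuisance_extension_keeps_geometry(self):
        cfg = rare_tagging_scenario(n_common_extra=3)
        assert cfg.system.m == 6
        assert haplotype_variance(cfg.system) == pytest.approx(0.01, abs=1e-12)

    def test_rejects_common_frequency(self):
        with pytest.raises(ValueError):
            rare_tagging_scenario(f_rare=0.05)


class TestRunScenario:
    def test_no_type_i_inflation_under_null(self, sys_r2_02):
        cfg = common_variant_scenario(
            sys_r2_02.pi, 0.006, 0.0, n=400, n_replicates=400,
            models=("additive", "interaction", "genotypic", "haplotype", "vc"),
            alpha=0.05, seed=3,
        )
        cfg.system.beta[:] = 0.0  # null: no genetic effect
        res = run_scenario(cfg)
        se = np.sqrt(0.05 * 0.95 / 400)
        for mdl in cfg.models:
            assert res.row(mdl)["power"] == pytest.approx(0.05, abs=4 * se)

    def test_deterministic_given_seed(self, sys_r2_zero):
        cfg = common_variant_scenario(PI_A, 0.006, 0.3, n=300, n_replicates=30,
                                      models=("additive",), seed=11)
        t1 = run_scenario(cfg).table
        t2 = run_scenario(cfg).table
        assert t1.equals(t2)

    def test_all_models_unbiased_at_tau_zero(self):
        # tau' = 0, no masking: every model family's adjusted variance
        # estimate agrees with sigma2_H within Monte-Carlo error
        cfg = common_variant_scenario(
            PI_A, 0.02, 0.0, n=1000, n_replicates=300,
            models=("additive", "interaction", "genotypic", "haplotype", "vc"),
            alpha=1e-3, seed=29,
        )
        res = run_scenario(cfg)
        for mdl in cfg.models:
            row = res.row(mdl)
            tol = 3 * row["se_sigma2_adj"]
            assert row["mean_sigma2_adj"] == pytest.approx(0.02, abs=tol)

    def test_typed_rare_variant_reverses_model_ordering(self):
        """With the rare causal SNP genotyped (five common SNPs, two of which
        tag it), the low-df additive model beats the genotypic and haplotype
        models on power: their class/haplotype spaces explode with m."""
        n_rep = 200
        cfg = rare_tagging_scenario(
            variance_explained=0.0025, n=3000, n_replicates=n_rep, mask_rare=False,
            n_common_extra=3, models=("additive", "genotypic", "haplotype"),
            alpha=1e-3, seed=17,
        )
        res = run_scenario(cfg)
        p_add = res.row("additive")["power"]
        for mdl in ("genotypic", "haplotype"):
            p_other = res.row(mdl)["power"]
            se = np.sqrt(
                max(p_add * (1 - p_add), p_other * (1 - p_other), 0.01) / n_rep
            )
            assert p_add > p_other + 3 * se
        # and the additive estimate is unbiased for the full rare-SNP variance
        row = res.row("additive")
        assert row["mean_sigma2_adj"] == pytest.approx(
            0.0025, abs=3 * row["se_sigma2_adj"]
        )


class TestFixturePanel:
    def test_maf_bounds_and_determinism(self):
        p1 = generate_fixture_panel(200, 150, 0.1, (0.05, 0.45), seed=9)
        p2 = generate_fixture_panel(200, 150, 0.1, (0.05, 0.45), seed=9)
        assert (p1.haplotypes == p2.haplotypes).all()
        maf = p1.maf()
        assert maf.min() >= 0.05 and maf.max() <= 0.45

    def test_ld_decays_with_distance(self):
        panel = generate_fixture_panel(300, 200, 0.08, (0.1, 0.5), seed=2)
        r2 = panel.r2_matrix()
        lags = [1, 3, 10, 40]
        means = []
        for lag in lags:
            vals = [r2[i, i + lag] for i in range(panel.m - lag)]
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_positions_increasing(self):
        panel = generate_fixture_panel(100, 50, 0.2, (0.05, 0.5), seed=4)
        pos = panel.snp_meta["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()


@pytest.fixture(scope="module")
def panel():
    return generate_fixture_panel(400, 200, 0.12, (0.05, 0.5), seed=13)


class TestPanelWindowScenario:

    def test_window_filters_and_masking(self, panel):
        cfg = panel_window_scenario(
            panel, window_size=60, sigma2_H=0.006, tau_prime=0.0,
            mask_causal=True, n=500, n_replicates=2, seed=1,
        )
        assert cfg.system.m == 60
        assert len(cfg.mask) == 2
        assert len(cfg.visible_snps) == 58
        assert haplotype_variance(cfg.system) == pytest.approx(0.006, abs=1e-9)

    def test_prune_and_maf_postconditions(self, panel):
        cfg = panel_window_scenario(panel, window_size=60, n_replicates=2, seed=1)
        sys_h = cfg.system
        # reconstruct per-SNP frequencies from the collapsed system
        xi = allele_frequencies(sys_h)
        maf = np.minimum(xi, 1 - xi)
        assert (maf > 0.01).all()
        # no retained pair above the prune threshold
        for a in range(0, 60, 7):
            for b in range(a + 1, min(a + 8, 60)):
                assert pairwise_ld(sys_h, a, b)[2] <= 0.80 + 1e-9

    def test_panel_too_small_raises(self):
        tiny = generate_fixture_panel(100, 40, 0.2, (0.05, 0.5), seed=5)
        with pytest.raises(ValueError, match="window"):
            panel_window_scenario(tiny, window_size=100, n_replicates=1)

    def test_masked_additive_fit_runs(self, panel):
        cfg = panel_window_scenario(
            panel, window_size=40, sigma2_H=0.02, tau_prime=0.2,
            mask_causal=True, n=400, n_replicates=5,
            models=("additive",), alpha=1e-3, seed=21,
        )
        res = run_scenario(cfg)
        assert res.row("additive")["n_replicates"] == 5
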