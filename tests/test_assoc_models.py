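"""Design construction, least-squares fitting, EM dosages, and the HE variance
component, cross-checked against statsmodels and analytic oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from regjoint.assoc_models import (
    KinshipMatrix,
    design_additive,
    design_genotypic,
    design_haplotype,
    design_interaction,
    em_haplotype_dosages,
    fit_linear,
    fit_model,
    fit_vc_he,
    grm,
    vc_pvalue_davies,
)
from regjoint.hapcore import (
    GenotypeDataset,
    HaplotypeSystem,
    PhenotypeVector,
    default_snp_meta,
    genotypes_from_diplotypes,
)
from regjoint.simkit import sample_diplotypes

from conftest import H4, PI_A


def _dataset(G):
    G = np.asarray(G, dtype=np.int16)
    return GenotypeDataset(G, default_snp_meta(G.shape[1]))


class TestDesigns:
    def test_additive_is_identity_on_counts(self):
        G = _dataset([[0, 2, 1], [1, 1, 0]])
        X = design_additive(G)
        assert (X.X == G.G).all()
        assert X.q == 3

    def test_additive_column_means_are_twice_frequency(self, rng):
        G = _dataset(rng.integers(0, 3, size=(200, 4)))
        X = design_additive(G)
        np.testing.assert_allclose(X.X.mean(axis=0), 2 * G.G.mean(axis=0) / 2)

    def test_interaction_row(self):
        G = _dataset([[1, 2], [0, 1]])
        X = design_interaction(G)
        assert X.q == 3
        assert (X.X[0] == [1, 2, 2]).all()

    def test_interaction_column_count_m4(self, rng):
        G = _dataset(rng.integers(0, 3, size=(30, 4)))
        assert design_interaction(G).q == 4 + 6

    def test_interaction_needs_two_snps(self):
        with pytest.raises(ValueError):
            design_interaction(_dataset([[0], [1]]))

    def test_genotypic_indicators_partition_sample(self, rng):
        G = _dataset(rng.integers(0, 3, size=(100, 2)))
        X = design_genotypic(G)
        # with the reference class dropped, each row has at most one 1, kept
        # column sums equal the class counts, and the rows with all-zero
        # indicators are exactly the reference-class individuals
        assert set(np.unique(X.X)) <= {0.0, 1.0}
        assert (X.X.sum(axis=1) <= 1).all()
        classes, counts = np.unique(G.G, axis=0, return_counts=True)
        assert X.q == len(classes) - 1
        assert X.X.sum() == 100 - counts.max()
        kept_counts = sorted(X.X.sum(axis=0))
        expect = sorted(np.delete(counts, np.argmax(counts)))
        assert kept_counts == [float(c) for c in expect]

    def test_genotypic_degenerate_single_class(self):
        # one multilocus genotype class only: nothing to contrast against
        with pytest.raises(ValueError):
            design_genotypic(_dataset([[1, 1], [1, 1]]))

    def test_genotypic_refuses_large_m(self, rng):
        G = _dataset(rng.integers(0, 3, size=(10, 9)))
        with pytest.raises(ValueError, match="genotypic"):
            design_genotypic(G)


class TestEMDosages:
    def test_unambiguous_homozygote(self):
        G = _dataset([[0, 0], [0, 0], [2, 2]])
        dos = em_haplotype_dosages(G)
        labels = ["".join(map(str, h)) for h in dos.haplotypes]
        i00, i11 = labels.index("00"), labels.index("11")
        assert dos.M[0, i00] == pytest.approx(2.0, abs=1e-12)
        assert dos.M[2, i11] == pytest.approx(2.0, abs=1e-12)

    def test_double_het_balanced_frequencies(self):
        # equal numbers of all four unambiguous homozygote classes keep the
        # EM frequencies uniform, so both phasings of (1,1) stay equally likely
        G = _dataset([[0, 0], [0, 2], [2, 0], [2, 2], [1, 1]])
        dos = em_haplotype_dosages(G)
        i = {"".join(map(str, h)): j for j, h in enumerate(dos.haplotypes)}
        row = dos.M[4]
        assert row[i["00"]] == pytest.approx(row[i["11"]], abs=1e-6)
        assert row[i["01"]] == pytest.approx(row[i["10"]], abs=1e-6)
        assert row.sum() == pytest.approx(2.0, abs=1e-12)

    def test_double_het_with_impossible_phase(self):
        # when 01/10 haplotypes have zero estimated frequency, the double
        # heterozygote must be phased as 00 + 11
        G = _dataset([[0, 0]] * 5 + [[2, 2]] * 5 + [[1, 1]])
        dos = em_haplotype_dosages(G)
        i = {"".join(map(str, h)): j for j, h in enumerate(dos.haplotypes)}
        row = dos.M[-1]
        assert row[i["00"]] == pytest.approx(1.0, abs=1e-6)
        assert row[i["11"]] == pytest.approx(1.0, abs=1e-6)

    def test_loglik_monotone_and_frequencies_consistent(self, rng, sys_r2_02):
        sample = sample_diplotypes(sys_r2_02, 400, rng)
        G = genotypes_from_diplotypes(sample)
        dos = em_haplotype_dosages(G)
        assert dos.converged
        diffs = np.diff(dos.loglik_trace)
        assert (diffs >= -1e-9).all()
        # EM frequencies equal the mean posterior dosage / 2
        np.testing.assert_allclose(dos.em_frequencies, dos.M.mean(axis=0) / 2,
                                   atol=1e-6)

    def test_unambiguous_data_converges_immediately(self):
        G = _dataset([[0, 0], [2, 2], [0, 2]])
        dos = em_haplotype_dosages(G)
        assert len(dos.loglik_trace) <= 2


class TestFitLinear:
    def test_perfect_fit(self, rng):
        X = rng.integers(0, 3, size=(50, 2)).astype(np.int16)
        G = _dataset(X)
        y = X[:, 1].astype(float)
        fit = fit_linear(design_additive(G), y)
        assert fit.r2_raw == pytest.approx(1.0, abs=1e-10)
        assert fit.p_value < 1e-30

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.integers(0, 3, size=(120, 3)).astype(np.int16)
        y = rng.standard_normal(120) + X @ np.array([0.1, -0.2, 0.05])
        fit = fit_linear(design_additive(_dataset(X)), y)
        ref = sm.OLS(y, sm.add_constant(X.astype(float))).fit()
        np.testing.assert_allclose(fit.beta_hat, ref.params[1:], atol=1e-10)
        assert fit.r2_raw == pytest.approx(ref.rsquared, abs=1e-12)
        assert fit.f_stat == pytest.approx(ref.fvalue, rel=1e-10)
        assert fit.p_value == pytest.approx(ref.f_pvalue, rel=1e-8)
        assert fit.r2_adj == pytest.approx(ref.rsquared_adj, abs=1e-12)
        # per-coefficient stats
        np.testing.assert_allclose(
            fit.coef_table.sort_values("term")["se"].to_numpy(),
            ref.bse[1:],
            atol=1e-10,
        )

    def test_rank_deficiency_reported(self, rng):
        X = rng.integers(0, 3, size=(60, 2)).astype(np.int16)
        Xdup = np.column_stack([X, X[:, 0]])
        fit = fit_linear(design_additive(_dataset(Xdup)), rng.standard_normal(60))
        assert fit.df1 == 2
        assert len(fit.dropped_columns) == 1

    def test_null_p_values_uniform(self, rng):
        X = rng.integers(0, 3, size=(80, 3)).astype(np.int16)
        design = design_additive(_dataset(X))
        ps = [
            fit_linear(design, rng.standard_normal(80)).p_value for _ in range(400)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_y_rejected(self, rng):
        G = _dataset(rng.integers(0, 3, size=(30, 2)))
        with pytest.raises(ValueError):
            fit_linear(design_additive(G), np.ones(30))

    def test_adjusted_variance_unbiased_at_null(self, rng):
        X = rng.integers(0, 3, size=(100, 4)).astype(np.int16)
        design = design_additive(_dataset(X))
        est = np.array(
            [fit_linear(design, rng.standard_normal(100)).sigma2_adj
             for _ in range(600)]
        )
        se = est.std(ddof=1) / np.sqrt(600)
        assert abs(est.mean()) < 4 * se


class TestGRM:
    def test_z_columns_standardized(self, rng):
        # the sqrt(2 xi (1 - xi)) normalization assumes HWE genotype counts
        G = _dataset(rng.binomial(2, 0.35, size=(500, 5)))
        Gamma = grm(G)
        np.testing.assert_allclose(Gamma.Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Gamma.Z.std(axis=0) ** 2, 1.0, atol=0.15)

    def test_identical_individuals_share_kinship(self):
        G = _dataset([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 0, 1]])
        Gamma = grm(G).dense()
        assert Gamma[0, 1] == pytest.approx(Gamma[0, 0], abs=1e-10)

    def test_monomorphic_named(self):
        G = _dataset([[0, 1], [0, 2], [0, 0]])
        with pytest.raises(ValueError, match="snp1"):
            grm(G)

    def test_off_diagonal_mean_near_zero_in_le(self, rng):
        G = _dataset(rng.binomial(2, 0.3, size=(500, 20)))
        Gamma = grm(G).dense()
        off = Gamma[np.triu_indices(500, k=1)]
        assert abs(off.mean()) < 5e-3


class TestHasemanElston:
    def test_null_estimate_near_zero(self, rng):
        ests = []
        for _ in range(100):
            G = _dataset(rng.binomial(2, 0.4, size=(300, 10)))
            y = PhenotypeVector(rng.standard_normal(300)).standardize()
            s2, _, _ = fit_vc_he(grm(G), y)
            ests.append(s2)
        ests = np.array(ests)
        assert abs(ests.mean()) < 4 * ests.std(ddof=1) / 10

    def test_recovers_planted_genetic_variance(self, rng):
        # y = Z b + e with total genetic variance 0.3, SNPs in LE
        n, m, s2g = 2000, 50, 0.3
        ests = []
        for _ in range(120):
            G = rng.binomial(2, 0.3, size=(n, m)).astype(np.int16)
            Gd = _dataset(G)
            Gamma = grm(Gd)
            b = rng.standard_normal(m) * np.sqrt(s2g / m)
            y = Gamma.Z @ b + rng.standard_normal(n) * np.sqrt(1 - s2g)
            yv = PhenotypeVector(y).standardize()
            s2, _, _ = fit_vc_he(Gamma, yv)
            ests.append(s2)
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert ests.mean() == pytest.approx(s2g, abs=3 * se)

    def test_he_matches_dense_pair_regression(self, rng):
        # the O(nm) sufficient-statistic evaluation equals the explicit
        # regression over all pairs
        n = 60
        G = _dataset(rng.binomial(2, 0.4, size=(n, 4)))
        y = PhenotypeVector(rng.standard_normal(n)).standardize()
        Gamma = grm(G)
        s2, v0, v1 = fit_vc_he(Gamma, y)
        dense = Gamma.dense()
        iu = np.triu_indices(n, k=1)
        x = dense[iu]
        d = (y.y[iu[0]] - y.y[iu[1]]) ** 2
        slope, intercept = np.polyfit(x, d, 1)
        assert v1 == pytest.approx(slope, rel=1e-8)
        assert v0 == pytest.approx(intercept, rel=1e-8)
        assert s2 == pytest.approx(-slope / 2, rel=1e-8)


class TestEquivalenceAdditiveVC:
    def test_explained_variance_equals_quadratic_form(self, rng):
        """With exactly orthogonal standardized genotypes, the additive model's
        fitted genetic variance equals y'Z(Z'Z)^-1 Z'y / n = y'ZZ'y / n^2."""
        n, m = 240, 5
        A = rng.standard_normal((n, m))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        Z = Q * np.sqrt(n)  # Z'Z = nI, columns centered
        y = rng.standard_normal(n)
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        ess = float(((Z @ coef) ** 2).sum())
        quad = float(yc @ Z @ Z.T @ yc) / n
        assert ess == pytest.approx(quad, abs=1e-10)
        # and the module's quadratic form carries the same quantity up to
        # its documented ZZ'/m scaling: y'Gamma y = (ess * n) / m
        Gamma = KinshipMatrix(Z, m_snps=m)
        q_scaled = Gamma.quad_form(yc)
        assert q_scaled == pytest.approx(quad * n / m, rel=1e-12)


class TestDaviesPValue:
    def test_identity_kinship_is_chi_square(self, rng):
        n = 50
        Z = np.eye(n)
        Gamma = KinshipMatrix(Z, m_snps=n, scaling="zz_raw")
        y = PhenotypeVector(rng.standard_normal(n)).standardize()
        p = vc_pvalue_davies(Gamma, y)
        q = float(y.y @ y.y)
        assert p == pytest.approx(stats.chi2.sf(q, n), rel=1e-8)

    def test_rank_one_kinship(self, rng):
        n = 80
        v = rng.standard_normal(n)[:, None]
        Gamma = KinshipMatrix(v, m_snps=1, scaling="zz_raw")
        y = PhenotypeVector(rng.standard_normal(n)).standardize()
        p = vc_pvalue_davies(Gamma, y)
        lam = float(v.ravel() @ v.ravel())
        q = float((v.ravel() @ y.y) ** 2)
        assert p == pytest.approx(stats.chi2.sf(q / lam, 1), rel=1e-8)

    def test_null_type_i_error(self, rng):
        # fixed genotypes, repeated null traits: rejection at the Davies
        # critical value is binomial around alpha
        from regjoint.quadform import weighted_chi2_quantile

        n, m, reps, alpha = 400, 6, 4000, 0.05
        G = _dataset(rng.binomial(2, 0.3, size=(n, m)))
        Gamma = grm(G)
        lam = Gamma.eigenvalues()
        qcrit = weighted_chi2_quantile(alpha, lam)
        Y = rng.standard_normal((n, reps))
        Y = Y - Y.mean(axis=0)
        Y = Y / Y.std(axis=0)
        Q = ((Gamma.Z.T @ Y) ** 2).sum(axis=0) / m
        rate = float((Q > qcrit).mean())
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se


def test_fit_model_dispatch(rng, sys_r2_02):
    sample = sample_diplotypes(sys_r2_02.with_beta([0, 0.1, 0, 0.2]), 500, rng)
    G = genotypes_from_diplotypes(sample)
    y = rng.standard_normal(500)
    for name in ("additive", "interaction", "genotypic", "haplotype"):
        fit = fit_model(name, G, y)
        assert 0 <= fit.r2_raw <= 1
        assert 0 < fit.p_value <= 1
    vc = fit_model("vc", G, y)
    assert 0 < vc["p"] <= 1
    with pytest.raises(ValueError):
        fit_model("bogus", G, y)
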