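"""Polygenic/sporadic ML fits, boundary LRT and the derived trait tests."""

import numpy as np
import pytest
from scipy import stats

from cytoherit.pedigree import Individual, Pedigree, kinship_matrix
from cytoherit.simulate import simulate_polygenic_trait
from cytoherit.variance_components import (
    COVARIATE_COLUMNS,
    CovariateMatrix,
    DegenerateTraitError,
    PolygenicModel,
    TraitVector,
    VCFit,
    covariate_matrix,
    fc_sdr_association,
    fit_polygenic,
    fit_sporadic,
    heritability_test,
    inverse_normal_transform,
    lrt,
    mean_fc_test,
)


class TestInverseNormalTransform:
    def test_blom_quantiles_n3(self):
        out = inverse_normal_transform([3.1, 1.2, 2.0])
        # ranks 3, 1, 2 -> Phi^-1((r - 3/8) / 3.25)
        assert out[2] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(stats.norm.ppf(0.625 / 3.25))
        assert out[0] == pytest.approx(-out[1])  # symmetric ranks

    def test_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=50)
        out = inverse_normal_transform(x)
        assert np.array_equal(np.argsort(x), np.argsort(out))

    def test_ties_map_equal(self):
        out = inverse_normal_transform([1.0, 1.0, 2.0])
        assert out[0] == out[1]

    def test_normalizes_skewed_input(self):
        rng = np.random.default_rng(1)
        out = inverse_normal_transform(rng.exponential(size=100))
        assert stats.shapiro(out).pvalue > 0.2

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateTraitError):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0])


class TestCovariateMatrix:
    def test_columns_and_values(self):
        cm = covariate_matrix(["a", "b"], [40.0, 40.0], [1, 0])
        assert cm.columns == COVARIATE_COLUMNS
        np.testing.assert_allclose(cm.values[0], [40, 1, 40, 1600, 1600])
        np.testing.assert_allclose(cm.values[1], [40, 0, 0, 1600, 0])

    def test_age_zero(self):
        cm = covariate_matrix(["a"], [0.0], [1])
        np.testing.assert_allclose(cm.values[0], [0, 1, 0, 0, 0])

    def test_missing_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="missing age/sex"):
            cm = covariate_matrix(["a", "b"], [40.0, np.nan], [1, 0])
        assert cm.ids == ["a"]
        assert cm.values.shape == (1, 5)


def _founder_kinship(n):
    ped = Pedigree([Individual(f"I{i}", f"f{i}") for i in range(n)])
    return kinship_matrix(ped)


class TestFitSporadic:
    def test_mean_is_sample_mean(self):
        rng = np.random.default_rng(2)
        y = TraitVector([f"i{k}" for k in range(20)], rng.normal(3.0, 1.0, 20))
        fit = fit_sporadic(y, None)
        assert fit.mean == pytest.approx(float(np.mean(y.values)))
        assert fit.sigma2_g == 0.0
        assert fit.h2 == 0.0

    def test_loglik_matches_normal_mle(self):
        rng = np.random.default_rng(3)
        yv = rng.normal(size=15)
        fit = fit_sporadic(TraitVector([f"i{k}" for k in range(15)], yv), None)
        s2 = np.mean((yv - yv.mean()) ** 2)
        expect = float(np.sum(stats.norm.logpdf(yv, yv.mean(), np.sqrt(s2))))
        assert fit.loglik == pytest.approx(expect, abs=1e-9)

    def test_beta_matches_ols_on_centered_design(self):
        rng = np.random.default_rng(4)
        n = 30
        ids = [f"i{k}" for k in range(n)]
        age = rng.uniform(20, 70, n)
        sex = rng.integers(0, 2, n)
        X = covariate_matrix(ids, age, sex)
        yv = rng.normal(size=n)
        fit = fit_sporadic(TraitVector(ids, yv), X)
        M = np.column_stack([np.ones(n), X.values - X.values.mean(axis=0)])
        beta, *_ = np.linalg.lstsq(M, yv, rcond=None)
        assert fit.mean == pytest.approx(beta[0])
        np.testing.assert_allclose(fit.beta, beta[1:], atol=1e-8)

    def test_degenerate_trait(self):
        with pytest.raises(DegenerateTraitError):
            fit_sporadic(TraitVector(["a", "b"], [1.0, 1.0]), None)


def _dense_loglik(yv, M, rel, fit: VCFit) -> float:
    """Brute-force MVN log-likelihood at a fit's parameters."""
    n = yv.shape[0]
    V = fit.sigma2_g * rel + fit.sigma2_e * np.eye(n)
    beta = np.concatenate([[fit.mean], np.atleast_1d(fit.beta)]) if M.shape[1] \
        else np.zeros(0)
    r = yv - (M @ beta if M.shape[1] else 0.0)
    _, logdet = np.linalg.slogdet(V)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r)))


class TestFitPolygenic:
    def test_loglik_matches_dense_mvn(self, sibship):
        K = kinship_matrix(sibship)
        rng = np.random.default_rng(5)
        yv = rng.normal(size=len(K.ids))
        fit = fit_polygenic(TraitVector(K.ids, yv), None, K)
        M = np.ones((len(K.ids), 1))
        assert fit.loglik == pytest.approx(
            _dense_loglik(yv, M, K.relatedness, fit), abs=1e-8
        )

    def test_nested_likelihood_ordering(self, study_kinship_assayed):
        K = study_kinship_assayed
        rng = np.random.default_rng(6)
        yv = rng.normal(size=len(K.ids))
        y = TraitVector(K.ids, yv)
        full = fit_polygenic(y, None, K)
        constrained = fit_sporadic(y, None)
        assert full.loglik >= constrained.loglik - 1e-9

    def test_identity_kinship_warns(self):
        K = _founder_kinship(10)
        with pytest.warns(UserWarning, match="identity"):
            model = PolygenicModel(K)
        fit = model.fit(np.random.default_rng(7).normal(size=10))
        assert 0.0 <= fit.h2 < 1.0

    def test_rank_deficient_design_rejected(self, study_kinship_assayed):
        K = study_kinship_assayed
        n = len(K.ids)
        rng = np.random.default_rng(8)
        age = rng.uniform(20, 70, n)
        X = covariate_matrix(K.ids, age, rng.integers(0, 2, n))
        y = TraitVector(K.ids, rng.normal(size=n))
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            fit_polygenic(y, X, K, extra=age)  # duplicates the age column

    def test_too_many_fixed_effects_rejected(self, trio):
        K = kinship_matrix(trio)
        X = covariate_matrix(K.ids, [45.0, 43.0, 20.0], [1, 0, 1])
        with pytest.raises(np.linalg.LinAlgError):
            fit_polygenic(TraitVector(K.ids, [1.0, 2.0, 3.0]), X, K)

    def test_trait_id_alignment_enforced(self, trio):
        K = kinship_matrix(trio)
        with pytest.raises(KeyError, match="absent"):
            fit_polygenic(TraitVector(["ghost", "F"], [1.0, 2.0]), None, K)

    def test_family_constant_trait_is_strongly_familial(self, study,
                                                        study_kinship_assayed):
        ped, _ = study
        K = study_kinship_assayed
        rng = np.random.default_rng(9)
        fam_effect = {f: rng.normal() for f in ped.families}
        yv = np.array([fam_effect[ped[i].family_id] for i in K.ids])
        yv = yv + rng.normal(0.0, 0.1, size=yv.size)
        fit = fit_polygenic(TraitVector(K.ids, yv), None, K)
        assert fit.h2 > 0.5


class TestLRT:
    def _fit(self, ll, model="polygenic"):
        return VCFit(0.0, np.zeros(0), 0.0, 1.0, ll, model, 10)

    def test_boundary_mixture_at_zero(self):
        res = lrt(self._fit(-5.0), self._fit(-5.0), boundary=True)
        assert res.statistic == 0.0
        assert res.p == 0.5

    def test_interior_reference(self):
        res = lrt(self._fit(-3.0), self._fit(-5.0), boundary=False)
        assert res.statistic == pytest.approx(4.0)
        assert res.p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_boundary_halves_interior_p(self):
        interior = lrt(self._fit(-3.0), self._fit(-5.0), boundary=False)
        boundary = lrt(self._fit(-3.0), self._fit(-5.0), boundary=True)
        assert boundary.p == pytest.approx(0.5 * interior.p)

    def test_inverted_ordering_rejected(self):
        with pytest.raises(RuntimeError, match="optimization failure"):
            lrt(self._fit(-5.0), self._fit(-3.0), boundary=True)


class TestHeritabilityTest:
    def test_recovers_strong_signal(self, study_kinship_all):
        K = study_kinship_all
        rng = np.random.default_rng(10)
        y = simulate_polygenic_trait(K, 0.6, rng=rng)
        h2, test = heritability_test(TraitVector(K.ids, y), None, K)
        assert h2 > 0.3
        assert test.p < 0.05
        assert test.boundary

    def test_recovery_bias_bounded(self, study_kinship_all):
        """Mean ML estimate over replicates stays near the simulation truth.

        Full ML on 17 families carries a known small-sample downward bias of
        roughly 0.03-0.05; the tolerance reflects that, it is not a target.
        """
        K = study_kinship_all
        rng = np.random.default_rng(2024)
        for truth, tol in ((0.3, 0.08), (0.6, 0.08)):
            h2s = []
            for _ in range(60):
                y = simulate_polygenic_trait(K, truth, rng=rng)
                h2, _ = heritability_test(TraitVector(K.ids, y), None, K)
                h2s.append(h2)
            assert abs(float(np.mean(h2s)) - truth) < tol

    def test_null_often_lands_on_boundary(self, study_kinship_all):
        K = study_kinship_all
        rng = np.random.default_rng(11)
        zeros = 0
        for _ in range(20):
            y = simulate_polygenic_trait(K, 0.0, rng=rng)
            h2, test = heritability_test(TraitVector(K.ids, y), None, K)
            if h2 == 0.0:
                zeros += 1
                # statistic is 0 up to float noise in the two loglik paths
                assert test.p == pytest.approx(0.5, abs=1e-6)
        assert zeros >= 8  # point mass at zero has probability ~1/2


class TestMeanFCTest:
    def test_matches_classical_lrt_without_kinship(self, study_kinship_assayed):
        K = study_kinship_assayed
        rng = np.random.default_rng(12)
        yv = rng.normal(0.3, 1.0, size=len(K.ids))
        res = mean_fc_test(TraitVector(K.ids, yv), None, K, use_kinship=False)
        n = yv.size
        rss1 = float(np.sum((yv - yv.mean()) ** 2))
        rss0 = float(np.sum(yv**2))
        stat = n * np.log(rss0 / rss1)
        assert res.statistic == pytest.approx(stat, abs=1e-8)
        assert res.p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_power_with_kinship(self, study_kinship_assayed):
        K = study_kinship_assayed
        rng = np.random.default_rng(13)
        rejected = 0
        for _ in range(50):
            yv = rng.normal(0.5, 1.0, size=len(K.ids))
            if mean_fc_test(TraitVector(K.ids, yv), None, K).p < 0.05:
                rejected += 1
        assert rejected >= 40  # measured power ~0.97 at this effect size

    def test_zero_mean_usually_retained(self, study_kinship_assayed):
        K = study_kinship_assayed
        rng = np.random.default_rng(14)
        ps = [
            mean_fc_test(
                TraitVector(K.ids, rng.normal(size=len(K.ids))), None, K
            ).p
            for _ in range(40)
        ]
        assert np.mean(np.asarray(ps) < 0.05) < 0.25


class TestFCSDRAssociation:
    def test_recovers_planted_coefficient(self, study_kinship_assayed):
        K = study_kinship_assayed
        rng = np.random.default_rng(15)
        n = len(K.ids)
        fc = rng.normal(size=n)
        sdr_vals = 0.8 * fc + rng.normal(0.0, 0.5, size=n)
        coef, test = fc_sdr_association(
            TraitVector(K.ids, sdr_vals), TraitVector(K.ids, fc), None, K
        )
        assert coef == pytest.approx(0.8, abs=0.25)
        assert test.p < 1e-4
        assert not test.boundary

    def test_misaligned_ids_rejected(self, study_kinship_assayed):
        K = study_kinship_assayed
        ids = K.ids
        with pytest.raises(ValueError, match="aligned"):
            fc_sdr_association(
                TraitVector(ids, np.arange(len(ids), dtype=float)),
                TraitVector(list(reversed(ids)), np.arange(len(ids), dtype=float)),
                None,
                K,
            )

    def test_constant_fc_rejected(self, study_kinship_assayed):
        K = study_kinship_assayed
        n = len(K.ids)
        with pytest.raises(DegenerateTraitError, match="collinear"):
            fc_sdr_association(
                TraitVector(K.ids, np.random.default_rng(16).normal(size=n)),
                TraitVector(K.ids, np.ones(n)),
                None,
                K,
            )
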