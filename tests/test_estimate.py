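"""EM estimation: parameter counting, monotonicity, recovery, oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sogmm import (
    ModelSpec,
    MixturePopulation,
    count_free_parameters,
    fit_mixture,
    generate_dataset,
    initialize_starts,
    mixture_loglik,
)
from sogmm.estimate import _extract
from sogmm.model import GrowthParams, LatentClass, MeasurementParams


@pytest.fixture(scope="module")
def composite_data(reference_class):
    pop = MixturePopulation([reference_class])
    return generate_dataset(pop, 5000, seed=77), pop


@pytest.fixture(scope="module")
def separated_sogmm_data(mean_diff_population):
    return generate_dataset(mean_diff_population, 5000, seed=78), mean_diff_population


class TestParamCounts:
    @pytest.mark.parametrize(
        "family,C,k,k0,kc",
        [
            ("composite_gmm", 1, 9, 7, (2,)),
            ("composite_gmm", 2, 12, 7, (2, 2)),
            ("composite_gmm", 3, 15, 7, (2, 2, 2)),
            ("sogmm", 1, 25, 13, (12,)),
            ("sogmm", 2, 38, 13, (12, 12)),
        ],
    )
    def test_enumerated_counts(self, family, C, k, k0, kc):
        got = count_free_parameters(ModelSpec(family, C))
        assert (got.k, got.k0, got.kc) == (k, k0, tuple(kc))

    def test_identity_holds_including_class_specific_covariance(self):
        for family in ("composite_gmm", "sogmm"):
            for C in (1, 2, 3):
                for pooled in (True, False):
                    cnt = count_free_parameters(ModelSpec(family, C, pooled))
                    assert cnt.k == cnt.k0 + (C - 1) + sum(cnt.kc)


class TestStarts:
    def test_all_starts_satisfy_invariants(self, composite_data):
        ds, _ = composite_data
        starts = initialize_starts(ds, ModelSpec("composite_gmm", 2), n_starts=4, seed=3)
        assert len(starts) == 4
        for pop in starts:
            for cls in pop.classes:
                assert np.min(np.linalg.eigvalsh(cls.growth.phi)) >= -1e-10
                assert np.all(cls.growth.psi >= 0)
            assert sum(c.pi for c in pop.classes) == pytest.approx(1.0)

    def test_distinct_seeds_give_distinct_start_sets(self, composite_data):
        ds, _ = composite_data
        a = initialize_starts(ds, ModelSpec("composite_gmm", 2), n_starts=3, seed=1)
        b = initialize_starts(ds, ModelSpec("composite_gmm", 2), n_starts=3, seed=2)
        assert not np.allclose(a[1].classes[0].growth.kappa, b[1].classes[0].growth.kappa)


class TestEMProperties:
    def test_loglik_monotone_every_iteration(self, composite_data):
        ds, _ = composite_data
        for C in (1, 2):
            fit = fit_mixture(ds, ModelSpec("composite_gmm", C), n_starts=2, seed=5)
            path = np.array(fit.loglik_path)
            assert np.all(np.diff(path) >= -1e-6)

    def test_responsibilities_normalized(self, composite_data):
        ds, _ = composite_data
        fit = fit_mixture(ds, ModelSpec("composite_gmm", 2), n_starts=2, seed=5)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            fit.class_proportions, fit.responsibilities.mean(axis=0), atol=1e-12
        )

    def test_permuting_fitted_classes_preserves_loglik(self, separated_sogmm_data):
        ds, _ = separated_sogmm_data
        fit = fit_mixture(ds, ModelSpec("sogmm", 2), n_starts=2, seed=5)
        ll = mixture_loglik(ds.items, fit.estimates, "item")
        ll_perm = mixture_loglik(ds.items, fit.estimates.permuted([1, 0]), "item")
        assert ll == pytest.approx(ll_perm, abs=1e-8)
        assert ll == pytest.approx(fit.loglik, abs=1e-6)


class TestSingleClassOracle:
    def test_composite_ml_matches_direct_optimization(self, composite_data):
        """EM solution equals a direct quasi-Newton maximization of the
        structured single-class likelihood (independent route)."""
        ds, _ = composite_data
        Y = ds.composites[:500]
        fit = fit_mixture(Y, ModelSpec("composite_gmm", 1), tol=1e-11, max_iter=4000)

        def unpack(x):
            kappa = x[:2]
            l11, l21, l22 = x[2:5]
            chol = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
            phi = chol @ chol.T
            psi = np.exp(x[5:9])
            growth = GrowthParams(kappa, phi, psi)
            return MixturePopulation(
                [LatentClass(1.0, growth, MeasurementParams.identity())]
            )

        def negll(x):
            try:
                return -mixture_loglik(Y, unpack(x), "composite")
            except Exception:
                return 1e10

        x0 = np.array([0.0, 1.0, np.log(0.6), 0.0, np.log(0.3), *np.log([0.3] * 4)])
        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
        assert fit.loglik >= -res.fun - 0.02
        est = fit.estimates.classes[0]
        ora = unpack(res.x).classes[0]
        np.testing.assert_allclose(est.growth.kappa, ora.growth.kappa, atol=0.02)

    def test_composite_ml_recovers_composite_truth(self, composite_data):
        """(kappa_I, kappa_S) at n=5000 close to the composite-metric truth
        (nu-bar, lam-bar) = (0.0067, 1.0)."""
        ds, _ = composite_data
        fit = fit_mixture(ds, ModelSpec("composite_gmm", 1))
        kappa = fit.estimates.classes[0].growth.kappa
        se = np.sqrt(np.array([0.8, 0.1]) / 5000)  # generous SE scale
        assert abs(kappa[0] - 0.0067) < 3 * se[0]
        assert abs(kappa[1] - 1.0) < 3 * se[1]


class TestRecovery:
    def test_sogmm_recovers_loading_dif_and_means(self, separated_sogmm_data):
        from sogmm.evaluate import align_classes

        ds, pop = separated_sogmm_data
        fit = fit_mixture(ds, ModelSpec("sogmm", 2), n_starts=3, seed=11)
        assert fit.converged
        perm = align_classes(fit, pop)
        aligned = [fit.estimates.classes[i] for i in perm]
        for est, true in zip(aligned, pop.classes):
            np.testing.assert_allclose(est.growth.kappa, true.growth.kappa, atol=0.08)
            np.testing.assert_allclose(est.meas.lam, true.meas.lam, atol=0.06)
            np.testing.assert_allclose(est.meas.nu, true.meas.nu, atol=0.08)
        dlam = np.mean(aligned[0].meas.lam[[1, 2]]) - np.mean(aligned[1].meas.lam[[1, 2]])
        assert dlam == pytest.approx(-0.40, abs=0.06)

    def test_sklearn_full_covariance_bound(self, composite_data):
        """The structured 2-class fit cannot beat an unconstrained Gaussian
        mixture with full covariances (strictly larger model family)."""
        sklearn = pytest.importorskip("sklearn.mixture")
        ds, _ = composite_data
        Y = ds.composites[:2000]
        fit = fit_mixture(Y, ModelSpec("composite_gmm", 2), n_starts=4, seed=1)
        gm = sklearn.GaussianMixture(2, covariance_type="full", n_init=5, random_state=0,
                                     tol=1e-6, max_iter=1000).fit(Y)
        assert fit.loglik <= gm.score(Y) * len(Y) + 1e-6

    def test_all_failed_starts_return_flagged_result(self, composite_data):
        ds, _ = composite_data
        fit = fit_mixture(ds.composites[:30], ModelSpec("composite_gmm", 2),
                          n_starts=1, seed=0, max_iter=1)
        assert not fit.converged  # one iteration cannot satisfy the tolerance


def test_extract_validates_dimensions(composite_data):
    ds, _ = composite_data
    with pytest.raises(ValueError):
        _extract(ds.composites, ModelSpec("sogmm", 1))
    assert _extract(ds, ModelSpec("sogmm", 1)).shape[1] == 24
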