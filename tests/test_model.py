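"""Model-implied moments, mixture density, class separation, reliability."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from sogmm import (
    GrowthParams,
    LatentClass,
    MeasurementParams,
    MixturePopulation,
    class_separation_md,
    implied_composite_moments,
    implied_item_moments,
    item_reliability,
    mixture_loglik,
)
from sogmm.design import PHI_REF, build_population, Condition
from sogmm.model import ModelError, N_ITEMS, N_OCCASIONS

from conftest import random_latent_class

# averaging matrix mapping the 24 items onto the 4 occasion composites
AVG = np.kron(np.eye(N_OCCASIONS), np.full((1, N_ITEMS), 1.0 / N_ITEMS))


def _deterministic_class():
    growth = GrowthParams([0.0, 1.0], np.zeros((2, 2)), np.zeros(4))
    meas = MeasurementParams(np.ones(6), np.zeros(6), np.zeros(6))
    return LatentClass(1.0, growth, meas)


class TestImpliedItemMoments:
    def test_deterministic_growth_collapses_to_trajectory(self):
        mu, sigma = implied_item_moments(_deterministic_class())
        expected = np.repeat([0.0, 1.0, 2.0, 3.0], 6)
        np.testing.assert_allclose(mu, expected)
        np.testing.assert_allclose(sigma, 0.0)

    def test_item_variance_matches_scalar_expansion(self, reference_class):
        # item 2 (lambda = 0.80) at occasion 1: 0.8^2 (0.5 + 0.3) + 0.36
        _, sigma = implied_item_moments(reference_class)
        assert sigma[1, 1] == pytest.approx(0.872, abs=1e-12)

    def test_covariance_matches_sampling(self, reference_class):
        from sogmm import generate_dataset

        pop = MixturePopulation([reference_class])
        ds = generate_dataset(pop, 200_000, seed=123)
        mu, sigma = implied_item_moments(reference_class)
        np.testing.assert_allclose(ds.items.mean(axis=0), mu, atol=0.02)
        np.testing.assert_allclose(np.cov(ds.items.T), sigma, atol=0.05)

    def test_non_psd_phi_rejected(self):
        with pytest.raises(ModelError):
            GrowthParams([0, 1], [[1.0, 2.0], [2.0, 1.0]], np.zeros(4))

    def test_covariance_symmetric_psd_over_random_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            _, sigma = implied_item_moments(random_latent_class(rng))
            np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
            assert np.min(np.linalg.eigvalsh(sigma)) > -1e-10


class TestImpliedCompositeMoments:
    def test_unit_measurement_gives_growth_line(self):
        mu, _ = implied_composite_moments(_deterministic_class())
        np.testing.assert_allclose(mu, [0, 1, 2, 3])

    def test_intercept_dif_shifts_every_occasion_by_average(self):
        pop = build_population(Condition("intercept", "small", "none", 100, "balanced"))
        mu_ref, _ = implied_composite_moments(pop.classes[0])
        mu_focal, _ = implied_composite_moments(pop.classes[1])
        np.testing.assert_allclose(mu_focal - mu_ref, 0.30 * 2 / 6, atol=1e-12)

    def test_equals_averaging_transform_of_item_moments(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            cls = random_latent_class(rng)
            mu_i, sig_i = implied_item_moments(cls)
            mu_c, sig_c = implied_composite_moments(cls)
            np.testing.assert_allclose(mu_c, AVG @ mu_i, atol=1e-12)
            np.testing.assert_allclose(sig_c, AVG @ sig_i @ AVG.T, atol=1e-12)


class TestMixtureLoglik:
    def test_single_class_equals_mvn_logpdf(self, reference_class):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 24))
        pop = MixturePopulation([reference_class])
        mu, sigma = implied_item_moments(reference_class)
        expected = multivariate_normal(mu, sigma).logpdf(data).sum()
        assert mixture_loglik(data, pop, "item") == pytest.approx(expected, abs=1e-8)

    def test_brute_force_two_class(self, mean_diff_population):
        rng = np.random.default_rng(1)
        data = rng.normal(loc=1.0, size=(5, 24))
        expected = 0.0
        for row in data:
            dens = 0.0
            for cls in mean_diff_population.classes:
                mu, sigma = implied_item_moments(cls)
                dens += cls.pi * multivariate_normal(mu, sigma).pdf(row)
            expected += np.log(dens)
        got = mixture_loglik(data, mean_diff_population, "item")
        assert got == pytest.approx(expected, abs=1e-10 * abs(expected))

    def test_label_switching_invariance(self, mean_diff_population):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(8, 24))
        ll = mixture_loglik(data, mean_diff_population, "item")
        ll_perm = mixture_loglik(data, mean_diff_population.permuted([1, 0]), "item")
        assert ll == pytest.approx(ll_perm, abs=1e-9)

    def test_degenerate_mixing_reduces_to_one_class(self, reference_class, mean_diff_population):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 4))
        lone = MixturePopulation([LatentClass(1.0, reference_class.growth, reference_class.meas)])
        # pi -> (1, ~0) with an arbitrary second class
        c1 = LatentClass(1 - 1e-14, reference_class.growth, reference_class.meas)
        c2 = mean_diff_population.classes[1]
        degen = MixturePopulation(
            [c1, LatentClass(1e-14, c2.growth, c2.meas)]
        )
        assert mixture_loglik(data, degen, "composite") == pytest.approx(
            mixture_loglik(data, lone, "composite"), abs=1e-8
        )


class TestModelProperties:
    """Invariants over the whole valid parameter space (hypothesis-driven)."""

    from hypothesis import given, settings, strategies as st

    params = st.fixed_dictionaries(
        {
            "kappa": st.tuples(st.floats(-2, 2), st.floats(-2, 2)),
            "chol": st.tuples(
                st.floats(0.1, 1.2), st.floats(-0.5, 0.5), st.floats(0.1, 1.2)
            ),
            "psi": st.lists(st.floats(0.05, 0.8), min_size=4, max_size=4),
            "lam": st.lists(st.floats(0.3, 1.6), min_size=6, max_size=6),
            "nu": st.lists(st.floats(-0.5, 0.5), min_size=6, max_size=6),
            "theta": st.lists(st.floats(0.05, 0.8), min_size=6, max_size=6),
        }
    )

    @staticmethod
    def _build(p):
        l11, l21, l22 = p["chol"]
        chol = np.array([[l11, 0.0], [l21, l22]])
        return LatentClass(
            1.0,
            GrowthParams(np.array(p["kappa"]), chol @ chol.T, np.array(p["psi"])),
            MeasurementParams(np.array(p["lam"]), np.array(p["nu"]), np.array(p["theta"])),
        )

    @given(params)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_item_covariance_psd_and_composite_is_average(self, p):
        cls = self._build(p)
        mu_i, sig_i = implied_item_moments(cls)
        assert np.min(np.linalg.eigvalsh(sig_i)) > -1e-9
        mu_c, sig_c = implied_composite_moments(cls)
        np.testing.assert_allclose(mu_c, AVG @ mu_i, atol=1e-10)
        np.testing.assert_allclose(sig_c, AVG @ sig_i @ AVG.T, atol=1e-10)

    @given(params, st.floats(0.1, 4.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_separation_sign_and_scale_invariances(self, p, scale):
        cls = self._build(p)
        d = np.array(p["kappa"]) + 0.1
        phi = cls.growth.phi + 0.05 * np.eye(2)
        base = class_separation_md(d, phi)
        assert class_separation_md(-d, phi) == pytest.approx(base, rel=1e-9)
        assert class_separation_md(scale * d, phi) == pytest.approx(
            scale * base, rel=1e-9
        )


class TestClassSeparation:
    def test_zero_difference(self):
        assert class_separation_md([0, 0], PHI_REF) == 0.0

    def test_generating_design_distance(self):
        assert class_separation_md([1.4, 0.4], PHI_REF) == pytest.approx(2.047, abs=5e-4)

    def test_euclidean_case_and_invariances(self):
        assert class_separation_md([3, 4], np.eye(2)) == pytest.approx(5.0)
        d = np.array([1.4, 0.4])
        assert class_separation_md(-d, PHI_REF) == pytest.approx(class_separation_md(d, PHI_REF))
        assert class_separation_md(2 * d, PHI_REF) == pytest.approx(
            2 * class_separation_md(d, PHI_REF)
        )

    def test_singular_phi_errors(self):
        with pytest.raises(ModelError):
            class_separation_md([1, 1], np.ones((2, 2)))


class TestItemReliability:
    def test_error_free_item(self, reference_growth):
        assert item_reliability(1.0, 0, reference_growth, 0.0) == 1.0

    @pytest.mark.parametrize(
        "lam,t,expected",
        [(0.80, 0, 0.5872), (1.25, 3, 0.9065)],  # the design's extremes (0.59 / 0.91)
    )
    def test_design_extremes(self, reference_growth, lam, t, expected):
        assert item_reliability(lam, t, reference_growth, 0.36) == pytest.approx(expected, abs=5e-4)

    def test_negative_variance_rejected(self, reference_growth):
        with pytest.raises(ModelError):
            item_reliability(1.0, 0, reference_growth, -0.1)
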