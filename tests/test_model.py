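"""Model structure: link functions, marginal likelihood, priors."""

import numpy as np
import pytest
from scipy.special import expit, logit

from dielocc.model import (
    LOGIT_CLAMP,
    ModelSpec,
    OccupancyData,
    ParamState,
    PriorSettings,
    detection_prob,
    occurrence_prob,
    overall_occurrence,
    prior_logdensity,
    site_marginal_loglik,
    total_loglik,
)


def make_data(n=4, k=5, n_occ=1, n_det=1, seed=0, y=None):
    rng = np.random.default_rng(seed)
    y = np.zeros((n, 2)) if y is None else np.asarray(y, float)
    return OccupancyData(
        y=y, k=np.full(n, k),
        X_occ=rng.normal(size=(n, n_occ)), X_det=rng.normal(size=(n, n_det)),
        occ_names=tuple(f"x{i}" for i in range(n_occ)),
        det_names=tuple(f"v{i}" for i in range(n_det)),
    )


def zero_state(spec, n):
    st = ParamState.initial(spec, n)
    for name in ("alpha_occ", "alpha_det", "beta", "gamma", "delta", "U", "S", "d", "e"):
        getattr(st, name)[...] = 0.0
    return st


class TestLinkFunctions:
    def test_all_zero_parameters_give_half(self):
        spec = ModelSpec(occ_covariates=("x0",), det_covariates=("v0",))
        data = make_data()
        st = zero_state(spec, 4)
        np.testing.assert_allclose(occurrence_prob(st, spec, data), 0.5)
        np.testing.assert_allclose(detection_prob(st, spec, data), 0.5)

    def test_intercept_sets_probability(self):
        spec = ModelSpec()
        data = make_data(n_occ=0, n_det=0)
        st = zero_state(spec, 4)
        st.alpha_occ[:] = logit(0.8)
        np.testing.assert_allclose(occurrence_prob(st, spec, data), 0.8)

    def test_single_covariate_effect(self):
        spec = ModelSpec(occ_covariates=("x0",))
        data = make_data(n_occ=1)
        data.X_occ[:] = 1.0
        st = zero_state(spec, 4)
        st.beta[:, 0] = -1.9
        np.testing.assert_allclose(
            occurrence_prob(st, spec, data), 1 / (1 + np.exp(1.9))
        )

    def test_understory_detection_worked_example(self):
        # delta(Und) = -0.61 at Und standardized to +1: p = expit(-0.61)
        spec = ModelSpec(det_covariates=("Und",))
        data = make_data(n_det=1)
        data.X_det[:] = 1.0
        st = zero_state(spec, 4)
        st.delta[:, 0] = -0.61
        np.testing.assert_allclose(
            detection_prob(st, spec, data), expit(-0.61), atol=1e-12
        )
        assert detection_prob(st, spec, data)[0, 0] == pytest.approx(0.352, abs=5e-4)

    def test_extreme_site_effect_is_clamped_inside_unit_interval(self):
        spec = ModelSpec(use_det_site_re=True)
        data = make_data(n_occ=0, n_det=0)
        st = zero_state(spec, 4)
        st.S[:] = 1e8
        p = detection_prob(st, spec, data)
        assert np.all(p < 1.0) and np.all(p > 0.0)
        np.testing.assert_allclose(p, expit(LOGIT_CLAMP))

    def test_excluded_covariate_drops_from_predictor(self):
        spec = ModelSpec(occ_covariates=("x0",), select=True)
        data = make_data(n_occ=1)
        st = zero_state(spec, 4)
        st.beta[:, 0] = 3.0
        st.w_beta[:, 0] = 0
        np.testing.assert_allclose(occurrence_prob(st, spec, data), 0.5)


class TestOverallOccurrence:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.5, 0.5, 0.75), (0.0, 0.37, 0.37), (0.80, 0.24, 0.848), (1.0, 0.2, 1.0)],
    )
    def test_union_values(self, a, b, expected):
        assert overall_occurrence(a, b) == pytest.approx(expected)

    def test_bounds(self, rng):
        a, b = rng.uniform(size=100), rng.uniform(size=100)
        out = overall_occurrence(a, b)
        assert np.all(out >= np.maximum(a, b) - 1e-12)
        assert np.all(out <= np.minimum(1.0, a + b) + 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            overall_occurrence(1.2, 0.5)


class TestMarginalLoglik:
    def test_hand_computed_mixture(self):
        # y=0, k=1, psi=0.5, p=0.5: 0.5*0.5 + 0.5 = 0.75
        ll = site_marginal_loglik([[0, 0]], [1], [[0.5, 0.5]], [[0.5, 0.5]])
        assert ll[0] == pytest.approx(2 * np.log(0.75))

    def test_certain_occupancy(self):
        ll = site_marginal_loglik([[1, 1]], [1], [[1.0, 1.0]], [[0.3, 0.3]])
        assert ll[0] == pytest.approx(2 * np.log(0.3))

    def test_matches_two_state_enumeration(self, rng):
        # oracle: explicit sum over z in {0, 1}
        from scipy.stats import binom

        for _ in range(200):
            k = int(rng.integers(1, 40))
            y = int(rng.integers(0, k + 1))
            psi, p = rng.uniform(0.01, 0.99, 2)
            brute = psi * binom.pmf(y, k, p) + (1 - psi) * (1.0 if y == 0 else 0.0)
            ours = site_marginal_loglik([[y, y]], [k], [[psi, psi]], [[p, p]])
            assert ours[0] == pytest.approx(2 * np.log(brute), abs=1e-12)

    def test_perfect_detection_identifies_absence(self):
        # p -> 1, y = 0: likelihood -> 1 - psi
        ll = site_marginal_loglik([[0, 0]], [5], [[0.37, 0.37]], [[1 - 1e-14, 1 - 1e-14]])
        assert ll[0] == pytest.approx(2 * np.log(0.63), rel=1e-9)

    def test_rejects_y_above_k(self):
        with pytest.raises(ValueError):
            site_marginal_loglik([[3, 0]], [2], [[0.5, 0.5]], [[0.5, 0.5]])

    def test_period_swap_symmetry(self, rng):
        spec = ModelSpec(occ_covariates=("x0",), det_covariates=("v0",))
        y = rng.integers(0, 5, size=(6, 2)).astype(float)
        data = make_data(n=6, y=y, seed=3)
        st = ParamState.initial(spec, 6, rng)
        ll = total_loglik(st, spec, data)
        # swap period labels in data and parameters
        data2 = make_data(n=6, y=y[:, ::-1], seed=3)
        st2 = st.copy()
        for name in ("alpha_occ", "alpha_det", "gamma"):
            getattr(st2, name)[:] = getattr(st, name)[::-1]
        for name in ("beta", "delta"):
            getattr(st2, name)[:] = getattr(st, name)[::-1, :]
        st2.d[:] = st.d[:, ::-1]
        assert total_loglik(st2, spec, data2) == pytest.approx(ll, rel=1e-12)


class TestPrior:
    SPEC = ModelSpec(occ_covariates=("x0",), det_covariates=("v0",),
                     use_diel_re=True, use_det_site_re=True)

    def test_large_coefficient_scores_lower(self):
        data = make_data()
        st = zero_state(self.SPEC, 4)
        base = prior_logdensity(st, self.SPEC, data)
        st.beta[0, 0] = 20.0
        assert prior_logdensity(st, self.SPEC, data) < base

    def test_degenerate_correlation_is_impossible(self):
        data = make_data()
        st = zero_state(self.SPEC, 4)
        st.rho = 1.0
        assert prior_logdensity(st, self.SPEC, data) == -np.inf

    def test_nonpositive_sd_is_impossible(self):
        data = make_data()
        st = zero_state(self.SPEC, 4)
        st.sigma_S = 0.0
        assert prior_logdensity(st, self.SPEC, data) == -np.inf

    def test_indicator_prior_contributes_log_half_per_flip(self):
        # with pseudo-prior equal to the coefficient prior, two states that
        # differ only in w score identically except for the Bernoulli terms
        spec = ModelSpec(
            occ_covariates=("a", "b"), select=True,
            priors=PriorSettings(coef_sd=10.0, pseudo_sd=10.0),
        )
        data = make_data(n_occ=2)
        st_on = zero_state(spec, 4)
        st_off = st_on.copy()
        st_off.w_beta[:] = 0
        on = prior_logdensity(st_on, spec, data)
        off = prior_logdensity(st_off, spec, data)
        assert on == pytest.approx(off)  # w prior 0.5 is symmetric

    def test_car_requires_adjacency(self):
        spec = ModelSpec(use_car=True)
        data = make_data(n_occ=0, n_det=0)
        st = zero_state(spec, 4)
        with pytest.raises(ValueError, match="adjacency"):
            prior_logdensity(st, spec, data)
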