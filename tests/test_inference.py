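"""Sampler correctness, diagnostics, and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dielocc.inference import (
    PosteriorSamples,
    day_night_correlation,
    fit_guild,
    inclusion_probabilities,
    model_averaged_coefficients,
    model_ranking,
    predict_psi_surface,
    psrf,
    run_mcmc,
)
from dielocc.model import ModelSpec, OccupancyData


def simulate_data(n=60, k=10, psi=0.6, p=0.7, beta=None, X=None, seed=5):
    """Direct draw from the observation model (no photo layer)."""
    rng = np.random.default_rng(seed)
    n_occ = 0 if beta is None else len(beta)
    if X is None:
        X = rng.normal(size=(n, n_occ))
    lp = np.log(psi / (1 - psi)) + (X @ np.asarray(beta) if beta is not None else 0.0)
    psi_i = expit(lp)[:, None] * np.ones((n, 2)) if np.ndim(lp) else np.full((n, 2), psi)
    z = rng.uniform(size=(n, 2)) < psi_i
    y = rng.binomial(k, p, size=(n, 2)) * z
    data = OccupancyData(
        y=y, k=np.full(n, k), X_occ=X, X_det=np.zeros((n, 0)),
        occ_names=tuple(f"x{i}" for i in range(n_occ)),
    )
    return data


def fake_samples(spec, **arrays):
    """Hand-built PosteriorSamples for summary-function tests."""
    first = next(iter(arrays.values()))
    n_chains, n_draws = first.shape[:2]
    n = 3
    shapes = {
        "alpha_occ": (2,), "alpha_det": (2,), "beta": (2, spec.n_occ),
        "gamma": (2,), "delta": (2, spec.n_det), "w_beta": (2, spec.n_occ),
        "w_gamma": (2,), "w_delta": (2, spec.n_det), "rho": (), "sd_d": (2,),
        "sigma_S": (), "tau_U": (), "rho_e": (), "sd_e": (2,), "loglik": (),
    }
    draws = {
        name: arrays.get(name, np.zeros((n_chains, n_draws, *shape)))
        for name, shape in shapes.items()
    }
    if "w_beta" not in arrays:
        draws["w_beta"] = np.ones((n_chains, n_draws, 2, spec.n_occ))
    if "w_gamma" not in arrays:
        draws["w_gamma"] = np.ones((n_chains, n_draws, 2))
    zero = np.zeros((n, 2))
    return PosteriorSamples(
        draws=draws, spec=spec, n_chains=n_chains, n_iter=0, burn_in=0, thin=1,
        seed=0, psi_mean=zero, psi_sd=zero, p_mean=zero, p_sd=zero,
        psi_overall_mean=np.zeros(n), psi_overall_sd=np.zeros(n),
    )


class TestSamplerContracts:
    def test_same_seed_gives_identical_draws(self):
        data = simulate_data(n=20, k=5)
        spec = ModelSpec()
        a = run_mcmc(data, spec, n_chains=2, n_iter=300, burn_in=100, thin=2, seed=11)
        b = run_mcmc(data, spec, n_chains=2, n_iter=300, burn_in=100, thin=2, seed=11)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_retained_draw_count(self):
        data = simulate_data(n=10, k=4)
        s = run_mcmc(data, ModelSpec(), n_chains=1, n_iter=250, burn_in=50, thin=4, seed=2)
        assert s.n_draws == 50

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            run_mcmc(simulate_data(n=10), ModelSpec(), n_iter=100, burn_in=10)

    def test_prior_recovery_with_no_occasions(self):
        # k = 0: the likelihood is flat, so inclusion probabilities must
        # revert to the Bernoulli(0.5) prior
        n = 12
        data = OccupancyData(
            y=np.zeros((n, 2)), k=np.zeros(n),
            X_occ=np.random.default_rng(0).normal(size=(n, 1)),
            X_det=np.zeros((n, 0)), occ_names=("x0",),
        )
        spec = ModelSpec(occ_covariates=("x0",), select=True)
        s = run_mcmc(data, spec, n_chains=2, n_iter=15_000, burn_in=2000, thin=2, seed=3)
        probs = inclusion_probabilities(s)
        assert np.all(np.abs(probs - 0.5) < 0.05)


class TestDiagnostics:
    def test_identical_chains_give_unit_psrf(self):
        chain = np.random.default_rng(0).normal(size=(1, 200))
        out = psrf({"theta": np.repeat(chain, 3, axis=0)})
        assert out["psrf"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_disjoint_constant_chains_diverge(self):
        out = psrf({"theta": np.stack([np.zeros(100), np.ones(100)])})
        assert out["psrf"].iloc[0] > 10 or np.isinf(out["psrf"].iloc[0])

    def test_same_distribution_chains_converge(self, rng):
        out = psrf({"theta": rng.normal(size=(4, 2000))})
        assert out["psrf"].iloc[0] < 1.02 and not out["flagged"].iloc[0]

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf({"theta": np.zeros((1, 100))})

    def test_few_draws_rejected(self):
        with pytest.raises(ValueError):
            psrf({"theta": np.zeros((2, 5))})

    def test_agrees_with_arviz_rhat(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.normal(size=(4, 500)) + np.linspace(0, 0.8, 4)[:, None]
        ours = psrf({"theta": chains})["psrf"].iloc[0]
        # arviz uses the rank-normalized split statistic; agreement is
        # approximate but both must flag the same pathology
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.1)
        assert (ours > 1.1) == (theirs > 1.1)


class TestSummaries:
    def test_degenerate_draws_summarize_exactly(self):
        spec = ModelSpec(occ_covariates=("x0",), select=True)
        beta = np.full((2, 100, 2, 1), 0.7)
        s = fake_samples(spec, beta=beta)
        out = model_averaged_coefficients(s).set_index(["coefficient", "period"])
        row = out.loc[("psi:x0", "day")]
        assert row["mean"] == pytest.approx(0.7)
        assert row["sd"] == 0.0
        assert (row["ci_low"], row["ci_high"]) == (0.7, 0.7)

    def test_normal_draws_percentile_interval(self, rng):
        spec = ModelSpec(occ_covariates=("x0",), select=True)
        beta = np.zeros((1, 40_000, 2, 1))
        beta[:, :, :, 0] = rng.normal(0.5, 0.1, size=(1, 40_000, 2))
        s = fake_samples(spec, beta=beta)
        row = model_averaged_coefficients(s).iloc[0]
        assert row["ci_low"] == pytest.approx(0.304, abs=0.01)
        assert row["ci_high"] == pytest.approx(0.696, abs=0.01)
        assert row["excludes_zero"]

    def test_never_included_reported_absent(self):
        spec = ModelSpec(occ_covariates=("x0",), select=True)
        s = fake_samples(
            spec,
            beta=np.full((1, 50, 2, 1), 2.0),
            w_beta=np.zeros((1, 50, 2, 1)),
        )
        out = model_averaged_coefficients(s)
        assert not out["included_ever"].any()
        assert out["mean"].isna().all()

    def test_single_model_space_has_probability_one(self):
        spec = ModelSpec(occ_covariates=("x0",), select=True, use_dog_covariate=True)
        s = fake_samples(
            spec,
            w_beta=np.ones((1, 30, 2, 1)),
            w_gamma=np.ones((1, 30, 2)),
        )
        ranking = model_ranking(s)
        assert ranking.entries[0][1] == 1.0
        assert len(ranking.entries) == 1
        probs = inclusion_probabilities(s)
        assert (probs == 1.0).all()

    def test_ranking_marginals_match_inclusion_probabilities(self, rng):
        spec = ModelSpec(occ_covariates=("x0", "x1"), select=True)
        w = (rng.uniform(size=(2, 500, 2, 2)) < 0.3).astype(float)
        s = fake_samples(spec, w_beta=w)
        probs = inclusion_probabilities(s)
        ranking = model_ranking(s)
        marg = np.zeros(4)
        for combo, prob in ranking.entries:
            marg += prob * np.asarray(combo)
        np.testing.assert_allclose(marg, probs.to_numpy(), atol=1e-12)

    def test_day_night_correlation_extracts_rho(self, rng):
        spec = ModelSpec(use_diel_re=True)
        rho = rng.normal(0.6, 0.05, size=(2, 300))
        s = fake_samples(spec, rho=rho)
        m, sd = day_night_correlation(s)
        assert m == pytest.approx(rho.mean())
        assert sd == pytest.approx(rho.std(ddof=1), rel=0.01)


class TestPsiSurface:
    def test_zero_coefficients_give_flat_surface(self):
        spec = ModelSpec(occ_covariates=("a", "b"))
        alpha = np.full((1, 50, 2), 0.8473)  # logit(0.7)
        s = fake_samples(spec, alpha_occ=alpha)
        grid = predict_psi_surface(s, "a", np.linspace(-2, 2, 5), "b", np.linspace(-2, 2, 5))
        np.testing.assert_allclose(grid, expit(0.8473), rtol=1e-12)

    def test_monotone_in_signed_coefficients(self):
        spec = ModelSpec(occ_covariates=("road", "forest"))
        beta = np.zeros((1, 40, 2, 2))
        beta[:, :, :, 0] = -1.0
        beta[:, :, :, 1] = 1.0
        s = fake_samples(spec, beta=beta)
        g = np.linspace(-2, 2, 9)
        surf = predict_psi_surface(s, "road", g, "forest", g)
        assert np.all(np.diff(surf, axis=0) <= 1e-12)  # decreasing in road
        assert np.all(np.diff(surf, axis=1) >= -1e-12)  # increasing in forest
        # corners match direct evaluation
        assert surf[0, -1, 0] == pytest.approx(expit(-(-2.0) + 2.0))
        assert surf[-1, 0, 1] == pytest.approx(expit(-(2.0) + -2.0))


class TestGuildPlumbing:
    @staticmethod
    def _history(species_y, n=8, k=6):
        rows = []
        for sp, detected in species_y.items():
            for i in range(n):
                for j, per in enumerate(("day", "night")):
                    rows.append(
                        {"site_id": f"T{i}", "species": sp, "period": per,
                         "y": int(detected and i % 2 == j), "k": k}
                    )
        return pd.DataFrame(rows)

    def test_two_stage_fit_consumes_dog_field(self):
        hist = self._history({"Dog": 1, "Kodkod": 1, "Cougar": 1})
        X_occ = pd.DataFrame({"NF500": np.random.default_rng(0).normal(size=8)})
        X_det = pd.DataFrame(index=range(8))
        spec = ModelSpec(occ_covariates=("NF500",), use_dog_covariate=True)
        fits = fit_guild(
            hist, X_occ, X_det, [f"T{i}" for i in range(8)], spec,
            n_chains=1, n_iter=200, burn_in=50, thin=5, seed=9,
        )
        assert set(fits) == {"Dog", "Dog:report", "Kodkod", "Cougar"}

    def test_missing_dog_is_an_error(self):
        hist = self._history({"Kodkod": 1})
        with pytest.raises(ValueError, match="Dog"):
            fit_guild(
                hist, pd.DataFrame(index=range(8)), pd.DataFrame(index=range(8)),
                [f"T{i}" for i in range(8)], ModelSpec(), seed=1,
            )

    def test_zero_detection_species_skipped_with_warning(self):
        hist = self._history({"Dog": 1, "Ghost": 0})
        X_occ = pd.DataFrame(index=range(8))
        X_det = pd.DataFrame(index=range(8))
        with pytest.warns(UserWarning, match="Ghost"):
            fits = fit_guild(
                hist, X_occ, X_det, [f"T{i}" for i in range(8)], ModelSpec(),
                n_chains=1, n_iter=150, burn_in=50, thin=5, seed=4,
            )
        assert "Ghost" not in fits
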