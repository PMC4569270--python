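"""MCMC estimation, indicator-variable model selection, and summaries.

The sampler is Metropolis-within-Gibbs: scalar random-walk updates with
adaptive proposal scales on the fixed effects and variance components
(adaptation ends at burn-in), vectorized single-site updates on the
random-effect fields (the CAR field is updated by graph-coloring classes
so simultaneous single-site moves never touch two neighbors), and a Gibbs
draw for the CAR precision.  Each inclusion indicator w_c is proposed for
a flip once per sweep; while a coefficient is excluded it is refreshed
from a pseudo-prior, so flips are always well defined and the stationary
distribution of the indicator vector is the exact posterior over models.

Posterior model probabilities are the relative frequencies of indicator
combinations among retained draws; model-averaged coefficients are
summarized conditional on inclusion (draws with w_c = 1), mirroring the
reporting convention of occupancy tables where a never-included covariate
appears as "-".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    ModelSpec,
    OccupancyData,
    ParamState,
    clamp_logit,
    detection_prob,
    occurrence_prob,
    overall_occurrence,
    site_marginal_loglik,
)
from .spatial import pairwise_deviance

__all__ = [
    "PosteriorSamples",
    "ModelRanking",
    "run_mcmc",
    "model_ranking",
    "inclusion_probabilities",
    "model_averaged_coefficients",
    "psrf",
    "day_night_correlation",
    "predict_psi_surface",
    "fit_guild",
    "SUPPORT_THRESHOLD",
    "CI_LEVEL",
]

#: a model is "supported" when its posterior probability exceeds this
SUPPORT_THRESHOLD = 0.05
CI_LEVEL = 0.95

_ADAPT_INTERVAL = 50
_TARGET_ACCEPT = 0.35
_MAX_INIT_RETRIES = 10


@dataclass
class PosteriorSamples:
    """Retained draws and run metadata for one species' fit.

    ``draws`` maps parameter names to arrays of shape
    (n_chains, n_draws, *param_shape).  Site-level fields (U, S, d, e) are
    not stored draw-by-draw; instead ``psi_mean``/``p_mean`` etc. hold
    their running posterior summaries, which is all the two-stage dog
    plug-in and the occupancy tables need.
    """

    draws: dict[str, np.ndarray]
    spec: ModelSpec
    n_chains: int
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    psi_mean: np.ndarray  # (n_sites, 2)
    psi_sd: np.ndarray
    p_mean: np.ndarray
    p_sd: np.ndarray
    psi_overall_mean: np.ndarray  # (n_sites,)
    psi_overall_sd: np.ndarray
    site_ids: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains."""
        a = self.draws[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """Every stored quantity unpacked to named scalar chains
        (n_chains, n_draws), for convergence diagnostics."""
        out: dict[str, np.ndarray] = {}
        periods = ("day", "night")
        for name, a in self.draws.items():
            if name.startswith("w_"):
                continue
            if a.ndim == 2:
                out[name] = a
            elif a.ndim == 3 and a.shape[2] == 2:
                for j, per in enumerate(periods):
                    out[f"{name}[{per}]"] = a[:, :, j]
            elif a.ndim == 4:
                labels = (
                    self.spec.occ_covariates if name == "beta" else self.spec.det_covariates
                )
                for j, per in enumerate(periods):
                    for c, lab in enumerate(labels):
                        out[f"{name}[{per},{lab}]"] = a[:, :, j, c]
        return out


@dataclass
class ModelRanking:
    """Posterior model probabilities over indicator combinations."""

    indicator_names: list[str]
    entries: list[tuple[tuple[int, ...], float]]  # sorted descending
    threshold: float = SUPPORT_THRESHOLD

    def supported(self) -> list[tuple[tuple[int, ...], float]]:
        return [e for e in self.entries if e[1] > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for combo, prob in self.entries:
            included = [n for n, w in zip(self.indicator_names, combo) if w]
            rows.append(
                {
                    "model": " + ".join(included) if included else "(null)",
                    "n_effects": sum(combo),
                    "posterior_probability": prob,
                }
            )
        return pd.DataFrame(rows)


class _Accumulator:
    """Running mean and variance (Welford) over retained draws."""

    def __init__(self, shape):
        self.n = 0
        self.mean = np.zeros(shape)
        self.m2 = np.zeros(shape)

    def add(self, x):
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    @property
    def sd(self):
        if self.n < 2:
            return np.zeros_like(self.mean)
        return np.sqrt(self.m2 / (self.n - 1))


class _Sampler:
    """One chain of the Metropolis-within-Gibbs sampler."""

    def __init__(self, data: OccupancyData, spec: ModelSpec, rng: np.random.Generator):
        self.data = data
        self.spec = spec
        self.rng = rng
        self.pr = spec.priors
        self.n = data.n_sites
        if spec.use_car:
            if data.adjacency is None:
                raise ValueError("CAR term requested but data has no adjacency")
            self.colors = data.adjacency.coloring()
            A = data.adjacency.matrix().astype(float)
            self.A = A
            self.degree = A.sum(axis=1)
            self.car_rank = data.adjacency.n_sites - data.adjacency.n_components()
        self.scales: dict[str, float] = {}
        self.accepts: dict[str, list[int]] = {}
        self.adapting = True

    # -- likelihood bookkeeping ------------------------------------------
    def site_ll(self, state: ParamState) -> np.ndarray:
        psi = occurrence_prob(state, self.spec, self.data)
        p = detection_prob(state, self.spec, self.data)
        return site_marginal_loglik(self.data.y, self.data.k, psi, p,
                                    self.data._log_choose)

    def total_ll(self, state: ParamState) -> float:
        return float(self.site_ll(state).sum())

    # -- adaptive scalar Metropolis --------------------------------------
    def _scale(self, key: str, default: float = 0.3) -> float:
        return self.scales.setdefault(key, default)

    def _record(self, key: str, accepted: bool):
        self.accepts.setdefault(key, []).append(int(accepted))
        hist = self.accepts[key]
        # indicator flips have no proposal scale to adapt
        if self.adapting and key in self.scales and len(hist) >= _ADAPT_INTERVAL:
            rate = float(np.mean(hist))
            self.scales[key] = float(
                np.clip(self.scales[key] * np.exp(rate - _TARGET_ACCEPT), 1e-3, 50.0)
            )
            hist.clear()

    def _mh_scalar(self, key, state, getter, setter, logpost, default=0.3):
        """Generic scalar random-walk Metropolis step."""
        cur = getter(state)
        cur_lp = logpost(state)
        prop = cur + self.rng.normal(0, self._scale(key, default))
        setter(state, prop)
        new_lp = logpost(state)
        loga = new_lp - cur_lp
        if np.log(self.rng.uniform()) < loga:
            self._record(key, True)
            return True
        setter(state, cur)
        self._record(key, False)
        return False

    # -- fixed-effect updates --------------------------------------------
    def _coef_logpost(self, state, value):
        return self.total_ll(state) - 0.5 * (value / self.pr.coef_sd) ** 2

    def _update_coefficient(self, state, key, get, set_, selected, w_get, w_set):
        """Coefficient update plus (optionally) an indicator flip."""
        if selected and w_get(state) == 0:
            # excluded: refresh from the pseudo-prior (exact Gibbs draw)
            set_(state, self.rng.normal(0, self.pr.pseudo_sd))
        else:
            self._mh_scalar(
                key, state, get, set_,
                lambda st: self._coef_logpost(st, get(st)),
            )
        if not selected:
            return
        # flip proposal with the coefficient value held fixed
        value = get(state)
        w = w_get(state)
        ll_cur = self.total_ll(state)
        w_set(state, 1 - w)
        ll_flip = self.total_ll(state)
        prior_on = -0.5 * (value / self.pr.coef_sd) ** 2 - np.log(self.pr.coef_sd)
        prior_off = -0.5 * (value / self.pr.pseudo_sd) ** 2 - np.log(self.pr.pseudo_sd)
        w_lor = np.log(self.pr.w_prior) - np.log1p(-self.pr.w_prior)
        if w == 0:  # proposing inclusion
            loga = (ll_flip - ll_cur) + (prior_on - prior_off) + w_lor
        else:  # proposing exclusion
            loga = (ll_flip - ll_cur) + (prior_off - prior_on) - w_lor
        if np.log(self.rng.uniform()) < loga:
            self._record(f"w:{key}", True)
        else:
            w_set(state, w)
            self._record(f"w:{key}", False)

    def update_fixed_effects(self, state: ParamState):
        for j in range(2):
            self._mh_scalar(
                f"alpha_occ{j}", state,
                lambda st, j=j: st.alpha_occ[j],
                lambda st, v, j=j: st.alpha_occ.__setitem__(j, v),
                lambda st, j=j: self._coef_logpost(st, st.alpha_occ[j]),
            )
            self._mh_scalar(
                f"alpha_det{j}", state,
                lambda st, j=j: st.alpha_det[j],
                lambda st, v, j=j: st.alpha_det.__setitem__(j, v),
                lambda st, j=j: self._coef_logpost(st, st.alpha_det[j]),
            )
        for j in range(2):
            for c in range(self.spec.n_occ):
                self._update_coefficient(
                    state, f"beta{j}_{c}",
                    lambda st, j=j, c=c: st.beta[j, c],
                    lambda st, v, j=j, c=c: st.beta.__setitem__((j, c), v),
                    self.spec.select,
                    lambda st, j=j, c=c: st.w_beta[j, c],
                    lambda st, v, j=j, c=c: st.w_beta.__setitem__((j, c), v),
                )
            if self.spec.use_dog_covariate:
                self._update_coefficient(
                    state, f"gamma{j}",
                    lambda st, j=j: st.gamma[j],
                    lambda st, v, j=j: st.gamma.__setitem__(j, v),
                    self.spec.select,
                    lambda st, j=j: st.w_gamma[j],
                    lambda st, v, j=j: st.w_gamma.__setitem__(j, v),
                )
            for c in range(self.spec.n_det):
                self._update_coefficient(
                    state, f"delta{j}_{c}",
                    lambda st, j=j, c=c: st.delta[j, c],
                    lambda st, v, j=j, c=c: st.delta.__setitem__((j, c), v),
                    self.spec.select_detection,
                    lambda st, j=j, c=c: st.w_delta[j, c],
                    lambda st, v, j=j, c=c: st.w_delta.__setitem__((j, c), v),
                )

    # -- site-level random effects ---------------------------------------
    def _vector_site_update(self, state, key, fld, prior_delta, default=0.5):
        """Simultaneous single-site Metropolis on an (n,) or (n, 2) field;
        sites are conditionally independent so per-site acceptance is
        exact."""
        cur = getattr(state, fld)
        cur_ll = self.site_ll(state)
        step = self.rng.normal(0, self._scale(key, default), size=cur.shape)
        prop = cur + step
        setattr(state, fld, prop)
        new_ll = self.site_ll(state)
        logr = (new_ll - cur_ll) + prior_delta(prop, cur)
        accept = np.log(self.rng.uniform(size=self.n)) < logr
        merged = np.where(
            accept[:, None] if cur.ndim == 2 else accept, prop, cur
        )
        setattr(state, fld, merged)
        self.accepts.setdefault(key, []).append(float(accept.mean()))
        hist = self.accepts[key]
        if self.adapting and len(hist) >= _ADAPT_INTERVAL:
            rate = float(np.mean(hist))
            self.scales[key] = float(
                np.clip(self.scales[key] * np.exp(rate - _TARGET_ACCEPT), 1e-3, 50.0)
            )
            hist.clear()

    @staticmethod
    def _bvn_site_lp(pairs, sd, rho):
        z1 = pairs[:, 0] / sd[0]
        z2 = pairs[:, 1] / sd[1]
        return -0.5 * (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (1 - rho * rho)

    def update_diel_re(self, state: ParamState):
        self._vector_site_update(
            state, "d", "d",
            lambda new, old: (
                self._bvn_site_lp(new, state.sd_d, state.rho)
                - self._bvn_site_lp(old, state.sd_d, state.rho)
            ),
        )
        # hyperparameters: log-sd walks and a rho walk against the d field
        def cov_lp(st: ParamState) -> float:
            if not (-1 < st.rho < 1) or (st.sd_d <= 0).any():
                return -np.inf
            lp = self._bvn_site_lp(st.d, st.sd_d, st.rho).sum()
            lp += -self.n * (np.log(st.sd_d).sum() + 0.5 * np.log1p(-st.rho**2))
            lp += -0.5 * float((st.sd_d / self.pr.sd_scale) ** 2 @ np.ones(2))
            return float(lp)

        for idx in range(2):
            self._mh_logsd(f"sd_d{idx}", state, "sd_d", idx, cov_lp)
        self._mh_scalar(
            "rho", state,
            lambda st: st.rho,
            lambda st, v: setattr(st, "rho", v),
            cov_lp,
            default=0.2,
        )
        # interweaved non-centered moves: rescale/rotate the field together
        # with its covariance so the likelihood drives the hyperparameters
        # (the centered conditional alone mixes through a funnel)
        for idx in range(2):
            self._interweave_scale(state, f"nc_sd_d{idx}", "d", "sd_d", idx)
        self._interweave_rho(state, "nc_rho", "d", "sd_d", "rho")

    def _interweave_scale(self, state, key, field_name, sd_name, idx):
        """Non-centered sd move: propose sd' on the log scale and rescale
        the field column by sd'/sd.  The Gaussian density ratio cancels
        against the transform Jacobian, so the acceptance ratio is the
        likelihood ratio times the Half-Normal prior and log-walk terms."""
        sd_arr = getattr(state, sd_name)
        scalar = np.isscalar(sd_arr) or np.ndim(sd_arr) == 0
        cur_sd = float(sd_arr if scalar else sd_arr[idx])
        fld = getattr(state, field_name)
        col = fld if fld.ndim == 1 else fld[:, idx]
        cur_col = col.copy()
        cur_ll = self.total_ll(state)
        ratio = float(np.exp(self.rng.normal(0, self._scale(key, 0.15))))
        new_sd = cur_sd * ratio
        if fld.ndim == 1:
            setattr(state, field_name, cur_col * ratio)
        else:
            fld[:, idx] = cur_col * ratio
        if scalar:
            setattr(state, sd_name, new_sd)
        else:
            sd_arr[idx] = new_sd
        new_ll = self.total_ll(state)
        prior_delta = -0.5 * (new_sd**2 - cur_sd**2) / self.pr.sd_scale**2
        loga = (new_ll - cur_ll) + prior_delta + np.log(ratio)
        if np.log(self.rng.uniform()) < loga:
            self._record(key, True)
        else:
            if fld.ndim == 1:
                setattr(state, field_name, cur_col)
            else:
                fld[:, idx] = cur_col
            if scalar:
                setattr(state, sd_name, cur_sd)
            else:
                sd_arr[idx] = cur_sd
            self._record(key, False)

    def _interweave_rho(self, state, key, field_name, sd_name, rho_name):
        """Non-centered correlation move: keep the whitened field fixed and
        re-correlate it under the proposed rho; the bivariate-normal density
        ratio cancels against the Jacobian, leaving the likelihood ratio
        (rho's prior is Uniform(-1, 1))."""
        cur_rho = float(getattr(state, rho_name))
        prop = cur_rho + self.rng.normal(0, self._scale(key, 0.15))
        if not -1.0 < prop < 1.0:
            self._record(key, False)
            return
        sd = np.asarray(getattr(state, sd_name), dtype=float)
        fld = getattr(state, field_name)
        cur_fld = fld.copy()
        cur_ll = self.total_ll(state)
        # chol factors of the two correlation structures (unit diagonals,
        # scaled by sd): L = [[sd1, 0], [sd2*rho, sd2*sqrt(1-rho^2)]]
        z1 = cur_fld[:, 0] / sd[0]
        u2 = (cur_fld[:, 1] / sd[1] - cur_rho * z1) / np.sqrt(1 - cur_rho**2)
        new_fld = cur_fld.copy()
        new_fld[:, 1] = sd[1] * (prop * z1 + np.sqrt(1 - prop**2) * u2)
        setattr(state, field_name, new_fld)
        setattr(state, rho_name, prop)
        new_ll = self.total_ll(state)
        if np.log(self.rng.uniform()) < new_ll - cur_ll:
            self._record(key, True)
        else:
            setattr(state, field_name, cur_fld)
            setattr(state, rho_name, cur_rho)
            self._record(key, False)

    def _mh_logsd(self, key, state, fld, idx, logpost):
        """Random walk on log(sd); the Jacobian term keeps the move exact."""
        arr = getattr(state, fld)
        scalar = np.isscalar(arr) or arr.ndim == 0
        cur = float(arr if scalar else arr[idx])
        cur_lp = logpost(state) + np.log(cur)
        prop = float(np.exp(np.log(cur) + self.rng.normal(0, self._scale(key, 0.3))))
        if scalar:
            setattr(state, fld, prop)
        else:
            arr[idx] = prop
        new_lp = logpost(state) + np.log(prop)
        if np.log(self.rng.uniform()) < new_lp - cur_lp:
            self._record(key, True)
        else:
            if scalar:
                setattr(state, fld, cur)
            else:
                arr[idx] = cur
            self._record(key, False)

    def update_det_site_re(self, state: ParamState):
        self._vector_site_update(
            state, "S", "S",
            lambda new, old: -0.5 * (new**2 - old**2) / state.sigma_S**2,
        )

        def sigma_lp(st: ParamState) -> float:
            if st.sigma_S <= 0:
                return -np.inf
            return float(
                -0.5 * (st.S / st.sigma_S) ** 2 @ np.ones(self.n)
                - self.n * np.log(st.sigma_S)
                - 0.5 * (st.sigma_S / self.pr.sd_scale) ** 2
            )

        self._mh_logsd("sigma_S", state, "sigma_S", 0, sigma_lp)
        self._interweave_scale(state, "nc_sigma_S", "S", "sigma_S", 0)

    def update_coupling(self, state: ParamState):
        self._vector_site_update(
            state, "e", "e",
            lambda new, old: (
                self._bvn_site_lp(new, state.sd_e, state.rho_e)
                - self._bvn_site_lp(old, state.sd_e, state.rho_e)
            ),
        )

        def cov_lp(st: ParamState) -> float:
            if not (-1 < st.rho_e < 1) or (st.sd_e <= 0).any():
                return -np.inf
            lp = self._bvn_site_lp(st.e, st.sd_e, st.rho_e).sum()
            lp += -self.n * (np.log(st.sd_e).sum() + 0.5 * np.log1p(-st.rho_e**2))
            lp += -0.5 * float((st.sd_e / self.pr.sd_scale) ** 2 @ np.ones(2))
            return float(lp)

        for idx in range(2):
            self._mh_logsd(f"sd_e{idx}", state, "sd_e", idx, cov_lp)
        self._mh_scalar(
            "rho_e", state,
            lambda st: st.rho_e,
            lambda st, v: setattr(st, "rho_e", v),
            cov_lp,
            default=0.2,
        )
        for idx in range(2):
            self._interweave_scale(state, f"nc_sd_e{idx}", "e", "sd_e", idx)
        self._interweave_rho(state, "nc_rho_e", "e", "sd_e", "rho_e")

    def update_car(self, state: ParamState):
        # color-class single-site moves: within a class no two sites are
        # adjacent, so the CAR conditionals do not interact
        for cls in self.colors:
            cur_ll = self.site_ll(state)
            U_old = state.U.copy()
            step = self.rng.normal(0, self._scale("U", 0.5), size=len(cls))
            state.U[cls] = U_old[cls] + step
            new_ll = self.site_ll(state)
            nb_sum = self.A[cls] @ U_old
            deg = self.degree[cls]
            prior_delta = -0.5 * state.tau_U * (
                (deg * state.U[cls] ** 2 - 2 * state.U[cls] * nb_sum)
                - (deg * U_old[cls] ** 2 - 2 * U_old[cls] * nb_sum)
            )
            logr = (new_ll[cls] - cur_ll[cls]) + prior_delta
            accept = np.log(self.rng.uniform(size=len(cls))) < logr
            state.U[cls] = np.where(accept, state.U[cls], U_old[cls])
            self.accepts.setdefault("U", []).append(float(accept.mean()))
        hist = self.accepts.get("U", [])
        if self.adapting and len(hist) >= _ADAPT_INTERVAL:
            rate = float(np.mean(hist))
            self.scales["U"] = float(
                np.clip(self.scales["U"] * np.exp(rate - _TARGET_ACCEPT), 1e-3, 50.0)
            )
            hist.clear()
        # Gibbs for the CAR precision
        ssd = pairwise_deviance(state.U, self.data.adjacency)
        state.tau_U = float(
            self.rng.gamma(self.pr.tau_shape + 0.5 * self.car_rank,
                           1.0 / (self.pr.tau_rate + 0.5 * ssd))
        )
        # recenter (sum-to-zero) and fold the mean into the intercepts;
        # likelihood and CAR prior are invariant, so only the intercept
        # prior enters the acceptance ratio
        m = float(state.U.mean())
        if m != 0.0:
            a_new = state.alpha_occ + m
            logr = -0.5 * float(
                (a_new**2 - state.alpha_occ**2).sum()
            ) / self.pr.coef_sd**2
            if np.log(self.rng.uniform()) < logr:
                state.U -= m
                state.alpha_occ = a_new

    def sweep(self, state: ParamState):
        self.update_fixed_effects(state)
        if self.spec.use_diel_re:
            self.update_diel_re(state)
        if self.spec.use_det_site_re:
            self.update_det_site_re(state)
        if self.spec.use_car:
            self.update_car(state)
        if self.spec.use_coupling:
            self.update_coupling(state)


def run_mcmc(
    data: OccupancyData,
    spec: ModelSpec,
    n_chains: int = 5,
    n_iter: int = 40_000,
    burn_in: int = 10_000,
    thin: int = 5,
    seed: int | None = None,
) -> PosteriorSamples:
    """Sample the posterior of the day/night occupancy model.

    Identical inputs and seed give bit-identical retained draws.  The
    number of retained draws per chain is ``(n_iter - burn_in) // thin``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible runs")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    n_draws = (n_iter - burn_in) // thin
    if n_draws < 1:
        raise ValueError("no retained draws with these settings")

    n = data.n_sites
    shapes = {
        "alpha_occ": (2,), "alpha_det": (2,),
        "beta": (2, spec.n_occ), "gamma": (2,), "delta": (2, spec.n_det),
        "w_beta": (2, spec.n_occ), "w_gamma": (2,), "w_delta": (2, spec.n_det),
        "rho": (), "sd_d": (2,), "sigma_S": (), "tau_U": (),
        "rho_e": (), "sd_e": (2,), "loglik": (),
    }
    draws = {
        name: np.zeros((n_chains, n_draws, *shape)) for name, shape in shapes.items()
    }
    psi_acc = _Accumulator((n, 2))
    p_acc = _Accumulator((n, 2))
    overall_acc = _Accumulator((n,))

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(n_chains)
    for ci in range(n_chains):
        rng = np.random.default_rng(chain_seeds[ci])
        sampler = _Sampler(data, spec, rng)
        state = None
        for _attempt in range(_MAX_INIT_RETRIES):
            cand = ParamState.initial(spec, n, rng)
            if np.isfinite(sampler.total_ll(cand)):
                state = cand
                break
        if state is None:
            raise RuntimeError("could not find a finite-likelihood initial state")
        t = 0
        for it in range(n_iter):
            sampler.adapting = it < burn_in
            sampler.sweep(state)
            if it >= burn_in and (it - burn_in) % thin == 0 and t < n_draws:
                for name in ("alpha_occ", "alpha_det", "beta", "gamma", "delta",
                             "w_beta", "w_gamma", "w_delta", "sd_d", "sd_e"):
                    draws[name][ci, t] = getattr(state, name.removeprefix(""))
                draws["rho"][ci, t] = state.rho
                draws["sigma_S"][ci, t] = state.sigma_S
                draws["tau_U"][ci, t] = state.tau_U
                draws["rho_e"][ci, t] = state.rho_e
                psi = occurrence_prob(state, spec, data)
                p = detection_prob(state, spec, data)
                draws["loglik"][ci, t] = site_marginal_loglik(
                    data.y, data.k, psi, p, data._log_choose
                ).sum()
                psi_acc.add(psi)
                p_acc.add(p)
                overall_acc.add(overall_occurrence(psi[:, 0], psi[:, 1]))
                t += 1

    return PosteriorSamples(
        draws=draws,
        spec=spec,
        n_chains=n_chains,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        psi_mean=psi_acc.mean,
        psi_sd=psi_acc.sd,
        p_mean=p_acc.mean,
        p_sd=p_acc.sd,
        psi_overall_mean=overall_acc.mean,
        psi_overall_sd=overall_acc.sd,
        site_ids=data.site_ids,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def _indicator_draws(samples: PosteriorSamples) -> tuple[list[str], np.ndarray]:
    """(names, (n_total_draws, n_ind)) indicator matrix in roster order."""
    spec = samples.spec
    if not spec.select:
        raise ValueError("indicator sampling was not enabled for this fit")
    blocks = []
    for j in range(2):
        blocks.append(samples.flat("w_beta")[:, j, :])
        if spec.use_dog_covariate:
            blocks.append(samples.flat("w_gamma")[:, j : j + 1])
    if spec.select_detection:
        for j in range(2):
            blocks.append(samples.flat("w_delta")[:, j, :])
    W = np.concatenate(blocks, axis=1).astype(int)
    names = spec.indicator_names()
    assert W.shape[1] == len(names)
    return names, W


def model_ranking(samples: PosteriorSamples, threshold: float = SUPPORT_THRESHOLD) -> ModelRanking:
    """Posterior model probabilities: the relative frequency of each
    indicator combination among retained draws, pooled across chains.
    Ties are broken by fewer included effects, then lexicographically."""
    names, W = _indicator_draws(samples)
    combos, counts = np.unique(W, axis=0, return_counts=True)
    total = counts.sum()
    entries = [
        (tuple(int(v) for v in combo), count / total)
        for combo, count in zip(combos, counts)
    ]
    entries.sort(key=lambda e: (-e[1], sum(e[0]), e[0]))
    return ModelRanking(names, entries, threshold)


def inclusion_probabilities(samples: PosteriorSamples) -> pd.Series:
    """Pr(w_c = 1) per fixed effect — the marginals of the model ranking."""
    names, W = _indicator_draws(samples)
    return pd.Series(W.mean(axis=0), index=names, name="inclusion_probability")


def _coefficient_blocks(samples: PosteriorSamples):
    """Yield (label, period, coef_draws, w_draws) per reportable effect."""
    spec = samples.spec
    periods = ("day", "night")
    ones = None
    for j, per in enumerate(periods):
        beta = samples.flat("beta")
        w_beta = samples.flat("w_beta") if spec.select else None
        for c, name in enumerate(spec.occ_covariates):
            w = w_beta[:, j, c] if w_beta is not None else np.ones(len(beta))
            yield f"psi:{name}", per, beta[:, j, c], w
        if spec.use_dog_covariate:
            g = samples.flat("gamma")[:, j]
            w = samples.flat("w_gamma")[:, j] if spec.select else np.ones(len(g))
            yield "psi:Dog", per, g, w
        delta = samples.flat("delta")
        w_delta = samples.flat("w_delta") if spec.select_detection else None
        for c, name in enumerate(spec.det_covariates):
            w = w_delta[:, j, c] if w_delta is not None else np.ones(len(delta))
            yield f"p:{name}", per, delta[:, j, c], w


def model_averaged_coefficients(
    samples: PosteriorSamples, conditional: bool = True
) -> pd.DataFrame:
    """Posterior summaries per fixed effect: mean, sd, 95% CI, inclusion
    probability, and whether the CI excludes zero.

    With ``conditional=True`` (default) statistics are computed over the
    draws in which the effect was included (w_c = 1); an effect never
    included is reported absent (NaN statistics), the "-" convention of
    occupancy coefficient tables.  ``conditional=False`` averages over all
    draws, zeros included.
    """
    lo, hi = 100 * (1 - CI_LEVEL) / 2, 100 * (1 + CI_LEVEL) / 2
    rows = []
    for label, period, values, w in _coefficient_blocks(samples):
        inc = float(np.mean(w))
        sel = values[w.astype(bool)] if conditional else np.where(w.astype(bool), values, 0.0)
        if sel.size == 0:
            rows.append(
                dict(coefficient=label, period=period, mean=np.nan, sd=np.nan,
                     ci_low=np.nan, ci_high=np.nan, inclusion_probability=inc,
                     excludes_zero=False, included_ever=False)
            )
            continue
        ci = np.percentile(sel, [lo, hi])
        rows.append(
            dict(
                coefficient=label, period=period,
                mean=float(sel.mean()), sd=float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
                ci_low=float(ci[0]), ci_high=float(ci[1]),
                inclusion_probability=inc,
                excludes_zero=bool(ci[0] > 0 or ci[1] < 0),
                included_ever=True,
            )
        )
    return pd.DataFrame(rows)


def psrf(samples: PosteriorSamples | dict[str, np.ndarray], threshold: float = 1.1) -> pd.DataFrame:
    """Split-chain Potential Scale Reduction factor per parameter.

    Each chain is split in half; the statistic is the usual
    between/within-chain variance ratio, near 1 at convergence.  Rows with
    PSRF above ``threshold`` are flagged.
    """
    chains = samples.scalar_chains() if isinstance(samples, PosteriorSamples) else samples
    rows = []
    for name, arr in chains.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("psrf needs >= 2 chains of draws")
        if arr.shape[1] < 10:
            raise ValueError("psrf needs >= 10 retained draws per chain")
        half = arr.shape[1] // 2
        split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
        m, nn = split.shape
        means = split.mean(axis=1)
        variances = split.var(axis=1, ddof=1)
        W = float(variances.mean())
        B = nn * float(means.var(ddof=1))
        if W == 0.0:
            rhat = 1.0 if B == 0.0 else np.inf
        else:
            rhat = float(np.sqrt(((nn - 1) / nn * W + B / nn) / W))
        rows.append({"parameter": name, "psrf": rhat, "flagged": rhat > threshold})
    return pd.DataFrame(rows)


def day_night_correlation(samples: PosteriorSamples) -> tuple[float, float]:
    """Posterior mean and sd of rho, the day/night occurrence correlation."""
    rho = samples.flat("rho")
    return float(rho.mean()), float(rho.std(ddof=1))


def predict_psi_surface(
    samples: PosteriorSamples,
    cov_a: str,
    grid_a: np.ndarray,
    cov_b: str,
    grid_b: np.ndarray,
    max_draws: int = 400,
) -> np.ndarray:
    """Posterior-mean occurrence surface over two covariates.

    Returns a (len(grid_a), len(grid_b), 2) array of psi values per diel
    period, with the remaining covariates at their (standardized) mean of
    zero and the random effects at zero.  Each retained draw contributes
    its own inverse-logit surface (indicators included), so the average is
    the model-averaged prediction.
    """
    spec = samples.spec
    ia = spec.occ_covariates.index(cov_a)
    ib = spec.occ_covariates.index(cov_b)
    alpha = samples.flat("alpha_occ")
    beta = samples.flat("beta")
    w = samples.flat("w_beta") if spec.select else np.ones_like(beta)
    n_total = len(alpha)
    step = max(1, n_total // max_draws)
    idx = np.arange(0, n_total, step)
    A, B = np.meshgrid(np.asarray(grid_a, float), np.asarray(grid_b, float),
                       indexing="ij")
    out = np.zeros((*A.shape, 2))
    for j in range(2):
        ba = (w[idx, j, ia] * beta[idx, j, ia])[:, None, None]
        bb = (w[idx, j, ib] * beta[idx, j, ib])[:, None, None]
        lp = alpha[idx, j][:, None, None] + ba * A[None] + bb * B[None]
        out[:, :, j] = expit(clamp_logit(lp)).mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# guild fitting (two-stage dog plug-in)


def _species_data(
    history: pd.DataFrame,
    species: str,
    X_occ: np.ndarray,
    X_det: np.ndarray,
    occ_names,
    det_names,
    site_ids,
    adjacency=None,
    psi_dog=None,
) -> OccupancyData:
    sub = history[history["species"] == species]
    piv_y = sub.pivot_table(index="site_id", columns="period", values="y").loc[list(site_ids)]
    piv_k = sub.pivot_table(index="site_id", columns="period", values="k").loc[list(site_ids)]
    y = piv_y[["day", "night"]].to_numpy(float)
    k = piv_k["day"].to_numpy(float)
    return OccupancyData(
        y=y, k=k, X_occ=X_occ, X_det=X_det,
        occ_names=tuple(occ_names), det_names=tuple(det_names),
        psi_dog=psi_dog, adjacency=adjacency, site_ids=tuple(site_ids),
    )


def fit_guild(
    history: pd.DataFrame,
    X_occ: pd.DataFrame,
    X_det: pd.DataFrame,
    site_ids: list[str],
    species_spec: ModelSpec,
    dog_species: str = "Dog",
    adjacency=None,
    n_chains: int = 5,
    n_iter: int = 40_000,
    burn_in: int = 10_000,
    thin: int = 5,
    seed: int | None = None,
) -> dict[str, PosteriorSamples]:
    """Fit every species in a guild with the two-stage dog plug-in.

    Stage 1 fits the dog with a covariate-free occurrence model (its
    detection model keeps its covariates) and exports the posterior-mean
    site/period occurrence psi_D.  Stage 2 fits each native species with
    psi_D entered as the Dog covariate.  The dog's own covariate-bearing
    occurrence model is fitted as well (keyed ``f"{dog_species}:report"``)
    for its coefficient table.

    Species with zero detections in both periods are skipped with a
    warning.  Seeds for the per-species fits are derived from ``seed`` by
    fixed offsets, so a guild fit is reproducible end to end.
    """
    if seed is None:
        raise ValueError("a seed is required")
    all_species = sorted(history["species"].unique())
    if dog_species not in all_species:
        raise ValueError(
            f"required species {dog_species!r} absent from the detection history"
        )
    occ_names = tuple(X_occ.columns)
    det_names = tuple(X_det.columns)
    Xo = X_occ.to_numpy(float)
    Xd = X_det.to_numpy(float)

    def data_for(sp, psi_dog=None):
        return _species_data(history, sp, Xo, Xd, occ_names, det_names,
                             site_ids, adjacency, psi_dog)

    mcmc = dict(n_chains=n_chains, n_iter=n_iter, burn_in=burn_in, thin=thin)
    results: dict[str, PosteriorSamples] = {}

    # stage 1: null-psi dog model -> plug-in psi_D
    from dataclasses import replace as _replace

    dog_null_spec = _replace(
        species_spec, occ_covariates=(), use_dog_covariate=False, select=False
    )
    dog_data = data_for(dog_species)
    results[dog_species] = run_mcmc(dog_data, dog_null_spec, seed=seed + 1, **mcmc)
    psi_dog = results[dog_species].psi_mean

    # the dog's own covariate-bearing occurrence model, for reporting
    dog_report_spec = _replace(species_spec, use_dog_covariate=False)
    results[f"{dog_species}:report"] = run_mcmc(
        dog_data, dog_report_spec, seed=seed + 2, **mcmc
    )

    # stage 2: native species with the plug-in dog covariate
    for offset, sp in enumerate(s for s in all_species if s != dog_species):
        data = data_for(sp, psi_dog if species_spec.use_dog_covariate else None)
        if data.y.sum() == 0:
            warnings.warn(f"species {sp!r}: zero detections in both periods; skipped")
            continue
        results[sp] = run_mcmc(data, species_spec, seed=seed + 10 + offset, **mcmc)
    return results
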