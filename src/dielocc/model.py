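"""The day/night occupancy model: occurrence, detection, priors, likelihood.

For each site i and diel period j (1 = day, 2 = night) the species is
present with probability psi_ij and, if present, detected on each of the
k_i trap-day occasions with probability p_ij:

    z_ij ~ Bernoulli(psi_ij)
    y_ij | z_ij ~ Binomial(k_i, z_ij * p_ij)

    logit(psi_ij) = alpha1_j + beta_j' X_i + gamma_j * psiD_ij + U_i + d_ij
    logit(p_ij)   = alpha2_j + delta_j' X_i + S_i

where X_i are standardized site covariates, psiD_ij is the plug-in
occurrence probability of free-ranging dogs (fitted first, entered as a
covariate in the native-species models), U_i is an intrinsic-CAR spatial
field on the Voronoi neighbor graph, S_i is an unstructured detection
site effect, and d_i = (d_i1, d_i2) is a site-level bivariate normal diel
random effect whose correlation rho measures the coupling between day and
night occurrence.  An optional site-level bivariate residual e_i =
(e_psi, e_p) couples the occurrence and detection logits.

Overall (24-hour) occurrence is the union of the two periods:

    psi_i = 1 - (1 - psi_i1)(1 - psi_i2)

The latent z is marginalized analytically, so the exported likelihood is
exact:

    P(y_ij) = psi_ij * C(k,y) p^y (1-p)^(k-y) + 1{y_ij = 0} (1 - psi_ij)

Each coefficient can carry a Bernoulli(0.5) inclusion indicator w_c for
indicator-variable model selection; an excluded coefficient is dropped
from the linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .spatial import Adjacency, car_logdensity

__all__ = [
    "PriorSettings",
    "ModelSpec",
    "ParamState",
    "OccupancyData",
    "occurrence_prob",
    "detection_prob",
    "overall_occurrence",
    "site_marginal_loglik",
    "total_loglik",
    "prior_logdensity",
    "clamp_logit",
    "LOGIT_CLAMP",
]

#: linear predictors are clamped at this magnitude before inverse-logit
LOGIT_CLAMP = 35.0

N_PERIODS = 2  # day, night


def clamp_logit(lp: np.ndarray) -> np.ndarray:
    return np.clip(lp, -LOGIT_CLAMP, LOGIT_CLAMP)


@dataclass(frozen=True)
class PriorSettings:
    """Vague priors for every model parameter.

    coef_sd         N(0, coef_sd^2) on intercepts and slope coefficients
    tau_shape/rate  Gamma prior on the CAR precision tau_U
    sd_scale        Half-Normal(0, sd_scale) on sigma_S and the sds of the
                    diel and coupling covariance matrices.  The default of
                    1.5 is deliberate: with a single presence pair per site
                    the random-effect scale is identified mainly through
                    its prior, and logit-scale heterogeneity much beyond
                    1.5 saturates the probabilities it generates.
    w_prior         Bernoulli inclusion prior for each indicator
    pseudo_sd       sd of the distribution an *excluded* coefficient is
                    drawn from during sampling (a Carlin-Chib pseudo-prior;
                    affects mixing only, never the posterior)
    """

    coef_sd: float = 10.0
    tau_shape: float = 0.5
    tau_rate: float = 0.0005
    sd_scale: float = 1.5
    w_prior: float = 0.5
    pseudo_sd: float = 1.5


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one species' model: covariate rosters and random-effect
    flags.

    ``select`` enables inclusion indicators on the occurrence-side fixed
    effects (the default roster: every occurrence covariate plus the dog
    term, per period — 2 x (9 + 1) = 20 indicators for the full covariate
    set).  ``select_detection`` extends selection to the detection-side
    coefficients.
    """

    occ_covariates: tuple[str, ...] = ()
    det_covariates: tuple[str, ...] = ()
    use_dog_covariate: bool = False
    use_car: bool = False
    use_diel_re: bool = False
    use_det_site_re: bool = False
    use_coupling: bool = False
    select: bool = False
    select_detection: bool = False
    priors: PriorSettings = field(default_factory=PriorSettings)

    @property
    def n_occ(self) -> int:
        return len(self.occ_covariates)

    @property
    def n_det(self) -> int:
        return len(self.det_covariates)

    def n_indicators(self) -> int:
        """Size of the selectable fixed-effect roster (model space = 2**n)."""
        if not self.select:
            return 0
        n = N_PERIODS * (self.n_occ + (1 if self.use_dog_covariate else 0))
        if self.select_detection:
            n += N_PERIODS * self.n_det
        return n

    def indicator_names(self) -> list[str]:
        names: list[str] = []
        if not self.select:
            return names
        for j, period in enumerate(("day", "night")):
            for c in self.occ_covariates:
                names.append(f"psi_{period}:{c}")
            if self.use_dog_covariate:
                names.append(f"psi_{period}:Dog")
        if self.select_detection:
            for j, period in enumerate(("day", "night")):
                for c in self.det_covariates:
                    names.append(f"p_{period}:{c}")
        return names


@dataclass
class OccupancyData:
    """Arrays the likelihood consumes, aligned on sites.

    y : (n, 2) detected-occasion counts (day, night)
    k : (n,) trap days per site (occasions per period)
    X_occ : (n, n_occ) standardized occurrence covariates
    X_det : (n, n_det) standardized detection covariates
    psi_dog : (n, 2) plug-in dog occurrence, or None
    adjacency : Voronoi neighbor graph, or None
    """

    y: np.ndarray
    k: np.ndarray
    X_occ: np.ndarray
    X_det: np.ndarray
    occ_names: tuple[str, ...] = ()
    det_names: tuple[str, ...] = ()
    psi_dog: np.ndarray | None = None
    adjacency: Adjacency | None = None
    site_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        n = len(self.k)
        if self.y.shape != (n, N_PERIODS):
            raise ValueError("y must be (n_sites, 2)")
        if (self.y < 0).any() or (self.y > self.k[:, None]).any():
            raise ValueError("need 0 <= y <= k")
        self.X_occ = np.atleast_2d(np.asarray(self.X_occ, dtype=float).reshape(n, -1))
        self.X_det = np.atleast_2d(np.asarray(self.X_det, dtype=float).reshape(n, -1))
        if self.psi_dog is not None:
            self.psi_dog = np.asarray(self.psi_dog, dtype=float)
            if self.psi_dog.shape != (n, N_PERIODS):
                raise ValueError("psi_dog must be (n_sites, 2)")
            if (self.psi_dog < 0).any() or (self.psi_dog > 1).any():
                raise ValueError("psi_dog must lie in [0, 1]")
        # log C(k, y): constant across parameters, cached once
        self._log_choose = (
            gammaln(self.k[:, None] + 1)
            - gammaln(self.y + 1)
            - gammaln(self.k[:, None] - self.y + 1)
        )

    @property
    def n_sites(self) -> int:
        return len(self.k)


def _zeros(*shape):
    return np.zeros(shape, dtype=float)


@dataclass
class ParamState:
    """One point in parameter space (a single MCMC state).

    Shapes: alpha_occ/alpha_det (2,), beta (2, n_occ), gamma (2,),
    delta (2, n_det), U (n,), S (n,), d (n, 2), e (n, 2); indicator blocks
    mirror beta/gamma/delta.
    """

    alpha_occ: np.ndarray
    alpha_det: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    w_beta: np.ndarray
    w_gamma: np.ndarray
    w_delta: np.ndarray
    U: np.ndarray
    tau_U: float
    S: np.ndarray
    sigma_S: float
    d: np.ndarray
    sd_d: np.ndarray  # (2,)
    rho: float
    e: np.ndarray
    sd_e: np.ndarray  # (2,) for (e_psi, e_p)
    rho_e: float

    @classmethod
    def initial(cls, spec: ModelSpec, n_sites: int, rng: np.random.Generator | None = None) -> "ParamState":
        rng = rng or np.random.default_rng(0)
        j = N_PERIODS
        return cls(
            alpha_occ=rng.normal(0, 0.5, j),
            alpha_det=rng.normal(0, 0.5, j),
            beta=rng.normal(0, 0.25, (j, spec.n_occ)),
            gamma=rng.normal(0, 0.25, j) if spec.use_dog_covariate else _zeros(j),
            delta=rng.normal(0, 0.25, (j, spec.n_det)),
            w_beta=np.ones((j, spec.n_occ), dtype=int),
            w_gamma=np.ones(j, dtype=int),
            w_delta=np.ones((j, spec.n_det), dtype=int),
            U=_zeros(n_sites),
            tau_U=1.0,
            S=_zeros(n_sites),
            sigma_S=0.5,
            d=_zeros(n_sites, j),
            sd_d=np.full(j, 0.5),
            rho=0.0,
            e=_zeros(n_sites, j),
            sd_e=np.full(j, 0.5),
            rho_e=0.0,
        )

    def copy(self) -> "ParamState":
        return ParamState(
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )


def occurrence_logit(state: ParamState, spec: ModelSpec, data: OccupancyData) -> np.ndarray:
    """(n, 2) occurrence linear predictor with active terms only."""
    lp = np.broadcast_to(state.alpha_occ, (data.n_sites, N_PERIODS)).copy()
    if spec.n_occ:
        lp += data.X_occ @ (state.w_beta * state.beta).T
    if spec.use_dog_covariate:
        if data.psi_dog is None:
            raise ValueError("model includes the dog covariate but data has no psi_dog")
        lp += (state.w_gamma * state.gamma)[None, :] * data.psi_dog
    if spec.use_car:
        lp += state.U[:, None]
    if spec.use_diel_re:
        lp += state.d
    if spec.use_coupling:
        lp += state.e[:, [0]]
    return clamp_logit(lp)


def detection_logit(state: ParamState, spec: ModelSpec, data: OccupancyData) -> np.ndarray:
    lp = np.broadcast_to(state.alpha_det, (data.n_sites, N_PERIODS)).copy()
    if spec.n_det:
        lp += data.X_det @ (state.w_delta * state.delta).T
    if spec.use_det_site_re:
        lp += state.S[:, None]
    if spec.use_coupling:
        lp += state.e[:, [1]]
    return clamp_logit(lp)


def occurrence_prob(state: ParamState, spec: ModelSpec, data: OccupancyData) -> np.ndarray:
    """psi_ij, the (n, 2) matrix of day/night occurrence probabilities."""
    return expit(occurrence_logit(state, spec, data))


def detection_prob(state: ParamState, spec: ModelSpec, data: OccupancyData) -> np.ndarray:
    """p_ij, the (n, 2) matrix of day/night detection probabilities."""
    return expit(detection_logit(state, spec, data))


def overall_occurrence(psi_day, psi_night):
    """Union probability of occurring in either period:
    psi = 1 - (1 - psi_day)(1 - psi_night)."""
    psi1 = np.asarray(psi_day, dtype=float)
    psi2 = np.asarray(psi_night, dtype=float)
    if ((psi1 < 0) | (psi1 > 1)).any() or ((psi2 < 0) | (psi2 > 1)).any():
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    out = 1.0 - (1.0 - psi1) * (1.0 - psi2)
    if out.ndim == 0:
        return float(out)
    return out


def site_marginal_loglik(
    y: np.ndarray,
    k: np.ndarray,
    psi: np.ndarray,
    p: np.ndarray,
    log_choose: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site log likelihood with the latent presence z summed out.

    Arguments are (n, 2) arrays (or broadcastable); the return is the (n,)
    vector of per-site log likelihoods, the two periods being conditionally
    independent given psi:

        log P(y_ij) = log[ psi * C(k,y) p^y (1-p)^(k-y) + 1{y=0} (1-psi) ]
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    k = np.asarray(k, dtype=float).reshape(-1, 1)
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if (y > k).any() or (y < 0).any():
        raise ValueError("need 0 <= y <= k")
    if log_choose is None:
        log_choose = gammaln(k + 1) - gammaln(y + 1) - gammaln(k - y + 1)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    psi = np.clip(psi, 1e-300, 1 - 1e-16)
    with np.errstate(divide="ignore"):
        log_binom = log_choose + y * np.log(p) + (k - y) * np.log1p(-p)
        present = np.log(psi) + log_binom
        absent = np.where(y == 0, np.log1p(-psi), -np.inf)
    return np.logaddexp(present, absent).sum(axis=1)


def total_loglik(state: ParamState, spec: ModelSpec, data: OccupancyData) -> float:
    psi = occurrence_prob(state, spec, data)
    p = detection_prob(state, spec, data)
    return float(
        site_marginal_loglik(data.y, data.k, psi, p, data._log_choose).sum()
    )


def _normal_lpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return float((-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)).sum())


def _halfnormal_lpdf(x, scale):
    if np.any(np.asarray(x) <= 0):
        return -np.inf
    return _normal_lpdf(x, scale) + np.log(2.0) * np.size(x)


def _bvn_lpdf(pairs: np.ndarray, sd: np.ndarray, rho: float) -> float:
    """Sum of centered bivariate-normal log densities over rows."""
    z1 = pairs[:, 0] / sd[0]
    z2 = pairs[:, 1] / sd[1]
    q = (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (1 - rho * rho)
    n = len(pairs)
    return float(
        -0.5 * q.sum()
        - n * (np.log(2 * np.pi) + np.log(sd[0]) + np.log(sd[1]) + 0.5 * np.log1p(-rho * rho))
    )


def prior_logdensity(state: ParamState, spec: ModelSpec, data: OccupancyData) -> float:
    """Joint log prior of a parameter state (up to additive constants).

    Coefficients: N(0, coef_sd); CAR precision: Gamma(tau_shape, tau_rate);
    sds: Half-Normal(sd_scale); correlations: Uniform(-1, 1); inclusion
    indicators: Bernoulli(w_prior).  Excluded coefficients score under the
    pseudo-prior (see PriorSettings).  Invariant violations return -inf.
    """
    pr = spec.priors
    lp = 0.0
    lp += _normal_lpdf(state.alpha_occ, pr.coef_sd)
    lp += _normal_lpdf(state.alpha_det, pr.coef_sd)

    def coef_block(values, w):
        v = np.asarray(values, dtype=float).ravel()
        inc = np.asarray(w).ravel().astype(bool)
        out = 0.0
        if inc.any():
            out += _normal_lpdf(v[inc], pr.coef_sd)
        if (~inc).any():
            out += _normal_lpdf(v[~inc], pr.pseudo_sd)
        n_w = inc.size
        n_on = int(inc.sum())
        out += n_on * np.log(pr.w_prior) + (n_w - n_on) * np.log1p(-pr.w_prior)
        return out

    if spec.n_occ:
        lp += coef_block(state.beta, state.w_beta if spec.select else np.ones_like(state.beta))
    if spec.use_dog_covariate:
        lp += coef_block(state.gamma, state.w_gamma if spec.select else np.ones_like(state.gamma))
    if spec.n_det:
        lp += coef_block(
            state.delta,
            state.w_delta if spec.select_detection else np.ones_like(state.delta),
        )

    if spec.use_car:
        if data.adjacency is None:
            raise ValueError("CAR term requested but data has no adjacency")
        if state.tau_U <= 0:
            return -np.inf
        lp += car_logdensity(state.U, data.adjacency, state.tau_U)
        # Gamma(shape, rate) on tau, plus the tau-dependent CAR normalizer
        # tau^(rank/2); rank = n - number of graph components
        rank = data.adjacency.n_sites - data.adjacency.n_components()
        lp += (pr.tau_shape - 1 + 0.5 * rank) * np.log(state.tau_U) - pr.tau_rate * state.tau_U

    if spec.use_det_site_re:
        if state.sigma_S <= 0:
            return -np.inf
        lp += _halfnormal_lpdf(state.sigma_S, pr.sd_scale)
        lp += _normal_lpdf(state.S, state.sigma_S)

    if spec.use_diel_re:
        if not (-1 < state.rho < 1) or (state.sd_d <= 0).any():
            return -np.inf
        lp += _halfnormal_lpdf(state.sd_d, pr.sd_scale)
        lp += _bvn_lpdf(state.d, state.sd_d, state.rho)

    if spec.use_coupling:
        if not (-1 < state.rho_e < 1) or (state.sd_e <= 0).any():
            return -np.inf
        lp += _halfnormal_lpdf(state.sd_e, pr.sd_scale)
        lp += _bvn_lpdf(state.e, state.sd_e, state.rho_e)

    return lp
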