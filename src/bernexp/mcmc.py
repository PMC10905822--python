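"""Posterior construction, Metropolis-within-Gibbs sampling, summaries, DIC.

The full conditionals of the joint model are non-conjugate, so each scalar
parameter is updated in turn by a Gaussian random-walk Metropolis step
targeting its full conditional -- the component-wise structure of a Gibbs
sweep with Metropolis inner kernels.  The fixed update order is
``alpha_1..alpha_p, psi, vartheta, xi, gamma``.

During burn-in, proposal standard deviations adapt in batches of 50 sweeps
(Roberts-Rosenthal diminishing adaptation) toward an acceptance rate of 0.44,
the optimum for univariate random-walk Metropolis, and are frozen afterwards
so the post-burn-in chain is a genuine Markov chain.

Thinning keeps post-burn-in sweep ``j`` (1-based) iff ``(j - 1) % thin == 0``,
so the number of retained draws is ``ceil((n_iter - burn_in) / thin)``
(6667 under the defaults 30000 / 10000 / 3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .model import LikelihoodState, ModelParameters, PanelDataset, deviance
from .priors import PriorScheme, jeffreys_log_prior_alpha, log_prior_gaussian, _normal_logpdf

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "DICResult",
    "log_posterior",
    "run_mcmc",
    "posterior_summary",
    "compute_dic",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``proposal_scales`` may be a scalar, a mapping from parameter name to
    scale, or None for the default 0.5.  ``update`` optionally restricts
    sampling to a subset of parameter names (the rest stay at their initial
    values) -- useful for degenerate subproblems and calibration checks.
    """

    n_iter: int = 30000
    burn_in: int = 10000
    thin: int = 3
    seed: int = 0
    proposal_scales: object = None
    adapt: bool = True
    n_chains: int = 1
    update: tuple = None

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError(f"need 0 <= burn_in < n_iter, got {self.burn_in}, {self.n_iter}")
        if self.thin < 1:
            raise ValueError(f"thin must be >= 1, got {self.thin}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return math.ceil((self.n_iter - self.burn_in) / self.thin)

    def scale_for(self, name: str) -> float:
        s = self.proposal_scales
        if s is None:
            return 0.5
        if np.isscalar(s):
            return float(s)
        return float(s.get(name, 0.5))


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained draws (rows = kept sweeps, columns = named parameters)."""

    draws: np.ndarray
    names: tuple
    acceptance: dict
    config: MCMCConfig
    p: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.names))

    def mean_parameters(self) -> ModelParameters:
        return ModelParameters.from_vector(self.draws.mean(axis=0), self.p)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion decomposition.

    Dbar -- posterior mean deviance; Dhat -- deviance at the posterior mean;
    pD = Dbar - Dhat (effective number of parameters); DIC = Dhat + 2*pD.
    """

    Dbar: float
    Dhat: float
    pD: float = field(init=False)
    DIC: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "pD", self.Dbar - self.Dhat)
        object.__setattr__(self, "DIC", self.Dhat + 2.0 * self.pD)

    def to_dict(self) -> dict:
        return {"Dbar": self.Dbar, "Dhat": self.Dhat, "pD": self.pD, "DIC": self.DIC}


def log_posterior(params: ModelParameters, data: PanelDataset, scheme: PriorScheme) -> float:
    """Log posterior density up to an additive constant."""
    state = LikelihoodState(data)
    ll = state.bernoulli_loglik(params.alpha, params.psi, params.vartheta) + state.exponential_loglik(
        params.xi, params.gamma
    )
    if scheme.is_jeffreys:
        lp = jeffreys_log_prior_alpha(
            params.alpha, data, (params.psi, params.vartheta), _state=state
        )
        for name in ("psi", "vartheta", "xi", "gamma"):
            mean, var = getattr(scheme.gaussian, name)
            lp += _normal_logpdf(getattr(params, name), mean, var)
    else:
        lp = log_prior_gaussian(params, scheme.gaussian)
    return float(ll + lp)


class _Target:
    """Cached component-wise evaluation of the log posterior.

    Splits the target into the Bernoulli block (alpha, psi, vartheta), the
    exponential block (xi, gamma) and the priors, so one-coordinate updates
    only recompute what they touch.
    """

    def __init__(self, data: PanelDataset, scheme: PriorScheme):
        self.state = LikelihoodState(data)
        self.scheme = scheme
        self.p = data.p
        g = scheme.gaussian
        if not scheme.is_jeffreys:
            self._alpha_chol = linalg.cho_factor(g.alpha_cov, lower=True)
        self._scalar_hyper = {n: getattr(g, n) for n in ("psi", "vartheta", "xi", "gamma")}

    # -- prior pieces ------------------------------------------------------
    def alpha_log_prior(self, alpha, psi, vartheta, xalpha=None):
        if self.scheme.is_jeffreys:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                w = self.state.weights(alpha, psi, vartheta, xalpha)
                info = (self.state.X * w[:, None]).T @ self.state.X
                sign, logdet = np.linalg.slogdet(info)
            return 0.5 * logdet if sign > 0 and np.isfinite(logdet) else -np.inf
        g = self.scheme.gaussian
        dev = alpha - g.alpha_mean
        return -0.5 * float(dev @ linalg.cho_solve(self._alpha_chol, dev))

    def scalar_log_prior(self, name, value):
        mean, var = self._scalar_hyper[name]
        return -0.5 * (value - mean) ** 2 / var

    # -- likelihood pieces -------------------------------------------------
    def bern(self, alpha, psi, vartheta, xalpha=None):
        return self.state.bernoulli_loglik(alpha, psi, vartheta, xalpha)

    def expo(self, xi, gamma):
        return self.state.exponential_loglik(xi, gamma)


def _run_single_chain(target: _Target, config: MCMCConfig, init: ModelParameters, seed: int):
    p = target.p
    names = ModelParameters.names(p)
    update = set(names if config.update is None else config.update)
    unknown = update - set(names)
    if unknown:
        raise ValueError(f"unknown parameter names in update set: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    theta = init.to_vector().copy()
    alpha = theta[:p]
    psi, vartheta, xi, gamma = theta[p:]

    st = target.state
    xalpha = st.X @ alpha
    bern = target.bern(alpha, psi, vartheta, xalpha)
    expo = target.expo(xi, gamma)
    prior_alpha = target.alpha_log_prior(alpha, psi, vartheta, xalpha)
    if not np.isfinite(bern + expo + prior_alpha):
        raise ValueError("initial parameters have non-finite log posterior")

    scales = np.array([config.scale_for(n) for n in names])
    kept = np.empty((config.n_kept, p + 4))
    accept_post = np.zeros(p + 4)
    batch_acc = np.zeros(p + 4)
    batch_len = 50
    n_batches = 0
    kept_i = 0

    for it in range(1, config.n_iter + 1):
        in_burn = it <= config.burn_in
        for j, name in enumerate(names):
            if name not in update:
                continue
            step = scales[j] * rng.standard_normal()
            logu = np.log(rng.random())
            if j < p:  # alpha_j
                new_xalpha = xalpha + step * st.X[:, j]
                new_alpha = alpha.copy()
                new_alpha[j] += step
                new_bern = target.bern(new_alpha, psi, vartheta, new_xalpha)
                new_pa = target.alpha_log_prior(new_alpha, psi, vartheta, new_xalpha)
                delta = (new_bern + new_pa) - (bern + prior_alpha)
                if logu < delta:
                    alpha, xalpha, bern, prior_alpha = new_alpha, new_xalpha, new_bern, new_pa
                    accepted = True
                else:
                    accepted = False
            elif name in ("psi", "vartheta"):
                new_psi = psi + step if name == "psi" else psi
                new_vt = vartheta + step if name == "vartheta" else vartheta
                cur = psi if name == "psi" else vartheta
                new_bern = target.bern(alpha, new_psi, new_vt, xalpha)
                delta = new_bern - bern + (
                    target.scalar_log_prior(name, cur + step) - target.scalar_log_prior(name, cur)
                )
                if target.scheme.is_jeffreys:
                    new_pa = target.alpha_log_prior(alpha, new_psi, new_vt, xalpha)
                    delta += new_pa - prior_alpha
                else:
                    new_pa = prior_alpha
                if logu < delta:
                    psi, vartheta, bern, prior_alpha = new_psi, new_vt, new_bern, new_pa
                    accepted = True
                else:
                    accepted = False
            else:  # xi or gamma
                new_xi = xi + step if name == "xi" else xi
                new_gamma = gamma + step if name == "gamma" else gamma
                cur = xi if name == "xi" else gamma
                new_expo = target.expo(new_xi, new_gamma)
                delta = new_expo - expo + (
                    target.scalar_log_prior(name, cur + step) - target.scalar_log_prior(name, cur)
                )
                if logu < delta:
                    xi, gamma, expo = new_xi, new_gamma, new_expo
                    accepted = True
                else:
                    accepted = False
            if accepted:
                batch_acc[j] += 1
                if not in_burn:
                    accept_post[j] += 1

        if in_burn and config.adapt and it % batch_len == 0:
            n_batches += 1
            adj = min(0.1, n_batches ** -0.5)
            rates = batch_acc / batch_len
            scales *= np.exp(np.where(rates > 0.44, adj, -adj))
            batch_acc[:] = 0.0

        if not in_burn:
            jj = it - config.burn_in  # 1-based post-burn-in index
            if (jj - 1) % config.thin == 0:
                kept[kept_i, :p] = alpha
                kept[kept_i, p:] = (psi, vartheta, xi, gamma)
                kept_i += 1

    assert kept_i == config.n_kept
    denom = config.n_iter - config.burn_in
    acc = {n: accept_post[j] / denom for j, n in enumerate(names) if n in update}
    for n, r in acc.items():
        if not 0.05 <= r <= 0.95:
            warnings.warn(
                f"acceptance rate {r:.3f} for {n} is outside [0.05, 0.95] after adaptation",
                RuntimeWarning,
                stacklevel=3,
            )
    return kept, acc


def run_mcmc(
    data: PanelDataset,
    scheme: PriorScheme,
    config: MCMCConfig = MCMCConfig(),
    init: ModelParameters = None,
) -> PosteriorDraws:
    """Sample the posterior by Metropolis-within-Gibbs.

    ``init`` defaults to the prior means of the Gaussian bundle (all zeros
    under the non-informative and Jeffreys schemes).  Fully reproducible
    given ``config.seed``; chains beyond the first use seed + chain index and
    their draws are stacked row-wise.
    """
    if init is None:
        g = scheme.gaussian
        alpha0 = np.zeros(data.p) if scheme.is_jeffreys else g.alpha_mean.copy()
        init = ModelParameters(
            alpha=alpha0, psi=g.psi[0], vartheta=g.vartheta[0], xi=g.xi[0], gamma=g.gamma[0]
        )
    if init.p != data.p:
        raise ValueError(f"init alpha length {init.p} does not match data p={data.p}")
    target = _Target(data, scheme)
    blocks, acc = [], {}
    for c in range(config.n_chains):
        kept, acc = _run_single_chain(target, config, init, config.seed + c)
        blocks.append(kept)
    return PosteriorDraws(
        draws=np.vstack(blocks),
        names=tuple(ModelParameters.names(data.p)),
        acceptance=acc,
        config=config,
        p=data.p,
    )


def posterior_summary(draws) -> pd.DataFrame:
    """Per-parameter posterior mean, sd and equal-tailed 95% credible bounds.

    Sample sd uses the n-1 denominator; quantiles are empirical with linear
    (type-7) interpolation.  Columns follow the reporting layout
    ``Mean, SD, Lower(2.50%), Upper(97.50%)``.
    """
    frame = draws.to_frame() if isinstance(draws, PosteriorDraws) else pd.DataFrame(draws)
    if len(frame) < 2:
        raise ValueError("need at least 2 draws to summarise")
    q = frame.quantile([0.025, 0.975], interpolation="linear")
    return pd.DataFrame(
        {
            "Mean": frame.mean(),
            "SD": frame.std(ddof=1),
            "Lower(2.50%)": q.loc[0.025],
            "Upper(97.50%)": q.loc[0.975],
        }
    )


def compute_dic(draws: PosteriorDraws, data: PanelDataset) -> DICResult:
    """DIC from retained draws: Dbar over draws, Dhat at the column means."""
    state = LikelihoodState(data)
    if state.p != draws.p:
        raise ValueError("draws and data disagree on the number of covariates")
    devs = np.empty(draws.n_draws)
    for i, row in enumerate(draws.draws):
        pars = ModelParameters.from_vector(row, draws.p)
        devs[i] = -2.0 * (
            state.bernoulli_loglik(pars.alpha, pars.psi, pars.vartheta)
            + state.exponential_loglik(pars.xi, pars.gamma)
        )
    dhat = deviance(draws.mean_parameters(), data)
    return DICResult(Dbar=float(devs.mean()), Dhat=float(dhat))
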