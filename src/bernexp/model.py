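"""Core data structures and the joint Bernoulli-Exponential log-likelihood.

The model couples a binary longitudinal outcome process with an informative
visit-time process.  For subject ``i`` with subject-level covariates ``x_i``
(first entry the intercept constant 1) and visits ``k = 1..n_i``:

* the first outcome follows ``y_i1 ~ Bernoulli(mu_i1)`` with
  ``logit(mu_i1) = x_i' alpha``;
* later outcomes follow ``y_ik ~ Bernoulli(mu_ik)`` with
  ``logit(mu_ik) = x_i' alpha + vartheta * t_ik + psi * y_{i,k-1}``, where
  ``t_ik > 0`` is the gap time since the previous visit;
* later gap times follow ``t_ik ~ Exponential(rate = exp(xi + gamma * y_{i,k-1}))``,
  so the visit intensity depends on the previous outcome (the "informative
  time" mechanism).

The likelihood contains no density for the first gap time ``t_i1``: the first
visit contributes only its Bernoulli term.  Gap times are increments since the
previous visit, never cumulative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectRecord",
    "PanelDataset",
    "ModelParameters",
    "linear_predictor",
    "mean_response",
    "visit_rate",
    "log_likelihood",
    "deviance",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: covariate vector and ordered (gap time, outcome) visits."""

    subject_id: object
    x: np.ndarray
    visits: tuple  # tuple of (t, y) pairs, k = 1..n_i

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or not np.all(np.isfinite(x)):
            raise ValueError(f"subject {self.subject_id}: covariate vector must be 1-D and finite")
        visits = tuple((float(t), int(y)) for t, y in self.visits)
        if len(visits) < 1:
            raise ValueError(f"subject {self.subject_id}: needs at least one visit")
        for k, (t, y) in enumerate(visits, start=1):
            if not (t > 0 and np.isfinite(t)):
                raise ValueError(f"subject {self.subject_id}, visit {k}: gap time must be > 0, got {t}")
            if y not in (0, 1):
                raise ValueError(f"subject {self.subject_id}, visit {k}: outcome must be 0/1, got {y}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "visits", visits)

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class PanelDataset:
    """Validated panel of subjects.

    ``p`` is the number of covariate columns including the intercept column.
    ``tau`` is an optional upper validation bound for gap times (the follow-up
    horizon); the exponential density itself is never truncated.
    """

    subjects: tuple
    p: int = field(init=False)
    tau: float = np.inf

    def __init__(self, subjects: Sequence[SubjectRecord], tau: float = np.inf):
        subjects = tuple(subjects)
        if not subjects:
            raise ValueError("dataset needs at least one subject")
        p = subjects[0].x.size
        for s in subjects:
            if s.x.size != p:
                raise ValueError(
                    f"covariate length mismatch: subject {s.subject_id} has {s.x.size}, expected {p}"
                )
            for k, (t, _) in enumerate(s.visits, start=1):
                if t > tau:
                    raise ValueError(
                        f"subject {s.subject_id}, visit {k}: gap time {t} exceeds tau={tau}"
                    )
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "tau", float(tau))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_visits for s in self.subjects)

    def design_matrix(self) -> np.ndarray:
        """Subject-level design matrix X (n_subjects x p)."""
        return np.vstack([s.x for s in self.subjects])


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector Theta = (alpha, psi, vartheta, xi, gamma).

    alpha    -- covariate effects on the outcome logit (length p)
    psi      -- effect of the lagged outcome on the current logit
    vartheta -- effect of the current gap time on the logit
    xi       -- log baseline visit rate
    gamma    -- effect of the lagged outcome on the log visit rate
    """

    alpha: np.ndarray
    psi: float
    vartheta: float
    xi: float
    gamma: float

    def __post_init__(self):
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        scalars = (self.psi, self.vartheta, self.xi, self.gamma)
        if not (np.all(np.isfinite(alpha)) and all(np.isfinite(v) for v in scalars)):
            raise ValueError("all model parameters must be finite")
        object.__setattr__(self, "alpha", alpha)
        for name in ("psi", "vartheta", "xi", "gamma"):
            object.__setattr__(self, name, float(getattr(self, name)))

    @property
    def p(self) -> int:
        return self.alpha.size

    def to_vector(self) -> np.ndarray:
        """Concatenate in the canonical order alpha_1..alpha_p, psi, vartheta, xi, gamma."""
        return np.concatenate([self.alpha, [self.psi, self.vartheta, self.xi, self.gamma]])

    @classmethod
    def from_vector(cls, vec: np.ndarray, p: int) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.size != p + 4:
            raise ValueError(f"expected vector of length {p + 4}, got {vec.size}")
        return cls(alpha=vec[:p], psi=vec[p], vartheta=vec[p + 1], xi=vec[p + 2], gamma=vec[p + 3])

    @staticmethod
    def names(p: int) -> list:
        return [f"alpha_{j}" for j in range(1, p + 1)] + ["psi", "vartheta", "xi", "gamma"]


def linear_predictor(params: ModelParameters, x, t=None, y_prev=None) -> float:
    """Outcome-logit linear predictor.

    First visit (``y_prev is None``): ``alpha . x``.
    Later visits: ``alpha . x + vartheta * t + psi * y_prev``.
    """
    x = np.asarray(x, dtype=float)
    if x.size != params.alpha.size:
        raise ValueError(
            f"covariate length {x.size} does not match alpha length {params.alpha.size}"
        )
    eta = float(params.alpha @ x)
    if y_prev is None:
        return eta
    if t is None or not t > 0:
        raise ValueError(f"gap time must be > 0 for non-first visits, got {t}")
    return eta + params.vartheta * float(t) + params.psi * float(y_prev)


def _logistic(eta: float) -> float:
    # overflow-safe: never forms exp(eta) for large positive eta
    if eta >= 0:
        return 1.0 / (1.0 + np.exp(-eta))
    z = np.exp(eta)
    return z / (1.0 + z)


def mean_response(params: ModelParameters, x, t=None, y_prev=None) -> float:
    """Bernoulli mean mu = logistic(linear predictor), strictly inside (0, 1)."""
    mu = _logistic(linear_predictor(params, x, t, y_prev))
    tiny = np.finfo(float).tiny
    return float(min(max(mu, tiny), 1.0 - np.finfo(float).epsneg))


def visit_rate(params: ModelParameters, y_prev) -> float:
    """Exponential visit rate exp(xi + gamma * y_prev) for a k >= 2 gap."""
    if y_prev not in (0, 1):
        raise ValueError(f"y_prev must be 0 or 1, got {y_prev}")
    return float(np.exp(params.xi + params.gamma * float(y_prev)))


def _bernoulli_logterms(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)) computed in log space
    return y * eta - np.logaddexp(0.0, eta)


def log_likelihood(params: ModelParameters, data: PanelDataset) -> float:
    """Joint log-likelihood of the Bernoulli-Exponential model.

    Sum over subjects of the first-visit Bernoulli term plus, for k >= 2,
    the Bernoulli term and the exponential gap-time log-density
    ``(xi + gamma*y_prev) - exp(xi + gamma*y_prev) * t``.  The first gap time
    carries no density term.  Bernoulli terms use log1p-style evaluation, so
    the result is finite for any finite parameters.
    """
    if data.p != params.p:
        raise ValueError(f"data has p={data.p} covariates but alpha has length {params.p}")
    state = LikelihoodState(data)
    return state.bernoulli_loglik(params.alpha, params.psi, params.vartheta) + state.exponential_loglik(
        params.xi, params.gamma
    )


def deviance(params: ModelParameters, data: PanelDataset) -> float:
    """Model deviance, -2 * log_likelihood."""
    return -2.0 * log_likelihood(params, data)


class LikelihoodState:
    """Flattened visit-level arrays for fast repeated likelihood evaluation.

    Rows are grouped by subject in dataset order.  Per-subject partial sums
    are accumulated and then summed in sorted order, which makes the total
    exactly invariant under relabelling/permutation of subjects.
    """

    def __init__(self, data: PanelDataset):
        rows_x, rows_t, rows_y, rows_prev, first = [], [], [], [], []
        bounds = [0]
        for s in data.subjects:
            prev = 0.0
            for k, (t, y) in enumerate(s.visits, start=1):
                rows_x.append(s.x)
                rows_t.append(t)
                rows_y.append(float(y))
                rows_prev.append(prev if k > 1 else 0.0)
                first.append(k == 1)
                prev = float(y)
            bounds.append(bounds[-1] + s.n_visits)
        self.X = np.vstack(rows_x)
        self.t = np.asarray(rows_t)
        self.y = np.asarray(rows_y)
        self.y_prev = np.asarray(rows_prev)
        self.is_first = np.asarray(first, dtype=bool)
        # effective regressors: zero at first visits so a single vectorised
        # expression covers both mean structures
        self.t_eff = np.where(self.is_first, 0.0, self.t)
        self.yprev_eff = np.where(self.is_first, 0.0, self.y_prev)
        self._starts = np.asarray(bounds[:-1], dtype=np.intp)
        self.n_gap = int((~self.is_first).sum())
        self.p = data.p

    def _subject_sum(self, terms: np.ndarray) -> float:
        partial = np.add.reduceat(terms, self._starts)
        partial.sort()
        return float(partial.sum())

    def eta(self, alpha, psi, vartheta, xalpha=None) -> np.ndarray:
        if xalpha is None:
            xalpha = self.X @ alpha
        return xalpha + vartheta * self.t_eff + psi * self.yprev_eff

    def bernoulli_loglik(self, alpha, psi, vartheta, xalpha=None) -> float:
        eta = self.eta(alpha, psi, vartheta, xalpha)
        return self._subject_sum(_bernoulli_logterms(eta, self.y))

    def exponential_loglik(self, xi, gamma) -> float:
        log_rate = xi + gamma * self.y_prev
        terms = np.where(self.is_first, 0.0, log_rate - np.exp(log_rate) * self.t)
        return self._subject_sum(terms)

    def weights(self, alpha, psi, vartheta, xalpha=None) -> np.ndarray:
        """Per-row Bernoulli variance weights w = mu(1 - mu)."""
        eta = self.eta(alpha, psi, vartheta, xalpha)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        return mu * (1.0 - mu)
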