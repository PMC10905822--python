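import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from bernexp import ModelParameters, PanelDataset, SubjectRecord


def oracle_log_likelihood(params: ModelParameters, data: PanelDataset) -> float:
    """Independent per-term density sum: Bernoulli pmf for every visit plus
    the exponential gap density for visits k >= 2, via scipy distributions."""
    ll = 0.0
    for s in data.subjects:
        y_prev = None
        for k, (t, y) in enumerate(s.visits, start=1):
            if k == 1:
                mu = expit(s.x @ params.alpha)
            else:
                mu = expit(s.x @ params.alpha + params.vartheta * t + params.psi * y_prev)
                rate = np.exp(params.xi + params.gamma * y_prev)
                ll += stats.expon.logpdf(t, scale=1.0 / rate)
            ll += stats.bernoulli.logpmf(y, mu)
            y_prev = y
    return float(ll)


def random_tiny_panel(rng: np.random.Generator, p: int = 3, max_subjects: int = 3,
                      max_visits: int = 4) -> PanelDataset:
    subjects = []
    for i in range(rng.integers(1, max_subjects + 1)):
        x = np.concatenate([[1.0], rng.normal(size=p - 1)])
        visits = [
            (float(rng.exponential(1.0) + 1e-3), int(rng.integers(0, 2)))
            for _ in range(rng.integers(1, max_visits + 1))
        ]
        subjects.append(SubjectRecord(subject_id=i, x=x, visits=visits))
    return PanelDataset(subjects)


def random_params(rng: np.random.Generator, p: int = 3) -> ModelParameters:
    return ModelParameters(
        alpha=rng.normal(scale=0.5, size=p),
        psi=rng.normal(scale=0.5),
        vartheta=rng.normal(scale=0.3),
        xi=rng.normal(scale=0.3),
        gamma=rng.normal(scale=0.3),
    )


def synthetic_bladder_table(seed: int = 0, n_placebo: int = 38, n_thiotepa: int = 47,
                            n_visits: int = 4):
    """Synthetic recurrence table shaped like the standard bladder-tumour
    panel (id, rx, number, size, stop, enum, event), drawn from the joint
    model at a plausible truth with a negative lagged-outcome effect.  This
    is a stand-in generated from the model itself, not the real trial data.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    truth = ModelParameters(alpha=[0.2, 0.2, 0.04, 0.05], psi=-0.4, vartheta=0.15,
                            xi=-0.3, gamma=0.05)
    rows = []
    arms = [1] * n_placebo + [2] * n_thiotepa
    for sid, rx in enumerate(arms, start=1):
        number = int(rng.integers(1, 9))
        size = int(rng.integers(1, 8))
        x = np.array([1.0, rx, number, size])
        y_prev = None
        for enum in range(1, n_visits + 1):
            rate = np.exp(truth.xi + (truth.gamma * y_prev if enum > 1 else 0.0))
            t = float(rng.exponential(1.0 / rate))
            eta = x @ truth.alpha + ((truth.vartheta * t + truth.psi * y_prev) if enum > 1 else 0.0)
            y = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            rows.append(dict(id=sid, rx=rx, number=number, size=size,
                             stop=round(t, 3) or 0.001, enum=enum, event=y))
            y_prev = y
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel() -> PanelDataset:
    """Two hand-built subjects: n_1 = 2 visits, n_2 = 1 visit, p = 2."""
    return PanelDataset(
        [
            SubjectRecord(subject_id="a", x=[1.0, 0.5], visits=[(1.2, 1), (0.7, 0)]),
            SubjectRecord(subject_id="b", x=[1.0, -1.0], visits=[(2.5, 1)]),
        ]
    )


@pytest.fixture
def tiny_params() -> ModelParameters:
    return ModelParameters(alpha=[0.3, -0.2], psi=0.4, vartheta=0.1, xi=-0.2, gamma=0.3)
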