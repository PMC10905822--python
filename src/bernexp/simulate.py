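"""Panel-data generator and the sample-size x visit-pattern x prior study.

The generator emulates a longitudinal trial with informative visit times:
subject-level covariates are an intercept, two uniformly distributed 3-level
factors (dummy coded against a reference level) and two standard-normal
continuous covariates, giving 7 design columns.  Outcomes and gap times are
drawn sequentially per subject from the joint Bernoulli-Exponential model:
the first gap time from Exponential(exp(xi)) -- there is no lagged outcome
yet -- and later gaps from Exponential(exp(xi + gamma * y_prev)).  The fitted
likelihood ignores the first gap time, so the generator is slightly richer
than the fitter; this mismatch is deliberate and documented.

The study grid crosses sample sizes {18, 54, 180} with visit patterns
balanced(10), unbalanced(5 & 3) and unbalanced(20 & 6) (half the subjects,
by index, take the first count) and the three prior schemes, 27 cells in
total.

The default ground truth is alpha = (0.4, 0.2, 0.3, 0.1, 0.3, 0.4, 0.9),
psi = 0.8, vartheta = 0.12, xi = 0.01, and gamma = 0.4; gamma's published
value is ambiguous, so it is explicitly configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelParameters, PanelDataset, SubjectRecord, mean_response
from .mcmc import MCMCConfig, compute_dic, posterior_summary, run_mcmc
from .diagnostics import hw_report
from .priors import preset_scheme

__all__ = [
    "DesignScheme",
    "GeneratingParameters",
    "PATTERNS",
    "make_design",
    "generate_covariates",
    "simulate_panel",
    "run_study",
    "default_truth",
]

# canonical visit patterns: name -> per-half visit counts (balanced patterns
# repeat one count for everyone)
PATTERNS = {
    "10": (10,),
    "5&3": (5, 3),
    "20&6": (20, 6),
}


@dataclass(frozen=True)
class DesignScheme:
    """One (sample size, visit pattern) cell of the simulation matrix."""

    sample_size: int
    pattern: str
    visit_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        key = _normalise_pattern(self.pattern)
        counts = PATTERNS[key]
        n = self.sample_size
        if n < 1:
            raise ValueError("sample_size must be >= 1")
        if len(counts) == 1:
            per = np.full(n, counts[0], dtype=int)
        else:
            if n % 2:
                raise ValueError(
                    f"unbalanced pattern {key!r} requires an even sample size, got {n}"
                )
            per = np.concatenate([np.full(n // 2, counts[0]), np.full(n // 2, counts[1])])
        object.__setattr__(self, "pattern", key)
        object.__setattr__(self, "visit_counts", per)

    @property
    def total_observations(self) -> int:
        return int(self.visit_counts.sum())


def _normalise_pattern(pattern) -> str:
    if isinstance(pattern, (tuple, list)):
        key = "&".join(str(int(c)) for c in pattern)
    else:
        key = str(pattern).replace("x", "&").replace(" ", "")
    if key not in PATTERNS:
        raise ValueError(f"unknown visit pattern {pattern!r}; valid: {sorted(PATTERNS)}")
    return key


def make_design(sample_size: int, pattern) -> DesignScheme:
    """Build a design cell; totals follow the closed form sum of visit counts."""
    return DesignScheme(sample_size=int(sample_size), pattern=pattern)


@dataclass(frozen=True)
class GeneratingParameters:
    """Ground-truth parameters plus covariate-generation settings.

    ``n_levels`` fixes the two categorical factors at three levels each
    (2 dummies apiece) and there are two continuous covariates, so alpha has
    length 7 = 1 + 2 + 2 + 2.
    """

    params: ModelParameters
    n_levels: int = 3
    n_continuous: int = 2

    def __post_init__(self):
        expected = 1 + 2 * (self.n_levels - 1) + self.n_continuous
        if self.params.p != expected:
            raise ValueError(
                f"alpha length {self.params.p} does not match the covariate design ({expected})"
            )


def default_truth(gamma: float = 0.4) -> GeneratingParameters:
    """Canonical simulation truth; gamma is configurable (its published value
    is ambiguous)."""
    return GeneratingParameters(
        params=ModelParameters(
            alpha=np.array([0.4, 0.2, 0.3, 0.1, 0.3, 0.4, 0.9]),
            psi=0.8,
            vartheta=0.12,
            xi=0.01,
            gamma=gamma,
        )
    )


def generate_covariates(sample_size: int, seed) -> np.ndarray:
    """Covariate matrix: intercept, 2x dummy-coded 3-level factors, 2 normals.

    ``seed`` may be an int or a numpy Generator.  Factor levels are uniform
    over {0, 1, 2} with level 0 the dropped reference.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.empty((sample_size, 7))
    X[:, 0] = 1.0
    for block in (1, 3):
        levels = rng.integers(0, 3, size=sample_size)
        X[:, block] = levels == 1
        X[:, block + 1] = levels == 2
    X[:, 5:7] = rng.standard_normal((sample_size, 2))
    return X


def simulate_panel(design: DesignScheme, truth: GeneratingParameters, seed) -> PanelDataset:
    """Draw one panel dataset from the joint model at the given truth.

    Per subject: t_1 ~ Exp(exp(xi)); y_1 ~ Bernoulli(logistic(x'alpha));
    for k >= 2: t_k ~ Exp(exp(xi + gamma*y_{k-1})),
    y_k ~ Bernoulli(logistic(x'alpha + vartheta*t_k + psi*y_{k-1})).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = generate_covariates(design.sample_size, rng)
    pars = truth.params
    subjects = []
    for i in range(design.sample_size):
        x = X[i]
        visits = []
        y_prev = None
        for k in range(1, int(design.visit_counts[i]) + 1):
            rate = np.exp(pars.xi + (pars.gamma * y_prev if k > 1 else 0.0))
            t = rng.exponential(1.0 / rate)
            mu = mean_response(pars, x, None if k == 1 else t, y_prev if k > 1 else None)
            y = int(rng.random() < mu)
            visits.append((t, y))
            y_prev = y
        subjects.append(SubjectRecord(subject_id=i + 1, x=x, visits=visits))
    return PanelDataset(subjects)


def run_study(
    designs,
    priors,
    truth: GeneratingParameters,
    n_replicates: int,
    mcmc: MCMCConfig,
    seed: int,
) -> pd.DataFrame:
    """Simulate-fit-summarise over a grid of design cells and prior presets.

    For each (design, prior) cell and replicate the panel is simulated, the
    model fitted, posterior summaries, Heidelberger-Welch verdicts and DIC
    computed.  The returned tidy table contains one row per replicate and
    parameter plus aggregate rows (``replicate == "aggregate"``) holding the
    averages over replicates, the convention used for reported estimates.
    Replicates that fail to initialise are recorded and skipped.

    ``priors`` is an iterable of preset names ("informative",
    "noninformative", "jeffreys").  Each replicate draws fresh data from a
    child seed, so the whole table is a deterministic function of ``seed``.
    """
    priors = list(priors)
    root = np.random.SeedSequence(seed)
    rows = []
    for design in designs:
        for prior_name in priors:
            scheme = preset_scheme(prior_name, 7)
            cell_seeds = np.random.SeedSequence(
                entropy=root.entropy,
                spawn_key=(design.sample_size, PATTERNS_INDEX[design.pattern],
                           priors.index(prior_name)),
            ).generate_state(n_replicates)
            n_failed = 0
            for rep in range(n_replicates):
                rep_seed = int(cell_seeds[rep] % (2**31 - 1))
                panel = simulate_panel(design, truth, np.random.default_rng(rep_seed))
                cfg = replace(mcmc, seed=rep_seed)
                try:
                    draws = run_mcmc(panel, scheme, cfg)
                except ValueError:
                    n_failed += 1
                    continue
                summ = posterior_summary(draws)
                hw = hw_report(draws).set_index("Parameter")
                dic = compute_dic(draws, panel)
                for name in draws.names:
                    rows.append(
                        {
                            "sample_size": design.sample_size,
                            "pattern": design.pattern,
                            "prior": prior_name,
                            "replicate": rep,
                            "parameter": name,
                            "mean": summ.loc[name, "Mean"],
                            "sd": summ.loc[name, "SD"],
                            "lower": summ.loc[name, "Lower(2.50%)"],
                            "upper": summ.loc[name, "Upper(97.50%)"],
                            "ci_width": summ.loc[name, "Upper(97.50%)"] - summ.loc[name, "Lower(2.50%)"],
                            "hw_stationarity": hw.loc[name, "Stationarity Test"],
                            "hw_halfwidth": hw.loc[name, "Halfwidth Test"],
                            "DIC": dic.DIC,
                            "pD": dic.pD,
                            "n_failed": n_failed,
                        }
                    )
            rows.extend(_aggregate_cell(rows, design, prior_name, n_failed))
    return pd.DataFrame(rows)


PATTERNS_INDEX = {k: i for i, k in enumerate(PATTERNS)}


def _aggregate_cell(rows, design, prior_name, n_failed):
    cell = [
        r for r in rows
        if r["sample_size"] == design.sample_size
        and r["pattern"] == design.pattern
        and r["prior"] == prior_name
        and r["replicate"] != "aggregate"
    ]
    if not cell:
        return []
    frame = pd.DataFrame(cell)
    agg_rows = []
    for name, grp in frame.groupby("parameter", sort=False):
        agg_rows.append(
            {
                "sample_size": design.sample_size,
                "pattern": design.pattern,
                "prior": prior_name,
                "replicate": "aggregate",
                "parameter": name,
                "mean": grp["mean"].mean(),
                "sd": grp["sd"].mean(),
                "lower": grp["lower"].mean(),
                "upper": grp["upper"].mean(),
                "ci_width": grp["ci_width"].mean(),
                "hw_stationarity": "passed" if (grp["hw_stationarity"] == "passed").all() else "failed",
                "hw_halfwidth": "passed" if (grp["hw_halfwidth"] == "passed").all() else "failed",
                "DIC": grp["DIC"].mean(),
                "pD": grp["pD"].mean(),
                "n_failed": n_failed,
            }
        )
    return agg_rows
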