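# bernexp

A Bayesian joint model for **binary longitudinal outcomes with informative
visit times**, aimed at panel studies — such as recurrent-tumour follow-up —
where *when* a subject is seen carries information about *what* was seen
last time.

Standard longitudinal models assume visit schedules fixed by design. In many
clinical settings the next visit is moved up or pushed back depending on the
previous outcome, so the visit process and the outcome process must be
modelled jointly. `bernexp` implements a Bernoulli–Exponential joint model:
for subject *i* with subject-level covariates *xᵢ* and visits *k = 1..nᵢ*,

```
logit(μ_i1) = xᵢ'α                                   y_i1 ~ Bernoulli(μ_i1)
logit(μ_ik) = xᵢ'α + ϑ t_ik + ψ y_ik−1               y_ik ~ Bernoulli(μ_ik)
t_ik ~ Exponential( exp(ξ + γ y_ik−1) ),  k ≥ 2
```

where `t_ik` is the gap time since the previous visit, `ψ` the carry-over
effect of the previous outcome, `ϑ` the effect of the current gap, and `γ`
ties the visit intensity to the previous outcome — the "informative time"
mechanism. Inference is Bayesian: Gaussian informative, Gaussian vague or
Jeffreys-reference priors (the latter proportional to
`|X'WX|^{1/2}` with `W = diag(μ(1−μ))`), a Metropolis-within-Gibbs sampler,
equal-tailed credible intervals, Heidelberger–Welch convergence tests, and
model comparison by DIC.

## Worked example

```python
import bernexp as bx

design = bx.make_design(54, "5&3")            # 54 subjects, half 5 visits, half 3
panel  = bx.simulate_panel(design, bx.default_truth(), seed=1)
scheme = bx.preset_scheme("jeffreys", panel.p)
draws  = bx.run_mcmc(panel, scheme, bx.MCMCConfig(n_iter=30000, burn_in=10000,
                                                  thin=3, seed=1))
print(bx.posterior_summary(draws).round(3))
print(bx.compute_dic(draws, panel).to_dict())
```

prints (seed 1):

```
           Mean     SD  Lower(2.50%)  Upper(97.50%)
alpha_1   0.534  0.399        -0.240          1.329
alpha_2   0.220  0.453        -0.668          1.112
alpha_3   0.410  0.409        -0.391          1.215
alpha_4   0.308  0.465        -0.604          1.225
alpha_5   0.389  0.467        -0.515          1.325
alpha_6   0.634  0.215         0.223          1.064
alpha_7   0.821  0.211         0.418          1.251
psi       0.277  0.344        -0.376          0.946
vartheta  0.246  0.260        -0.256          0.771
xi        0.052  0.149        -0.241          0.342
gamma     0.391  0.174         0.051          0.726
{'Dbar': 447.73, 'Dhat': 436.88, 'pD': 10.85, 'DIC': 458.57}
```

The posterior means sit near the generating truth
(α = 0.4, 0.2, 0.3, 0.1, 0.3, 0.4, 0.9; ψ = 0.8; ϑ = 0.12; ξ = 0.01;
γ = 0.4) given only 216 observations — the continuous-covariate effects
α₆, α₇ and the visit-intensity effect γ are credibly positive — and
`pD ≈ 11` matches the eleven free parameters. DIC is reported so fits under
different priors can be ranked (smaller is better).

A `bernexp` command-line tool wraps the same pipeline:

```sh
bernexp simulate --n 18 --pattern 5x3 --seed 1 --out out/sim
bernexp fit --input out/sim/panel.csv --prior jeffreys --seed 1 --out out/fit
bernexp diagnose --input out/fit/draws.csv --out out/diag
bernexp study --config study.yaml --seed 1 --out out/study
bernexp bladder --input bladder.csv --seed 1 --out out/app
```

The `bladder` subcommand consumes recurrence tables in the standard
bladder-tumour layout (`id, rx, number, size, stop, enum, event`), fits all
three prior scenarios and selects the one with the smallest DIC. The real
trial data ships with the standard survival-analysis distributions and is
not bundled here.

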