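# effortdm

Simulation, hierarchical Bayesian modelling and downstream statistics for
an adaptive **effort-expenditure decision task**, built for computational
psychiatry research on motivation: how apathy, anhedonia, depression and
circadian phenotype relate to the willingness to exert physical effort
for reward.

The package is a complete, self-contained pipeline over synthetic agents —
no participant data are required — and is aimed at researchers who want to
prototype, power, validate or extend effort-discounting analyses:
task-design simulation, model comparison, parameter recovery, reliability
studies, and covariate-linkage statistics.

## The task and the models

Participants (here: simulated agents) face 64 accept/reject offers, each
pairing an effort level *E* ∈ {1..4} (clicking at 30–90% of an
individually calibrated capacity for 8–17 s) with a reward *R* ∈ {2..5}
points. Sixteen interleaved staircases — one starting from each cell of
the 4×4 effort × reward grid — adapt offers toward harder challenges
after acceptance and easier ones after rejection; rejected offers always
pay 1 point.

Choice is modelled by subjective-value softmax models. With standardized
effort e = E/4 and reward r = R/5:

    SV(e, r) = β_R · r − cost_βE(e)
    p(accept) = 1 / (1 + exp(−(α + SV)))

where cost is linear (β_E·e), parabolic (β_E·e²) or exponential
(β_E·(eᵉ − 1)); α is the acceptance bias, β_R / β_E reward and effort
sensitivity. Crossing three costs with three parameter configurations
({β_E}, {β_E, β_R}, {α, β_R, β_E}) gives the nine-model space; the
three-parameter parabolic model (`full_parabolic`) is the reference
winner. Models are fit to multi-subject trial logs with a non-centered
hierarchical Bayesian model (adaptive HMC with analytic gradients),
compared by PSIS-LOO (ELPD / LOOIC = −2·ELPD), and validated by posterior
predictive checks and parameter recovery. The statistics layer adds
compliance exclusions, effort × reward F tests, PLS regression with
permutation testing, Gibbs-sampled Bayesian GLMs with an HDI-width
stopping rule, chronotype phenotyping (MEQ + free-day mid-sleep), and
test–retest reliability (ICC and cross-session predictive accuracy).

See `docs/methods.md` for model details, priors, calibration of the
synthetic cohorts, and known limitations.

## Worked example

Simulate a cohort under the default study conditions, fit two competing
models, and compare them:

```python
import numpy as np
from effortdm import inference as inf
from effortdm import synthetic_data as sd

agents, covariates = sd.generate_population(
    sd.paper_like_config(n_subjects=40, seed=3))
trials = sd.generate_sessions(agents, model="full_parabolic", seed=4)

cfg = inf.MCMCConfig(warmup=500, sampling=500, chains=4, seed=7,
                     target_accept=0.85, on_bad_convergence="warn")
fit = inf.fit_hierarchical(trials, "full_parabolic", cfg)
print("max split R-hat:", round(fit.diagnostics["rhat_max"], 3))

means = fit.subject_means()
truth = covariates.set_index("subject_id")
for p in ("alpha", "beta_R", "beta_E"):
    r = np.corrcoef(truth["true_" + p], means[p])[0, 1]
    print(f"{p}: recovery r = {r:.2f}")
```

prints (exact values depend on the seeds):

```
max split R-hat: 1.025
alpha: recovery r = 0.78
beta_R: recovery r = 0.37
beta_E: recovery r = 0.60
```

i.e. the fit converges and posterior means track the generating
parameters — tightly for the acceptance bias α, more loosely for the
reward sensitivity β_R, whose four-level reward range makes it the
hardest parameter to pin down (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
effortdm pipeline --preset paper-like --n-subjects 60 --seed 1 \
    --models full_parabolic,full_linear,full_exponential --out report/
```

which writes trial logs, exclusion reports, per-subject posterior
summaries, the LOO comparison table, posterior-predictive tables and
covariate analyses into `report/`, all reproducible byte-for-byte from
the seed. Subcommands `synth`, `simulate`, `exclude`, `fit`, `compare`,
`ppc`, `recover` and `analyze` expose the individual stages.

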