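# rxmsm

Refill-based drug-exposure reconstruction and marginal structural Cox
models for pharmacoepidemiology, with a synthetic-cohort generator that
carries known ground-truth effects.

## The problem

Observational cohorts built from electronic medical records — for example a
registry of people living with HIV followed after virologic suppression —
record *pharmacy refills*, not drug intake. Estimating the effect of
preventive cardiovascular medication (lipid-lowering therapy,
antihypertensives, aspirin) on mortality from such data requires

1. turning fills, days-supply and hospital stays into day-level coverage
   calendars and a trailing one-year **percent of days covered** (PDC);
2. binning coverage into mutually exclusive, weekly-updated exposure
   levels — *consistent* (use in ≥ 11 of 12 trailing months **and**
   PDC > 0.91), *recent inconsistent*, *remote* (prior use, none in the
   last year), and *never* (reference);
3. removing indication bias (sicker patients are prescribed more) with
   **stabilized, asymmetrically truncated inverse-probability-of-treatment
   weights** and an inverse-probability-of-censoring weight for informative
   loss to follow-up (care gaps > 13 months);
4. fitting a weighted multi-level Cox model on counting-process
   person-periods with cluster-robust (sandwich) variance — a **marginal
   structural model** (MSM), which unlike ever-user/baseline designs is not
   subject to immortal-time bias.

For class group *g* with exposure level *A_g(t)* and covariate history
*L*, each person-period gets the weight

```
w(t) = Π_g  [ P(A_g(t)=a) / P(A_g(t)=a | L) ]_trunc(5%,95%)  ×  w_cens(t)
```

and the weighted partial likelihood estimates hazard ratios
HR(level vs never) for the three class groups simultaneously.

Because no registry data can ship with the package, a first-class
synthetic-cohort module simulates refill-driven coverage, confounding by
indication (a latent frailty score drives both prescribing and death, and
is emitted as a measured lab covariate), adherence clustering,
suppression-based entry, care-gap censoring and competing explanatory
endpoints — with configurable true hazard ratios, so every pipeline stage
is testable against known truth.

## Worked example

```python
import numpy as np
from rxmsm import SimulationConfig, simulate_cohort, run_pipeline
from rxmsm.config import PipelineConfig

sim = SimulationConfig(n_patients=2000, seed=7,
                       true_log_hr={("llt", "consistent"): np.log(0.5)})
cohort = simulate_cohort(sim)                      # six delimited tables
res = run_pipeline(cohort.tables, sim.horizon_days, PipelineConfig(),
                   endpoints=["death"], fit_unweighted=True, screen=False)
print(res.results["death"].estimates.loc["llt:consistent",
                                         ["hr", "ci_low", "ci_high"]])
print(res.results_unweighted["death"].estimates.loc["llt:consistent", "hr"])
```

prints (seed 7):

```
hr         0.662321
ci_low     0.315621
ci_high    1.389864
Name: llt:consistent, dtype: float64
0.9122717699419542
```

The weighted hazard ratio for consistent lipid-lowering therapy (0.66, CI
0.32–1.39) covers the simulated truth of 0.50 — a single replicate at
n = 2000 is noisy; averaged over replicates the weighted estimator is
unbiased (see `scripts/acceptance.py`) — while the unweighted estimate
(0.91) is pulled far toward harm because frail patients are preferentially
treated. `res.weight_summary` shows per-level stabilized
weight means (all within 0.9–1.1 on a correctly specified run) and
`res.balance` the absolute standardized differences before/after weighting.

A thin CLI mirrors the library: `rxmsm simulate`, `rxmsm exposure`,
`rxmsm fit`, `rxmsm report` (see `rxmsm --help`).

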