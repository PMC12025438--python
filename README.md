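# seqcea

Cost-effectiveness analysis of advanced prostate-cancer treatment
**sequences** — a semi-Markov microsimulation pipeline for health
economists and methodologists comparing androgen receptor pathway
inhibitor (ARPI) timing strategies from published trial survival curves.

Advanced prostate cancer runs from castration-sensitive disease
(nonmetastatic nmCSPC; metastatic mCSPC, split into low- and high-risk)
through castration-resistant disease (nmCRPC; two mCRPC treatment lines)
to a terminal progressed state and death. Guidelines admit many treatment
sequences over these states — ADT alone, ARPIs (abiraterone, apalutamide,
darolutamide, enzalutamide), chemotherapy (docetaxel, cabazitaxel) and
combinations — but exclude ARPI rechallenge. `seqcea` enumerates the
admissible sequences, estimates transition parameters from trial
Kaplan-Meier curves, microsimulates cohorts, and ranks sequences by net
health benefit.

## The model

For each treatment-state pair, monthly transition probabilities follow a
flexible functional form in the time `t` (months) spent in the state:

    P(s → p) = α (1 + β)^(t−1)      progression
    P(s → d) = γ                     death before progression
    P(p → d) = δ                     death after progression

Population-level survival implied by (α, β, γ, δ) follows the recursion
`u(t) = u(t−1)(1 − P(s→p)(t) − γ)`, `v(t) = v(t−1)(1 − δ) + u(t−1)P(s→p)(t)`
with PFS(t) = u(t) and OS(t) = u(t) + v(t). Because published curves only
partially identify the four parameters, they are estimated by a **grid
search** minimising the mean-squared error of the implied PFS/OS curves
against the empirical ones (with a coarse-to-fine refinement pass), and
benchmarked against Weibull and Lognormal fits. Digitized curves are
converted to patient-level data with the Guyot reconstruction algorithm.

Cohorts of identical patients are simulated in 1-month cycles over a
15-year horizon (defaults: 200,000 patients, 1.5%/year discounting),
accruing life-years, quality-adjusted life-years (state utilities minus
treatment disutilities) and Canadian public-payer costs (drug, monitoring,
end-of-life care; intermittent nmCSPC therapy with beta-distributed
suspension phases). Sequences are compared by net health benefit

    NHB = Benefit − Cost / CET

at cost-effectiveness thresholds (CET) such as CAD 50K and 100K per QALY,
with bootstrap acceptability curves over ARPI-timing groups (early / late /
none) and payer, price and horizon sensitivity scenarios.

## Worked example

Fit parameters from a (here: synthetic) trial, then simulate and rank all
20 admissible low-risk-mCSPC-starting sequences:

```python
import numpy as np
from seqcea import *

# 1. fit transition parameters from a trial's PFS/OS curves
truth = TransitionParams(alpha=0.083, beta=0.013, gamma=0.021, delta=0.046)
trial = generate_trial(SyntheticTrialSpec(truth=truth, n_patients=20_000,
                                          follow_up=60, seed=7))
fit = grid_search_fit((trial.pfs, trial.os))
print(fit.params, fit.mse)

# 2. simulate every admissible sequence and rank by NHB at CAD 100K/QALY
catalogue = default_catalogue()
params = generate_param_catalogue(seed=1)   # or trial-fitted parameters
cfg = SimulationConfig(n_patients=20_000, horizon=180, seed=11)
rows = []
for seq in enumerate_sequences(catalogue, HealthState.mCSPC_low):
    res = simulate_cohort(seq, params, cfg)
    rows.append({"label": seq.label, "benefit": res.mean_qaly,
                 "cost": res.mean_cost,
                 "arpi_use": classify_arpi_use(seq, catalogue)})
ranked = rank_sequences(rows, cet=100_000, reference_label="(adt, doce)")
print(ranked.head(5).round(2))
```

This prints the recovered parameters — `(α=0.082, β=0.014, γ=0.0215,
δ=0.0455)`, within one refined grid step of the truth, MSE `1.7e-06` —
and the ranking table:

```
 rank                 label arpi_use  benefit     cost  nhb  incremental_nhb
    1 (adt, doce then enza)     late     3.07 97308.07 2.09             0.77
    2 (abi, doce then caba)    early     2.42 51902.26 1.90             0.58
    3           (abi, doce)    early     2.19 42703.57 1.76             0.44
    4            (adt, abi)     late     2.00 29874.28 1.70             0.38
    5  (adt, doce then abi)     late     1.95 25074.23 1.70             0.37
```

`benefit` is mean discounted QALYs per patient, `cost` mean discounted CAD,
`nhb` the net health benefit at the chosen CET, and `incremental_nhb` the
gain over the no-ARPI reference `(adt, doce)`. (Numbers reflect the
synthetic parameter catalogue seeded above, not any published estimate.)

A thin CLI mirrors the library: `seqcea reconstruct-ipd`,
`seqcea fit-transitions`, `seqcea synth trial|catalogue`,
`seqcea simulate`.

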