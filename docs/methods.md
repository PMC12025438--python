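# Methods

This note documents the model, its parameters and defaults, the numerical
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Disease model and treatment sequences

Health states follow the advanced prostate-cancer pathway: nmCSPC →
mCSPC (low- or high-risk) → mCRPC line 1 → optional mCRPC line 2 →
progressed mCRPC → death, with an nmCRPC branch out of nmCSPC that is
disabled by default (see below). Death is absorbing; progressed mCRPC is
absorbing except for death. There is no remission/recovery state.

A treatment sequence assigns one regimen per state. Admissibility rules:

* every regimen must have trial evidence in its state (the availability
  catalogue mirrors the trials backing each treatment-state pair, with
  second-line mCRPC options — abiraterone, enzalutamide, cabazitaxel —
  evidenced only post-docetaxel and hence reachable only after first-line
  docetaxel);
* no ARPI may appear after any earlier ARPI exposure (cross-resistance:
  no rechallenge), evaluated along every temporally possible path;
* nmCSPC-starting sequences with late ARPI use assign the same ARPI in
  mCSPC and nmCRPC.

With the default catalogue this enumeration yields 11 / 20 / 26 sequences
for nmCSPC / low-risk mCSPC / high-risk mCSPC starts. Two rules that the
published counts imply but the main sources do not state explicitly are
configurable (`SequenceRules`): nmCSPC-starting sequences do not defer
ARPI use to mCRPC (late use means mCSPC/nmCRPC), and the all-non-ARPI
nmCSPC-starting reference is the single sequence (adt, adt, doce). The
expected counts are a soft check (`EXPECTED_SEQUENCE_COUNTS`), not an
invariant of the enumeration algorithm.

On progression out of nmCSPC, 65.1% of patients enter low-risk and 34.9%
high-risk mCSPC. Only this split is quantified in the literature we
model, so the nmCSPC → nmCRPC branch probability defaults to 0 and is
exposed as `SequenceRules.p_nm_to_nmcrpc` rather than invented.

## Transition functional form and identification

Monthly transition probabilities per treatment-state pair:
P(s→p) = α(1+β)^(t−1), P(s→d) = γ, P(p→d) = δ, with t the months spent in
the state. Trial curves only partially identify (α, β, γ, δ): deaths
observed in a trial cannot be split into pre- and post-progression deaths
from the curves alone. The functional-form restriction plus a grid search
resolves this: every grid point is scored by the mean-squared error
between the implied cohort PFS/OS curves and the empirical ones, and the
minimiser is returned.

Numerical choices:

* **Grid.** Defaults α ∈ [0, 0.25], β ∈ [−0.10, 0.10], γ ∈ [0, 0.10],
  δ ∈ [0, 0.25], all at step 0.005, followed by one refinement pass at
  1/10 step spanning one coarse step around the incumbent. Monthly
  probabilities above these bounds are clinically implausible for these
  states. The full default search evaluates ≈2.4M points in ~1.5 s
  (vectorised over the grid).
* **MSE grid and weighting.** Every integer month from 1 to the
  empirical follow-up; PFS and OS pooled with equal weight; both curves
  evaluated as step functions (last observation carried forward). PFS and
  OS are fitted jointly — whether the original analysis fitted them
  jointly or sequentially is not stated, and joint equal-weight fitting is
  the symmetric default.
* **Tie-breaking.** Among grid points tied at the minimal MSE (relative
  tolerance 1e−9): smallest |β|, then α, then γ, then δ — prefer the most
  constant hazard, deterministically.
* **Clamping.** α(1+β)^(t−1) is clamped at 1−γ wherever it would exceed
  it; a fit whose optimum clamps within the horizon is flagged
  (`flags["clamped"]`) rather than rejected, keeping probabilities valid
  without silently distorting fits.
* **δ identifiability.** When the OS curve carries no post-progression
  information (e.g. no one progresses), δ is pinned by the tie-break at
  its grid minimum and flagged `delta_unidentified` (detected by swapping
  δ to the extremes of its range and checking the MSE is tied).
* A design subtlety of the cohort recursion: a patient progressing in
  month t occupies the progressed state for at least one month, so even
  δ = 1 leaves OS strictly above PFS by the one-month progression inflow.
  This matches the microsimulation's end-of-month event convention.

Weibull and Lognormal maximum-likelihood fits (via lifelines) on
reconstructed patient-level data serve as parametric benchmarks
(`parametric_benchmark_fit`), mirroring how the grid-search fit's error is
judged "comparable" to standard families.

## Kaplan-Meier input and Guyot reconstruction

Digitized curves are read as (time, survival) tables (months; other units
converted via a header declaration) and validated: S(0)=1, nonincreasing,
within [0,1], risk tables nonincreasing. Curves are resampled to the
monthly grid by step-function evaluation before fitting, because the model
operates in 1-month cycles; the digitization grid density of the source
figures is unknown, so monthly resampling is this package's choice.

Individual patient data are reconstructed with the published
interval-allocation scheme: within each numbers-at-risk interval, the
number censored is adjusted (censoring times spread uniformly) until the
implied number at risk matches the next risk-table entry, with event
counts at each curve step derived from the product-limit relation.
Boundary convention: a patient with an event exactly at a risk-table time
still counts as at risk at that time, so steps at a boundary belong to the
interval starting there, and steps at the end of follow-up are processed
after the final boundary count. After the last risk-table time (or when no
interior risk information exists) no censoring is assumed except
administratively at the last follow-up, and the assumption is visible in
the output (all remaining patients censored at the final time).

## Microsimulation

Defaults: 200,000 patients, 180 monthly cycles (15 years), 1.5% annual
discounting of benefits and costs. Patients are identical (no covariate
heterogeneity — trial evidence does not support subgroup curves), and no
separate background mortality is added since trial OS already embeds it.

Conventions:

* competing monthly events are resolved by one uniform draw partitioned
  as [0, P_prog), [P_prog, P_prog + γ), remainder stay;
* events take effect at month end; a patient dying in month m accrues
  month m; no half-cycle correction;
* month m is discounted by (1+r)^(−(m−1)/12) (discounting by calendar
  month, beginning-of-cycle);
* the months-in-state clock resets to 1 on every state entry (semi-Markov);
* the progressed state's death probability is the final treatment line's δ.

Utilities (annual): nmCSPC 0.95, mCSPC 0.85, nmCRPC 0.90, mCRPC 0.75,
progressed mCRPC 0.60, death 0. Treatment disutilities (annual):
abiraterone 0.021, apalutamide 0.019, cabazitaxel 0.042, darolutamide
0.019, docetaxel 0.042, enzalutamide 0.022; combinations sum their
components' disutilities.

Costs (CAD/month): ADT 322 (backbone, added to every non-suspended month
— all regimens combine with ADT, and castration is maintained lifelong,
including in the progressed state), abiraterone 919, apalutamide 3401,
cabazitaxel 4134, darolutamide 3401, docetaxel 103, enzalutamide 3401;
non-IV management 92, IV management 455 (during chemotherapy-infusion
months). End-of-life care: 1449/month over the final min(12, months spent
in progressed mCRPC) months of patients who die in the progressed state
(assigned retrospectively, discounted at those months; patients alive at
the horizon receive none). Chemotherapy runs a fixed number of monthly
cycles — docetaxel 6 in mCSPC and 10 in mCRPC, cabazitaxel 10 — with one
cycle per model month (the underlying protocols use 3-weekly cycles, which
monthly granularity cannot represent; a documented approximation). After
the cycles end, any ARPI component plus ADT continue with non-IV
management, and the chemotherapy component's cost and disutility stop.

Intermittent therapy applies only in nmCSPC: active phases of 9 months at
full drug cost alternate with suspended phases whose length is
round(Beta(a, b)·scale) months (min 1). Suspended months incur only the
non-IV monitoring cost and pause the treatment disutility (whether
disutility pauses during suspension is not stated in the sources; pausing
is this package's choice). Progression and death hazards are identical in
active and suspended months, because the trial curves the parameters are
fitted to already integrate over the protocol's on/off schedule. The
default suspension parameters (a=2, b=2, scale=24) are synthetic
placeholders, flagged on the object, to be overridden with trial-derived
values when available.

Reproducibility: all randomness flows from one seed through fixed-order
block draws; the same seed and configuration give bit-identical results,
and a one-patient cohort consumes the stream exactly as
`simulate_patient`, so the two paths agree to machine precision.

A deterministic oracle (`expected_occupancy`) propagates the exact
occupancy distribution by expanding each state with its months-in-state
clock; the microsimulation must agree with it to within Monte Carlo error.
Because that comparison spans many simultaneous occupancy points, the
acceptance test applies a Šidák family-wise bound that preserves the
confidence level of a single 3-standard-error test.

## Cost-effectiveness layer

NHB = benefit − cost/CET holds as an exact identity on every reported row.
Sequences are ranked by NHB (ties: lower cost, then label), incremental to
a no-ARPI reference — (adt, adt, doce) for nmCSPC starts and (adt, doce)
for mCSPC starts, configurable. Acceptability curves resample stored
per-patient outcomes (2000 iterations of 100 patients per ARPI-timing
group by default) rather than re-simulating: a seeded bootstrap is
distributionally equivalent for means and orders of magnitude cheaper.
The default CET grid runs to CAD 300K in steps of 1K; argmax ties in an
iteration go to the lower-cost group, then label. The tornado threshold is
the lowest grid CET at which a group wins more than a coverage fraction
(default 99%) of iterations.

Scenarios: 10- and 20-year horizons; ARPI prices equalised to
abiraterone's 919 CAD/month; US public (Veterans Affairs) and private
payers at 3% discounting with CETs compared via 1.3698 CAD/USD; UK public
payer at 3.5% discounting via 1.7504 CAD/GBP. The US/UK price tables
shipped here are editable synthetic placeholders (the published tariffs
are not redistributed); conclusions under those scenarios are therefore
structural, not quantitative.

## Synthetic data: what it does and does not show

`generate_trial` emulates a digitized trial read-out: patient-level
progression/death under known (α, β, γ, δ), monthly dropout (default
0.002/month) plus administrative censoring, monthly-resolution KM curves,
and 6-monthly risk tables. `generate_param_catalogue` draws plausible
monthly parameters (α ∈ [0.01, 0.15], β ∈ [−0.03, 0.03], γ, δ ∈
[0.002, 0.08], constrained so no clamping occurs within 240 months) with
an enforced effect ordering: ARPI-containing regimens get strictly lower α
and γ than ADT alone in the same state.

Passing tests on these inputs demonstrate that the estimation machinery
recovers known truths, that the simulator agrees with its deterministic
limit, and that the CEA layer's identities and orderings hold. They do
not validate the published clinical parameter estimates themselves: the
trial-fitted transition parameters are inputs this pipeline consumes, not
outputs it reproduces, so headline cohort totals computed from synthetic
catalogues are illustrative only.

## Problem sizes used in the checks

Parameter-recovery checks use 50 on-grid truths at 60-month follow-up and
one off-grid truth estimated from a 100,000-patient synthetic trial;
microsimulation-vs-recursion checks use 50,000 patients over 180 months on
5 random catalogues; acceptability and ranking properties use 2,000-patient
cohorts. These sizes make the full suite complete in a few minutes while
keeping Monte Carlo error far below the tolerances tested.

## Known limitations

* Later-line mCRPC options outside the modelled catalogue (PARP
  inhibitors, radium-223, lutetium-177) are not included.
* Prednisone-monitoring cost nuances of long-term abiraterone are not
  modelled.
* Exact per-trial chemotherapy cycle counts live in the cited protocols;
  the defaults here are configurable approximations.
* The enumeration rule set reproducing the published sequence counts is
  partly inferred (see above) and configurable rather than hard-coded.
* Monthly cycles cannot represent 3-weekly chemotherapy scheduling or
  sub-month event timing.
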