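"""Synthetic trial curves, parameter catalogues and default tables.

Published trial curves arrive as digitized figures, which cannot be
redistributed; this module generates every input the pipeline needs with
the same statistical structure, so estimation, simulation and CEA stages
are testable end to end.  Synthetic trials simulate patient-level
progression and death under known transition parameters, apply dropout and
administrative censoring, and emit monthly-resolution Kaplan-Meier PFS/OS
curves with numbers-at-risk tables - the format a digitized trial figure
would provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .km import IPDRecord, KMCurve, km_estimate, risk_table_from_ipd
from .model import Catalogue, HealthState, default_catalogue
from .simulate import DEFAULT_DISUTILITIES, CostTable, SuspensionModel, UtilityTable
from .transitions import TransitionParams

__all__ = [
    "SyntheticTrialSpec",
    "SyntheticTrial",
    "generate_trial",
    "generate_param_catalogue",
    "default_tables",
]


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Design of one synthetic trial read-out.

    ``dropout`` is a constant monthly censoring probability applied on top
    of administrative censoring at ``follow_up``; ``risk_interval`` is the
    spacing of the numbers-at-risk table rows.
    """

    truth: TransitionParams
    n_patients: int = 500
    follow_up: int = 60          # months
    dropout: float = 0.002       # monthly dropout probability
    risk_interval: int = 6       # months between risk-table rows
    seed: int = 0
    label: str = "synthetic-trial"

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.follow_up < 12:
            raise ValueError("follow_up must be >= 12 months")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class SyntheticTrial:
    """Synthetic trial output: curves, risk tables, and the true IPD."""

    pfs: KMCurve
    os: KMCurve
    ipd_pfs: list
    ipd_os: list
    spec: SyntheticTrialSpec


def _monthly_curve(ipd, follow_up, risk_interval, label) -> KMCurve:
    """KM estimate resampled to the monthly grid with a risk table."""
    est = km_estimate(ipd, label=label)
    months = np.arange(follow_up + 1, dtype=float)
    rt_times = np.arange(0, follow_up + 1, risk_interval, dtype=float)
    return KMCurve(label=label, times=months, survival=est.evaluate(months),
                   risk_table=risk_table_from_ipd(ipd, rt_times))


def generate_trial(spec: SyntheticTrialSpec) -> SyntheticTrial:
    """Simulate one trial under known transition parameters.

    Patients progress with monthly probability ``alpha*(1+beta)**(t-1)``
    (clamped at ``1-gamma``), die pre-progression with ``gamma`` and
    post-progression with ``delta``. Dropout censors both endpoints;
    everyone still under follow-up is censored administratively at
    ``follow_up``. Returns monthly-resolution PFS and OS curves with
    6-monthly (by default) risk tables plus the underlying IPD for oracle
    checks. Fully reproducible from ``spec.seed``.
    """
    p = spec.truth
    rng = np.random.default_rng(spec.seed)
    n, fu = spec.n_patients, spec.follow_up
    u = rng.random((n, fu))        # event draws, pre-progression phase order
    u_post = rng.random((n, fu))   # post-progression death draws
    u_drop = rng.random((n, fu))   # dropout draws
    pfs_time = np.full(n, fu, dtype=float)
    pfs_event = np.zeros(n, dtype=int)
    os_time = np.full(n, fu, dtype=float)
    os_event = np.zeros(n, dtype=int)
    state = np.zeros(n, dtype=int)  # 0 progression-free, 1 progressed, 2 dead, 3 censored
    for m in range(1, fu + 1):
        pre = state == 0
        pp = np.minimum(p.alpha * (1.0 + p.beta) ** (m - 1), 1.0 - p.gamma)
        um = u[:, m - 1]
        progressing = pre & (um < pp)
        dying_pre = pre & ~progressing & (um < pp + p.gamma)
        post = state == 1
        dying_post = post & (u_post[:, m - 1] < p.delta)
        # PFS event at progression or pre-progression death
        ev = progressing | dying_pre
        pfs_time[ev] = m
        pfs_event[ev] = 1
        state[progressing] = 1
        dead = dying_pre | dying_post
        os_time[dead] = m
        os_event[dead] = 1
        state[dead] = 2
        # dropout censors survivors at the end of the month
        at_risk = state != 2
        dropping = at_risk & (u_drop[:, m - 1] < spec.dropout) & (state != 3)
        os_time[dropping] = m
        state[dropping] = 3
        pfs_drop = dropping & (pfs_event == 0) & (pfs_time >= m)
        pfs_time[pfs_drop] = m
    ipd_pfs = [IPDRecord(float(t), int(e)) for t, e in zip(pfs_time, pfs_event)]
    ipd_os = [IPDRecord(float(t), int(e)) for t, e in zip(os_time, os_event)]
    pfs = _monthly_curve(ipd_pfs, fu, spec.risk_interval, f"{spec.label}:PFS")
    os_ = _monthly_curve(ipd_os, fu, spec.risk_interval, f"{spec.label}:OS")
    return SyntheticTrial(pfs=pfs, os=os_, ipd_pfs=ipd_pfs, ipd_os=ipd_os, spec=spec)


def _sample_params(rng, horizon: int = 240) -> TransitionParams:
    """One plausible monthly parameter set, valid without clamping."""
    gamma = rng.uniform(0.002, 0.08)
    delta = rng.uniform(0.002, 0.08)
    beta = rng.uniform(-0.03, 0.03)
    alpha_cap = 0.15
    if beta > 0:
        alpha_cap = min(alpha_cap, (1.0 - gamma - 0.01) / (1.0 + beta) ** (horizon - 1))
    if alpha_cap < 0.01:
        beta = -abs(beta)
        alpha_cap = 0.15
    alpha = rng.uniform(0.01, alpha_cap)
    return TransitionParams(alpha, beta, gamma, delta)


def generate_param_catalogue(seed: int = 0, effect_ordering: bool = True,
                             catalogue: Catalogue | None = None,
                             horizon: int = 240) -> dict:
    """Synthetic transition parameters for every (state, treatment) pair.

    Stands in for trial-fitted parameters when none are supplied. With
    ``effect_ordering`` on, ARPI-containing regimens get strictly lower
    progression (alpha) and pre-progression death (gamma) probabilities
    than ADT alone in the same state, so treatment-effect direction is
    realistic. All parameter sets satisfy the no-clamping condition over
    ``horizon`` months. Seeded and reproducible.
    """
    catalogue = catalogue or default_catalogue()
    rng = np.random.default_rng(seed)
    out: dict = {}
    states = list(catalogue.availability) + [HealthState.mCRPC_L2]
    for state in states:
        if state is HealthState.mCRPC_L2:
            names = sorted({t for opts in catalogue.mcrpc_l2_after.values()
                            for t in opts})
        else:
            names = list(catalogue.available(state))
        base = _sample_params(rng, horizon)
        for name in sorted(names):
            treat = catalogue.get(name)
            p = _sample_params(rng, horizon)
            if effect_ordering and treat.arpi is not None:
                shrink_a = rng.uniform(0.5, 0.9)
                shrink_g = rng.uniform(0.5, 0.9)
                p = TransitionParams(min(base.alpha * shrink_a, p.alpha),
                                     p.beta,
                                     min(base.gamma * shrink_g, p.gamma),
                                     p.delta)
            if treat.arpi is None and not treat.components:
                p = base  # the ADT backbone itself
            out[(state, name)] = p
    return out


def default_tables():
    """Default utility, cost, disutility and suspension tables.

    Utilities and costs are the Canadian public-payer values the model uses
    (annual utilities 0.95 / 0.85 / 0.9 / 0.75 / 0.6 by state; monthly CAD
    drug costs 322 / 919 / 3401 / 4134 / 3401 / 103 / 3401; management 92
    and 455; end-of-life 1449). Suspension parameters are synthetic
    placeholders, flagged on the object.
    """
    return (UtilityTable(), CostTable(), dict(DEFAULT_DISUTILITIES),
            SuspensionModel())
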