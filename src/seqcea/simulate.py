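"""Monte Carlo semi-Markov microsimulation of treatment sequences.

Each simulated patient advances in 1-month cycles through the health states
of a treatment sequence. Monthly transition probabilities depend on the time
already spent in the current state (semi-Markov): progression occurs with
probability ``alpha * (1 + beta) ** (t - 1)``, pre-progression death with
``gamma``, and - in the terminal progressed-mCRPC state - death with the
final treatment line's ``delta``.  Competing monthly events are resolved by
a single uniform draw partitioned as [0, P_prog), [P_prog, P_prog + gamma),
remainder = stay.

Accrued outcomes are discounted life-years, quality-adjusted life-years
(state utility minus treatment disutility), and costs (drug + monitoring +
end-of-life). Events take effect at month end; a patient dying in month m
accrues month m. Month m is discounted by ``(1 + r) ** (-(m - 1) / 12)``
(beginning-of-cycle convention, no half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (Catalogue, HealthState, SequenceRules, TreatmentSequence,
                    default_catalogue)
from .transitions import TransitionParams

__all__ = [
    "SimulationConfig",
    "UtilityTable",
    "CostTable",
    "SuspensionModel",
    "PatientPath",
    "CohortResult",
    "ConfigurationError",
    "discount_factor",
    "sample_suspension",
    "simulate_patient",
    "accrue_utility",
    "accrue_cost",
    "simulate_cohort",
    "expected_occupancy",
    "chemo_cycles",
]


class ConfigurationError(ValueError):
    """A (state, treatment) pair required by the sequence lacks parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort size, horizon and discounting for a microsimulation run."""

    n_patients: int = 200_000
    horizon: int = 180          # months (15 years)
    annual_discount: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 month")
        if not 0.0 <= self.annual_discount < 1.0:
            raise ValueError("annual discount rate must be in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass(frozen=True)
class UtilityTable:
    """Annual health-state utilities (0 = death, 1 = ideal health)."""

    nmCSPC: float = 0.95
    mCSPC: float = 0.85
    nmCRPC: float = 0.90
    mCRPC: float = 0.75
    progressed_mCRPC: float = 0.60

    def by_state(self) -> dict:
        return {
            HealthState.nmCSPC: self.nmCSPC,
            HealthState.mCSPC_low: self.mCSPC,
            HealthState.mCSPC_high: self.mCSPC,
            HealthState.nmCRPC: self.nmCRPC,
            HealthState.mCRPC_L1: self.mCRPC,
            HealthState.mCRPC_L2: self.mCRPC,
            HealthState.progressed_mCRPC: self.progressed_mCRPC,
            HealthState.death: 0.0,
        }


#: annual treatment-specific disutilities per drug component
DEFAULT_DISUTILITIES = {
    "abi": 0.021, "apa": 0.019, "caba": 0.042,
    "daro": 0.019, "doce": 0.042, "enza": 0.022,
}


@dataclass(frozen=True)
class CostTable:
    """Monthly costs in CAD: drugs, monitoring/administration, end of life."""

    drug: dict = field(default_factory=lambda: {
        "adt": 322.0, "abi": 919.0, "apa": 3401.0, "caba": 4134.0,
        "daro": 3401.0, "doce": 103.0, "enza": 3401.0,
    })
    non_iv_management: float = 92.0
    iv_management: float = 455.0
    end_of_life_monthly: float = 1449.0
    end_of_life_months: int = 12


@dataclass(frozen=True)
class SuspensionModel:
    """Beta-distributed length of suspended treatment phases in nmCSPC.

    An active phase lasts ``active_months``; each suspension lasts
    ``round(Beta(a, b) * scale)`` months (minimum 1). The default shape
    parameters are synthetic placeholders (no published fit is packaged
    here) and should be overridden with trial-derived values when available.
    """

    a: float = 2.0
    b: float = 2.0
    scale: float = 24.0
    active_months: int = 9
    synthetic: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.scale < 1:
            raise ValueError("scale must be >= 1 month")


#: fixed chemotherapy cycle counts (one cycle = one model month)
_CHEMO_CYCLES = {
    ("doce", "CSPC"): 6,
    ("doce", "CRPC"): 10,
    ("caba", "CRPC"): 10,
}


def chemo_cycles(drug: str, state: HealthState) -> int:
    """Number of monthly chemotherapy cycles for a drug in a health state."""
    phase = "CSPC" if state in (HealthState.nmCSPC, HealthState.mCSPC_low,
                                HealthState.mCSPC_high) else "CRPC"
    try:
        return _CHEMO_CYCLES[(drug, phase)]
    except KeyError:
        raise ConfigurationError(f"no cycle count for {drug} in {state.value}") from None


def discount_factor(month: float, annual_rate: float) -> float:
    """Discount factor (1 + r) ** (-month / 12) at a calendar month index."""
    if month < 0:
        raise ValueError("month must be >= 0")
    return float((1.0 + annual_rate) ** (-month / 12.0))


def sample_suspension(model: SuspensionModel, treatment, rng) -> int:
    """Draw one suspended-phase length in months for an intermittent regimen."""
    if not getattr(treatment, "intermittent", False):
        raise ValueError(f"treatment {getattr(treatment, 'name', treatment)!r} "
                         "is not intermittent")
    draw = rng.beta(model.a, model.b)
    return max(1, int(round(draw * model.scale)))


@dataclass(frozen=True)
class MonthRecord:
    month: int                # calendar month, 1-based
    state: HealthState
    months_in_state: int      # semi-Markov clock, resets to 1 on entry
    treatment: str | None
    phase: str                # "active" | "suspended" | "off_chemo"


@dataclass
class PatientPath:
    """One simulated patient's monthly trajectory to death or horizon."""

    records: list
    death_month: int | None = None
    died_in_progressed: bool = False


@dataclass
class CohortResult:
    """Aggregate and per-patient discounted outcomes of a cohort run."""

    label: str
    config: SimulationConfig
    qaly: np.ndarray
    ly: np.ndarray
    cost: np.ndarray
    occupancy: np.ndarray    # (horizon, n_states) mean fraction per month

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def mean_ly(self) -> float:
        return float(self.ly.mean())

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())


# ---------------------------------------------------------------------------
# sequence "engine" tables: per-state parameter and costing vectors

_STATE_CODES = {s: i for i, s in enumerate(HealthState)}
_N_STATES = len(HealthState)
_DEATH = _STATE_CODES[HealthState.death]
_PROG = _STATE_CODES[HealthState.progressed_mCRPC]

#: deterministic successor codes (nmCSPC handled separately via branch draw)
_NEXT = {
    HealthState.mCSPC_low: HealthState.mCRPC_L1,
    HealthState.mCSPC_high: HealthState.mCRPC_L1,
    HealthState.nmCRPC: HealthState.mCRPC_L1,
    HealthState.mCRPC_L2: HealthState.progressed_mCRPC,
}


class _Engine:
    """Precomputed per-state vectors for one sequence."""

    def __init__(self, seq: TreatmentSequence, params: dict,
                 config: SimulationConfig, utilities: UtilityTable,
                 costs: CostTable, disutilities: dict, suspension: SuspensionModel,
                 catalogue: Catalogue, rules: SequenceRules):
        self.seq, self.config, self.rules = seq, config, rules
        self.costs, self.suspension = costs, suspension
        self.catalogue = catalogue
        mapping = seq.mapping
        reachable = set(mapping)
        if HealthState.nmCSPC in reachable and rules.p_nm_to_nmcrpc <= 0:
            reachable.discard(HealthState.nmCRPC)
        self.alpha = np.zeros(_N_STATES)
        self.beta = np.zeros(_N_STATES)
        self.gamma = np.zeros(_N_STATES)
        self.util = np.zeros(_N_STATES)
        self.dis_base = np.zeros(_N_STATES)   # non-chemo disutility
        self.dis_chemo = np.zeros(_N_STATES)
        self.drug_base = np.zeros(_N_STATES)  # non-chemo drug cost (excl. ADT)
        self.drug_chemo = np.zeros(_N_STATES)
        self.cycles = np.zeros(_N_STATES, dtype=int)
        self.has_chemo = np.zeros(_N_STATES, dtype=bool)
        util_map = utilities.by_state()
        for state, u in util_map.items():
            self.util[_STATE_CODES[state]] = u
        for state in reachable:
            name = mapping[state]
            if (state, name) not in params:
                raise ConfigurationError(
                    f"missing transition parameters for ({state.value}, {name})")
            p = params[(state, name)]
            i = _STATE_CODES[state]
            self.alpha[i], self.beta[i], self.gamma[i] = p.alpha, p.beta, p.gamma
            treat = catalogue.get(name)
            for comp in treat.components:
                if comp in ("doce", "caba"):
                    self.has_chemo[i] = True
                    self.dis_chemo[i] += disutilities.get(comp, 0.0)
                    self.drug_chemo[i] += costs.drug[comp]
                    self.cycles[i] = chemo_cycles(comp, state)
                else:
                    self.dis_base[i] += disutilities.get(comp, 0.0)
                    self.drug_base[i] += costs.drug[comp]
        final_line = (HealthState.mCRPC_L2 if seq.has_second_line
                      else HealthState.mCRPC_L1)
        self.delta_final = params[(final_line, mapping[final_line])].delta
        self.treatment_name = {_STATE_CODES[s]: mapping.get(s) for s in mapping}
        start = seq.starting_state
        self.start_code = _STATE_CODES[start]
        self.intermittent = (start is HealthState.nmCSPC
                             and catalogue.get(mapping[start]).intermittent)
        # branch successors
        self.next_code = np.full(_N_STATES, _DEATH, dtype=int)
        for s, nxt in _NEXT.items():
            self.next_code[_STATE_CODES[s]] = _STATE_CODES[nxt]
        self.next_code[_STATE_CODES[HealthState.mCRPC_L1]] = _STATE_CODES[
            HealthState.mCRPC_L2 if seq.has_second_line
            else HealthState.progressed_mCRPC]

    def p_prog(self, state_codes, clock):
        """Clamped monthly progression probability per patient."""
        a = self.alpha[state_codes]
        p = a * (1.0 + self.beta[state_codes]) ** (clock - 1)
        return np.minimum(p, 1.0 - self.gamma[state_codes])

def _suspension_mask(raw: np.ndarray, active_months: int, scale: float,
                     horizon: int) -> np.ndarray:
    """Vectorised suspended-month mask (n, horizon) from beta draws (n, K)."""
    n, k = raw.shape
    lengths = np.maximum(1, np.rint(raw * scale)).astype(np.int64)
    starts = active_months + np.concatenate(
        [np.zeros((n, 1), dtype=np.int64),
         np.cumsum(lengths[:, :-1] + active_months, axis=1)], axis=1)
    ends = starts + lengths
    months = np.arange(horizon)
    out = np.zeros((n, horizon), dtype=bool)
    for j in range(k):
        s = np.clip(starts[:, j], 0, horizon)
        e = np.clip(ends[:, j], 0, horizon)
        live = s < horizon
        if not live.any():
            break
        mask = (months[None, :] >= s[:, None]) & (months[None, :] < e[:, None])
        out |= mask
    return out


def _rng_blocks(engine: _Engine, n: int, rng: np.random.Generator):
    """Draw the per-run random blocks in a fixed order (reproducibility)."""
    horizon = engine.config.horizon
    u_event = rng.random((n, horizon))
    u_branch = rng.random(n)
    susp = None
    if engine.intermittent:
        k = horizon // (engine.suspension.active_months + 1) + 2
        raw = rng.beta(engine.suspension.a, engine.suspension.b, (n, k))
        susp = _suspension_mask(raw, engine.suspension.active_months,
                                engine.suspension.scale, horizon)
    return u_event, u_branch, susp


def _run_vectorised(engine: _Engine, n: int, rng: np.random.Generator):
    """Simulate n patients; returns per-patient outcomes and occupancy."""
    cfg = engine.config
    horizon, r = cfg.horizon, cfg.annual_discount
    u_event, u_branch, susp = _rng_blocks(engine, n, rng)
    rules = engine.rules
    state = np.full(n, engine.start_code, dtype=np.int64)
    clock = np.ones(n, dtype=np.int64)
    death_month = np.zeros(n, dtype=np.int64)
    prog_entry = np.zeros(n, dtype=np.int64)
    died_in_prog = np.zeros(n, dtype=bool)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    cost = np.zeros(n)
    occupancy = np.zeros((horizon, _N_STATES))
    disc = (1.0 + r) ** (-(np.arange(1, horizon + 1) - 1) / 12.0)
    cum_disc = np.concatenate([[0.0], np.cumsum(disc)])
    c = engine.costs
    nm_code = _STATE_CODES[HealthState.nmCSPC]
    for m in range(1, horizon + 1):
        alive = state != _DEATH
        d_m = disc[m - 1]
        occupancy[m - 1] = np.bincount(state, minlength=_N_STATES) / n
        # --- accrual for month m (state at month start) ---
        suspended = np.zeros(n, dtype=bool)
        if susp is not None:
            suspended = (state == nm_code) & susp[:, m - 1]
        chemo_on = engine.has_chemo[state] & (clock <= engine.cycles[state]) & alive
        disutil = np.where(suspended, 0.0,
                           engine.dis_base[state] + engine.dis_chemo[state] * chemo_on)
        ly += alive * (d_m / 12.0)
        qaly += alive * (engine.util[state] - disutil) / 12.0 * d_m
        month_cost = np.where(
            suspended,
            c.non_iv_management,
            c.drug["adt"] + engine.drug_base[state]
            + engine.drug_chemo[state] * chemo_on
            + np.where(chemo_on, c.iv_management, c.non_iv_management))
        cost += alive * month_cost * d_m
        # --- transition at month end ---
        in_prog = state == _PROG
        p_prog = np.where(alive & ~in_prog, engine.p_prog(state, clock), 0.0)
        p_death = np.where(in_prog, engine.delta_final, engine.gamma[state])
        u = u_event[:, m - 1]
        progressing = alive & ~in_prog & (u < p_prog)
        dying = alive & ~progressing & (u < p_prog + p_death)
        death_month[dying] = m
        died_in_prog |= dying & in_prog
        state[dying] = _DEATH
        if progressing.any():
            new_state = engine.next_code[state[progressing]]
            from_nm = state[progressing] == nm_code
            if from_nm.any():
                ub = u_branch[progressing]
                to_nmcrpc = ub < rules.p_nm_to_nmcrpc
                ub2 = (ub - rules.p_nm_to_nmcrpc) / max(1 - rules.p_nm_to_nmcrpc, 1e-12)
                dest = np.where(ub2 < rules.p_low_risk,
                                _STATE_CODES[HealthState.mCSPC_low],
                                _STATE_CODES[HealthState.mCSPC_high])
                dest = np.where(to_nmcrpc, _STATE_CODES[HealthState.nmCRPC], dest)
                new_state = np.where(from_nm, dest, new_state)
            entered_prog = new_state == _PROG
            if entered_prog.any():
                idx = np.flatnonzero(progressing)[entered_prog]
                prog_entry[idx] = m + 1
            state[progressing] = new_state
        clock = np.where(progressing, 1, clock + 1)
    # --- end-of-life costs for deaths in progressed mCRPC ---
    sel = died_in_prog
    if sel.any():
        months_in_prog = death_month[sel] - prog_entry[sel] + 1
        k = np.minimum(c.end_of_life_months, months_in_prog)
        cost[sel] += c.end_of_life_monthly * (
            cum_disc[death_month[sel]] - cum_disc[death_month[sel] - k])
    return qaly, ly, cost, occupancy, death_month, died_in_prog


def simulate_cohort(seq: TreatmentSequence, params: dict,
                    config: SimulationConfig | None = None,
                    utilities: UtilityTable | None = None,
                    costs: CostTable | None = None,
                    disutilities: dict | None = None,
                    suspension: SuspensionModel | None = None,
                    catalogue: Catalogue | None = None,
                    rules: SequenceRules | None = None,
                    rng: np.random.Generator | None = None) -> CohortResult:
    """Simulate a cohort on one treatment sequence.

    ``params`` maps (HealthState, treatment name) to
    :class:`~seqcea.transitions.TransitionParams`. Per-patient discounted
    QALY, LY and cost vectors are retained for bootstrap resampling. Results
    are reproducible: the same seed and configuration give bit-identical
    output.
    """
    config = config or SimulationConfig()
    engine = _Engine(seq, params, config,
                     utilities or UtilityTable(), costs or CostTable(),
                     DEFAULT_DISUTILITIES if disutilities is None else disutilities,
                     suspension or SuspensionModel(),
                     catalogue or default_catalogue(), rules or SequenceRules())
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    qaly, ly, cost, occ, _, _ = _run_vectorised(engine, config.n_patients, rng)
    return CohortResult(label=seq.label, config=config, qaly=qaly, ly=ly,
                        cost=cost, occupancy=occ)


def simulate_patient(seq: TreatmentSequence, params: dict,
                     config: SimulationConfig, rng: np.random.Generator,
                     utilities: UtilityTable | None = None,
                     costs: CostTable | None = None,
                     disutilities: dict | None = None,
                     suspension: SuspensionModel | None = None,
                     catalogue: Catalogue | None = None,
                     rules: SequenceRules | None = None) -> PatientPath:
    """Simulate one patient path, consuming the same random layout as a
    one-patient cohort on the same generator."""
    config = config or SimulationConfig()
    engine = _Engine(seq, params, config,
                     utilities or UtilityTable(), costs or CostTable(),
                     DEFAULT_DISUTILITIES if disutilities is None else disutilities,
                     suspension or SuspensionModel(),
                     catalogue or default_catalogue(), rules or SequenceRules())
    horizon = config.horizon
    u_event, u_branch, susp = _rng_blocks(engine, 1, rng)
    u_event, u_branch = u_event[0], u_branch[0]
    susp_row = susp[0] if susp is not None else np.zeros(horizon, dtype=bool)
    code = engine.start_code
    clock = 1
    records = []
    death_month = None
    died_in_prog = False
    rules_ = engine.rules
    codes_to_state = list(HealthState)
    for m in range(1, horizon + 1):
        state_enum = codes_to_state[code]
        suspended = code == _STATE_CODES[HealthState.nmCSPC] and bool(susp_row[m - 1])
        chemo_on = bool(engine.has_chemo[code]) and clock <= int(engine.cycles[code])
        if suspended:
            phase = "suspended"
        elif engine.has_chemo[code] and not chemo_on:
            phase = "off_chemo"
        else:
            phase = "active"
        records.append(MonthRecord(month=m, state=state_enum, months_in_state=clock,
                                   treatment=engine.treatment_name.get(code),
                                   phase=phase))
        in_prog = code == _PROG
        if in_prog:
            p_prog, p_death = 0.0, engine.delta_final
        else:
            a, b, g = engine.alpha[code], engine.beta[code], engine.gamma[code]
            p_prog = min(a * (1.0 + b) ** (clock - 1), 1.0 - g)
            p_death = g
        u = u_event[m - 1]
        if u < p_prog:
            if code == _STATE_CODES[HealthState.nmCSPC]:
                if u_branch < rules_.p_nm_to_nmcrpc:
                    code = _STATE_CODES[HealthState.nmCRPC]
                else:
                    ub2 = (u_branch - rules_.p_nm_to_nmcrpc) / max(
                        1 - rules_.p_nm_to_nmcrpc, 1e-12)
                    code = _STATE_CODES[HealthState.mCSPC_low if ub2 < rules_.p_low_risk
                                        else HealthState.mCSPC_high]
            else:
                code = int(engine.next_code[code])
            clock = 1
        elif u < p_prog + p_death:
            death_month = m
            died_in_prog = in_prog
            break
        else:
            clock += 1
    return PatientPath(records=records, death_month=death_month,
                       died_in_progressed=died_in_prog)


def _effective_disutility(record: MonthRecord, disutilities: dict,
                          catalogue: Catalogue) -> float:
    if record.treatment is None or record.phase == "suspended":
        return 0.0
    total = 0.0
    for comp in catalogue.get(record.treatment).components:
        if comp in ("doce", "caba") and record.phase != "active":
            continue
        total += disutilities.get(comp, 0.0)
    return total


def accrue_utility(path: PatientPath, utilities: UtilityTable | None = None,
                   disutilities: dict | None = None,
                   config: SimulationConfig | None = None,
                   catalogue: Catalogue | None = None) -> tuple[float, float]:
    """Discounted (QALY, LY) for one patient path."""
    utilities = utilities or UtilityTable()
    disutilities = DEFAULT_DISUTILITIES if disutilities is None else disutilities
    config = config or SimulationConfig()
    catalogue = catalogue or default_catalogue()
    util_map = utilities.by_state()
    qaly = ly = 0.0
    for rec in path.records:
        d = discount_factor(rec.month - 1, config.annual_discount)
        ly += d / 12.0
        dis = _effective_disutility(rec, disutilities, catalogue)
        qaly += (util_map[rec.state] - dis) / 12.0 * d
    return qaly, ly


def accrue_cost(path: PatientPath, costs: CostTable | None = None,
                config: SimulationConfig | None = None,
                catalogue: Catalogue | None = None) -> float:
    """Total discounted cost (CAD) for one patient path, incl. end of life."""
    costs = costs or CostTable()
    config = config or SimulationConfig()
    catalogue = catalogue or default_catalogue()
    total = 0.0
    for rec in path.records:
        d = discount_factor(rec.month - 1, config.annual_discount)
        if rec.phase == "suspended":
            total += costs.non_iv_management * d
            continue
        month_cost = costs.drug["adt"]
        chemo_on = False
        if rec.treatment is not None:
            for comp in catalogue.get(rec.treatment).components:
                if comp in ("doce", "caba"):
                    if rec.phase == "active":
                        month_cost += costs.drug[comp]
                        chemo_on = True
                else:
                    month_cost += costs.drug[comp]
        month_cost += costs.iv_management if chemo_on else costs.non_iv_management
        total += month_cost * d
    if path.died_in_progressed:
        prog_months = [r.month for r in path.records
                       if r.state is HealthState.progressed_mCRPC]
        k = min(costs.end_of_life_months, len(prog_months))
        for m in prog_months[-k:]:
            total += costs.end_of_life_monthly * discount_factor(
                m - 1, config.annual_discount)
    return total


def expected_occupancy(seq: TreatmentSequence, params: dict,
                       config: SimulationConfig | None = None,
                       rules: SequenceRules | None = None,
                       catalogue: Catalogue | None = None,
                       utilities: UtilityTable | None = None,
                       costs: CostTable | None = None,
                       disutilities: dict | None = None,
                       suspension: SuspensionModel | None = None):
    """Deterministic cohort recursion over the sequence's chained states.

    Expands each semi-Markov state by its months-in-state clock and
    propagates the exact occupancy distribution month by month - the
    law-of-large-numbers limit of :func:`simulate_cohort`. Returns
    ``(occupancy, mean_ly)`` where ``occupancy[m-1, s]`` is the probability
    of spending month m in state s and ``mean_ly`` the discounted expected
    life-years.
    """
    config = config or SimulationConfig()
    rules = rules or SequenceRules()
    engine = _Engine(seq, params, config,
                     utilities or UtilityTable(), costs or CostTable(),
                     DEFAULT_DISUTILITIES if disutilities is None else disutilities,
                     suspension or SuspensionModel(),
                     catalogue or default_catalogue(), rules)
    horizon = config.horizon
    mass = np.zeros((_N_STATES, horizon + 1))   # [state, clock-1]
    dead = 0.0
    mass[engine.start_code, 0] = 1.0
    occupancy = np.zeros((horizon, _N_STATES))
    disc = (1.0 + config.annual_discount) ** (-(np.arange(horizon)) / 12.0)
    nm = _STATE_CODES[HealthState.nmCSPC]
    lo = _STATE_CODES[HealthState.mCSPC_low]
    hi = _STATE_CODES[HealthState.mCSPC_high]
    nmcrpc = _STATE_CODES[HealthState.nmCRPC]
    clocks = np.arange(1, horizon + 2, dtype=float)
    for m in range(1, horizon + 1):
        occupancy[m - 1] = mass.sum(axis=1)
        occupancy[m - 1, _DEATH] = dead
        new = np.zeros_like(mass)
        inflow = np.zeros(_N_STATES)
        for s in range(_N_STATES):
            if s == _DEATH or not mass[s].any():
                continue
            if s == _PROG:
                stay = mass[s] * (1.0 - engine.delta_final)
                dead += mass[s].sum() * engine.delta_final
                new[s, 1:] += stay[:-1]
                new[s, -1] += stay[-1]
                continue
            a, b, g = engine.alpha[s], engine.beta[s], engine.gamma[s]
            p = np.minimum(a * (1.0 + b) ** (clocks - 1), 1.0 - g)
            prog_flow = float(mass[s] @ p)
            dead += mass[s].sum() * g
            stay = mass[s] * (1.0 - p - g)
            new[s, 1:] += stay[:-1]
            new[s, -1] += stay[-1]
            if s == nm:
                inflow[nmcrpc] += prog_flow * rules.p_nm_to_nmcrpc
                rest = prog_flow * (1.0 - rules.p_nm_to_nmcrpc)
                inflow[lo] += rest * rules.p_low_risk
                inflow[hi] += rest * (1.0 - rules.p_low_risk)
            else:
                inflow[engine.next_code[s]] += prog_flow
        new[:, 0] += inflow
        mass = new
    alive = occupancy[:, :_DEATH].sum(axis=1) + occupancy[:, _DEATH + 1:].sum(axis=1)
    mean_ly = float((alive / 12.0) @ disc)
    return occupancy, mean_ly
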