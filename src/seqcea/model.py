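"""Health-state topology, treatment catalogue, and sequence rules.

The disease pathway runs from castration-sensitive states (nonmetastatic
nmCSPC; metastatic mCSPC split into low- and high-risk) through
castration-resistant states (nmCRPC; two mCRPC treatment lines) to a
terminal progressed-mCRPC state and death.  A treatment sequence assigns
one regimen per health state, subject to guideline rules - most notably no
ARPI rechallenge after any prior ARPI exposure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "HealthState",
    "Treatment",
    "TreatmentSequence",
    "Catalogue",
    "SequenceRules",
    "default_catalogue",
    "classify_arpi_use",
    "validate_sequence",
    "enumerate_sequences",
    "successor_state",
    "EXPECTED_SEQUENCE_COUNTS",
]


class HealthState(Enum):
    """Modelled health states, in pathway order."""

    nmCSPC = "nmCSPC"
    mCSPC_low = "mCSPC_low"
    mCSPC_high = "mCSPC_high"
    nmCRPC = "nmCRPC"
    mCRPC_L1 = "mCRPC_L1"
    mCRPC_L2 = "mCRPC_L2"
    progressed_mCRPC = "progressed_mCRPC"
    death = "death"


#: fraction of nmCSPC progressions that enter low-risk (vs high-risk) mCSPC
P_LOW_RISK_SPLIT = 0.651

ARPI_DRUGS = frozenset({"abi", "apa", "daro", "enza"})
CHEMO_DRUGS = frozenset({"doce", "caba"})


@dataclass(frozen=True)
class Treatment:
    """One regimen: drug components on top of the ADT backbone.

    ``components`` excludes ADT itself (every regimen is combined with ADT;
    the plain-ADT regimen has no components). ``intermittent`` marks
    regimens given on the on/off schedule used in nmCSPC.
    """

    name: str
    components: tuple[str, ...]
    intermittent: bool = False

    @property
    def arpi(self) -> str | None:
        for c in self.components:
            if c in ARPI_DRUGS:
                return c
        return None

    @property
    def chemo(self) -> str | None:
        for c in self.components:
            if c in CHEMO_DRUGS:
                return c
        return None

    @property
    def treatment_class(self) -> str:
        has_arpi, has_chemo = self.arpi is not None, self.chemo is not None
        if has_arpi and has_chemo:
            return "ARPI_plus_chemo"
        if has_arpi:
            return "ARPI"
        if has_chemo:
            return "chemo"
        return "ADT_only"


def _t(name, *components, intermittent=False):
    return Treatment(name=name, components=tuple(components), intermittent=intermittent)


_TREATMENTS = {
    "adt": _t("adt"),
    "adt (intermittent)": _t("adt (intermittent)", intermittent=True),
    "abi": _t("abi", "abi"),
    "apa": _t("apa", "apa"),
    "daro": _t("daro", "daro"),
    "enza": _t("enza", "enza"),
    "enza (intermittent)": _t("enza (intermittent)", "enza", intermittent=True),
    "doce": _t("doce", "doce"),
    "caba": _t("caba", "caba"),
    "doce + abi": _t("doce + abi", "doce", "abi"),
    "doce + daro": _t("doce + daro", "doce", "daro"),
    "doce + enza": _t("doce + enza", "doce", "enza"),
}


@dataclass(frozen=True)
class Catalogue:
    """Treatment availability per health state, following the trial evidence.

    ``mcrpc_l2_after`` lists second-line mCRPC options, all evidenced in the
    post-docetaxel setting, hence only reachable when line 1 is docetaxel.
    """

    treatments: dict = field(default_factory=lambda: dict(_TREATMENTS))
    availability: dict = field(default_factory=lambda: {
        HealthState.nmCSPC: ("adt (intermittent)", "enza (intermittent)"),
        HealthState.mCSPC_low: ("adt", "abi", "apa", "daro", "enza",
                                "doce + abi", "doce + daro", "doce + enza"),
        HealthState.mCSPC_high: ("adt", "doce", "abi", "apa", "daro", "enza",
                                 "doce + abi", "doce + daro", "doce + enza"),
        HealthState.nmCRPC: ("adt", "abi", "apa", "daro", "enza"),
        HealthState.mCRPC_L1: ("abi", "enza", "doce"),
    })
    mcrpc_l2_after: dict = field(default_factory=lambda: {
        "doce": ("abi", "enza", "caba"),
    })

    def get(self, name: str) -> Treatment:
        try:
            return self.treatments[name]
        except KeyError:
            raise KeyError(f"unknown treatment {name!r}") from None

    def available(self, state: HealthState) -> tuple[str, ...]:
        return self.availability.get(state, ())


def default_catalogue() -> Catalogue:
    return Catalogue()


#: starting states exposed to users
START_STATES = (HealthState.nmCSPC, HealthState.mCSPC_low, HealthState.mCSPC_high)

#: published sequence counts per starting state (soft check; the precise
#: admissibility rules behind them are configurable, see SequenceRules)
EXPECTED_SEQUENCE_COUNTS = {HealthState.nmCSPC: 11,
                            HealthState.mCSPC_low: 20,
                            HealthState.mCSPC_high: 26}


@dataclass(frozen=True)
class SequenceRules:
    """Configurable admissibility rules beyond the hard no-rechallenge rule.

    ``allow_mcrpc_only_arpi_nmcspc``: whether nmCSPC-starting sequences may
    defer ARPI use to mCRPC (default off: late use means mCSPC/nmCRPC).
    ``no_arpi_nmcspc_plans``: mCRPC plans examined for the all-non-ARPI
    nmCSPC-starting sequence(s); default keeps the single reference
    (adt, adt, doce).
    ``p_nm_to_nmcrpc``: probability that an nmCSPC progression goes to
    nmCRPC instead of mCSPC (default 0: only the mCSPC route is quantified).
    """

    allow_mcrpc_only_arpi_nmcspc: bool = False
    no_arpi_nmcspc_plans: tuple = (("doce", None),)
    p_nm_to_nmcrpc: float = 0.0
    p_low_risk: float = P_LOW_RISK_SPLIT


@dataclass(frozen=True)
class TreatmentSequence:
    """A mapping from health states to treatment names, with a printed label.

    nmCSPC-starting sequences are labelled ``(nmCSPC, mCSPC/nmCRPC, mCRPC)``
    and mCSPC-starting ones ``(mCSPC, mCRPC)``; a two-line mCRPC plan prints
    as ``"doce then caba"``.
    """

    starting_state: HealthState
    assignment: tuple  # ((HealthState, treatment name), ...)

    @property
    def mapping(self) -> dict:
        return dict(self.assignment)

    def treatment_in(self, state: HealthState) -> str | None:
        return self.mapping.get(state)

    @property
    def has_second_line(self) -> bool:
        return HealthState.mCRPC_L2 in self.mapping

    @property
    def label(self) -> str:
        m = self.mapping
        plan = m[HealthState.mCRPC_L1]
        if self.has_second_line:
            plan = f"{plan} then {m[HealthState.mCRPC_L2]}"
        def stem(name):
            return name.replace(" (intermittent)", "")
        if self.starting_state is HealthState.nmCSPC:
            mid = m.get(HealthState.mCSPC_low) or m.get(HealthState.nmCRPC)
            return f"({stem(m[HealthState.nmCSPC])}, {stem(mid)}, {plan})"
        return f"({stem(m[self.starting_state])}, {plan})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _ordered_stages(seq: TreatmentSequence) -> list[list[HealthState]]:
    """Pathway stages in temporal order; states within a stage are parallel
    branches (a patient passes through at most one of them)."""
    if seq.starting_state is HealthState.nmCSPC:
        stages = [[HealthState.nmCSPC],
                  [HealthState.mCSPC_low, HealthState.mCSPC_high, HealthState.nmCRPC]]
    else:
        stages = [[seq.starting_state]]
    stages.append([HealthState.mCRPC_L1])
    if seq.has_second_line:
        stages.append([HealthState.mCRPC_L2])
    return stages


def classify_arpi_use(seq: TreatmentSequence, catalogue: Catalogue | None = None) -> str:
    """Classify a sequence as "early", "late", or "none" ARPI use.

    Early: the starting state's regimen includes an ARPI (alone or in
    combination); late: a later state's does; none otherwise.
    """
    catalogue = catalogue or default_catalogue()
    start = seq.treatment_in(seq.starting_state)
    if start is not None and catalogue.get(start).arpi is not None:
        return "early"
    for state, name in seq.assignment:
        if state is seq.starting_state:
            continue
        if catalogue.get(name).arpi is not None:
            return "late"
    return "none"


def validate_sequence(seq: TreatmentSequence,
                      catalogue: Catalogue | None = None) -> list[str]:
    """Return the list of rule violations (empty when the sequence is valid).

    Checks availability per state, the no-ARPI-rechallenge rule along every
    possible disease path, and the requirement that nmCSPC-starting late-ARPI
    sequences use the same ARPI in mCSPC and nmCRPC.
    """
    catalogue = catalogue or default_catalogue()
    violations = []
    m = seq.mapping
    for state, name in seq.assignment:
        t = catalogue.get(name)  # raises on unknown names
        if state is HealthState.mCRPC_L2:
            l1 = m.get(HealthState.mCRPC_L1)
            allowed = catalogue.mcrpc_l2_after.get(l1, ())
            if name not in allowed:
                violations.append(
                    f"availability: {name} not evidenced in mCRPC line 2 after {l1}")
        elif state in catalogue.availability and name not in catalogue.available(state):
            violations.append(f"availability: {name} not available in {state.value}")
    # no ARPI after prior ARPI exposure, along any temporal path
    stages = _ordered_stages(seq)
    exposed = False
    for stage in stages:
        stage_arpi = any(
            catalogue.get(m[s]).arpi is not None for s in stage if s in m)
        if exposed and stage_arpi:
            states = [s.value for s in stage if s in m
                      and catalogue.get(m[s]).arpi is not None]
            violations.append(f"ARPI rechallenge: ARPI assigned in {states} "
                              "after earlier ARPI exposure")
        exposed = exposed or stage_arpi
    if seq.starting_state is HealthState.nmCSPC:
        arpis = {catalogue.get(m[s]).arpi
                 for s in (HealthState.mCSPC_low, HealthState.mCSPC_high,
                           HealthState.nmCRPC) if s in m}
        if len(arpis) > 1:
            violations.append(
                "same-ARPI rule: mCSPC and nmCRPC assignments must use the same ARPI")
    return violations


def _mcrpc_plans(catalogue: Catalogue, arpi_allowed: bool):
    """All mCRPC (line 1, optional line 2) plans under the rechallenge rule."""
    plans = []
    for l1 in catalogue.available(HealthState.mCRPC_L1):
        if not arpi_allowed and catalogue.get(l1).arpi is not None:
            continue
        plans.append((l1, None))
        for l2 in catalogue.mcrpc_l2_after.get(l1, ()):
            if catalogue.get(l2).arpi is not None and (
                    not arpi_allowed or catalogue.get(l1).arpi is not None):
                continue
            plans.append((l1, l2))
    return plans


def _assemble(start: HealthState, entries, l1, l2) -> TreatmentSequence:
    assignment = list(entries) + [(HealthState.mCRPC_L1, l1)]
    if l2 is not None:
        assignment.append((HealthState.mCRPC_L2, l2))
    return TreatmentSequence(starting_state=start, assignment=tuple(assignment))


def enumerate_sequences(catalogue: Catalogue | None = None,
                        starting_state: HealthState = HealthState.nmCSPC,
                        rules: SequenceRules | None = None) -> list[TreatmentSequence]:
    """Enumerate all admissible treatment sequences for a starting state.

    Ordering is deterministic: by ARPI timing (early, late, none), then by
    canonical label. Every returned sequence passes
    :func:`validate_sequence`.
    """
    catalogue = catalogue or default_catalogue()
    rules = rules or SequenceRules()
    seqs: list[TreatmentSequence] = []
    if starting_state is HealthState.nmCSPC:
        mid_states = (HealthState.mCSPC_low, HealthState.mCSPC_high,
                      HealthState.nmCRPC)
        mids = [n for n in catalogue.available(HealthState.mCSPC_low)
                if n in catalogue.available(HealthState.mCSPC_high)
                and n in catalogue.available(HealthState.nmCRPC)]
        for s0 in catalogue.available(HealthState.nmCSPC):
            s0_arpi = catalogue.get(s0).arpi is not None
            for mid in mids:
                mid_arpi = catalogue.get(mid).arpi is not None
                if s0_arpi and mid_arpi:
                    continue  # rechallenge
                exposed = s0_arpi or mid_arpi
                if exposed:
                    plans = _mcrpc_plans(catalogue, arpi_allowed=False)
                else:
                    plans = (rules.no_arpi_nmcspc_plans
                             if not rules.allow_mcrpc_only_arpi_nmcspc
                             else _mcrpc_plans(catalogue, arpi_allowed=True))
                entries = [(HealthState.nmCSPC, s0)] + [(s, mid) for s in mid_states]
                for l1, l2 in plans:
                    seqs.append(_assemble(starting_state, entries, l1, l2))
    elif starting_state in (HealthState.mCSPC_low, HealthState.mCSPC_high):
        for s0 in catalogue.available(starting_state):
            exposed = catalogue.get(s0).arpi is not None
            for l1, l2 in _mcrpc_plans(catalogue, arpi_allowed=not exposed):
                seqs.append(_assemble(starting_state, [(starting_state, s0)], l1, l2))
    else:
        raise ValueError(f"{starting_state} is not a modelled starting state")
    seqs = [s for s in seqs if not validate_sequence(s, catalogue)]
    timing_order = {"early": 0, "late": 1, "none": 2}
    seqs.sort(key=lambda s: (timing_order[classify_arpi_use(s, catalogue)], s.label))
    return seqs


def successor_state(state: HealthState, progressed: bool, seq: TreatmentSequence,
                    rules: SequenceRules | None = None,
                    u: float = 0.0) -> HealthState:
    """Next health state on progression (or the same state if not progressed).

    ``u`` is a uniform draw deciding branch destinations: from nmCSPC a
    progression goes to nmCRPC with probability ``rules.p_nm_to_nmcrpc``,
    otherwise to low-risk mCSPC with probability ``rules.p_low_risk`` and
    high-risk mCSPC with the rest. From mCRPC line 1 the destination is line
    2 when the sequence assigns one, else the terminal progressed state.
    """
    rules = rules or SequenceRules()
    if state is HealthState.death:
        raise ValueError("death is absorbing; no successor")
    if not progressed:
        return state
    if state is HealthState.nmCSPC:
        if u < rules.p_nm_to_nmcrpc:
            return HealthState.nmCRPC
        u2 = (u - rules.p_nm_to_nmcrpc) / max(1.0 - rules.p_nm_to_nmcrpc, 1e-12)
        return (HealthState.mCSPC_low if u2 < rules.p_low_risk
                else HealthState.mCSPC_high)
    if state in (HealthState.mCSPC_low, HealthState.mCSPC_high, HealthState.nmCRPC):
        return HealthState.mCRPC_L1
    if state is HealthState.mCRPC_L1:
        return (HealthState.mCRPC_L2 if seq is not None and seq.has_second_line
                else HealthState.progressed_mCRPC)
    if state is HealthState.mCRPC_L2:
        return HealthState.progressed_mCRPC
    if state is HealthState.progressed_mCRPC:
        return HealthState.death
    raise ValueError(f"no successor defined for {state}")
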