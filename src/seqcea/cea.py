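"""Cost-effectiveness layer: net health benefit, ranking, acceptability.

The headline statistic is the net health benefit

    NHB = Benefit - Cost / CET

in benefit units (QALYs or LYs), where the cost-effectiveness threshold
(CET, CAD per QALY or LY) expresses the payer's opportunity cost.
Sequences are ranked by NHB and reported incrementally against a "no ARPI"
reference sequence; acceptability curves give the probability, over
bootstrap iterations, that each strategy group attains the highest NHB at
each CET.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import CostTable, SimulationConfig

__all__ = [
    "compute_nhb",
    "rank_sequences",
    "acceptability_curve",
    "tornado_threshold",
    "ScenarioConfig",
    "apply_scenario",
    "default_cet_grid",
    "SCENARIOS",
]


def compute_nhb(benefit: float, cost: float, cet: float) -> float:
    """Net health benefit = benefit - cost / cet, in benefit units."""
    if cet <= 0:
        raise ValueError("the cost-effectiveness threshold must be positive")
    return benefit - cost / cet


def rank_sequences(results, cet: float, reference_label: str) -> pd.DataFrame:
    """Rank sequences by NHB at one CET, incremental to a reference.

    ``results`` is a DataFrame (or list of mappings) with columns ``label``,
    ``benefit``, ``cost`` and optionally ``arpi_use``. Rows are sorted by
    descending NHB with ties broken by lower cost, then label; incremental
    columns are relative to ``reference_label``.
    """
    df = pd.DataFrame(results).copy()
    if reference_label not in set(df["label"]):
        raise ValueError(f"reference sequence {reference_label!r} not in results")
    df["nhb"] = df["benefit"] - df["cost"] / cet
    ref = df.loc[df["label"] == reference_label].iloc[0]
    df["incremental_benefit"] = df["benefit"] - ref["benefit"]
    df["incremental_cost"] = df["cost"] - ref["cost"]
    df["incremental_nhb"] = df["nhb"] - ref["nhb"]
    df = df.sort_values(["nhb", "cost", "label"],
                        ascending=[False, True, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def default_cet_grid(lo: float = 1_000, hi: float = 300_000,
                     step: float = 1_000) -> np.ndarray:
    """Default CET grid, CAD 1K to 300K per benefit unit in 1K steps."""
    return np.arange(lo, hi + step / 2, step, dtype=float)


def acceptability_curve(outcomes: dict, cet_grid=None, iterations: int = 2000,
                        iteration_size: int = 100,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Probability each strategy group is most cost-effective, per CET.

    ``outcomes`` maps group label -> (benefit, cost) per-patient arrays
    (pooled over the group's sequences). Each iteration bootstraps
    ``iteration_size`` patients per group, computes the group's mean benefit
    and cost, and records which group attains the highest NHB at each CET
    (ties broken by lower mean cost, then label). The returned frame is
    indexed by CET with one column per group; rows sum to 1.
    """
    if cet_grid is None:
        cet_grid = default_cet_grid()
    cet_grid = np.asarray(cet_grid, dtype=float)
    if cet_grid.size == 0:
        raise ValueError("empty CET grid")
    groups = sorted(outcomes)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mean_b = np.empty((len(groups), iterations))
    mean_c = np.empty((len(groups), iterations))
    for gi, g in enumerate(groups):
        benefit, cost = (np.asarray(a, dtype=float) for a in outcomes[g])
        if benefit.size < iteration_size:
            raise ValueError(
                f"group {g!r} has {benefit.size} patients, fewer than the "
                f"iteration size {iteration_size}")
        idx = rng.integers(0, benefit.size, size=(iterations, iteration_size))
        mean_b[gi] = benefit[idx].mean(axis=1)
        mean_c[gi] = cost[idx].mean(axis=1)
    # NHB per (group, iteration, cet); argmax over groups with tie-break
    nhb = mean_b[:, :, None] - mean_c[:, :, None] / cet_grid[None, None, :]
    order = np.lexsort((  # last key is primary
        np.broadcast_to(np.arange(len(groups))[:, None, None], nhb.shape),
        np.broadcast_to(mean_c[:, :, None], nhb.shape),
        -nhb), axis=0)
    winner = order[0]
    frac = np.stack([(winner == gi).mean(axis=0) for gi in range(len(groups))],
                    axis=1)
    return pd.DataFrame(frac, index=pd.Index(cet_grid, name="cet"), columns=groups)


def tornado_threshold(ac: pd.Series, coverage: float = 0.99):
    """Lowest CET at which a group's win probability exceeds ``coverage``.

    ``ac`` is one column of :func:`acceptability_curve` (indexed by CET).
    Returns the CET, or ``None`` when the coverage is never reached.
    """
    if len(ac) == 0:
        raise ValueError("empty acceptability series")
    above = ac[ac > coverage]
    return None if above.empty else float(above.index[0])


@dataclass(frozen=True)
class ScenarioConfig:
    """A named sensitivity scenario: horizon, discounting, prices, currency.

    ``cad_per_unit`` converts the scenario currency to CAD so CETs stated in
    local currency can be compared on the CAD grid. ``price_override`` maps
    drug name to monthly cost; unlisted drugs keep base prices.
    """

    name: str
    horizon: int = 180
    annual_discount: float = 0.015
    price_override: dict = field(default_factory=dict)
    cad_per_unit: float = 1.0
    currency: str = "CAD"


# US/UK price tables are editable placeholders (the published US Veterans
# Affairs / wholesale and UK public tariffs are not redistributed here);
# values are synthetic and flagged as such.
_US_VA_PRICES = {"synthetic": True, "abi": 500.0, "apa": 4200.0, "daro": 4200.0,
                 "enza": 4200.0, "doce": 120.0, "caba": 4500.0, "adt": 350.0}
_US_PRIVATE_PRICES = {"synthetic": True, "abi": 4500.0, "apa": 6000.0,
                      "daro": 6000.0, "enza": 6000.0, "doce": 200.0,
                      "caba": 6500.0, "adt": 400.0}
_UK_PUBLIC_PRICES = {"synthetic": True, "abi": 1500.0, "apa": 3000.0,
                     "daro": 3000.0, "enza": 1000.0, "doce": 90.0,
                     "caba": 3500.0, "adt": 250.0}

SCENARIOS = {
    "base": ScenarioConfig(name="base"),
    "horizon10": ScenarioConfig(name="horizon10", horizon=120),
    "horizon20": ScenarioConfig(name="horizon20", horizon=240),
    "price_equalized": ScenarioConfig(
        name="price_equalized",
        price_override={"apa": 919.0, "daro": 919.0, "enza": 919.0}),
    "us_va": ScenarioConfig(name="us_va", annual_discount=0.03,
                            price_override=_US_VA_PRICES,
                            cad_per_unit=1.3698, currency="USD"),
    "us_private": ScenarioConfig(name="us_private", annual_discount=0.03,
                                 price_override=_US_PRIVATE_PRICES,
                                 cad_per_unit=1.3698, currency="USD"),
    "uk_public": ScenarioConfig(name="uk_public", annual_discount=0.035,
                                price_override=_UK_PUBLIC_PRICES,
                                cad_per_unit=1.7504, currency="GBP"),
}


@dataclass(frozen=True)
class ResolvedScenario:
    """A scenario applied to a base configuration, ready to simulate."""

    scenario: ScenarioConfig
    config: SimulationConfig
    costs: CostTable
    cet_grid_cad: np.ndarray


def apply_scenario(base_config: SimulationConfig | None = None,
                   base_costs: CostTable | None = None,
                   scenario="base", cet_grid=None) -> ResolvedScenario:
    """Resolve a named (or explicit) scenario into a runnable configuration.

    The price-equalised scenario lowers apalutamide, darolutamide and
    enzalutamide to abiraterone's monthly cost; US/UK payer scenarios swap
    price tables and discount rates and carry a currency conversion for CET
    comparison. Unlisted prices keep their base values.
    """
    base_config = base_config or SimulationConfig()
    base_costs = base_costs or CostTable()
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(f"unknown scenario {scenario!r}; "
                             f"choose from {sorted(SCENARIOS)}") from None
    drug = dict(base_costs.drug)
    for name, price in scenario.price_override.items():
        if name == "synthetic":
            continue
        drug[name] = price * scenario.cad_per_unit
    costs = replace(base_costs, drug=drug)
    config = replace(base_config, horizon=scenario.horizon,
                     annual_discount=scenario.annual_discount)
    if cet_grid is None:
        cet_grid = default_cet_grid()
    return ResolvedScenario(scenario=scenario, config=config, costs=costs,
                            cet_grid_cad=np.asarray(cet_grid, dtype=float))
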