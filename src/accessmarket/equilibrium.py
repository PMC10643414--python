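"""Steady-state biomass from policy functions and stock growth curves.

A country's counterfactual equilibrium biomass is the stable intersection of
its total-catch policy function with its Pella-Tomlinson growth curve: below
the crossing growth exceeds harvest and the stock rises, above it harvest
exceeds growth and the stock falls.  The crossing is located by a sign scan
on a refined grid followed by bracketed root refinement; an ambiguous market
(no stable crossing, or several) raises rather than silently picking one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .biology import StockBio
from .calibration import UnitScales
from .errors import DomainError, MultipleEquilibriaError, NoEquilibriumError, ValidationError
from .oligopoly import MarketState
from .policy import PolicyFunction

__all__ = [
    "CountryEquilibrium",
    "ScenarioResult",
    "find_equilibrium_biomass",
    "summarize_scenario",
    "percent_change",
]

#: Aggregate fields of a scenario summary (all annual, USD 2020 where priced).
AGGREGATE_KEYS = (
    "access_catch_tons",
    "nonaccess_catch_tons",
    "total_catch_tons",
    "biomass_tons",
    "fee_usd_per_ton",
    "seller_profit_usd",
    "buyer_profit_usd",
)


@dataclass(frozen=True)
class CountryEquilibrium:
    country: str
    scenario: str
    biomass: float          # tons
    access_catch: float     # tons/yr
    nonaccess_catch: float  # tons/yr
    total_catch: float      # tons/yr
    growth_at_b: float      # tons/yr


@dataclass
class ScenarioResult:
    """Per-country equilibria plus continent-level aggregates for one scenario."""

    scenario: str
    countries: pd.DataFrame
    aggregates: dict[str, float]
    extras: dict[str, float] = field(default_factory=dict)

    def pct_diff(self, reference: "ScenarioResult") -> dict[str, float]:
        """Percent difference of each aggregate versus a reference scenario."""
        return {
            key: percent_change(reference.aggregates[key], self.aggregates[key])
            for key in AGGREGATE_KEYS
        }

    def table_vs(self, reference: "ScenarioResult") -> pd.DataFrame:
        """Summary table: reference, counterfactual, difference, % difference."""
        rows = []
        for key in AGGREGATE_KEYS:
            ref, cf = reference.aggregates[key], self.aggregates[key]
            rows.append(
                {
                    "quantity": key,
                    reference.scenario: ref,
                    self.scenario: cf,
                    "difference": cf - ref,
                    "pct_difference": percent_change(ref, cf),
                }
            )
        return pd.DataFrame(rows)


def percent_change(reference: float, counterfactual: float) -> float:
    """``100 * (counterfactual - reference) / reference``.

    Not antisymmetric under swapping arguments; the reference is always the
    denominator.
    """
    if reference == 0:
        raise DomainError("percent change undefined for zero reference")
    return 100.0 * (counterfactual - reference) / reference


def find_equilibrium_biomass(
    policy: PolicyFunction,
    stock: StockBio,
    tol: float = 1e-6,
    refine: int = 20,
) -> CountryEquilibrium:
    """Stable crossing of growth and total-catch policy.

    Scans ``refine`` subdivisions of each policy-grid cell (clipped to the
    stock's [grid start, k] range) for sign changes of growth minus harvest,
    keeps the stable ones (positive to negative), and refines the unique
    stable crossing by Brent's method to ``tol * k``.
    """
    lo = policy.biomass_grid[0]
    hi = min(policy.biomass_grid[-1], stock.k)
    if hi <= lo:
        raise NoEquilibriumError(
            f"{policy.country}: policy grid and growth domain do not overlap"
        )
    b_scan = np.unique(
        np.concatenate(
            [
                np.linspace(lo, hi, refine * policy.biomass_grid.size),
                policy.biomass_grid[policy.biomass_grid <= hi],
            ]
        )
    )
    diff = stock.growth(b_scan) - policy.total(b_scan)
    sign = np.sign(diff)
    # stable crossing: growth above harvest on the left, below on the right
    stable = np.flatnonzero((sign[:-1] > 0) & (sign[1:] <= 0))
    if stable.size == 0:
        raise NoEquilibriumError(
            f"{policy.country}/{policy.scenario}: growth never crosses total "
            f"catch from above on [{lo:.6g}, {hi:.6g}]; "
            f"diff range [{diff.min():.6g}, {diff.max():.6g}]"
        )
    if stable.size > 1:
        crossings = [
            0.5 * (b_scan[i] + b_scan[i + 1]) for i in stable
        ]
        raise MultipleEquilibriaError(
            f"{policy.country}/{policy.scenario}: multiple stable crossings "
            f"near biomasses {crossings}"
        )
    i = stable[0]
    f = lambda b: stock.growth(b) - policy.total(b)
    if diff[i + 1] == 0:
        b_star = float(b_scan[i + 1])
    else:
        b_star = float(brentq(f, b_scan[i], b_scan[i + 1], xtol=tol * stock.k))
    return CountryEquilibrium(
        country=policy.country,
        scenario=policy.scenario,
        biomass=b_star,
        access_catch=float(policy.access(b_star)),
        nonaccess_catch=float(policy.nonaccess(b_star)),
        total_catch=float(policy.total(b_star)),
        growth_at_b=float(stock.growth(b_star)),
    )


def summarize_scenario(
    equilibria: list[CountryEquilibrium],
    market_solution: MarketState,
    scales: UnitScales,
    seller_profit_units: float | None = None,
    extras: dict[str, float] | None = None,
) -> ScenarioResult:
    """Assemble a scenario's per-country table and continent-level aggregates.

    Catch and biomass aggregates sum the per-country equilibria; the fee and
    profits come from the scenario's market solution, converted through the
    status-quo unit anchors.  ``seller_profit_units`` overrides the summed
    per-seller profit when the market's sellers are merged coalitions.
    """
    if not equilibria:
        raise ValidationError("no country equilibria to summarize")
    scenarios = {e.scenario for e in equilibria}
    if len(scenarios) > 1:
        raise ValidationError(f"mixed scenarios in equilibria: {sorted(scenarios)}")
    (scenario,) = scenarios

    countries = pd.DataFrame(
        {
            "country": [e.country for e in equilibria],
            "biomass_tons": [e.biomass for e in equilibria],
            "access_tons": [e.access_catch for e in equilibria],
            "nonaccess_tons": [e.nonaccess_catch for e in equilibria],
            "total_tons": [e.total_catch for e in equilibria],
        }
    )
    if seller_profit_units is None:
        seller_profit_units = sum(s.profit for s in market_solution.sellers)
    buyer_profit_units = sum(b.profit for b in market_solution.buyers)
    aggregates = {
        "access_catch_tons": float(countries["access_tons"].sum()),
        "nonaccess_catch_tons": float(countries["nonaccess_tons"].sum()),
        "total_catch_tons": float(countries["total_tons"].sum()),
        "biomass_tons": float(countries["biomass_tons"].sum()),
        "fee_usd_per_ton": float(scales.fee_units_to_usd(market_solution.price)),
        "seller_profit_usd": float(scales.profit_units_to_usd(seller_profit_units)),
        "buyer_profit_usd": float(scales.profit_units_to_usd(buyer_profit_units)),
    }
    return ScenarioResult(
        scenario=scenario,
        countries=countries,
        aggregates=aggregates,
        extras=dict(extras or {}),
    )
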