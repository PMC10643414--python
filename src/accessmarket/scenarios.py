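"""Scenario orchestration: status quo, coalitions, PNA reversal, robustness.

Each scenario follows the same pipeline: solve the bilateral-oligopoly Nash
equilibrium in share units, derive per-country catch policy functions,
intersect total-catch policies with growth curves to obtain steady-state
biomass, and summarize fee / catch / profit / biomass aggregates against a
reference scenario.  Counterfactual fees and profits are evaluated by
re-solving the market once at the scenario's equilibrium biomass shares
(each merged seller's true share equals its equilibrium biomass divided by
status-quo total biomass).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibratedMarket,
    UnitScales,
    build_market,
    build_scales,
    identify_participants,
    solve_calibrated,
)
from .biology import DEFAULT_DEPLETION, DEFAULT_PHI
from .equilibrium import (
    CountryEquilibrium,
    ScenarioResult,
    find_equilibrium_biomass,
    summarize_scenario,
)
from .errors import DomainError, ValidationError
from .oligopoly import MarketParams, MarketState, solve_buyer_reports, solve_nash
from .policy import (
    PolicyFunction,
    derive_access_policy,
    derive_coalition_access_policy,
    derive_regional_access_policy,
    nonaccess_slope,
    repair_negative_slope,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioRun",
    "run_status_quo",
    "run_continental",
    "run_regional",
    "run_pna",
    "assign_regions",
    "sweep",
]

_SCENARIO_NAMES = {"status_quo", "continental", "regional", "pna_dissolution"}


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one scenario run."""

    name: str
    params: MarketParams = MarketParams()
    depletion: float = DEFAULT_DEPLETION
    region_map: dict[str, str] | None = None
    access_fraction: float = 1.0
    coalition_true_share: float | None = None  # emergent output, never an input

    def __post_init__(self) -> None:
        if self.name not in _SCENARIO_NAMES:
            raise ValidationError(f"unknown scenario '{self.name}'")
        if not (0 < self.access_fraction <= 1):
            raise DomainError("access_fraction must lie in (0, 1]")
        if (self.region_map is not None) != (self.name == "regional"):
            raise ValidationError("region_map present iff scenario is regional")


@dataclass
class ScenarioRun:
    """Everything one scenario produced, for reuse by dependent scenarios."""

    market: CalibratedMarket
    solution: MarketState
    scales: UnitScales
    buyer_reports: np.ndarray
    policies: dict[str, PolicyFunction]
    slopes: dict[str, float]
    equilibria: list[CountryEquilibrium]
    result: ScenarioResult
    grid_pct: float = 1.0
    extras: dict = field(default_factory=dict)


def _nonaccess_slopes(
    market: CalibratedMarket, q_star_tons: np.ndarray
) -> dict[str, float]:
    """Per-country non-access slopes with negative-slope repair."""
    raw = np.array(
        [
            nonaccess_slope(market.stocks[cid].h, q_star_tons[i], market.stocks[cid].b)
            for i, cid in enumerate(market.seller_ids)
        ]
    )
    if (raw < 0).any():
        bad = [c for c, s in zip(market.seller_ids, raw) if s < 0]
        warnings.warn(
            f"negative non-access slope repaired for: {bad}", stacklevel=2
        )
    repaired = repair_negative_slope(raw)
    return dict(zip(market.seller_ids, repaired))


def _solve_at_equilibrium_shares(
    market: CalibratedMarket,
    buyer_reports: np.ndarray,
    group_biomass_tons: np.ndarray,
    seller_ids: list[str],
) -> MarketState:
    """Re-solve the market with merged sellers at equilibrium biomass shares."""
    shares = group_biomass_tons / market.total_biomass_tons
    return solve_nash(
        shares,
        market.buyer_shares,
        market.params,
        seller_ids=seller_ids,
        buyer_ids=market.buyer_ids,
        buyer_reports=buyer_reports,
    )


# --------------------------------------------------------------------------
# status quo
# --------------------------------------------------------------------------

def run_status_quo(
    market: CalibratedMarket,
    anchor_buyer_id: str | None = None,
    anchor_purchase_tons: float | None = None,
    anchor_fee_usd: float | None = None,
    scales: UnitScales | None = None,
    grid_pct: float = 1.0,
) -> ScenarioRun:
    """Individual-seller baseline: every coastal state reports on its own.

    Builds the unit anchors from the solved market (unless ``scales`` is
    supplied), derives per-country policy functions and non-access slopes,
    and recovers each country's steady-state biomass — which, by
    construction, equals its calibrated biomass.
    """
    buyer_reports = solve_buyer_reports(market.buyer_shares, market.params)
    solution = solve_calibrated(market, buyer_reports=buyer_reports)
    if scales is None:
        if anchor_buyer_id is None or anchor_purchase_tons is None or anchor_fee_usd is None:
            raise ValidationError(
                "either scales or (anchor_buyer_id, anchor_purchase_tons, "
                "anchor_fee_usd) must be given"
            )
        scales = build_scales(solution, anchor_buyer_id, anchor_purchase_tons, anchor_fee_usd)

    q_star_tons = np.array(
        [float(scales.qty_units_to_tons(s.q_access)) for s in solution.sellers]
    )
    slopes = _nonaccess_slopes(market, q_star_tons)

    policies: dict[str, PolicyFunction] = {}
    equilibria: list[CountryEquilibrium] = []
    for cid in market.seller_ids:
        pol = derive_access_policy(
            cid, market, scales, grid_pct=grid_pct, buyer_reports=buyer_reports
        ).with_nonaccess_slope(slopes[cid])
        policies[cid] = pol
        equilibria.append(find_equilibrium_biomass(pol, market.stocks[cid]))

    result = summarize_scenario(equilibria, solution, scales)
    result.extras["access_quantity_units"] = solution.quantity
    result.extras["fee_units"] = solution.price
    result.extras["total_report_units"] = solution.B_hat
    return ScenarioRun(
        market=market,
        solution=solution,
        scales=scales,
        buyer_reports=buyer_reports,
        policies=policies,
        slopes=slopes,
        equilibria=equilibria,
        result=result,
        grid_pct=grid_pct,
    )


# --------------------------------------------------------------------------
# continental coalition
# --------------------------------------------------------------------------

def run_continental(sq: ScenarioRun, grid_pct: float | None = None) -> ScenarioRun:
    """All sellers merge into one coalition; buyers unchanged.

    The coalition's true biomass share is an *output*: it equals the summed
    equilibrium biomass divided by status-quo total biomass, emerging from
    the policy-function / growth-curve intersections.
    """
    market, scales = sq.market, sq.scales
    grid_pct = grid_pct or sq.grid_pct
    apportion = market.seller_biomass_tons / market.total_biomass_tons
    cpols = derive_coalition_access_policy(
        market, scales, apportion, grid_pct=grid_pct, buyer_reports=sq.buyer_reports
    )
    policies = {
        cid: cpols[cid].with_nonaccess_slope(sq.slopes[cid])
        for cid in market.seller_ids
    }
    equilibria = [
        find_equilibrium_biomass(policies[cid], market.stocks[cid])
        for cid in market.seller_ids
    ]
    eq_biomass = np.array([e.biomass for e in equilibria])
    coalition_share = float(eq_biomass.sum() / market.total_biomass_tons)
    solution = _solve_at_equilibrium_shares(
        market, sq.buyer_reports, np.array([eq_biomass.sum()]), ["coalition"]
    )
    result = summarize_scenario(equilibria, solution, scales)
    result.extras["coalition_true_share"] = coalition_share
    result.extras["access_quantity_units"] = solution.quantity
    result.extras["fee_units"] = solution.price
    result.extras["total_report_units"] = solution.B_hat
    return ScenarioRun(
        market=market,
        solution=solution,
        scales=scales,
        buyer_reports=sq.buyer_reports,
        policies=policies,
        slopes=sq.slopes,
        equilibria=equilibria,
        result=result,
        grid_pct=grid_pct,
        extras={"coalition_true_share": coalition_share},
    )


# --------------------------------------------------------------------------
# regional coalitions
# --------------------------------------------------------------------------

def assign_regions(
    membership: dict[str, list[str]],
    sellers: list[str],
    exclude: tuple[str, ...] = (),
    reassign: dict[str, str] | None = None,
) -> dict[str, str]:
    """Map each selling country to exactly one regional bloc.

    Iterates blocs in ascending order of selling-country membership
    (alphabetical on ties, with a warning), assigning each bloc's members
    unless already assigned.  ``reassign`` forces specific countries into a
    named region afterwards; sellers in no bloc become their own singleton
    region.
    """
    reassign = reassign or {}
    seller_set = set(sellers)
    candidates = {
        rec: [c for c in members if c in seller_set]
        for rec, members in membership.items()
        if rec not in exclude
    }
    sizes = sorted((len(m), rec) for rec, m in candidates.items())
    tied = {
        a[1] for a, b in itertools.pairwise(sizes) if a[0] == b[0]
    } | {b[1] for a, b in itertools.pairwise(sizes) if a[0] == b[0]}
    if tied:
        warnings.warn(
            f"REC size ties broken alphabetically among: {sorted(tied)}",
            stacklevel=2,
        )
    region_map: dict[str, str] = {}
    for _, rec in sizes:
        for country in candidates[rec]:
            region_map.setdefault(country, rec)
    for country, rec in reassign.items():
        if country in seller_set:
            region_map[country] = rec
    for country in sellers:
        region_map.setdefault(country, country)  # singleton fallback
    return region_map


def run_regional(
    sq: ScenarioRun, region_map: dict[str, str], grid_pct: float | None = None
) -> ScenarioRun:
    """One merged seller per regional bloc; within-bloc apportionment by biomass."""
    market, scales = sq.market, sq.scales
    grid_pct = grid_pct or sq.grid_pct
    rpols = derive_regional_access_policy(
        market, region_map, scales, grid_pct=grid_pct, buyer_reports=sq.buyer_reports
    )
    policies = {
        cid: rpols[cid].with_nonaccess_slope(sq.slopes[cid])
        for cid in market.seller_ids
    }
    equilibria = [
        find_equilibrium_biomass(policies[cid], market.stocks[cid])
        for cid in market.seller_ids
    ]
    eq_b = {e.country: e.biomass for e in equilibria}
    regions = sorted({region_map[c] for c in market.seller_ids})
    region_biomass = np.array(
        [sum(eq_b[c] for c in market.seller_ids if region_map[c] == r) for r in regions]
    )
    solution = _solve_at_equilibrium_shares(
        market, sq.buyer_reports, region_biomass, regions
    )
    result = summarize_scenario(equilibria, solution, scales)
    result.extras["access_quantity_units"] = solution.quantity
    result.extras["fee_units"] = solution.price
    result.extras["total_report_units"] = solution.B_hat
    return ScenarioRun(
        market=market,
        solution=solution,
        scales=scales,
        buyer_reports=sq.buyer_reports,
        policies=policies,
        slopes=sq.slopes,
        equilibria=equilibria,
        result=result,
        grid_pct=grid_pct,
        extras={"region_map": dict(region_map)},
    )


# --------------------------------------------------------------------------
# PNA dissolution
# --------------------------------------------------------------------------

def run_pna(
    seller_table: pd.DataFrame,
    buyer_table: pd.DataFrame,
    foreign_catch_tons: float,
    access_fraction: float = 1.0,
    anchor_fee_usd: float = 307.0,
    params: MarketParams | None = None,
    depletion: float = DEFAULT_DEPLETION,
    phi: float = DEFAULT_PHI,
    grid_pct: float = 1.0,
) -> tuple[ScenarioRun, ScenarioRun]:
    """Bloc-selling Pacific market: coalition is the status quo, dissolution
    the counterfactual.

    ``access_fraction`` of observed foreign catch is treated as access catch
    (1.0 in the main specification, 0.5 as robustness).  The quantity anchor
    is the coalition equilibrium quantity against that access catch; the fee
    anchor is the observed weighted-average access fee (default $307/ton).
    Countries whose apportioned access exceeds observed total catch get a
    repaired (peer-average) non-access slope.  Returns
    ``(coalition_run, dissolution_run)`` with the coalition as reference.
    """
    if not (0 < access_fraction <= 1):
        raise DomainError("access_fraction must lie in (0, 1]")
    params = params or MarketParams()
    market = build_market(seller_table, buyer_table, params, depletion=depletion, phi=phi)
    buyer_reports = solve_buyer_reports(market.buyer_shares, params)

    # coalition reference: single seller with true share 1
    sol_c = solve_nash(
        np.array([1.0]), market.buyer_shares, params,
        seller_ids=["coalition"], buyer_ids=market.buyer_ids,
        buyer_reports=buyer_reports,
    )
    access_tons = access_fraction * foreign_catch_tons
    scales = UnitScales(
        qty_anchor_units=sol_c.quantity,
        qty_anchor_tons=access_tons,
        fee_anchor_units=sol_c.price,
        fee_anchor_usd=anchor_fee_usd,
    )
    apportion = market.seller_biomass_tons / market.total_biomass_tons
    q_star_tons = apportion * access_tons
    slopes = _nonaccess_slopes(market, q_star_tons)

    cpols = derive_coalition_access_policy(
        market, scales, apportion, grid_pct=grid_pct,
        buyer_reports=buyer_reports, scenario="pna_coalition",
    )
    cpolicies = {c: cpols[c].with_nonaccess_slope(slopes[c]) for c in market.seller_ids}
    c_equilibria = [
        find_equilibrium_biomass(cpolicies[c], market.stocks[c])
        for c in market.seller_ids
    ]
    c_biomass = np.array([e.biomass for e in c_equilibria])
    c_solution = _solve_at_equilibrium_shares(
        market, buyer_reports, np.array([c_biomass.sum()]), ["coalition"]
    )
    c_result = summarize_scenario(c_equilibria, c_solution, scales)
    coalition = ScenarioRun(
        market=market, solution=c_solution, scales=scales,
        buyer_reports=buyer_reports, policies=cpolicies, slopes=slopes,
        equilibria=c_equilibria, result=c_result, grid_pct=grid_pct,
        extras={"access_fraction": access_fraction},
    )

    # dissolution counterfactual: members sell individually
    ipolicies: dict[str, PolicyFunction] = {}
    i_equilibria: list[CountryEquilibrium] = []
    for cid in market.seller_ids:
        pol = derive_access_policy(
            cid, market, scales, grid_pct=grid_pct,
            buyer_reports=buyer_reports, scenario="pna_dissolved",
        ).with_nonaccess_slope(slopes[cid])
        ipolicies[cid] = pol
        i_equilibria.append(find_equilibrium_biomass(pol, market.stocks[cid]))
    i_biomass = np.array([e.biomass for e in i_equilibria])
    i_solution = _solve_at_equilibrium_shares(
        market, buyer_reports, i_biomass, market.seller_ids
    )
    i_result = summarize_scenario(i_equilibria, i_solution, scales)
    dissolution = ScenarioRun(
        market=market, solution=i_solution, scales=scales,
        buyer_reports=buyer_reports, policies=ipolicies, slopes=slopes,
        equilibria=i_equilibria, result=i_result, grid_pct=grid_pct,
        extras={"access_fraction": access_fraction},
    )
    return coalition, dissolution


# --------------------------------------------------------------------------
# robustness sweeps
# --------------------------------------------------------------------------

def sweep(
    seller_table: pd.DataFrame,
    buyer_table: pd.DataFrame,
    anchor_buyer_id: str,
    anchor_purchase_tons: float,
    anchor_fee_usd: float,
    etas=(1.0,),
    epsilons=(2.0,),
    depletions=(DEFAULT_DEPLETION,),
    thresholds=(None,),
    hours: pd.DataFrame | None = None,
    phi: float = DEFAULT_PHI,
    grid_pct: float = 1.0,
) -> pd.DataFrame:
    """Status-quo + continental run per grid point; tabulated aggregate deltas.

    A non-None threshold re-identifies participants from the hours table and
    restricts both sides of the market accordingly.  Invalid grid points are
    skipped with a warning.
    """
    rows = []
    for eta, eps, d, thr in itertools.product(etas, epsilons, depletions, thresholds):
        try:
            params = MarketParams(eta=eta, epsilon=eps)
            s_tab, b_tab = seller_table, buyer_table
            if thr is not None:
                if hours is None:
                    raise ValidationError("threshold sweep requires an hours table")
                sellers, buyers = identify_participants(hours, threshold=thr)
                s_tab = seller_table[seller_table["id"].isin(sellers)]
                b_tab = buyer_table[buyer_table["id"].isin(buyers)]
            market = build_market(s_tab, b_tab, params, depletion=d, phi=phi)
            sq = run_status_quo(
                market, anchor_buyer_id, anchor_purchase_tons, anchor_fee_usd,
                grid_pct=grid_pct,
            )
            co = run_continental(sq)
        except (DomainError, ValidationError) as exc:
            warnings.warn(
                f"skipping grid point (eta={eta}, eps={eps}, d={d}, thr={thr}): {exc}",
                stacklevel=2,
            )
            continue
        row = {"eta": eta, "epsilon": eps, "depletion": d, "threshold": thr}
        for key, val in sq.result.aggregates.items():
            row[f"sq_{key}"] = val
        for key, val in co.result.aggregates.items():
            row[f"co_{key}"] = val
        for key, val in co.result.pct_diff(sq.result).items():
            row[f"pct_{key}"] = val
        row["sq_report_units"] = sq.solution.B_hat
        row["co_report_units"] = co.solution.B_hat
        row["coalition_true_share"] = co.extras["coalition_true_share"]
        rows.append(row)
    return pd.DataFrame(rows)
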