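"""Numerical derivation of access / non-access / total catch policy functions.

A country's access policy function maps its stock biomass to the access
catch it would allow at the market equilibrium: hold everything else fixed,
replace the country's biomass with a grid value (rescaling its model share
proportionally), re-solve the Nash equilibrium, convert the total access
quantity to tons, and assign the country its reported share of the total.
The grid runs from 1% to 100% of the relevant carrying capacity in steps of
``grid_pct`` percent.

Non-access catch (domestic plus unauthorized foreign catch) is modeled as
linear through the origin with slope ``(h - q*) / b`` fixed at the
status-quo point, so access + non-access reproduces observed catch at the
calibrated biomass.  A negative slope (access exceeding observed total
catch) is repaired by substituting the mean slope of the other countries.

Coalition and regional variants grid the merged seller's biomass and
apportion the total access quantity to member countries in proportion to
their status-quo true biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import CalibratedMarket, UnitScales, rescale_share
from .errors import DomainError, ValidationError
from .oligopoly import solve_buyer_reports, solve_seller_reports
from . import oligopoly

__all__ = [
    "PolicyFunction",
    "nonaccess_slope",
    "repair_negative_slope",
    "derive_access_policy",
    "derive_coalition_access_policy",
    "derive_regional_access_policy",
]


@dataclass(frozen=True)
class PolicyFunction:
    """Tabulated catch-vs-biomass mapping for one country under one scenario."""

    country: str
    scenario: str
    biomass_grid: np.ndarray   # tons, ascending
    access_catch: np.ndarray   # tons/yr
    nonaccess_catch: np.ndarray  # tons/yr

    def __post_init__(self) -> None:
        g = np.asarray(self.biomass_grid, dtype=float)
        a = np.asarray(self.access_catch, dtype=float)
        n = np.asarray(self.nonaccess_catch, dtype=float)
        if not (g.shape == a.shape == n.shape) or g.ndim != 1 or g.size < 2:
            raise ValidationError("policy arrays must be 1-D, equal length >= 2")
        if np.any(np.diff(g) <= 0):
            raise ValidationError("biomass grid must be strictly ascending")
        if np.any(a < -1e-9) or np.any(n < -1e-9):
            raise ValidationError("catches must be non-negative")
        object.__setattr__(self, "biomass_grid", g)
        object.__setattr__(self, "access_catch", a)
        object.__setattr__(self, "nonaccess_catch", n)

    @property
    def total_catch(self) -> np.ndarray:
        return self.access_catch + self.nonaccess_catch

    def with_nonaccess_slope(self, slope: float) -> "PolicyFunction":
        """Attach a linear-through-origin non-access policy."""
        if slope < 0:
            raise DomainError("non-access slope must be non-negative (repair first)")
        return replace(self, nonaccess_catch=slope * self.biomass_grid)

    def _interp(self, b, values) -> np.ndarray | float:
        b_arr = np.asarray(b, dtype=float)
        lo, hi = self.biomass_grid[0], self.biomass_grid[-1]
        if np.any(b_arr < lo - 1e-9 * hi) or np.any(b_arr > hi * (1 + 1e-12)):
            raise DomainError(
                f"biomass outside tabulated range [{lo:.6g}, {hi:.6g}] "
                f"for {self.country}/{self.scenario}; extrapolation forbidden"
            )
        out = np.interp(b_arr, self.biomass_grid, values)
        return float(out) if out.ndim == 0 else out

    def access(self, b):
        """Access catch at biomass ``b`` by linear interpolation."""
        return self._interp(b, self.access_catch)

    def nonaccess(self, b):
        return self._interp(b, self.nonaccess_catch)

    def total(self, b):
        return self._interp(b, self.total_catch)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": self.country,
                "scenario": self.scenario,
                "biomass_tons": self.biomass_grid,
                "access_tons": self.access_catch,
                "nonaccess_tons": self.nonaccess_catch,
                "total_tons": self.total_catch,
            }
        )


# --------------------------------------------------------------------------
# non-access policy
# --------------------------------------------------------------------------

def nonaccess_slope(h: float, q_star: float, b_true: float) -> float:
    """Slope of the linear non-access policy: ``(h - q*) / b``.

    ``h`` is observed mean annual total catch, ``q*`` the status-quo
    equilibrium access catch (both tons/yr), ``b_true`` calibrated biomass.
    May be negative when modeled access exceeds observed catch; callers
    repair such slopes before use.
    """
    if b_true <= 0:
        raise DomainError("true biomass must be positive")
    return (h - q_star) / b_true


def repair_negative_slope(slopes) -> np.ndarray:
    """Replace negative slopes by the mean of the non-negative ones.

    Negative non-access catch is impossible, so a country whose modeled
    access exceeds its observed catch inherits the average slope of the
    remaining countries.
    """
    s = np.asarray(slopes, dtype=float).copy()
    neg = s < 0
    if neg.all():
        raise DomainError("all non-access slopes negative: market unrecoverable")
    if neg.any():
        s[neg] = s[~neg].mean()
    return s


# --------------------------------------------------------------------------
# access policies by scenario
# --------------------------------------------------------------------------

def _grid_fractions(grid_pct: float) -> np.ndarray:
    if not (0 < grid_pct <= 100):
        raise DomainError("grid_pct must lie in (0, 100]")
    n = int(round(100.0 / grid_pct))
    return np.arange(1, n + 1) / n


def derive_access_policy(
    country: str,
    market: CalibratedMarket,
    scales: UnitScales,
    grid_pct: float = 1.0,
    buyer_reports: np.ndarray | None = None,
    tol: float = 1e-10,
    warm_start: bool = True,
    scenario: str = "status_quo",
) -> PolicyFunction:
    """Individual-seller access policy of one country.

    For each grid biomass (1% to 100% of the country's carrying capacity):
    rescale the country's model share proportionally to the new biomass,
    re-solve the Nash equilibrium with all other endowments fixed, convert
    the total access quantity to tons and assign the country its reported
    share.  Buyer-subgame reports are independent of seller endowments and
    are computed once and reused.
    """
    idx = market.seller_index(country)
    stock = market.stocks[country]
    grid = stock.k * _grid_fractions(grid_pct)
    if buyer_reports is None:
        buyer_reports = solve_buyer_reports(market.buyer_shares, market.params, tol=tol)
    T_hat = buyer_reports.sum()

    shares = market.seller_shares.astype(float).copy()
    base_share, base_b = shares[idx], stock.b
    access = np.empty_like(grid)
    init = None
    for gpos, b_new in enumerate(grid):
        shares[idx] = rescale_share(base_share, base_b, b_new)
        reports = solve_seller_reports(shares, market.params, tol=tol, init=init)
        if warm_start:
            init = reports
        B_hat = reports.sum()
        Q_units = oligopoly.clearing_quantity(B_hat, T_hat, market.params)
        access[gpos] = reports[idx] / B_hat * scales.qty_units_to_tons(Q_units)
    return PolicyFunction(
        country=country,
        scenario=scenario,
        biomass_grid=grid,
        access_catch=access,
        nonaccess_catch=np.zeros_like(grid),
    )


def derive_coalition_access_policy(
    market: CalibratedMarket,
    scales: UnitScales,
    apportion_shares: np.ndarray | None = None,
    grid_pct: float = 1.0,
    buyer_reports: np.ndarray | None = None,
    tol: float = 1e-10,
    scenario: str = "continental",
) -> dict[str, PolicyFunction]:
    """Coalition access policies, one per member country.

    A single merged seller's biomass runs from 1% to 100% of the summed
    carrying capacity; at each grid point the single-seller Nash equilibrium
    is re-solved and the total access quantity (tons) is apportioned to
    countries in proportion to their status-quo true biomass.  Each
    country's policy is tabulated against its apportioned biomass slice, so
    member grids and catches sum back to the coalition totals.
    """
    if apportion_shares is None:
        apportion_shares = market.seller_biomass_tons / market.total_biomass_tons
    apportion_shares = np.asarray(apportion_shares, dtype=float)
    if apportion_shares.shape != (market.n_sellers,) or not np.isclose(
        apportion_shares.sum(), 1.0
    ):
        raise ValidationError("apportion_shares must sum to 1 over sellers")

    total_k = float(sum(s.k for s in market.stocks.values()))
    total_b = market.total_biomass_tons
    grid = total_k * _grid_fractions(grid_pct)
    if buyer_reports is None:
        buyer_reports = solve_buyer_reports(market.buyer_shares, market.params, tol=tol)
    T_hat = buyer_reports.sum()

    # Single seller: its share equals sigma = 1 at every grid point, so the
    # report ratio is the closed-form monopoly ratio; solve anyway for
    # uniformity with the multi-seller path.
    access_total = np.empty_like(grid)
    for gpos, b_new in enumerate(grid):
        share = rescale_share(1.0, total_b, b_new)
        reports = solve_seller_reports(np.array([share]), market.params, tol=tol)
        Q_units = oligopoly.clearing_quantity(reports.sum(), T_hat, market.params)
        access_total[gpos] = scales.qty_units_to_tons(Q_units)

    out: dict[str, PolicyFunction] = {}
    for i, cid in enumerate(market.seller_ids):
        w = apportion_shares[i]
        out[cid] = PolicyFunction(
            country=cid,
            scenario=scenario,
            biomass_grid=w * grid,
            access_catch=w * access_total,
            nonaccess_catch=np.zeros_like(grid),
        )
    return out


def derive_regional_access_policy(
    market: CalibratedMarket,
    region_map: dict[str, str],
    scales: UnitScales,
    grid_pct: float = 1.0,
    buyer_reports: np.ndarray | None = None,
    tol: float = 1e-10,
) -> dict[str, PolicyFunction]:
    """Regional-coalition access policies, one per country.

    One merged seller per region.  Each region's biomass is gridded from 1%
    to 100% of the regional carrying capacity while the other regions stay
    at their status-quo endowments; the region's access catch is its
    reported share of the re-solved total, apportioned within the region by
    each member's share of regional status-quo biomass.
    """
    unmapped = [c for c in market.seller_ids if c not in region_map]
    if unmapped:
        raise ValidationError(f"sellers missing from region_map: {unmapped}")

    regions = sorted({region_map[c] for c in market.seller_ids})
    r_index = {r: pos for pos, r in enumerate(regions)}
    members: dict[str, list[int]] = {r: [] for r in regions}
    for i, cid in enumerate(market.seller_ids):
        members[region_map[cid]].append(i)

    biomass = market.seller_biomass_tons
    region_share = np.array(
        [market.seller_shares[members[r]].sum() for r in regions]
    )
    region_b = np.array([biomass[members[r]].sum() for r in regions])
    region_k = np.array(
        [sum(market.stocks[market.seller_ids[i]].k for i in members[r]) for r in regions]
    )

    if buyer_reports is None:
        buyer_reports = solve_buyer_reports(market.buyer_shares, market.params, tol=tol)
    T_hat = buyer_reports.sum()

    out: dict[str, PolicyFunction] = {}
    fracs = _grid_fractions(grid_pct)
    for r in regions:
        ri = r_index[r]
        grid = region_k[ri] * fracs
        shares = region_share.astype(float).copy()
        access_region = np.empty_like(grid)
        init = None
        for gpos, b_new in enumerate(grid):
            shares[ri] = rescale_share(region_share[ri], region_b[ri], b_new)
            reports = solve_seller_reports(shares, market.params, tol=tol, init=init)
            init = reports
            B_hat = reports.sum()
            Q_units = oligopoly.clearing_quantity(B_hat, T_hat, market.params)
            access_region[gpos] = reports[ri] / B_hat * scales.qty_units_to_tons(Q_units)
        for i in members[r]:
            w = biomass[i] / region_b[ri]
            out[market.seller_ids[i]] = PolicyFunction(
                country=market.seller_ids[i],
                scenario="regional",
                biomass_grid=w * grid,
                access_catch=w * access_region,
                nonaccess_catch=np.zeros_like(grid),
            )
    return out


def policies_to_frame(policies: dict[str, PolicyFunction]) -> pd.DataFrame:
    """Concatenate policy functions into one tidy CSV-ready table."""
    return pd.concat([p.to_frame() for p in policies.values()], ignore_index=True)
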