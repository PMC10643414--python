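"""Build a model-ready market from raw tables.

Responsibilities:

* participant identification from pairwise fishing-hours records (a foreign
  flag is a buyer if it exceeds the hours threshold in some coastal state's
  waters in some year; that coastal state is then a seller);
* distant-water-fleet (DWF) classification of vessels and buyer gross
  tonnage aggregation;
* carrying-capacity-weighted growth parameters;
* Pella-Tomlinson biomass calibration per seller;
* normalization of endowments into shares (the model's dimensionless units);
* the unit-scale anchors that translate model units back into tons/yr and
  2020 USD/ton.

CSV schemas (UTF-8, header row required):

* ``sellers.csv``: id,catch_tons,growth_g[,depletion,phi]
* ``buyers.csv``:  id,gross_tonnage
* ``hours.csv``:   buyer_flag,seller_eez,year,hours
* ``vessels.csv``: vessel_id,flag,hours_inside,hours_outside,gross_tonnage
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import oligopoly
from .biology import DEFAULT_DEPLETION, DEFAULT_PHI, StockBio, calibrate_stock
from .errors import DomainError, ValidationError
from .oligopoly import MarketParams, MarketState

#: Fishing-hours threshold (h) above which a flag/EEZ pair marks participation.
DEFAULT_THRESHOLD_HOURS = 2420.0

__all__ = [
    "UnitScales",
    "CalibratedMarket",
    "identify_participants",
    "classify_dwf",
    "buyer_tonnage",
    "weighted_growth",
    "normalize_shares",
    "rescale_share",
    "build_market",
    "build_scales",
    "load_config",
    "DEFAULT_THRESHOLD_HOURS",
]


@dataclass(frozen=True)
class UnitScales:
    """Linear anchors mapping model units to physical units.

    ``qty_anchor_units`` model units of access quantity correspond to
    ``qty_anchor_tons`` tons/yr, and ``fee_anchor_units`` fee model units to
    ``fee_anchor_usd`` 2020 USD/ton.  Both maps are linear through the
    origin.
    """

    qty_anchor_units: float
    qty_anchor_tons: float
    fee_anchor_units: float
    fee_anchor_usd: float

    def __post_init__(self) -> None:
        for name in ("qty_anchor_units", "qty_anchor_tons",
                     "fee_anchor_units", "fee_anchor_usd"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")

    # -- conversions -------------------------------------------------------
    def qty_units_to_tons(self, q_units):
        return np.asarray(q_units, dtype=float) * (self.qty_anchor_tons / self.qty_anchor_units)

    def qty_tons_to_units(self, q_tons):
        return np.asarray(q_tons, dtype=float) * (self.qty_anchor_units / self.qty_anchor_tons)

    def fee_units_to_usd(self, p_units):
        return np.asarray(p_units, dtype=float) * (self.fee_anchor_usd / self.fee_anchor_units)

    def fee_usd_to_units(self, p_usd):
        return np.asarray(p_usd, dtype=float) * (self.fee_anchor_units / self.fee_anchor_usd)

    def profit_units_to_usd(self, profit_units):
        """Profit is fee units x quantity units, so both anchors apply."""
        return (
            np.asarray(profit_units, dtype=float)
            * (self.fee_anchor_usd / self.fee_anchor_units)
            * (self.qty_anchor_tons / self.qty_anchor_units)
        )

    def profit_usd_to_units(self, profit_usd):
        return (
            np.asarray(profit_usd, dtype=float)
            * (self.fee_anchor_units / self.fee_anchor_usd)
            * (self.qty_anchor_units / self.qty_anchor_tons)
        )


@dataclass
class CalibratedMarket:
    """Model-ready market: shares, stocks, and the raw endowments behind them."""

    params: MarketParams
    seller_ids: list[str]
    buyer_ids: list[str]
    seller_shares: np.ndarray      # true biomass shares, sum to 1
    buyer_shares: np.ndarray       # true gross tonnage shares, sum to 1
    seller_biomass_tons: np.ndarray
    buyer_tonnage_gt: np.ndarray
    stocks: dict[str, StockBio]
    depletion: float = DEFAULT_DEPLETION
    phi: float = DEFAULT_PHI

    @property
    def n_sellers(self) -> int:
        return len(self.seller_ids)

    @property
    def n_buyers(self) -> int:
        return len(self.buyer_ids)

    @property
    def total_biomass_tons(self) -> float:
        return float(self.seller_biomass_tons.sum())

    def seller_index(self, country: str) -> int:
        return self.seller_ids.index(country)


# --------------------------------------------------------------------------
# participant identification and DWF classification
# --------------------------------------------------------------------------

_HOURS_COLS = {"buyer_flag", "seller_eez", "year", "hours"}
_VESSEL_COLS = {"vessel_id", "flag", "hours_inside", "hours_outside", "gross_tonnage"}


def identify_participants(
    hours: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD_HOURS
) -> tuple[list[str], list[str]]:
    """Participants of the access market from pairwise fishing-hours records.

    A flag state is a buyer if in at least one year it fishes more hours
    than ``threshold`` in at least one foreign EEZ; that EEZ's state is then
    a seller.  Returns sorted (sellers, buyers) label lists.
    """
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    missing = _HOURS_COLS - set(hours.columns)
    if missing:
        raise ValidationError(f"hours table missing columns: {sorted(missing)}")
    if hours.empty:
        warnings.warn("empty hours table: no participants identified", stacklevel=2)
        return [], []
    qualifying = hours[
        (hours["hours"] > threshold) & (hours["buyer_flag"] != hours["seller_eez"])
    ]
    buyers = sorted(qualifying["buyer_flag"].unique())
    sellers = sorted(qualifying["seller_eez"].unique())
    return sellers, buyers


def classify_dwf(vessels: pd.DataFrame) -> pd.Series:
    """Flag each vessel as distant-water (DWF) or not.

    A vessel is DWF iff strictly more than half of its fishing hours occur
    outside its flag state's EEZ; an exact 50/50 split is domestic.  Vessels
    with zero recorded hours are non-DWF with a warning.
    """
    missing = _VESSEL_COLS - set(vessels.columns)
    if missing:
        raise ValidationError(f"vessel table missing columns: {sorted(missing)}")
    total = vessels["hours_inside"] + vessels["hours_outside"]
    if (total == 0).any():
        warnings.warn(
            f"{int((total == 0).sum())} vessel(s) with zero hours classified non-DWF",
            stacklevel=2,
        )
    is_dwf = vessels["hours_outside"] > vessels["hours_inside"]
    is_dwf &= total > 0
    return pd.Series(is_dwf.to_numpy(), index=vessels.index, name="is_dwf")


def buyer_tonnage(vessels: pd.DataFrame) -> pd.Series:
    """Total DWF-fleet gross tonnage per flag (buyers' true endowments)."""
    dwf = vessels[classify_dwf(vessels).to_numpy()]
    return dwf.groupby("flag")["gross_tonnage"].sum().sort_index()


# --------------------------------------------------------------------------
# parameter aggregation and share algebra
# --------------------------------------------------------------------------

def weighted_growth(stock_g, stock_k) -> float:
    """Country-level growth parameter: stock g weighted by stock carrying capacity."""
    g = np.asarray(stock_g, dtype=float)
    k = np.asarray(stock_k, dtype=float)
    if g.size == 0 or g.shape != k.shape:
        raise DomainError("stock_g and stock_k must be equal-length, non-empty")
    if np.any(k <= 0):
        raise DomainError("carrying-capacity weights must be positive")
    return float(np.sum(g * k) / np.sum(k))


def normalize_shares(values) -> np.ndarray:
    """Normalize non-negative endowments to shares summing to 1 exactly.

    The last share is set by complement so floating-point round-off cannot
    break the sum-to-one contract.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise DomainError("endowments must be non-negative")
    total = v.sum()
    if total <= 0:
        raise DomainError("cannot normalize: endowments sum to zero")
    shares = v / total
    shares[-1] = 1.0 - shares[:-1].sum()
    return shares


def rescale_share(base_share: float, base_biomass: float, new_biomass: float) -> float:
    """Model share of a country whose physical biomass is counterfactually moved.

    Only the perturbed country's share changes (proportionally to its new
    biomass), so the model's total true endowment departs from 1 under
    perturbation — by design.
    """
    if base_share <= 0 or base_biomass <= 0 or new_biomass <= 0:
        raise DomainError("shares and biomasses must be positive")
    return base_share * (new_biomass / base_biomass)


# --------------------------------------------------------------------------
# market construction
# --------------------------------------------------------------------------

def build_market(
    seller_table: pd.DataFrame,
    buyer_table: pd.DataFrame,
    params: MarketParams | None = None,
    depletion: float = DEFAULT_DEPLETION,
    phi: float = DEFAULT_PHI,
) -> CalibratedMarket:
    """Calibrate a model-ready market from seller and buyer tables.

    Per seller: carrying capacity from observed catch and growth parameter,
    biomass from the depletion assumption, share from normalization.  Per
    buyer: gross-tonnage share.  Per-row ``depletion``/``phi`` columns, if
    present, override the scalar defaults.
    """
    params = params or MarketParams()
    for col in ("id", "catch_tons", "growth_g"):
        if col not in seller_table.columns:
            raise ValidationError(f"seller table missing column '{col}'")
    for col in ("id", "gross_tonnage"):
        if col not in buyer_table.columns:
            raise ValidationError(f"buyer table missing column '{col}'")
    if seller_table.empty or buyer_table.empty:
        raise ValidationError("seller and buyer tables must be non-empty")
    if seller_table["id"].duplicated().any() or buyer_table["id"].duplicated().any():
        raise ValidationError("duplicate country ids in input tables")

    stocks: dict[str, StockBio] = {}
    biomass = np.empty(len(seller_table))
    for pos, row in enumerate(seller_table.itertuples(index=False)):
        if row.catch_tons <= 0 or row.growth_g <= 0:
            raise ValidationError(
                f"seller '{row.id}': catch_tons and growth_g must be positive"
            )
        d_row = float(getattr(row, "depletion", depletion) or depletion)
        phi_row = float(getattr(row, "phi", phi) or phi)
        stock = calibrate_stock(row.id, float(row.catch_tons), float(row.growth_g),
                                d=d_row, phi=phi_row)
        stocks[str(row.id)] = stock
        biomass[pos] = stock.b

    tonnage = buyer_table["gross_tonnage"].to_numpy(dtype=float)
    if np.any(tonnage <= 0):
        bad = buyer_table.loc[tonnage <= 0, "id"].tolist()
        raise ValidationError(f"buyers with non-positive gross tonnage: {bad}")

    return CalibratedMarket(
        params=params,
        seller_ids=[str(x) for x in seller_table["id"]],
        buyer_ids=[str(x) for x in buyer_table["id"]],
        seller_shares=normalize_shares(biomass),
        buyer_shares=normalize_shares(tonnage),
        seller_biomass_tons=biomass,
        buyer_tonnage_gt=tonnage,
        stocks=stocks,
        depletion=depletion,
        phi=phi,
    )


def build_scales(
    solution: MarketState,
    anchor_buyer_id: str,
    anchor_purchase_tons: float,
    anchor_fee_usd: float,
) -> UnitScales:
    """Unit anchors from a solved status-quo market plus observed anchor data.

    The anchor buyer's observed annual purchases (tons/yr, e.g. from
    published access agreements) pin the quantity scale: total access tons =
    observed tons / anchor's equilibrium purchase share.  The observed
    average fee (USD/ton) pins the fee scale against the model fee.
    """
    try:
        anchor = next(b for b in solution.buyers if b.id == anchor_buyer_id)
    except StopIteration:
        raise ValidationError(f"anchor buyer '{anchor_buyer_id}' not in market") from None
    share = anchor.q_access / solution.quantity
    if share <= 0:
        raise DomainError("anchor buyer has zero equilibrium purchase share")
    return UnitScales(
        qty_anchor_units=solution.quantity,
        qty_anchor_tons=anchor_purchase_tons / share,
        fee_anchor_units=solution.price,
        fee_anchor_usd=anchor_fee_usd,
    )


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML superset) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} did not parse to a mapping")
    return cfg


def solve_calibrated(
    market: CalibratedMarket,
    tol: float = 1e-10,
    buyer_reports: np.ndarray | None = None,
) -> MarketState:
    """Solve the Nash equilibrium of a calibrated market in share units."""
    return oligopoly.solve_nash(
        market.seller_shares,
        market.buyer_shares,
        market.params,
        tol=tol,
        seller_ids=market.seller_ids,
        buyer_ids=market.buyer_ids,
        buyer_reports=buyer_reports,
    )
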