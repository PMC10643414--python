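"""Synthetic market inputs with the statistical structure of the real data.

The generator emulates the structure of a continent-scale access market: a
few dozen heterogeneous coastal sellers whose mean annual catches are
right-skewed (log-normal), country-level intrinsic growth parameters, a few
dozen heterogeneous distant-water buyers with right-skewed fleet gross
tonnage, and an EU-like "anchor" buyer holding a known slice of the market
whose published agreement catch and average fee pin the unit conversions.

Defaults reproduce the study conditions: 32 sellers and 33 buyers, a
continent-scale total catch around 11-12 million tons/yr, an anchor buyer
purchasing ~11.5% of access at $128.20/ton, depletion 0.8 and shape 0.188.
Everything is deterministic given the seed, and ground truth (which flags
are buyers, which vessels are distant-water) is planted and returned so
identification and classification can be asserted without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .biology import DEFAULT_DEPLETION, DEFAULT_PHI
from .calibration import DEFAULT_THRESHOLD_HOURS
from .errors import ValidationError

__all__ = ["SynthSpec", "SyntheticMarket", "HoursTruth",
           "gen_market", "gen_hours", "worked_example_fixture"]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic generator."""

    n_sellers: int = 32
    n_buyers: int = 33
    seed: int = 0
    # mean annual catch h (tons/yr): log-normal location/scale
    catch_logmean: float = math.log(1.5e5)
    catch_logsd: float = 1.3
    # intrinsic growth g (1/yr): uniform bounds
    growth_low: float = 0.1
    growth_high: float = 0.5
    # DWF gross tonnage (GT): log-normal location/scale
    tonnage_logmean: float = math.log(2.0e4)
    tonnage_logsd: float = 1.2
    # EU-like anchor buyer
    anchor_buyer_share: float = 0.115   # share of access purchases
    anchor_fee_usd: float = 128.20      # USD/ton, 2020
    # access catch as a fraction of total catch in sellers' waters
    # (continent-scale access/total catch ratio)
    access_catch_fraction: float = 0.21
    depletion: float = DEFAULT_DEPLETION
    phi: float = DEFAULT_PHI
    # fishing-hours matrix
    hours_years: tuple[int, ...] = (2016, 2017)
    hours_threshold: float = DEFAULT_THRESHOLD_HOURS

    def __post_init__(self) -> None:
        if self.n_sellers < 1 or self.n_buyers < 1:
            raise ValidationError("need at least one seller and one buyer")
        if self.catch_logsd <= 0 or self.tonnage_logsd <= 0:
            raise ValidationError("distribution scales must be positive")
        if not (0 < self.anchor_buyer_share < 1):
            raise ValidationError("anchor_buyer_share must lie in (0, 1)")
        if not (0 < self.access_catch_fraction < 1):
            raise ValidationError("access_catch_fraction must lie in (0, 1)")
        if not (0 < self.growth_low <= self.growth_high):
            raise ValidationError("growth bounds must be positive and ordered")


class SyntheticMarket(NamedTuple):
    sellers: pd.DataFrame  # id, catch_tons, growth_g
    buyers: pd.DataFrame   # id, gross_tonnage
    anchor: dict           # anchor_buyer_id, anchor_purchase_tons, anchor_fee_usd


class HoursTruth(NamedTuple):
    hours: pd.DataFrame    # buyer_flag, seller_eez, year, hours
    vessels: pd.DataFrame  # vessel_id, flag, hours_inside, hours_outside, gross_tonnage
    buyers: set[str]       # planted buyer flags
    sellers: set[str]      # planted seller EEZs
    dwf: set[str]          # planted DWF vessel ids
    threshold: float


def gen_market(spec: SynthSpec = SynthSpec()) -> SyntheticMarket:
    """Seller and buyer tables plus unit-scale anchor data.

    The anchor buyer ("EU") is assigned ~13% of true gross tonnage so its
    equilibrium purchase share (which shrinks slightly through strategic
    underreporting) lands near ``anchor_buyer_share``; its published
    agreement catch is its purchase share of the implied total access catch.
    """
    rng = np.random.default_rng(spec.seed)
    catch = rng.lognormal(spec.catch_logmean, spec.catch_logsd, spec.n_sellers)
    growth = rng.uniform(spec.growth_low, spec.growth_high, spec.n_sellers)
    sellers = pd.DataFrame(
        {
            "id": [f"SEL{i:02d}" for i in range(spec.n_sellers)],
            "catch_tons": catch,
            "growth_g": growth,
        }
    )

    n_other = spec.n_buyers - 1
    other_gt = rng.lognormal(spec.tonnage_logmean, spec.tonnage_logsd, n_other)
    ids = [f"BUY{j:02d}" for j in range(n_other)]
    if n_other:
        # anchor true-tonnage share a touch above the purchase-share target,
        # anticipating that larger agents underreport more
        f = min(0.95, spec.anchor_buyer_share * 1.13)
        anchor_gt = f * other_gt.sum() / (1.0 - f)
    else:
        anchor_gt = math.exp(spec.tonnage_logmean)
    buyers = pd.DataFrame(
        {
            "id": ["EU"] + ids,
            "gross_tonnage": np.concatenate([[anchor_gt], other_gt]),
        }
    )
    # the anchor buyer's published agreement catch implies, at its purchase
    # share, a total access quantity equal to the target fraction of the
    # realized total catch in sellers' waters
    total_access_tons = spec.access_catch_fraction * float(catch.sum())
    anchor = {
        "anchor_buyer_id": "EU",
        "anchor_purchase_tons": spec.anchor_buyer_share * total_access_tons,
        "anchor_fee_usd": spec.anchor_fee_usd,
    }
    return SyntheticMarket(sellers=sellers, buyers=buyers, anchor=anchor)


def gen_hours(spec: SynthSpec = SynthSpec()) -> HoursTruth:
    """Pairwise fishing-hours records and a vessel register with planted truth.

    Roughly a third of the candidate flags are planted as buyers (one
    above-threshold record each, in a randomly chosen EEZ and year); all
    other flag/EEZ/year cells stay strictly below threshold.  Each flag
    receives a few vessels with known inside/outside hour splits, so the
    distant-water classification has a known answer key.
    """
    rng = np.random.default_rng(spec.seed + 1)
    thr = spec.hours_threshold
    flags = [f"FLAG{j:02d}" for j in range(max(3, spec.n_buyers))]
    eezs = [f"EEZ{i:02d}" for i in range(max(3, spec.n_sellers))]
    years = list(spec.hours_years)

    planted_buyers = set(rng.choice(flags, size=max(1, len(flags) // 3), replace=False))
    records = []
    planted_sellers: set[str] = set()
    for flag in flags:
        for eez in eezs:
            for year in years:
                records.append(
                    {
                        "buyer_flag": flag,
                        "seller_eez": eez,
                        "year": year,
                        "hours": float(rng.uniform(0, 0.8 * thr)),
                    }
                )
    for flag in sorted(planted_buyers):
        eez = str(rng.choice(eezs))
        year = int(rng.choice(years))
        planted_sellers.add(eez)
        records.append(
            {
                "buyer_flag": flag,
                "seller_eez": eez,
                "year": year,
                "hours": float(thr * rng.uniform(1.2, 3.0)),
            }
        )
    hours = pd.DataFrame.from_records(records)

    vessels = []
    dwf: set[str] = set()
    for flag in flags:
        for v in range(3):
            vid = f"{flag}-V{v}"
            total = float(rng.uniform(500, 5000))
            outside_frac = float(rng.uniform(0.05, 0.95))
            if abs(outside_frac - 0.5) < 0.05:  # keep the planted answer unambiguous
                outside_frac = 0.7
            inside = total * (1 - outside_frac)
            outside = total * outside_frac
            if outside > inside:
                dwf.add(vid)
            vessels.append(
                {
                    "vessel_id": vid,
                    "flag": flag,
                    "hours_inside": inside,
                    "hours_outside": outside,
                    "gross_tonnage": float(rng.lognormal(math.log(1500), 0.8)),
                }
            )
    return HoursTruth(
        hours=hours,
        vessels=pd.DataFrame.from_records(vessels),
        buyers=planted_buyers,
        sellers=planted_sellers,
        dwf=dwf,
        threshold=thr,
    )


def worked_example_fixture() -> dict:
    """A fixed small market pinning the share-rescaling arithmetic.

    One seller ("Madagascar") holds biomass 2,213,411 tons and true biomass
    share 0.0189; the rest of the continent holds the complementary share.
    Moving Madagascar's biomass to 3,458,613 tons rescales its model share
    to 0.0295 and lifts the model's total true endowment to 1.0106.
    """
    base_share = 0.0189
    base_biomass = 2_213_411.0
    rest_biomass = base_biomass * (1 - base_share) / base_share
    g = 0.2
    d, phi = DEFAULT_DEPLETION, DEFAULT_PHI

    from .biology import bmsy_from_k, growth

    def catch_for_biomass(b: float) -> float:
        k = b / (d * bmsy_from_k(1.0, phi))  # k such that b = d * bMSY(k)
        return float(growth(b, k, g, phi))

    sellers = pd.DataFrame(
        {
            "id": ["Madagascar", "RestOfContinent"],
            "catch_tons": [catch_for_biomass(base_biomass), catch_for_biomass(rest_biomass)],
            "growth_g": [g, g],
        }
    )
    buyers = pd.DataFrame({"id": ["EU", "OtherBuyer"], "gross_tonnage": [3.0e5, 2.0e6]})
    return {
        "sellers": sellers,
        "buyers": buyers,
        "country": "Madagascar",
        "base_share": base_share,
        "base_biomass": base_biomass,
        "counterfactual_biomass": 3_458_613.0,
        "depletion": d,
        "phi": phi,
    }
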