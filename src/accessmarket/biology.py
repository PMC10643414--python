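"""Pella-Tomlinson surplus-production algebra.

Each selling country carries one aggregate stock with surplus production

    growth(b) = (phi+1)/phi * g * b * (1 - (b/k)**phi)

where ``g`` is the intrinsic growth parameter (1/yr), ``k`` the carrying
capacity (tons) and ``phi`` the shape parameter.  ``phi = 0.188`` places
biomass at maximum sustainable yield at 40% of carrying capacity.  Carrying
capacity is calibrated from observed mean annual catch ``h`` under the
assumption that the stock sits at its equilibrium (growth = catch) with a
known depletion level ``d = b / b_MSY``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: Default shape parameter: bMSY at 40% of carrying capacity.
DEFAULT_PHI = 0.188
#: Default depletion b/bMSY for partially depleted stocks.
DEFAULT_DEPLETION = 0.8

__all__ = [
    "StockBio",
    "bmsy_from_k",
    "growth",
    "k_from_catch",
    "biomass_from_depletion",
    "calibrate_stock",
    "DEFAULT_PHI",
    "DEFAULT_DEPLETION",
]


@dataclass(frozen=True)
class StockBio:
    """Calibrated Pella-Tomlinson parameters for one country's aggregate stock."""

    id: str
    g: float      # intrinsic growth (1/yr)
    phi: float    # shape parameter
    k: float      # carrying capacity (tons)
    b: float      # current biomass (tons)
    h: float      # mean annual total catch (tons/yr)
    d: float      # assumed depletion b/bMSY

    def __post_init__(self) -> None:
        if self.g <= 0 or self.phi <= 0 or self.k <= 0 or self.d <= 0:
            raise DomainError(f"stock {self.id}: g, phi, k, d must be positive")
        if not (0 < self.b <= self.k):
            raise DomainError(f"stock {self.id}: biomass must lie in (0, k]")
        if self.h < 0:
            raise DomainError(f"stock {self.id}: catch must be non-negative")

    @property
    def bmsy(self) -> float:
        return bmsy_from_k(self.k, self.phi)

    def growth(self, b) -> np.ndarray | float:
        return growth(b, self.k, self.g, self.phi)


def bmsy_from_k(k, phi):
    """Biomass at maximum sustainable yield: ``k / (phi+1)**(1/phi)``."""
    k = np.asarray(k, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(k <= 0) or np.any(phi <= 0):
        raise DomainError("k and phi must be positive")
    out = k / (phi + 1.0) ** (1.0 / phi)
    return float(out) if out.ndim == 0 else out


def growth(b, k, g, phi):
    """Surplus production (tons/yr) at biomass ``b``.

    Zero at ``b = 0`` and ``b = k``, with a single interior maximum at bMSY.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or np.any(b > k):
        raise DomainError("biomass must lie in [0, k]")
    if k <= 0 or g <= 0 or phi <= 0:
        raise DomainError("k, g, phi must be positive")
    out = (phi + 1.0) / phi * g * b * (1.0 - (b / k) ** phi)
    return float(out) if out.ndim == 0 else out


def biomass_from_depletion(k, phi, d):
    """Biomass at depletion ``d = b/bMSY``: ``d * k / (phi+1)**(1/phi)``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("depletion must be non-negative")
    if np.any(d > (np.asarray(phi) + 1.0) ** (1.0 / np.asarray(phi))):
        raise DomainError("depletion implies biomass above carrying capacity")
    out = d * bmsy_from_k(k, phi)
    return float(out) if np.ndim(out) == 0 else out


def k_from_catch(h, g, phi=DEFAULT_PHI, d=DEFAULT_DEPLETION):
    """Carrying capacity consistent with equilibrium catch ``h`` at depletion ``d``.

    Inverts the equilibrium condition growth(b) = h with b = d*bMSY:

        k = h * (1/(d*g)) * phi * (phi+1)**(1/phi) / (phi + 1 - d**phi)

    For ``d = 0.8`` this is the familiar ``h * 1.25/g * ...`` closed form.
    Requires ``d < (phi+1)**(1/phi)`` so the denominator stays positive
    (equivalently, calibrated biomass stays below carrying capacity).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise DomainError("catch h must be positive to calibrate a stock")
    if g <= 0 or phi <= 0:
        raise DomainError("g and phi must be positive")
    if not (0 < d < (phi + 1.0) ** (1.0 / phi)):
        raise DomainError(
            f"depletion d={d} outside (0, (phi+1)**(1/phi)) calibration range"
        )
    out = h / (d * g) * phi * (phi + 1.0) ** (1.0 / phi) / (phi + 1.0 - d**phi)
    return float(out) if out.ndim == 0 else out


def calibrate_stock(
    stock_id: str,
    h: float,
    g: float,
    d: float = DEFAULT_DEPLETION,
    phi: float = DEFAULT_PHI,
) -> StockBio:
    """Build a fully calibrated stock from observed catch and growth rate."""
    k = k_from_catch(h, g, phi, d)
    b = biomass_from_depletion(k, phi, d)
    return StockBio(id=str(stock_id), g=float(g), phi=float(phi), k=float(k),
                    b=float(b), h=float(h), d=float(d))
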