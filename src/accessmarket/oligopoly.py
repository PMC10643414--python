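"""Bilateral oligopoly for fishing-access markets.

Sellers (coastal states) are endowed with true biomass ``b_i`` and buyers
(distant-water fishing nations) with true fleet gross tonnage ``t_j``.  Each
agent strategically *reports* an endowment (b-hat, t-hat) to a market
mechanism that clears the access-fee market and allocates access quantity in
proportion to reported shares.  Under constant-elasticity cost and value
functions

    c(z) = eta/(eta+1) * z**((eta+1)/eta)        (seller opportunity cost)
    v(z) = eps/(eps-1) * z**((eps-1)/eps)        (buyer fishing profit)

the clearing fee and quantity have closed forms in the report totals, and
each agent's best response solves a one-dimensional polynomial equation in
its own report.  Market power manifests as underreporting: every Nash report
lies in (0, true value], shrinking toward the truth as an agent's market
share vanishes.

All quantities here are dimensionless ("share/model units"); unit conversion
to tons and USD lives in :mod:`accessmarket.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DegenerateMarketError, DomainError

__all__ = [
    "MarketParams",
    "SellerState",
    "BuyerState",
    "MarketState",
    "cost_fn",
    "value_fn",
    "marginal_cost",
    "marginal_value",
    "clearing_price",
    "clearing_quantity",
    "allocate",
    "seller_profit",
    "buyer_profit",
    "report_ratio_seller",
    "report_ratio_buyer",
    "seller_best_response",
    "buyer_best_response",
    "solve_seller_reports",
    "solve_buyer_reports",
    "solve_nash",
]


@dataclass(frozen=True)
class MarketParams:
    """Elasticity pair governing cost/value curvature.

    Parameters
    ----------
    eta:
        Seller opportunity-cost elasticity, ``eta > 0``.
    epsilon:
        Buyer fishing-profit elasticity, ``epsilon > 1``.
    """

    eta: float = 1.0
    epsilon: float = 2.0

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise DomainError(f"eta must be positive, got {self.eta}")
        if not (self.epsilon > 1):
            raise DomainError(f"epsilon must exceed 1, got {self.epsilon}")


@dataclass
class SellerState:
    """One selling country: true and reported biomass, allocation, profit."""

    id: str
    b_true: float
    b_report: float = np.nan
    q_access: float = np.nan
    profit: float = np.nan


@dataclass
class BuyerState:
    """One buying country: true and reported gross tonnage, allocation, profit."""

    id: str
    t_true: float
    t_report: float = np.nan
    q_access: float = np.nan
    profit: float = np.nan


@dataclass
class MarketState:
    """A cleared market: agent states plus the clearing fee and quantity."""

    params: MarketParams
    sellers: list[SellerState] = field(default_factory=list)
    buyers: list[BuyerState] = field(default_factory=list)
    price: float = np.nan
    quantity: float = np.nan
    iterations: int = 0

    @property
    def B_hat(self) -> float:
        return float(sum(s.b_report for s in self.sellers))

    @property
    def T_hat(self) -> float:
        return float(sum(b.t_report for b in self.buyers))

    def seller_reports(self) -> np.ndarray:
        return np.array([s.b_report for s in self.sellers])

    def buyer_reports(self) -> np.ndarray:
        return np.array([b.t_report for b in self.buyers])


# --------------------------------------------------------------------------
# functional forms and market clearing
# --------------------------------------------------------------------------

def cost_fn(z, params: MarketParams):
    """Opportunity cost per unit biomass of supplying at intensity ``z = q/b``."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise DomainError("supply intensity z must be non-negative")
    eta = params.eta
    return eta / (eta + 1.0) * z ** ((eta + 1.0) / eta)


def value_fn(z, params: MarketParams):
    """Fishing profit per unit tonnage of catching at intensity ``z = q/t``."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise DomainError("catch intensity z must be non-negative")
    eps = params.epsilon
    return eps / (eps - 1.0) * z ** ((eps - 1.0) / eps)


def marginal_cost(z, params: MarketParams):
    """c'(z) = z**(1/eta)."""
    return np.asarray(z, dtype=float) ** (1.0 / params.eta)


def marginal_value(z, params: MarketParams):
    """v'(z) = z**(-1/epsilon)."""
    return np.asarray(z, dtype=float) ** (-1.0 / params.epsilon)


def clearing_price(B_hat, T_hat, params: MarketParams):
    """Equilibrium access fee given report totals.

    ``p = B_hat**(-1/(eps+eta)) * T_hat**(1/(eps+eta))`` — decreasing in
    reported supply, increasing in reported demand.
    """
    B_hat = np.asarray(B_hat, dtype=float)
    T_hat = np.asarray(T_hat, dtype=float)
    if np.any(B_hat <= 0) or np.any(T_hat <= 0):
        raise DomainError("report totals must be positive to clear the market")
    se = params.epsilon + params.eta
    return B_hat ** (-1.0 / se) * T_hat ** (1.0 / se)


def clearing_quantity(B_hat, T_hat, params: MarketParams):
    """Equilibrium total access quantity given report totals.

    ``Q = B_hat**(eps/(eps+eta)) * T_hat**(eta/(eps+eta))`` — increasing in
    both totals, and satisfying ``c'(Q/B_hat) = v'(Q/T_hat) = p``.
    """
    B_hat = np.asarray(B_hat, dtype=float)
    T_hat = np.asarray(T_hat, dtype=float)
    if np.any(B_hat <= 0) or np.any(T_hat <= 0):
        raise DomainError("report totals must be positive to clear the market")
    se = params.epsilon + params.eta
    return B_hat ** (params.epsilon / se) * T_hat ** (params.eta / se)


def allocate(market: MarketState) -> MarketState:
    """Assign each agent its share of the clearing quantity, in place.

    Seller ``i`` receives ``(b_report_i / B_hat) * Q`` and buyer ``j``
    receives ``(t_report_j / T_hat) * Q``, so both sides sum to ``Q``.
    """
    B_hat, T_hat = market.B_hat, market.T_hat
    if B_hat <= 0 or T_hat <= 0:
        raise DegenerateMarketError("cannot allocate with zero total reports")
    Q = market.quantity
    for s in market.sellers:
        s.q_access = s.b_report / B_hat * Q
    for b in market.buyers:
        b.q_access = b.t_report / T_hat * Q
    return market


def seller_profit(seller: SellerState, market: MarketState) -> float:
    """Seller profit: fee revenue minus opportunity cost of foregone growth."""
    if seller.b_true <= 0:
        raise DomainError("seller true biomass must be positive")
    q = seller.q_access
    if q == 0:
        return 0.0
    return float(
        market.price * q
        - seller.b_true * cost_fn(q / seller.b_true, market.params)
    )


def buyer_profit(buyer: BuyerState, market: MarketState) -> float:
    """Buyer profit: fishing profit minus the cost of access permits."""
    if buyer.t_true <= 0:
        raise DomainError("buyer true tonnage must be positive")
    q = buyer.q_access
    if q == 0:
        return 0.0
    return float(
        buyer.t_true * value_fn(q / buyer.t_true, market.params)
        - market.price * q
    )


# --------------------------------------------------------------------------
# report ratios (share form of the equilibrium conditions)
# --------------------------------------------------------------------------

def report_ratio_seller(sigma, params: MarketParams):
    """Equilibrium report/true ratio for a seller with quantity share ``sigma``.

    ``b_hat/b = (1 - sigma/(eps + eta*(1-sigma)))**eta``; equals 1 for a
    price taker (sigma -> 0) and is strictly decreasing in sigma.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0) or np.any(sigma > 1):
        raise DomainError("seller share sigma must lie in [0, 1]")
    eta, eps = params.eta, params.epsilon
    return (1.0 - sigma / (eps + eta * (1.0 - sigma))) ** eta


def report_ratio_buyer(s, params: MarketParams):
    """Equilibrium report/true ratio for a buyer with quantity share ``s``.

    ``t_hat/t = (1 + s/(eps*(1-s) + eta))**(-eps)``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise DomainError("buyer share s must lie in [0, 1]")
    eta, eps = params.eta, params.epsilon
    return (1.0 + s / (eps * (1.0 - s) + eta)) ** (-eps)


# --------------------------------------------------------------------------
# best responses
# --------------------------------------------------------------------------

def _seller_residual(bhat, b_true, b_others, params: MarketParams):
    eta, eps = params.eta, params.epsilon
    return (
        eps * bhat ** ((eta + 1.0) / eta)
        + b_true ** (1.0 / eta) * (1.0 - eps) * bhat
        + b_others * (eps + eta) * bhat ** (1.0 / eta)
        - b_true ** (1.0 / eta) * b_others * (eps + eta)
    )


def _buyer_residual(that, t_true, t_others, params: MarketParams):
    eta, eps = params.eta, params.epsilon
    return (
        (eta + 1.0) * that ** ((eps + 1.0) / eps)
        - eta * t_true ** (1.0 / eps) * that
        + t_others * (eps + eta) * that ** (1.0 / eps)
        - t_true ** (1.0 / eps) * t_others * (eps + eta)
    )


# Bracket floor relative to the true endowment.  The economic root always
# lies in (0, true]; at the truth the residual is positive and near zero it
# is negative, so a sign change is guaranteed.
_BRACKET_DELTA = 1e-12
_BISECT_STEPS = 60  # 2**-60 relative width: below double precision


def _bisect_vec(residual, true_vals, others, params: MarketParams) -> np.ndarray:
    """Vectorized bracketed bisection for the best-response equations.

    scipy offers no vectorized bracketed scalar root finder, and the Nash
    fixed point calls this once per iteration for a whole side of the
    market, so a fixed-step bisection on (delta*true, true] is used.
    """
    true_vals = np.asarray(true_vals, dtype=float)
    others = np.asarray(others, dtype=float)
    lo = _BRACKET_DELTA * true_vals
    hi = true_vals.copy()
    f_lo = residual(lo, true_vals, others, params)
    f_hi = residual(hi, true_vals, others, params)
    if np.any(f_lo * f_hi > 0):
        raise ConvergenceError(
            "best-response bracket has no sign change; "
            f"true={true_vals!r} others={others!r}"
        )
    for _ in range(_BISECT_STEPS):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid, true_vals, others, params)
        take_lo = f_mid * f_lo <= 0
        hi = np.where(take_lo, mid, hi)
        lo = np.where(take_lo, lo, mid)
        f_lo = np.where(take_lo, f_lo, f_mid)
    return 0.5 * (lo + hi)


def seller_best_response(b_true: float, b_others: float, params: MarketParams) -> float:
    """Profit-maximizing biomass report given rival sellers' summed reports."""
    if b_true <= 0:
        raise DomainError("seller true biomass must be positive")
    if b_others < 0:
        raise DomainError("rival report sum must be non-negative")
    return float(
        _bisect_vec(_seller_residual, np.array([b_true]), np.array([b_others]), params)[0]
    )


def buyer_best_response(t_true: float, t_others: float, params: MarketParams) -> float:
    """Profit-maximizing tonnage report given rival buyers' summed reports."""
    if t_true <= 0:
        raise DomainError("buyer true tonnage must be positive")
    if t_others < 0:
        raise DomainError("rival report sum must be non-negative")
    return float(
        _bisect_vec(_buyer_residual, np.array([t_true]), np.array([t_others]), params)[0]
    )


# --------------------------------------------------------------------------
# Nash fixed point
# --------------------------------------------------------------------------

def _solve_side(
    residual,
    true_vals: np.ndarray,
    params: MarketParams,
    tol: float,
    max_iter: int,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Synchronous best-response iteration for one side of the market.

    Each agent's best response depends on rivals only through the sum of
    their reports, so one vectorized update serves the whole side.  Starts
    from truthful reports (or ``init``, e.g. a neighbouring grid point's
    solution); a 0.5 damping factor engages if the update direction
    oscillates.  The fixed point is independent of the start; warm starts
    only shorten the iteration.
    """
    if init is not None:
        reports = np.clip(np.asarray(init, dtype=float), _BRACKET_DELTA * true_vals, true_vals)
    else:
        reports = true_vals.astype(float).copy()
    prev_delta = np.zeros_like(reports)
    for it in range(1, max_iter + 1):
        others = reports.sum() - reports
        new = _bisect_vec(residual, true_vals, others, params)
        delta = new - reports
        if np.dot(delta, prev_delta) < 0:  # oscillation: damp
            new = 0.5 * (new + reports)
            delta = new - reports
        change = np.max(np.abs(delta) / true_vals)
        reports = new
        prev_delta = delta
        if change < tol:
            return reports, it
    raise ConvergenceError(
        f"best-response iteration did not converge in {max_iter} iterations "
        f"(last relative change {change:.3e})"
    )


def solve_buyer_reports(
    t_true: np.ndarray,
    params: MarketParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Nash reports of the buyer subgame.

    Buyer best responses involve only rival buyer reports, never seller
    reports, so the buyer side solves once per market and is reusable
    across supply-side perturbations.
    """
    t_true = np.asarray(t_true, dtype=float)
    if t_true.size == 0 or np.any(t_true <= 0):
        raise DegenerateMarketError("need at least one buyer with positive tonnage")
    reports, _ = _solve_side(_buyer_residual, t_true, params, tol, max_iter)
    return reports


def solve_seller_reports(
    b_true: np.ndarray,
    params: MarketParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Nash reports of the seller subgame (rival-sum best responses)."""
    b_true = np.asarray(b_true, dtype=float)
    if b_true.size == 0 or np.any(b_true <= 0):
        raise DegenerateMarketError("need at least one seller with positive biomass")
    reports, _ = _solve_side(_seller_residual, b_true, params, tol, max_iter, init=init)
    return reports


def solve_nash(
    seller_endowments,
    buyer_endowments,
    params: MarketParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    seller_ids=None,
    buyer_ids=None,
    buyer_reports: np.ndarray | None = None,
) -> MarketState:
    """Solve the full market for its Nash equilibrium in reports.

    Parameters
    ----------
    seller_endowments, buyer_endowments:
        Positive true biomass / gross tonnage vectors (model units).
    buyer_reports:
        Optional precomputed buyer-subgame solution (the buyer side is
        invariant to seller endowments); validated for shape only.

    Returns
    -------
    MarketState
        With every report a best response to rivals, the market cleared via
        the closed-form fee and quantity, quantities allocated by reported
        share, and per-agent profits evaluated.
    """
    b_true = np.asarray(seller_endowments, dtype=float)
    t_true = np.asarray(buyer_endowments, dtype=float)
    if b_true.size == 0 or np.any(b_true <= 0):
        raise DegenerateMarketError("need at least one seller with positive biomass")
    if t_true.size == 0 or np.any(t_true <= 0):
        raise DegenerateMarketError("need at least one buyer with positive tonnage")

    b_hat, it_s = _solve_side(_seller_residual, b_true, params, tol, max_iter)
    if buyer_reports is None:
        t_hat, it_b = _solve_side(_buyer_residual, t_true, params, tol, max_iter)
    else:
        t_hat = np.asarray(buyer_reports, dtype=float)
        if t_hat.shape != t_true.shape:
            raise DomainError("buyer_reports shape mismatch")
        it_b = 0

    if seller_ids is None:
        seller_ids = [f"S{i}" for i in range(b_true.size)]
    if buyer_ids is None:
        buyer_ids = [f"B{j}" for j in range(t_true.size)]

    market = MarketState(
        params=params,
        sellers=[
            SellerState(id=str(sid), b_true=float(b), b_report=float(bh))
            for sid, b, bh in zip(seller_ids, b_true, b_hat)
        ],
        buyers=[
            BuyerState(id=str(bid), t_true=float(t), t_report=float(th))
            for bid, t, th in zip(buyer_ids, t_true, t_hat)
        ],
        iterations=max(it_s, it_b),
    )
    B_hat, T_hat = b_hat.sum(), t_hat.sum()
    market.price = float(clearing_price(B_hat, T_hat, params))
    market.quantity = float(clearing_quantity(B_hat, T_hat, params))
    allocate(market)
    for s in market.sellers:
        s.profit = seller_profit(s, market)
    for b in market.buyers:
        b.profit = buyer_profit(b, market)
    return market
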