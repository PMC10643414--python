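"""Bilateral-oligopoly mechanism: closed forms, best responses, Nash solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from accessmarket import (
    MarketParams,
    buyer_best_response,
    clearing_price,
    clearing_quantity,
    cost_fn,
    report_ratio_buyer,
    report_ratio_seller,
    seller_best_response,
    solve_nash,
    value_fn,
)
from accessmarket.errors import DegenerateMarketError, DomainError
from accessmarket.oligopoly import (
    allocate,
    buyer_profit,
    marginal_cost,
    marginal_value,
    solve_buyer_reports,
    solve_seller_reports,
    seller_profit,
)
from conftest import random_endowments


# --------------------------------------------------------------------------
# functional forms
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "z, eta, expected",
    [(0.0, 1.0, 0.0), (1.0, 1.0, 0.5), (4.0, 1.0, 8.0), (2.0, 0.5, 2.0**3 / 3.0)],
)
def test_cost_closed_form_matches_integrated_marginal(z, eta, expected):
    p = MarketParams(eta=eta, epsilon=2.0)
    assert cost_fn(z, p) == pytest.approx(expected, rel=1e-12)
    integral, _ = quad(lambda u: marginal_cost(u, p), 0, z)
    assert cost_fn(z, p) == pytest.approx(integral, rel=1e-8, abs=1e-12)


@pytest.mark.parametrize(
    "z, eps, expected", [(0.0, 2.0, 0.0), (1.0, 2.0, 2.0), (9.0, 2.0, 6.0)]
)
def test_value_closed_form_matches_integrated_marginal(z, eps, expected):
    p = MarketParams(eta=1.0, epsilon=eps)
    assert value_fn(z, p) == pytest.approx(expected, rel=1e-12)
    if z > 0:  # marginal value is singular at 0 but integrably so
        integral, _ = quad(lambda u: marginal_value(u, p), 0, z)
        assert value_fn(z, p) == pytest.approx(integral, rel=1e-6)


def test_curvature_domain_errors(params):
    with pytest.raises(DomainError):
        cost_fn(-0.1, params)
    with pytest.raises(DomainError):
        value_fn(-1.0, params)
    with pytest.raises(DomainError):
        MarketParams(eta=-1.0, epsilon=2.0)
    with pytest.raises(DomainError):
        MarketParams(eta=1.0, epsilon=1.0)


# --------------------------------------------------------------------------
# market clearing
# --------------------------------------------------------------------------

def _clearing_oracle(B, T, p):
    """Numerically equate marginal cost and marginal value over Q."""
    Q = brentq(
        lambda q: marginal_cost(q / B, p) - marginal_value(q / T, p), 1e-12, 1e6
    )
    return marginal_cost(Q / B, p), Q


@pytest.mark.parametrize("B, T", [(1.0, 1.0), (0.6, 1.0), (2.5, 0.3), (0.1, 7.0)])
def test_clearing_matches_marginal_condition_oracle(B, T, params):
    price_oracle, Q_oracle = _clearing_oracle(B, T, params)
    assert clearing_price(B, T, params) == pytest.approx(price_oracle, rel=1e-9)
    assert clearing_quantity(B, T, params) == pytest.approx(Q_oracle, rel=1e-9)


def test_clearing_price_derived_value(params):
    # 40% lower reported supply at fixed demand: the comparative static behind
    # the coalition's fee and quantity shifts
    assert clearing_price(0.6, 1.0, params) == pytest.approx(1.1856, abs=1e-4)
    assert clearing_quantity(0.6, 1.0, params) == pytest.approx(0.7114, abs=1e-4)


def test_clearing_symmetry_and_foc_identity(params):
    rng = np.random.default_rng(42)
    for _ in range(25):
        B, T = rng.uniform(0.05, 5.0, 2)
        p = clearing_price(B, T, params)
        Q = clearing_quantity(B, T, params)
        assert p * clearing_price(T, B, params) == pytest.approx(1.0, rel=1e-12)
        # first-order consistency: c'(Q/B) = v'(Q/T) = p
        assert marginal_cost(Q / B, params) == pytest.approx(p, rel=1e-10)
        assert marginal_value(Q / T, params) == pytest.approx(p, rel=1e-10)


def test_clearing_rejects_nonpositive(params):
    for bad in [(0.0, 1.0), (1.0, -2.0)]:
        with pytest.raises(DomainError):
            clearing_price(*bad, params)
        with pytest.raises(DomainError):
            clearing_quantity(*bad, params)


def test_allocation_sums_to_quantity(params):
    m = solve_nash([0.3, 0.7], [0.5, 0.25, 0.25], params)
    q_s = [s.q_access for s in m.sellers]
    q_b = [b.q_access for b in m.buyers]
    assert sum(q_s) == pytest.approx(m.quantity, rel=1e-12)
    assert sum(q_b) == pytest.approx(m.quantity, rel=1e-12)
    # allocation proportional to reports
    rep = m.seller_reports()
    np.testing.assert_allclose(q_s, rep / rep.sum() * m.quantity, rtol=1e-12)


# --------------------------------------------------------------------------
# profits
# --------------------------------------------------------------------------

def test_truthful_monopoly_profits(params):
    # hand-built market with truthful reports: revenue/cost evaluated term by term
    from accessmarket.oligopoly import BuyerState, MarketState, SellerState

    m = MarketState(params=params)
    m.sellers = [SellerState(id="s", b_true=1.0, b_report=1.0)]
    m.buyers = [BuyerState(id="b", t_true=1.0, t_report=1.0)]
    m.price = clearing_price(1.0, 1.0, params)
    m.quantity = clearing_quantity(1.0, 1.0, params)
    allocate(m)
    assert seller_profit(m.sellers[0], m) == pytest.approx(0.5, rel=1e-12)
    assert buyer_profit(m.buyers[0], m) == pytest.approx(1.0, rel=1e-12)


def test_zero_allocation_zero_profit(params):
    from accessmarket.oligopoly import BuyerState, MarketState, SellerState

    m = MarketState(params=params, price=1.0, quantity=1.0)
    s = SellerState(id="s", b_true=2.0, b_report=1.0, q_access=0.0)
    b = BuyerState(id="b", t_true=2.0, t_report=1.0, q_access=0.0)
    assert seller_profit(s, m) == 0.0
    assert buyer_profit(b, m) == 0.0


# --------------------------------------------------------------------------
# report ratios (share form)
# --------------------------------------------------------------------------

def test_report_ratio_endpoints(params):
    assert report_ratio_seller(1.0, params) == pytest.approx(0.5, abs=1e-15)
    assert report_ratio_seller(0.0, params) == pytest.approx(1.0, abs=1e-15)
    assert report_ratio_seller(0.5, params) == pytest.approx(0.8, abs=1e-12)
    assert report_ratio_buyer(1.0, params) == pytest.approx(0.25, abs=1e-15)
    assert report_ratio_buyer(0.0, params) == pytest.approx(1.0, abs=1e-15)


@pytest.mark.parametrize("eta, eps", [(1.0, 2.0), (0.5, 1.5), (1.5, 2.5)])
def test_report_ratios_decrease_in_share(eta, eps):
    p = MarketParams(eta=eta, epsilon=eps)
    s = np.linspace(0, 1, 101)
    assert np.all(np.diff(report_ratio_seller(s, p)) < 0)
    assert np.all(np.diff(report_ratio_buyer(s, p)) < 0)
    assert np.all(report_ratio_seller(s, p) <= 1.0)
    assert np.all(report_ratio_buyer(s, p) <= 1.0)


def test_report_ratio_rejects_bad_share(params):
    with pytest.raises(DomainError):
        report_ratio_seller(1.2, params)
    with pytest.raises(DomainError):
        report_ratio_buyer(-0.1, params)


# --------------------------------------------------------------------------
# best responses
# --------------------------------------------------------------------------

def test_monopoly_best_responses_closed_form():
    for eta, eps in [(1.0, 2.0), (0.5, 1.5), (1.5, 2.5)]:
        p = MarketParams(eta, eps)
        # sole seller has share 1: report ratio ((eps-1)/eps)**eta
        assert seller_best_response(1.0, 0.0, p) == pytest.approx(
            ((eps - 1) / eps) ** eta, rel=1e-12
        )
        # sole buyer: (eta/(eta+1))**eps
        assert buyer_best_response(1.0, 0.0, p) == pytest.approx(
            (eta / (eta + 1)) ** eps, rel=1e-12
        )


def test_vanishing_share_reports_truthfully(params):
    assert seller_best_response(1.0, 1e6, params) == pytest.approx(1.0, rel=1e-5)
    assert buyer_best_response(1.0, 1e6, params) == pytest.approx(1.0, rel=1e-5)


def _seller_profit_of_report(bhat, b_true, b_others, T_hat, p):
    B = bhat + b_others
    price, Q = clearing_price(B, T_hat, p), clearing_quantity(B, T_hat, p)
    return price * bhat / B * Q - b_true * cost_fn(bhat / B * Q / b_true, p)


def _buyer_profit_of_report(that, t_true, t_others, B_hat, p):
    T = that + t_others
    price, Q = clearing_price(B_hat, T, p), clearing_quantity(B_hat, T, p)
    return t_true * value_fn(that / T * Q / t_true, p) - price * that / T * Q


@pytest.mark.parametrize("eta, eps", [(1.0, 2.0), (0.5, 1.5), (1.5, 2.5)])
@pytest.mark.parametrize("rivals", [0.3, 1.0, 4.0])
def test_best_response_maximizes_profit_grid_oracle(eta, eps, rivals):
    """Nash report beats a 10,000-point brute-force grid of alternatives."""
    p = MarketParams(eta, eps)
    b_true, T_hat = 1.0, 0.8
    br = seller_best_response(b_true, rivals, p)
    grid = np.linspace(1e-6, b_true, 10_000)
    prof = _seller_profit_of_report(grid, b_true, rivals, T_hat, p)
    assert _seller_profit_of_report(br, b_true, rivals, T_hat, p) >= prof.max() - 1e-9
    assert abs(grid[prof.argmax()] - br) < 2 * (grid[1] - grid[0])

    t_true, B_hat = 1.0, 1.3
    br_b = buyer_best_response(t_true, rivals, p)
    prof_b = _buyer_profit_of_report(grid, t_true, rivals, B_hat, p)
    assert _buyer_profit_of_report(br_b, t_true, rivals, B_hat, p) >= prof_b.max() - 1e-9
    assert abs(grid[prof_b.argmax()] - br_b) < 2 * (grid[1] - grid[0])


def test_best_response_maximizer_independent_of_other_side(params):
    """The optimal seller report does not depend on buyer-side reports."""
    for T_hat in (0.3, 1.0, 5.0):
        br = minimize_scalar(
            lambda x: -_seller_profit_of_report(x, 1.0, 0.7, T_hat, params),
            bounds=(1e-9, 1.0),
            method="bounded",
        ).x
        assert br == pytest.approx(seller_best_response(1.0, 0.7, params), abs=1e-6)


@pytest.mark.parametrize("sigma", [0.05, 0.2, 0.5, 0.8, 0.95])
def test_share_relation_consistent_with_best_response(sigma, params):
    """The share-form report ratio and the best-response root agree.

    Given a target share sigma, construct the rival report sum implied by
    the ratio equation and check the best response reproduces the report.
    """
    b_true = 1.0
    bhat = report_ratio_seller(sigma, params) * b_true
    b_others = bhat * (1 - sigma) / sigma
    assert seller_best_response(b_true, b_others, params) == pytest.approx(bhat, rel=1e-9)

    t_true = 1.0
    that = report_ratio_buyer(sigma, params) * t_true
    t_others = that * (1 - sigma) / sigma
    assert buyer_best_response(t_true, t_others, params) == pytest.approx(that, rel=1e-9)


# --------------------------------------------------------------------------
# Nash fixed point
# --------------------------------------------------------------------------

def test_nash_one_on_one_closed_form(params):
    m = solve_nash([1.0], [1.0], params)
    assert m.sellers[0].b_report == pytest.approx(0.5, rel=1e-10)
    assert m.buyers[0].t_report == pytest.approx(0.25, rel=1e-10)
    assert m.price == pytest.approx(clearing_price(0.5, 0.25, params), rel=1e-12)
    assert m.quantity == pytest.approx(clearing_quantity(0.5, 0.25, params), rel=1e-12)


@pytest.mark.parametrize("n, m", [(2, 3), (5, 2), (8, 8)])
def test_nash_symmetric_matches_share_equation(n, m, params):
    """Identical agents hold share 1/n, so reports follow the ratio closed form."""
    sol = solve_nash(np.full(n, 1.0 / n), np.full(m, 1.0 / m), params)
    b_exp = report_ratio_seller(1.0 / n, params) / n
    t_exp = report_ratio_buyer(1.0 / m, params) / m
    np.testing.assert_allclose(sol.seller_reports(), b_exp, rtol=1e-9)
    np.testing.assert_allclose(sol.buyer_reports(), t_exp, rtol=1e-9)


def test_nash_competitive_limit(params):
    n = 400
    sol = solve_nash(np.full(n, 1.0 / n), np.full(n, 1.0 / n), params)
    assert sol.B_hat == pytest.approx(1.0, rel=2e-3)
    assert sol.T_hat == pytest.approx(1.0, rel=3e-3)


def test_nash_reports_underreport_and_satisfy_share_relation(params):
    rng = np.random.default_rng(3)
    b = random_endowments(rng, 5)
    t = random_endowments(rng, 4)
    sol = solve_nash(b, t, params)
    for s, b_true in zip(sol.sellers, b):
        assert 0 < s.b_report <= b_true
    for bb, t_true in zip(sol.buyers, t):
        assert 0 < bb.t_report <= t_true
    # realized-share consistency with the ratio equations
    rep = sol.seller_reports()
    sigma = rep / rep.sum()
    np.testing.assert_allclose(rep / b, report_ratio_seller(sigma, params), rtol=1e-8)
    rep_t = sol.buyer_reports()
    s_share = rep_t / rep_t.sum()
    np.testing.assert_allclose(rep_t / t, report_ratio_buyer(s_share, params), rtol=1e-8)


def test_nash_unique_across_initializations(params):
    rng = np.random.default_rng(9)
    b = random_endowments(rng, 6)
    base = solve_seller_reports(b, params)
    for _ in range(5):
        init = rng.uniform(0.01, 1.0, 6) * b
        np.testing.assert_allclose(
            solve_seller_reports(b, params, init=init), base, rtol=1e-8
        )


def test_nash_oracle_small_markets_grid(params):
    """Each Nash report maximizes its own profit on a fine grid, rivals fixed."""
    rng = np.random.default_rng(17)
    for _ in range(3):
        b = random_endowments(rng, int(rng.integers(2, 6)))
        t = random_endowments(rng, int(rng.integers(2, 6)))
        sol = solve_nash(b, t, params)
        T_hat, B_hat = sol.T_hat, sol.B_hat
        for i, s in enumerate(sol.sellers):
            rivals = B_hat - s.b_report
            grid = np.linspace(1e-6 * b[i], b[i], 10_000)
            prof = _seller_profit_of_report(grid, b[i], rivals, T_hat, params)
            own = _seller_profit_of_report(s.b_report, b[i], rivals, T_hat, params)
            assert own >= prof.max() - 1e-9
        for j, bb in enumerate(sol.buyers):
            rivals = T_hat - bb.t_report
            grid = np.linspace(1e-6 * t[j], t[j], 10_000)
            prof = _buyer_profit_of_report(grid, t[j], rivals, B_hat, params)
            own = _buyer_profit_of_report(bb.t_report, t[j], rivals, B_hat, params)
            assert own >= prof.max() - 1e-9


def test_buyer_subgame_invariant_to_sellers(params):
    """Buyer Nash reports are identical across different seller endowments."""
    rng = np.random.default_rng(5)
    t = random_endowments(rng, 6)
    ref = solve_buyer_reports(t, params)
    for n in (1, 3, 10):
        sol = solve_nash(random_endowments(rng, n), t, params)
        np.testing.assert_allclose(sol.buyer_reports(), ref, rtol=1e-10)


def test_merging_sellers_comparative_statics(params):
    """Merging sellers (total biomass fixed) lowers reports, raises the fee,
    lowers quantity, and raises the merged entity's profit."""
    rng = np.random.default_rng(23)
    for _ in range(5):
        n = int(rng.integers(3, 7))
        b = random_endowments(rng, n)
        t = random_endowments(rng, int(rng.integers(2, 6)))
        pre = solve_nash(b, t, params)
        k = int(rng.integers(2, n + 1))
        idx = rng.choice(n, size=k, replace=False)
        merged = np.concatenate([[b[idx].sum()], np.delete(b, idx)])
        post = solve_nash(merged, t, params)
        assert post.B_hat < pre.B_hat + 1e-12
        assert post.price > pre.price - 1e-12
        assert post.quantity < pre.quantity + 1e-12
        pre_profit = sum(pre.sellers[i].profit for i in idx)
        assert post.sellers[0].profit >= pre_profit - 1e-12


def test_truthful_reports_maximize_surplus(params):
    """Conditional on truthful reports the mechanism is efficient."""
    B, T = 0.8, 1.7
    p = clearing_price(B, T, params)
    Q = clearing_quantity(B, T, params)

    def neg_surplus(q):
        return -(T * value_fn(q / T, params) - B * cost_fn(q / B, params))

    res = minimize_scalar(neg_surplus, bounds=(1e-9, 10.0), method="bounded")
    assert Q == pytest.approx(res.x, rel=1e-5)
    assert p == pytest.approx(marginal_cost(Q / B, params), rel=1e-10)


def test_degenerate_markets_rejected(params):
    with pytest.raises(DegenerateMarketError):
        solve_nash([], [1.0], params)
    with pytest.raises(DegenerateMarketError):
        solve_nash([1.0], [0.0], params)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    eta=st.floats(0.3, 2.0),
    eps=st.floats(1.1, 3.0),
    b=st.lists(st.floats(0.05, 10.0), min_size=1, max_size=4),
    t=st.lists(st.floats(0.05, 10.0), min_size=1, max_size=4),
)
def test_nash_invariants_property(eta, eps, b, t):
    """Underreporting, clearing and first-order consistency for random markets."""
    p = MarketParams(eta, eps)
    sol = solve_nash(b, t, p)
    assert np.all(sol.seller_reports() <= np.asarray(b) + 1e-12)
    assert np.all(sol.seller_reports() > 0)
    assert np.all(sol.buyer_reports() <= np.asarray(t) + 1e-12)
    assert sum(s.q_access for s in sol.sellers) == pytest.approx(sol.quantity, rel=1e-10)
    assert marginal_cost(sol.quantity / sol.B_hat, p) == pytest.approx(sol.price, rel=1e-9)
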