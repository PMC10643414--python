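# accessmarket

Bilateral-oligopoly analysis of international fishing-access markets:
what happens to access fees, catch, profits and fish stocks when coastal
states that sell fishing access to foreign fleets form a cartel — or when an
existing cartel dissolves.

Coastal states in regions like West Africa sell the right to fish in their
Exclusive Economic Zones to distant-water fishing nations, mostly one by one
and at low fees; the Pacific bloc that sells tuna access jointly earns far
more per ton. This package implements the market model behind that
comparison and the machinery to simulate coalition counterfactuals on
calibrated or synthetic markets, for fisheries economists and bioeconomic
modellers.

## The model

**Market.** Seller *i* holds true biomass *bᵢ*, buyer *j* true distant-water
fleet gross tonnage *tⱼ* (both normalized to shares). Each agent reports an
endowment (b̂ᵢ, t̂ⱼ) to a mechanism that clears the market with
constant-elasticity cost and value functions

    c(z) = η/(η+1) · z^((η+1)/η)        (seller opportunity cost, η > 0)
    v(z) = ε/(ε−1) · z^((ε−1)/ε)        (buyer fishing profit,  ε > 1)

giving closed-form fee and total quantity in the report totals B̂ = Σb̂ᵢ,
T̂ = Σt̂ⱼ:

    p(B̂, T̂) = B̂^(−1/(ε+η)) · T̂^(1/(ε+η))
    Q(B̂, T̂) = B̂^(ε/(ε+η))  · T̂^(η/(ε+η))

with qᵢ = (b̂ᵢ/B̂)·Q and qⱼ = (t̂ⱼ/T̂)·Q. Market power is exercised by
underreporting: at the Nash equilibrium in reports,

    b̂ᵢ/bᵢ = (1 − σᵢ/(ε + η(1−σᵢ)))^η,   t̂ⱼ/tⱼ = (1 + sⱼ/(ε(1−sⱼ) + η))^(−ε)

where σᵢ, sⱼ are quantity shares — a price taker reports truthfully, a sole
seller at η=1, ε=2 reports exactly half its true biomass. The equilibrium is
found by synchronous best-response iteration on the per-agent polynomial
first-order conditions.

**Biology.** Each seller carries one aggregate Pella-Tomlinson stock,
growth(b) = (φ+1)/φ · g·b·(1 − (b/k)^φ), with φ = 0.188 so that b_MSY sits
at 40% of carrying capacity. Carrying capacity is calibrated from observed
mean annual catch *h* assuming the stock is in equilibrium at depletion
d = b/b_MSY (default 0.8).

**Counterfactuals.** A country's *access policy function* (access catch
allowed vs. its biomass) is derived numerically by perturbing its biomass on
a 1%-of-carrying-capacity grid and re-solving the market; non-access
(domestic + unauthorized) catch is linear with slope (h − q*)/b. Coalition
scenarios merge sellers, re-derive policies, and find each country's new
steady state where total catch crosses stock growth. Scenarios: status quo,
continental coalition, regional blocs, and bloc dissolution
(Pacific-style), plus robustness sweeps over (η, ε, d).

## Worked example

The numbered drivers under `analysis/` run the full pipeline on a
deterministic synthetic market (32 heterogeneous sellers, 33 buyers with an
EU-like anchor holding ~11.5% of purchases; see `analysis/config.yaml`).
`python analysis/02_status_quo.py && python analysis/03_continental_coalition.py`
prints:

```
Nash equilibrium: total biomass report 0.970 (truth 1.0), fee 0.997 units, quantity 0.966 units
...
            quantity     status_quo   continental     difference  pct_difference
   access_catch_tons     853,109.16    589,988.02    -263,121.15          -30.84
nonaccess_catch_tons   3,526,894.97  3,858,715.86     331,820.89            9.41
    total_catch_tons   4,380,004.13  4,448,703.88      68,699.75            1.57
        biomass_tons  13,771,491.60 15,366,616.29   1,595,124.68           11.58
     fee_usd_per_ton         128.20        154.14          25.94           20.23
   seller_profit_usd  56,289,218.85 68,224,275.76  11,935,056.91           21.20
    buyer_profit_usd 113,900,605.74 94,735,125.81 -19,165,479.93          -16.83

coalition biomass report: 0.558 units (42% below the status-quo total report 0.970)
emergent coalition true biomass share: 1.116 (status-quo total = 1)
```

Reading: merging 32 individual sellers into one cartel cuts reported supply
by ~42%, which lifts the clearing fee ~20% and cuts access catch ~31%;
the resulting stock recovery (+12% biomass) lets domestic catch rise enough
that *total* catch barely changes, while seller profits rise ~21% and buyer
profits fall ~17%. In the status quo every country's steady-state biomass
reproduces its calibrated value — the pipeline's core self-consistency
check. Drivers 04–06 run the regional-bloc scenario, the bloc-dissolution
(Pacific-style) scenario, and the (η, ε, depletion) robustness sweep;
summary tables land in `results/`.

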