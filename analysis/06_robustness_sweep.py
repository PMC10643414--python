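"""Robustness: the cartel's qualitative effects across elasticities and depletion.

Repeats status quo + continental coalition over a grid of cost elasticity
eta, value elasticity epsilon, and assumed depletion, on a reduced market
(the full market repeated 27 times would add nothing qualitative).  The
cartel directions — lower total reports and access catch, higher fee and
seller profit, higher biomass — hold at every grid point.
"""

from common import CONFIG, synth_spec, write

from accessmarket import sweep
from accessmarket.synth import gen_market


def main() -> None:
    syn = gen_market(synth_spec(n_sellers=8, n_buyers=8))
    table = sweep(
        syn.sellers, syn.buyers, **syn.anchor,
        etas=(0.5, 1.0, 1.5),
        epsilons=(1.5, 2.0, 2.5),
        depletions=(0.4, 0.6, 0.8),
        grid_pct=CONFIG["grid_pct"],
    )
    write(table, "robustness_sweep.csv")

    cols = ["eta", "epsilon", "depletion", "pct_access_catch_tons",
            "pct_fee_usd_per_ton", "pct_seller_profit_usd", "pct_biomass_tons"]
    print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.1f}"))
    ok = (
        (table["co_report_units"] < table["sq_report_units"])
        & (table["pct_access_catch_tons"] < 0)
        & (table["pct_fee_usd_per_ton"] > 0)
        & (table["pct_seller_profit_usd"] > 0)
        & (table["pct_biomass_tons"] > 0)
    )
    print(f"\ncartel directions hold at {int(ok.sum())}/{len(table)} grid points")


if __name__ == "__main__":
    main()
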