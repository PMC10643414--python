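"""Generate the synthetic access market and verify participant identification.

Writes the four input tables (sellers, buyers, pairwise fishing hours,
vessel register) under results/, and checks that the hours-threshold rule
and the distant-water classification recover the generator's planted truth.
"""

from common import CONFIG, synth_spec, write

from accessmarket import classify_dwf, identify_participants
from accessmarket.synth import gen_hours, gen_market


def main() -> None:
    spec = synth_spec()
    syn = gen_market(spec)
    write(syn.sellers, "synthetic_sellers.csv")
    write(syn.buyers, "synthetic_buyers.csv")
    total_catch = syn.sellers["catch_tons"].sum()
    print(f"{len(syn.sellers)} sellers, total catch {total_catch/1e6:.2f} M tons/yr")
    print(f"{len(syn.buyers)} buyers, total DWF tonnage "
          f"{syn.buyers['gross_tonnage'].sum()/1e6:.2f} M GT")
    print(f"anchor buyer {syn.anchor['anchor_buyer_id']}: agreements "
          f"{syn.anchor['anchor_purchase_tons']:,.0f} tons/yr at "
          f"${syn.anchor['anchor_fee_usd']}/ton")

    truth = gen_hours(spec)
    write(truth.hours.round({"hours": 1}), "synthetic_hours.csv")
    write(truth.vessels.round({"hours_inside": 1, "hours_outside": 1,
                               "gross_tonnage": 1}), "synthetic_vessels.csv")
    sellers, buyers = identify_participants(truth.hours, CONFIG["threshold_hours"])
    assert set(buyers) == truth.buyers and set(sellers) == truth.sellers
    dwf = classify_dwf(truth.vessels)
    assert set(truth.vessels.loc[dwf.to_numpy(), "vessel_id"]) == truth.dwf
    print(f"hours-threshold rule recovers {len(buyers)} planted buyers / "
          f"{len(sellers)} planted sellers; DWF classification recovers "
          f"{int(dwf.sum())} planted distant-water vessels")


if __name__ == "__main__":
    main()
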