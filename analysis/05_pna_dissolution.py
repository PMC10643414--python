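"""Cartel dissolution in a Pacific-style bloc market.

Here the bloc (nine island sellers jointly setting access) is the observed
status quo and individual selling is the counterfactual.  All foreign catch
is treated as access catch in the main specification (half, as a
robustness variant), and a member whose apportioned access exceeds its
observed catch gets a repaired, peer-average non-access slope.  Dissolving
the bloc depletes every member's stock and lowers member profits.
"""

import warnings

import pandas as pd
from common import CONFIG, write

from accessmarket import run_pna

# nine bloc members: similar stocks, one catch-light laggard whose
# apportioned access exceeds its observed catch (slope repair case)
SELLERS = pd.DataFrame(
    {
        "id": [f"ISL{i}" for i in range(8)] + ["LAG"],
        "catch_tons": [1.0e5] * 8 + [1.2e5],
        "growth_g": [0.2] * 8 + [0.17],
    }
)
BUYERS = pd.DataFrame(
    {"id": [f"DWF{j}" for j in range(4)], "gross_tonnage": [5e4, 2e4, 1e4, 5e3]}
)
FOREIGN_CATCH_TONS = 8.5e5
PNA_FEE_USD = 307.0


def main() -> None:
    for frac in (1.0, 0.5):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            coalition, dissolved = run_pna(
                SELLERS, BUYERS,
                foreign_catch_tons=FOREIGN_CATCH_TONS,
                access_fraction=frac,
                anchor_fee_usd=PNA_FEE_USD,
                depletion=CONFIG["depletion"],
            )
        repaired = [str(w.message) for w in caught if "repaired" in str(w.message)]
        table = dissolved.result.table_vs(coalition.result)
        print(f"\naccess fraction {frac}:"
              + (f" ({repaired[0]})" if repaired else " (no slope repair needed)"))
        print(table.to_string(index=False, float_format=lambda x: f"{x:,.2f}"))
        if frac == 1.0:
            write(table, "pna_dissolution_vs_coalition.csv")
            d = dissolved.result.pct_diff(coalition.result)
            print(f"\ndissolution: biomass {d['biomass_tons']:.0f}%, "
                  f"member profit {d['seller_profit_usd']:.0f}%")


if __name__ == "__main__":
    main()
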