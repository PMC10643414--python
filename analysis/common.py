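"""Shared plumbing for the numbered analysis drivers.

Every driver reconstructs its inputs deterministically from analysis/config.yaml,
so the scripts can run standalone and in any order.
"""

from pathlib import Path

from accessmarket import MarketParams, build_market, load_config, run_status_quo
from accessmarket.synth import SynthSpec, gen_market

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"
CONFIG = load_config(HERE / "config.yaml")


def synth_spec(**overrides) -> SynthSpec:
    base = dict(
        seed=CONFIG["seed"],
        n_sellers=CONFIG["n_sellers"],
        n_buyers=CONFIG["n_buyers"],
        anchor_buyer_share=CONFIG["anchor_buyer_share"],
        anchor_fee_usd=CONFIG["anchor_fee_usd"],
        access_catch_fraction=CONFIG["access_catch_fraction"],
        depletion=CONFIG["depletion"],
        phi=CONFIG["phi"],
    )
    base.update(overrides)
    return SynthSpec(**base)


def get_market(**overrides):
    syn = gen_market(synth_spec(**overrides))
    params = MarketParams(eta=CONFIG["eta"], epsilon=CONFIG["epsilon"])
    market = build_market(
        syn.sellers, syn.buyers, params,
        depletion=CONFIG["depletion"], phi=CONFIG["phi"],
    )
    return syn, market


def get_status_quo(**overrides):
    syn, market = get_market(**overrides)
    return syn, run_status_quo(market, grid_pct=CONFIG["grid_pct"], **syn.anchor)


def write(df, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, index=False)
    return path
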