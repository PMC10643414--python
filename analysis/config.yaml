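# Run configuration for the synthetic access-market analysis.
eta: 1.0
epsilon: 2.0
phi: 0.188
depletion: 0.8
threshold_hours: 2420
seed: 7
n_sellers: 32
n_buyers: 33
anchor_fee_usd: 128.20     # observed weighted-average access fee, 2020 USD/ton
anchor_buyer_share: 0.115  # anchor buyer's share of access purchases
access_catch_fraction: 0.21
grid_pct: 1.0
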