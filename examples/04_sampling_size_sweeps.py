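"""Sweep the per-round sampling sizes N_o and N_u.

Two protocol experiments on one synthetic table: first the artificial
minority count N_o is swept over multiples of the minority count with the
majority sample held at the minority count; then the majority sample N_u is
swept with N_o held fixed. Extra near-duplicate minority examples typically
buy little (flat N_o response), while growing N_u re-imbalances the round
samples and erodes the G-mean.
"""

import logging

import husdosboost as hb

logging.disable(logging.WARNING)

dataset, _ = hb.generate_eism(hb.SynthConfig(n_min=20, n_maj=600, seed=4))
config = hb.BoostConfig(n_rounds=50, seed=4)
protocol = hb.CVProtocol(n_folds=5, n_repeats=1, seed=4)

for name, sweep in [
    ("N_o (artificial minority per round)",
     hb.sweep_oversampling(dataset, [1, 2, 4, 6], config, protocol)),
    ("N_u (majority sample per round)",
     hb.sweep_undersampling(dataset, [1, 2, 4, 6], config, protocol)),
]:
    print(f"\nsweep over {name}:")
    frame = sweep.to_frame()
    for _, row in frame.iterrows():
        print(f"  {row['multiplier']:.0f} x minority -> "
              f"G-mean {row['g_mean_mean']:.2f}±{row['g_mean_sd']:.2f}")
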