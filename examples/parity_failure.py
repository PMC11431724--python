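"""The parity failure mode: where transparent models are set up to lose.

The target equals 1 exactly when a hidden 5-bit subset sums to an even
number.  No single bit, pair of bits, or quadratic carries any marginal
signal, so a method searching mains + pairwise interactions must score at
chance.  This is a structural limit, not a tuning failure.
"""

import numpy as np

from sparserank import auc, simulate, srl_fit, train_test_split

scores = []
for seed in range(5):
    df, info = simulate.gen_parity(seed=seed)
    tr, te = train_test_split(len(df), 0.2, seed=seed, labels=df["target"])
    model = srl_fit(df.iloc[tr], "target", seed=seed)
    pred = model.predict(df.iloc[te], at="min")
    scores.append(auc(df["target"].iloc[te], pred))
    print(
        f"seed {seed}: hidden subset {info['subset']}, "
        f"terms selected {len(model.selected_terms('min'))}, "
        f"held-out AUC {scores[-1]:.3f}"
    )

print(f"\nmean AUC over {len(scores)} seeds: {np.mean(scores):.3f}")
print("AUC ~ 0.5 means chance: pairwise expansion cannot express a 5-way parity.")
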