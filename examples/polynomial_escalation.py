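"""Escalating the polynomial order when the default is too stiff.

A binary outcome driven by a degree-7 oscillating polynomial of an
integer covariate defeats the default quadratic cap, but raising the cap
(poly=7) lets the ranked-sparsity weights consider higher powers while
still demanding more evidence for each additional order.
"""

import numpy as np

from sparserank import auc, simulate, srl_fit, train_test_split

df, info = simulate.gen_high_order_polynomial(seed=3)
print(f"n = {len(df)}, planted degree = {info['degree']}\n")

for poly in (2, 7):
    scores = []
    for split in range(5):
        tr, te = train_test_split(len(df), 0.2, seed=split, labels=df["target"])
        m = srl_fit(df.iloc[tr], "target", poly=poly, seed=split)
        scores.append(auc(df["target"].iloc[te], m.predict(df.iloc[te], at="min")))
    print(
        f"poly={poly}: median held-out AUC over {len(scores)} splits = "
        f"{np.median(scores):.3f}"
    )

print(
    "\nThe quadratic cap cannot express the oscillation (AUC near chance);"
    "\nallowing seventh-order terms recovers most of the discriminative signal."
)
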