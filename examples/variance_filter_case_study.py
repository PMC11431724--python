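"""When the default variance filter hides the signal.

The outcome here is zero-inflated and right-skewed, and almost all of its
variance comes from a rare event: two skewed categorical factors landing
on their top level simultaneously, which adds ~13,000 to the target.  The
corresponding interaction dummy is nearly constant, so the default
near-zero-variance (nzv) screen removes it — and every other candidate
interaction — before the supervised step ever sees it.  Switching to
zero-variance (zv) filtering keeps any interaction with variance, and the
planted term is selected, transforming the fit.
"""

from sparserank import simulate, srl_fit

df, info = simulate.gen_zero_inflated_outcome(seed=7)
print(
    f"n = {len(df)}, zero fraction = {(df['target'] == 0).mean():.2f}, "
    f"planted term: {info['interaction_term']}\n"
)

for mode in ("nzv", "zv"):
    model = srl_fit(df, "target", filter_mode=mode, seed=7)
    n_int = sum(":" in t for t in model.recipe.term_ids_)
    cv = model.cv
    print(
        f"filter={mode}: {n_int} interaction candidates survive | "
        f"CV R^2 (lambda_min) = {cv.cv_r2[cv.idx_min]:.3f}, "
        f"(lambda_1se) = {cv.cv_r2[cv.idx_1se]:.3f}"
    )
    print(f"  selected at lambda_min: {model.selected_terms('min')}")

print(
    "\nUnder nzv the interaction block is emptied and R^2 collapses; under zv"
    "\nthe planted dummy is recovered and the model explains the heavy tail."
)
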