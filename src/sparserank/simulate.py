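"""Synthetic data emulating the benchmark case-study structures.

Each generator is a pure function of its arguments (fixed seed gives
byte-identical output) and returns ``(DataFrame, info)`` where ``info``
records the ground truth needed to score recovery.

Scenarios:

* ``gen_parity`` — binary parity target on i.i.d. Bernoulli(1/2) bits:
  the outcome is 1 exactly when the sum over a hidden 5-bit subset is
  even.  Every feature and every low-order product is marginally
  independent of the target, so any method restricted to pairwise
  interactions is forced to chance-level AUC.
* ``gen_interaction_signal`` — Gaussian outcome with known main and
  pairwise-interaction coefficients on standard-normal covariates.
* ``gen_zero_inflated_outcome`` — an apnea-like regression target: point
  mass at zero, right-skewed positive part, and a very large bump when two
  skewed categorical factors simultaneously take their rare high level.
  All predictors are categorical with skewed margins, so every candidate
  interaction dummy is nearly constant — the structure that makes
  near-zero-variance filtering remove the entire interaction block while
  zero-variance filtering keeps the planted one.
* ``gen_high_order_polynomial`` — a boxing-like binary outcome driven by a
  degree-7 polynomial of a 1-12 integer covariate (a Chebyshev shape with
  essentially no linear or quadratic component), plus a weak binary main
  effect.
* ``gen_benchmark_suite`` — a mix of regression/classification datasets
  with known attainable signal, for offline end-to-end harness tests.
* ``gen_meta_table`` — per-dataset, per-algorithm metrics with planted
  algorithm offsets and dataset random effects, for meta-model tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "gen_parity",
    "gen_interaction_signal",
    "gen_zero_inflated_outcome",
    "gen_high_order_polynomial",
    "gen_benchmark_suite",
    "gen_meta_table",
]


def gen_parity(n: int = 1124, p_bits: int = 10, subset=(2, 3, 4, 6, 8), seed: int = 0):
    """Binary parity target: 1 iff the hidden subset's bit sum is even."""
    subset = tuple(subset)
    if len(subset) != 5 or not set(subset) <= set(range(1, p_bits + 1)):
        raise ValueError("subset must be 5 distinct indices in 1..p_bits")
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, p_bits))
    cols = [f"x{i}" for i in range(1, p_bits + 1)]
    s = X[:, [i - 1 for i in subset]].sum(axis=1)
    target = (s % 2 == 0).astype(int)
    df = pd.DataFrame(X, columns=cols)
    df["target"] = target
    return df, {"subset": subset}


def gen_interaction_signal(
    n: int = 500,
    p_main: int = 6,
    main_coefs=(1.0, 0.5, 0.5, 0.0, 0.0, 0.0),
    interactions=(((1, 2), 1.0),),
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Gaussian outcome with planted mains and pairwise interactions.

    Covariates are independent standard normal, so the population R^2 of
    the true model is (sum beta^2 + sum gamma^2) / (same + noise_sd^2).
    """
    main_coefs = np.asarray(main_coefs, dtype=float)
    if main_coefs.size != p_main:
        raise ValueError("main_coefs length must equal p_main")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p_main))
    y = X @ main_coefs
    for (i, j), g in interactions:
        y = y + g * X[:, i - 1] * X[:, j - 1]
    y = y + noise_sd * rng.standard_normal(n)
    cols = [f"x{i}" for i in range(1, p_main + 1)]
    df = pd.DataFrame(X, columns=cols)
    df["target"] = y
    signal_var = float(np.sum(main_coefs**2) + sum(g**2 for _, g in interactions))
    info = {
        "main_coefs": {c: float(b) for c, b in zip(cols, main_coefs)},
        "interactions": {
            f"x{min(i, j)}:x{max(i, j)}": float(g) for (i, j), g in interactions
        },
        "population_r2": signal_var / (signal_var + noise_sd**2),
    }
    return df, info


_LEVEL_PROBS = (0.6, 0.1, 0.1, 0.2)  # skewed margins; rare pairwise co-occurrence


def gen_zero_inflated_outcome(
    n: int = 475,
    zero_prob: float = 0.5,
    skew_scale: float = 1.2,
    factor_levels: int = 4,
    interaction_bump: float = 13_000.0,
    main_bump: float = 800.0,
    seed: int = 0,
):
    """Zero-inflated, right-skewed target with a huge two-factor interaction.

    Two categorical predictors with skewed level frequencies (levels
    "0".."3"), two skewed binary nuisance factors, a point mass at zero,
    a log-normal positive part, modest main bumps when either factor is at
    its top level, and ``interaction_bump`` added when both are.
    """
    if not 0 < zero_prob < 1:
        raise ValueError("zero_prob must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.asarray(_LEVEL_PROBS[:factor_levels], dtype=float)
    probs = probs / probs.sum()
    top = str(factor_levels - 1)
    a = rng.choice(factor_levels, size=n, p=probs).astype(str)
    b = rng.choice(factor_levels, size=n, p=probs).astype(str)
    z1 = (rng.random(n) < 0.07).astype(int)
    z2 = (rng.random(n) < 0.07).astype(int)

    base = np.where(
        rng.random(n) < zero_prob,
        0.0,
        rng.lognormal(mean=np.log(200.0), sigma=skew_scale, size=n),
    )
    y = (
        base
        + main_bump * (a == top)
        + main_bump * (b == top)
        + interaction_bump * ((a == top) & (b == top))
    )
    df = pd.DataFrame(
        {"factor_a": a, "factor_b": b, "noise_1": z1, "noise_2": z2, "target": y}
    )
    info = {
        "interaction_term": f"factor_a={top}:factor_b={top}",
        "top_level": top,
        "interaction_bump": interaction_bump,
    }
    return df, info


def gen_high_order_polynomial(
    n: int = 120, degree: int = 7, amplitude: float = 2.5, seed: int = 0
):
    """Binary outcome from a degree-7 Chebyshev polynomial of a 1-12 integer.

    The Chebyshev shape oscillates over the covariate range, so a
    quadratic approximation carries almost none of the signal while a
    degree-7 polynomial captures it fully.
    """
    rng = np.random.default_rng(seed)
    rounds = rng.integers(1, 13, size=n)
    official = rng.integers(0, 2, size=n)
    u = (rounds - 6.5) / 5.5
    cheb = np.polynomial.chebyshev.chebval(u, [0.0] * degree + [1.0])
    logit = amplitude * cheb + 0.4 * (official - 0.5)
    p = 1.0 / (1.0 + np.exp(-logit))
    target = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"official": official, "round": rounds, "target": target})
    return df, {"degree": degree, "amplitude": amplitude}


def gen_benchmark_suite(n_datasets: int = 6, n: int = 300, seed: int = 0):
    """Mixture of regression and classification datasets with known signal."""
    if n_datasets < 3:
        raise ValueError("need at least 3 datasets")
    rng = np.random.default_rng(seed)
    suite = []
    for d in range(n_datasets):
        ds_seed = int(rng.integers(0, 2**31 - 1))
        if d % 2 == 0:
            strength = 0.5 + 1.5 * (d % 3)
            df, info = gen_interaction_signal(
                n=n,
                main_coefs=(strength, 0.5, 0.5, 0.0, 0.0, 0.0),
                interactions=(((1, 2), 0.5),),
                seed=ds_seed,
            )
            endpoint = "continuous"
        else:
            sub_rng = np.random.default_rng(ds_seed)
            p = 5
            X = sub_rng.standard_normal((n, p))
            beta = np.zeros(p)
            beta[:2] = 1.0 + 0.5 * (d % 3)
            prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
            y = (sub_rng.random(n) < prob).astype(int)
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(1, p + 1)])
            df["target"] = y
            info = {"beta": beta.tolist()}
            endpoint = "binary"
        suite.append(
            {"name": f"synthetic_{d:02d}", "data": df, "endpoint": endpoint, "truth": info}
        )
    return suite


def gen_meta_table(
    n_datasets: int = 40,
    algorithms=("srl", "lasso", "nn"),
    offsets=(0.0, -0.05, -0.15),
    baseline_mean: float = 0.6,
    dataset_sd: float = 0.15,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dataset, per-algorithm metric table with planted structure."""
    rng = np.random.default_rng(seed)
    effects = baseline_mean + dataset_sd * rng.standard_normal(n_datasets)
    rows = []
    for d in range(n_datasets):
        for alg, off in zip(algorithms, offsets):
            rows.append(
                {
                    "dataset": f"ds{d:03d}",
                    "algorithm": alg,
                    "test_metric": effects[d] + off + noise_sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
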