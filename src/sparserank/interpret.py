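"""Transparency deliverables: coefficient tables and effect profiles.

The solver works on standardized columns, and interaction/polynomial
columns are built from centered-and-scaled parents and then standardized
again.  To report coefficients on the original scale, every model column
is expanded symbolically into a polynomial in the raw (encoded) features;
contributions are accumulated onto canonical monomials — intercept, mains,
pairwise-and-higher products, and pure powers — which are exactly the term
ids of the candidate set.  Predictions from the original-scale table on
raw features agree with the standardized-scale model to floating-point
accuracy.

Effect profiles trace the model's predicted outcome as one focal covariate
sweeps its observed training range, with every other covariate pinned at
its training median (continuous) or mode (categorical); an optional
moderator produces one curve per moderator level, which is how interaction
effects are visualized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import SRLModel
from .terms import interaction_id, polynomial_id

__all__ = ["CoefficientTable", "EffectProfile", "coefficient_table", "effect_profile"]

INTERCEPT = "(Intercept)"


# -- polynomial-in-raw-features algebra --------------------------------------
# A "poly" maps monomial keys to coefficients; a key is a sorted tuple of
# (variable, exponent) pairs, () being the constant monomial.


def _poly_scale(a: dict, s: float) -> dict:
    return {k: v * s for k, v in a.items()}


def _poly_add(a: dict, b: dict) -> dict:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0.0) + v
    return out


def _key_mul(k1, k2):
    powers: dict = {}
    for var, e in (*k1, *k2):
        powers[var] = powers.get(var, 0) + e
    return tuple(sorted(powers.items()))


def _poly_mul(a: dict, b: dict) -> dict:
    out: dict = {}
    for k1, v1 in a.items():
        for k2, v2 in b.items():
            k = _key_mul(k1, k2)
            out[k] = out.get(k, 0.0) + v1 * v2
    return out


def _poly_pow(a: dict, d: int) -> dict:
    out = {(): 1.0}
    for _ in range(d):
        out = _poly_mul(out, a)
    return out


def _monomial_term_id(key) -> str:
    if len(key) == 0:
        return INTERCEPT
    if len(key) == 1:
        var, e = key[0]
        return var if e == 1 else polynomial_id(var, e)
    if any(e != 1 for _, e in key):
        raise ValueError(f"unexpected mixed monomial {key}")
    return interaction_id([var for var, _ in key])


def _monomial_kind(key) -> str:
    if len(key) == 0:
        return "intercept"
    if len(key) == 1:
        return "main" if key[0][1] == 1 else "polynomial"
    return "interaction"


@dataclass
class CoefficientTable:
    table: pd.DataFrame  # term, kind, coef_original, coef_standardized, selected_at
    at: str

    def predict(self, data: pd.DataFrame, recipe) -> np.ndarray:
        """Evaluate the original-scale polynomial on raw (encoded) features."""
        parents = recipe.parent_frame(data)
        out = np.zeros(len(parents))
        for _, row in self.table.iterrows():
            out += row["coef_original"] * _eval_monomial(row["_key"], parents)
        return out


def _eval_monomial(key, parents: pd.DataFrame) -> np.ndarray:
    v = np.ones(len(parents))
    for var, e in key:
        v = v * parents[var].to_numpy(dtype=float) ** e
    return v


def coefficient_table(model: SRLModel, at: str = "1se") -> CoefficientTable:
    """Original-scale coefficient table for the selection ``at`` ("min"/"1se")."""
    recipe = model.recipe
    b0, beta, ids = model.coefficients(at)
    pmeans, pscales = recipe.parent_stats_
    dmeans, dscales = recipe.derived_stats_
    parent_poly = {
        name: {(): -m / s, ((name, 1),): 1.0 / s}
        for name, m, s in zip(recipe.parent_columns_, pmeans, pscales)
    }
    full_ids = recipe.full_termset_.ids
    dstat = {tid: (dmeans[j], dscales[j]) for j, tid in enumerate(full_ids)}
    terms = {t.id: t for t in recipe.termset_.terms}

    total = {(): float(b0)}
    for tid, b in zip(ids, beta):
        if b == 0.0:
            continue
        t = terms[tid]
        if t.kind == "main":
            q = parent_poly[t.parents[0]]
        elif t.kind == "interaction":
            q = parent_poly[t.parents[0]]
            for p in t.parents[1:]:
                q = _poly_mul(q, parent_poly[p])
        else:
            q = _poly_pow(parent_poly[t.parents[0]], t.order)
        m, s = dstat[tid]
        col_poly = _poly_scale(_poly_add(q, {(): -m}), 1.0 / s)
        total = _poly_add(total, _poly_scale(col_poly, float(b)))

    sel_min = set(model.selected_terms("min"))
    sel_1se = set(model.selected_terms("1se"))
    std_coef = dict(zip(ids, beta))

    rows = []
    seen_ids = set()
    for key, coef in sorted(total.items(), key=lambda kv: _monomial_term_id(kv[0])):
        tid = _monomial_term_id(key)
        seen_ids.add(tid)
        in_min, in_1se = tid in sel_min, tid in sel_1se
        selected = (
            "both" if in_min and in_1se else "lambda_min" if in_min else "lambda_1se" if in_1se else "none"
        )
        rows.append(
            {
                "term": tid,
                "kind": _monomial_kind(key),
                "coef_original": coef,
                "coef_standardized": float(std_coef.get(tid, 0.0)) if tid != INTERCEPT else float(b0),
                "selected_at": selected,
                "_key": key,
            }
        )
    # active terms whose original-scale monomial coefficient cancelled exactly
    for tid, b in std_coef.items():
        if b != 0.0 and tid not in seen_ids:
            t = terms[tid]
            rows.append(
                {
                    "term": tid,
                    "kind": t.kind,
                    "coef_original": 0.0,
                    "coef_standardized": float(b),
                    "selected_at": "both" if tid in sel_min and tid in sel_1se else "none",
                    "_key": None,
                }
            )
    return CoefficientTable(table=pd.DataFrame(rows), at=at)


@dataclass
class EffectProfile:
    focal: str
    grid: np.ndarray
    curves: dict  # moderator level (or "all") -> predictions on the response scale
    moderator: str | None
    reference_values: dict

    def as_frame(self) -> pd.DataFrame:
        out = {"focal_value": self.grid}
        out.update({str(k): v for k, v in self.curves.items()})
        return pd.DataFrame(out)


def _moderator_levels(recipe, name):
    if name in recipe.training_levels_:
        return list(recipe.training_levels_[name])
    lo, hi = recipe.ranges_[name]
    # continuous moderator: quartile slices of the training range
    return [lo, (lo + hi) / 2, hi]


def effect_profile(
    model: SRLModel,
    focal: str,
    moderator: str | None = None,
    grid_size: int = 100,
    at: str = "1se",
) -> EffectProfile:
    """Predicted-outcome profile of one covariate, optionally by moderator level."""
    recipe = model.recipe
    if focal not in recipe.input_columns_:
        raise ValueError(f"focal covariate {focal!r} was not in the training schema")
    if focal not in recipe.ranges_:
        raise ValueError(f"focal covariate {focal!r} is categorical; pick a numeric one")
    lo, hi = recipe.ranges_[focal]
    grid = np.linspace(lo, hi, grid_size)

    base = {}
    for col in recipe.input_columns_:
        base[col] = recipe.reference_values_[col]

    levels = [None] if moderator is None else _moderator_levels(recipe, moderator)
    curves = {}
    for lvl in levels:
        rows = {c: [base[c]] * grid_size for c in recipe.input_columns_}
        rows[focal] = list(grid)
        if moderator is not None:
            rows[moderator] = [lvl] * grid_size
        frame = pd.DataFrame(rows)
        key = "all" if lvl is None else lvl
        curves[key] = model.predict(frame, at=at)
    return EffectProfile(
        focal=focal,
        grid=grid,
        curves=curves,
        moderator=moderator,
        reference_values={c: base[c] for c in recipe.input_columns_ if c != focal},
    )
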