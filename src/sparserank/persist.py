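"""Save and load fitted models as plain-text artifacts.

A saved model directory holds three files: ``terms.csv`` (one row per
retained term: id, kind, order, group, penalty weight, coefficients at
both selections), ``recipe.json`` (everything needed to replay the
preparation on new data), and ``path.json`` (the lambda grid, the
coefficient path, and the CV summary).  ``load_model`` reconstructs a
fully functional :class:`~sparserank.selection.SRLModel`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recipe import Recipe, RecipeConfig, _DummySpec
from .selection import CVResult, SRLModel
from .solver import PathFit
from .terms import Covariate, PenaltyWeights, TermDescriptor, TermSet

__all__ = ["save_model", "load_model"]


def save_model(model: SRLModel, path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rec = model.recipe

    _, coef_min, _ = model.coefficients("min")
    _, coef_1se, ids = model.coefficients("1se")
    terms = pd.DataFrame(
        {
            "term": ids,
            "kind": [t.kind for t in rec.termset_.terms],
            "order": [t.order for t in rec.termset_.terms],
            "group": [t.group_id for t in rec.termset_.terms],
            "weight": [model.weights.weights[t] for t in ids],
            "coef_lambda_min": coef_min,
            "coef_lambda_1se": coef_1se,
        }
    )
    terms.to_csv(out / "terms.csv", index=False)

    recipe_doc = {
        "config": vars(rec.config),
        "k": rec.k,
        "poly": rec.poly,
        "input_columns": rec.input_columns_,
        "covariates": [
            {"name": c.name, "kind": c.kind, "levels": list(c.levels)}
            for c in rec.covariates_
        ],
        "encoded_covariates": [
            {"name": c.name, "kind": c.kind, "source": c.source}
            for c in rec.encoded_covariates_
        ],
        "merge_maps": rec.merge_maps_,
        "dummy_spec": {
            k: {"reference": v.reference, "levels": v.levels}
            for k, v in rec.dummy_spec_.items()
        },
        "parent_columns": rec.parent_columns_,
        "parent_stats": [list(map(float, a)) for a in rec.parent_stats_],
        "derived_stats": [list(map(float, a)) for a in rec.derived_stats_],
        "full_term_ids": rec.full_termset_.ids,
        "keep_mask": [bool(b) for b in rec.keep_mask_],
        "dropped": rec.dropped_,
        "reference_values": rec.reference_values_,
        "ranges": rec.ranges_,
        "training_levels": rec.training_levels_,
    }
    (out / "recipe.json").write_text(json.dumps(recipe_doc, indent=1))

    path_doc = {
        "family": model.family,
        "target": model.target,
        "gamma": model.gamma,
        "lambdas": model.path.lambdas.tolist(),
        "coef": model.path.coef.tolist(),
        "intercept": model.path.intercept.tolist(),
        "n_active": model.path.n_active.tolist(),
        "converged": model.path.converged.tolist(),
        "cv": {
            "mean_loss": model.cv.mean_loss.tolist(),
            "se_loss": model.cv.se_loss.tolist(),
            "idx_min": model.cv.idx_min,
            "idx_1se": model.cv.idx_1se,
            "loss": model.cv.loss,
            "fold_losses": model.cv.fold_losses.tolist(),
            "cv_r2": None if model.cv.cv_r2 is None else model.cv.cv_r2.tolist(),
        },
    }
    (out / "path.json").write_text(json.dumps(path_doc))
    return out


def _rebuild_termset(encoded_covs, k, poly, full_ids, keep_ids):
    from .terms import expand_terms

    ts = expand_terms(encoded_covs, k=k, poly=poly)
    if ts.ids != full_ids:  # sanity: expansion must be reproducible
        raise ValueError("saved term ids do not match re-expansion")
    return ts, ts.subset(keep_ids)


def load_model(path) -> SRLModel:
    src = Path(path)
    rdoc = json.loads((src / "recipe.json").read_text())
    pdoc = json.loads((src / "path.json").read_text())
    terms = pd.read_csv(src / "terms.csv")

    rec = Recipe(config=RecipeConfig(**rdoc["config"]), k=rdoc["k"], poly=rdoc["poly"])
    rec.input_columns_ = rdoc["input_columns"]
    rec.covariates_ = [
        Covariate(c["name"], c["kind"], tuple(c["levels"])) for c in rdoc["covariates"]
    ]
    rec.encoded_covariates_ = [
        Covariate(c["name"], c["kind"], source=c["source"])
        for c in rdoc["encoded_covariates"]
    ]
    rec.merge_maps_ = rdoc["merge_maps"]
    rec.dummy_spec_ = {
        k: _DummySpec(reference=v["reference"], levels=v["levels"])
        for k, v in rdoc["dummy_spec"].items()
    }
    rec.parent_columns_ = rdoc["parent_columns"]
    rec.parent_stats_ = tuple(np.array(a) for a in rdoc["parent_stats"])
    rec.derived_stats_ = tuple(np.array(a) for a in rdoc["derived_stats"])
    rec.keep_mask_ = np.array(rdoc["keep_mask"], dtype=bool)
    rec.dropped_ = rdoc["dropped"]
    rec.reference_values_ = rdoc["reference_values"]
    rec.ranges_ = {k: tuple(v) for k, v in rdoc["ranges"].items()}
    rec.training_levels_ = rdoc["training_levels"]
    keep_ids = [i for i, k in zip(rdoc["full_term_ids"], rec.keep_mask_) if k]
    rec.full_termset_, rec.termset_ = _rebuild_termset(
        rec.encoded_covariates_, rec.k, rec.poly, rdoc["full_term_ids"], keep_ids
    )
    rec.term_ids_ = keep_ids
    rec.fitted_ = True

    fit = PathFit(
        lambdas=np.array(pdoc["lambdas"]),
        coef=np.array(pdoc["coef"]),
        intercept=np.array(pdoc["intercept"]),
        n_active=np.array(pdoc["n_active"], dtype=int),
        converged=np.array(pdoc["converged"], dtype=bool),
        family=pdoc["family"],
        term_ids=keep_ids,
    )
    cvd = pdoc["cv"]
    cv = CVResult(
        lambdas=fit.lambdas,
        mean_loss=np.array(cvd["mean_loss"]),
        se_loss=np.array(cvd["se_loss"]),
        idx_min=cvd["idx_min"],
        idx_1se=cvd["idx_1se"],
        loss=cvd["loss"],
        fold_losses=np.array(cvd["fold_losses"]),
        cv_r2=None if cvd["cv_r2"] is None else np.array(cvd["cv_r2"]),
    )
    weights = PenaltyWeights(
        weights=dict(zip(terms["term"], terms["weight"])), gamma=pdoc["gamma"]
    )
    return SRLModel(
        recipe=rec,
        weights=weights,
        path=fit,
        cv=cv,
        family=pdoc["family"],
        target=pdoc["target"],
        gamma=pdoc["gamma"],
    )
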