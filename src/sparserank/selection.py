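"""Cross-validated tuning and the top-level SRL fit.

``srl_fit`` is the entry point: it prepares the data (recipe), expands
terms, assigns ranked-sparsity weights, fits the weighted lasso path, and
tunes lambda by K-fold cross-validation (RMSE for Gaussian outcomes,
deviance for binomial).  Two selections are reported: ``lambda_min``, the
grid minimizer of the CV loss, and ``lambda_1se`` — the "compact" model —
the largest lambda whose mean CV loss is within one standard error of the
minimum, trading a little loss for a sparser, more transparent model.

The lambda grid is computed once on the full training data and held fixed
across folds, and fold losses are aggregated to means and standard errors
(sd of fold losses / sqrt(K)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import binomial_deviance, r_squared, rmse
from .recipe import Recipe, RecipeConfig
from .solver import PathFit, PathSpec, fit_path, predict_path
from .terms import PenaltyWeights, assign_penalty_weights

__all__ = [
    "CVSpec",
    "CVResult",
    "SRLModel",
    "make_folds",
    "select_lambdas",
    "cross_validate",
    "srl_fit",
]


@dataclass
class CVSpec:
    n_folds: int = 10
    seed: int = 0
    loss: str | None = None  # rmse (gaussian) or deviance (binomial)
    stratified: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_loss: np.ndarray
    se_loss: np.ndarray
    idx_min: int
    idx_1se: int
    loss: str
    fold_losses: np.ndarray  # (n_folds, n_lambda)
    cv_r2: np.ndarray | None = None  # per-lambda pooled CV R^2 (gaussian)

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[self.idx_min])

    @property
    def lambda_1se(self) -> float:
        return float(self.lambdas[self.idx_1se])


def make_folds(n: int, spec: CVSpec, labels=None) -> np.ndarray:
    """Deterministic fold ids; sizes differ by at most one; optionally stratified."""
    if n < spec.n_folds:
        raise ValueError("more folds than observations")
    rng = np.random.default_rng(spec.seed)
    folds = np.empty(n, dtype=int)
    if labels is None or not spec.stratified:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % spec.n_folds
        return folds
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < spec.n_folds:
        warnings.warn("a class has fewer members than folds; stratification relaxed")
    offset = 0  # stagger round-robin starts so fold sizes stay within one
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx.size)
        folds[idx[perm]] = (np.arange(idx.size) + offset) % spec.n_folds
        offset += idx.size
    return folds


def select_lambdas(mean_loss, se_loss):
    """(idx_min, idx_1se) on a decreasing-lambda grid.

    Ties at the minimum go to the smallest index (largest lambda, sparser
    model); lambda_1se is the largest lambda with mean loss within one
    standard error of the minimum.
    """
    mean_loss = np.asarray(mean_loss, dtype=float)
    se_loss = np.asarray(se_loss, dtype=float)
    lo = np.nanmin(mean_loss)
    idx_min = int(np.flatnonzero(mean_loss <= lo + 1e-12)[0])
    cutoff = mean_loss[idx_min] + se_loss[idx_min]
    idx_1se = int(np.flatnonzero(mean_loss <= cutoff)[0])
    return idx_min, idx_1se


def cross_validate(
    X,
    y,
    weights,
    path_spec: PathSpec,
    cv_spec: CVSpec | None = None,
    term_ids=None,
) -> CVResult:
    """K-fold CV over a lambda grid fixed on the full training data."""
    cv_spec = cv_spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    binomial = path_spec.family == "binomial"
    loss_name = cv_spec.loss or ("deviance" if binomial else "rmse")

    if path_spec.lambdas is None:
        full = fit_path(X, y, weights, path_spec, term_ids=term_ids)
        lambdas = full.lambdas
    else:
        lambdas = np.asarray(path_spec.lambdas, dtype=float)
    L = len(lambdas)
    fold_spec = PathSpec(
        n_lambda=L,
        tol=path_spec.tol,
        max_iter=path_spec.max_iter,
        family=path_spec.family,
        lambdas=lambdas,
    )

    folds = make_folds(n, cv_spec, labels=y if binomial and cv_spec.stratified else None)
    losses = []
    pooled = np.full((n, L), np.nan)
    for f in range(cv_spec.n_folds):
        test = folds == f
        train = ~test
        if binomial and len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {f}: constant response in training part; fold skipped")
            continue
        fit = fit_path(X[train], y[train], weights, fold_spec, term_ids=term_ids)
        pred = predict_path(fit, X[test])  # (n_test, L), response scale
        pooled[test] = pred
        if binomial:
            loss = np.array(
                [binomial_deviance(y[test], pred[:, li]) / test.sum() for li in range(L)]
            )
        else:
            loss = np.array([rmse(y[test], pred[:, li]) for li in range(L)])
        losses.append(loss)
    fold_losses = np.vstack(losses)
    mean_loss = fold_losses.mean(axis=0)
    se_loss = fold_losses.std(axis=0, ddof=1) / np.sqrt(fold_losses.shape[0])
    idx_min, idx_1se = select_lambdas(mean_loss, se_loss)

    cv_r2 = None
    if not binomial:
        sst = np.sum((y - y.mean()) ** 2)
        seen = ~np.isnan(pooled[:, 0])
        sse = np.nansum((pooled[seen] - y[seen, None]) ** 2, axis=0)
        cv_r2 = 1.0 - sse / sst

    return CVResult(
        lambdas=lambdas,
        mean_loss=mean_loss,
        se_loss=se_loss,
        idx_min=idx_min,
        idx_1se=idx_1se,
        loss=loss_name,
        fold_losses=fold_losses,
        cv_r2=cv_r2,
    )


@dataclass
class SRLModel:
    """A fitted sparsity-ranked lasso: recipe + terms + weights + path + CV."""

    recipe: Recipe
    weights: PenaltyWeights
    path: PathFit
    cv: CVResult
    family: str
    target: str
    gamma: float

    @property
    def term_ids(self):
        return self.recipe.term_ids_

    def _index(self, at) -> int:
        if at == "min":
            return self.cv.idx_min
        if at == "1se":
            return self.cv.idx_1se
        return int(at)

    def coefficients(self, at="1se"):
        """(intercept, coefficient vector, term ids) on the standardized scale."""
        i = self._index(at)
        return float(self.path.intercept[i]), self.path.coef[:, i].copy(), list(self.term_ids)

    def selected_terms(self, at="1se") -> list:
        i = self._index(at)
        beta = self.path.coef[:, i]
        return [tid for tid, b in zip(self.term_ids, beta) if b != 0.0]

    def predict(self, data: pd.DataFrame, at="1se") -> np.ndarray:
        """Predictions on the response scale (probabilities for binomial)."""
        X, _ = self.recipe.transform(data)
        return predict_path(self.path, X, index=self._index(at))


def _infer_family(y: pd.Series) -> str:
    vals = pd.unique(y.dropna())
    return "binomial" if len(vals) == 2 else "gaussian"


def _encode_binary(y: pd.Series) -> np.ndarray:
    vals = sorted(pd.unique(y))
    if set(vals) == {0, 1}:
        return y.to_numpy(dtype=float)
    return (y == vals[1]).to_numpy(dtype=float)


def srl_fit(
    data: pd.DataFrame,
    target: str,
    family: str = "auto",
    k: int = 1,
    poly: int = 2,
    filter_mode: str = "nzv",
    gamma: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    config: RecipeConfig | None = None,
    path_spec: PathSpec | None = None,
    cv_spec: CVSpec | None = None,
) -> SRLModel:
    """Fit the SRL end to end on a tabular dataset.

    Defaults follow the out-of-the-box protocol: all pairwise interactions
    (k=1), quadratic polynomials (poly=2), near-zero-variance filtering,
    gamma=0.5, 10-fold CV.  ``gamma=0`` with ``k=0, poly=1`` reproduces a
    plain lasso on the main effects.
    """
    if target not in data.columns:
        raise ValueError(f"target column {target!r} not in data")
    y_raw = data[target]
    if y_raw.nunique(dropna=True) < 2:
        raise ValueError("constant target")
    if family == "auto":
        family = _infer_family(y_raw)
    y = _encode_binary(y_raw) if family == "binomial" else y_raw.to_numpy(dtype=float)

    cfg = config or RecipeConfig()
    cfg.filter_mode = filter_mode
    recipe = Recipe(config=cfg, k=k, poly=poly).fit(data.drop(columns=[target]))
    X, ids = recipe.transform(data.drop(columns=[target]))

    weights = assign_penalty_weights(recipe.termset_, gamma=gamma)
    wvec = weights.as_vector(ids)

    pspec = path_spec or PathSpec()
    pspec.family = family
    fit = fit_path(X, y, wvec, pspec, term_ids=ids)
    cvs = cv_spec or CVSpec(n_folds=n_folds, seed=seed)

    if X.shape[1] == 0:
        # everything filtered out: intercept-only model, trivial CV
        L = 1
        cv = CVResult(
            lambdas=fit.lambdas,
            mean_loss=np.zeros(L),
            se_loss=np.zeros(L),
            idx_min=0,
            idx_1se=0,
            loss="rmse" if family == "gaussian" else "deviance",
            fold_losses=np.zeros((1, L)),
        )
    else:
        cv = cross_validate(
            X,
            y,
            wvec,
            PathSpec(
                tol=pspec.tol,
                max_iter=pspec.max_iter,
                family=family,
                lambdas=fit.lambdas,
            ),
            cvs,
            term_ids=ids,
        )
    return SRLModel(
        recipe=recipe,
        weights=weights,
        path=fit,
        cv=cv,
        family=family,
        target=target,
        gamma=gamma,
    )
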