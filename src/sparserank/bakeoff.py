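"""Out-of-the-box benchmarking harness and meta-analysis.

The protocol: filter candidate datasets by endpoint type and size, give
every algorithm the same 80/20 train/test split per dataset, tune each arm
with its own default 10-fold cross-validation on the training part only,
and evaluate on the test part — AUC for binary endpoints, R-squared
(clamped at zero for meta-analysis) for continuous ones.  Summaries report
how often each algorithm is best and how often it lands within 5%
(relative) of the best.  Inference across datasets uses a linear mixed
model with a random intercept per dataset — absorbing dataset-specific
signal-to-noise — and fixed effects for the algorithms against a reference
arm.

The transparent arms (SRL and plain lasso, the lasso being the SRL with
gamma=0, k=0, poly=1) come from this package; black-box arms are thin
adapters over scikit-learn and xgboost with their published defaults and
are optional — the harness runs with any subset of arms.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import auc, clamp_r_squared, r_squared, train_test_split
from .selection import srl_fit

__all__ = [
    "DatasetMeta",
    "MetaModelResult",
    "filter_datasets",
    "read_pmlb",
    "run_bakeoff",
    "within_pct_of_best",
    "meta_analyze",
    "ARM_REGISTRY",
]

# Friedman-simulation datasets follow a registry naming convention; the
# list of prefixes is deliberately editable configuration.
FRIEDMAN_NAME_PREFIXES = ("fri_", "friedman")

MAX_OBSERVATIONS = 10_000
MAX_FEATURES = 50
MAX_CELLS = 100_000


@dataclass
class DatasetMeta:
    name: str
    endpoint: str  # binary | continuous | categorical
    n_obs: int
    n_features: int
    friedman: bool | None = None

    @property
    def n_cells(self) -> int:
        return self.n_obs * self.n_features

    @property
    def is_friedman(self) -> bool:
        if self.friedman is not None:
            return self.friedman
        return self.name.lower().startswith(FRIEDMAN_NAME_PREFIXES)


def filter_datasets(metadata) -> list:
    """Keep binary/continuous endpoints under the size caps, minus Friedman sets."""
    return [
        m
        for m in metadata
        if m.endpoint in ("binary", "continuous")
        and m.n_obs < MAX_OBSERVATIONS
        and m.n_features <= MAX_FEATURES
        and m.n_cells < MAX_CELLS
        and not m.is_friedman
    ]


def read_pmlb(path) -> pd.DataFrame:
    """Read a PMLB-format file: (gzipped) TSV with a column named 'target'."""
    df = pd.read_csv(path, sep="\t", compression="infer")
    if "target" not in df.columns:
        raise ValueError(f"{path}: no 'target' column; not a PMLB-format file")
    return df


# ---------------------------------------------------------------------------
# algorithm arms
# ---------------------------------------------------------------------------


def _one_hot(df: pd.DataFrame) -> pd.DataFrame:
    return pd.get_dummies(df, drop_first=True, dtype=float)


def _fit_srl_arm(params):
    def run(train, test, endpoint, seed):
        model = srl_fit(train, "target", seed=seed, **params)
        pred = model.predict(test, at="min")
        if endpoint == "continuous":
            cv_metric = float(model.cv.cv_r2[model.cv.idx_min])
        else:
            cv_metric = float(model.cv.mean_loss[model.cv.idx_min])
        return pred, cv_metric

    return run


def _fit_sklearn_arm(make_estimator):
    def run(train, test, endpoint, seed):
        X = _one_hot(pd.concat([train, test]).drop(columns=["target"]))
        Xtr, Xte = X.iloc[: len(train)], X.iloc[len(train) :]
        ytr = train["target"].to_numpy()
        est = make_estimator(endpoint, seed)
        est.fit(Xtr, ytr)
        if endpoint == "binary":
            if hasattr(est, "predict_proba"):
                pred = est.predict_proba(Xte)[:, 1]
            else:
                pred = est.decision_function(Xte)
        else:
            pred = est.predict(Xte)
        return np.asarray(pred, dtype=float), np.nan

    return run


def _rf(endpoint, seed):
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    cls = RandomForestClassifier if endpoint == "binary" else RandomForestRegressor
    return cls(random_state=seed)


def _svm(endpoint, seed):
    from sklearn.svm import SVC, SVR

    return SVC(random_state=seed) if endpoint == "binary" else SVR()


def _nn(endpoint, seed):
    from sklearn.neural_network import MLPClassifier, MLPRegressor

    cls = MLPClassifier if endpoint == "binary" else MLPRegressor
    return cls(random_state=seed, max_iter=500)


def _xgb(endpoint, seed):
    from xgboost import XGBClassifier, XGBRegressor

    cls = XGBClassifier if endpoint == "binary" else XGBRegressor
    return cls(random_state=seed, verbosity=0)


ARM_REGISTRY = {
    "srl": _fit_srl_arm({}),
    "lasso": _fit_srl_arm({"gamma": 0.0, "k": 0, "poly": 1}),
    "rf": _fit_sklearn_arm(_rf),
    "svm": _fit_sklearn_arm(_svm),
    "nn": _fit_sklearn_arm(_nn),
    "xgb": _fit_sklearn_arm(_xgb),
}


def _resolve_arm(arm):
    if isinstance(arm, str):
        return arm, ARM_REGISTRY[arm]
    if isinstance(arm, tuple) and len(arm) == 2:
        label, spec = arm
        if callable(spec):
            return label, spec
        return label, _fit_srl_arm(dict(spec))
    raise ValueError(f"cannot interpret arm {arm!r}")


def run_bakeoff(
    datasets,
    arms=("srl", "lasso"),
    seed: int = 0,
    test_fraction: float = 0.2,
    collapse_scope: str = "full",
    rare_threshold: float = 0.10,
):
    """One shared split per dataset, every arm fit on train, scored on test.

    ``datasets`` is a list of dicts with keys name, data (DataFrame with a
    'target' column) and endpoint ('binary'/'continuous').  A failing arm
    is recorded with NaN metrics and the run continues.

    ``collapse_scope='full'`` merges rare categorical levels on the whole
    dataset before splitting, mirroring the benchmark protocol's ordering;
    ``'train'`` leaves collapsing to each arm's train-only recipe.
    """
    from .recipe import collapse_rare_levels

    if collapse_scope not in ("full", "train"):
        raise ValueError("collapse_scope must be 'full' or 'train'")
    resolved = [_resolve_arm(a) for a in arms]
    rows = []
    for d_idx, ds in enumerate(datasets):
        df, endpoint = ds["data"], ds["endpoint"]
        if collapse_scope == "full":
            df = df.copy()
            for col in df.columns:
                if col != "target" and (
                    df[col].dtype == object
                    or isinstance(df[col].dtype, pd.CategoricalDtype)
                ):
                    df[col], _ = collapse_rare_levels(df[col], rare_threshold)
        n = len(df)
        ds_seed = int((seed * 100_003 + d_idx) % 2**31)
        labels = df["target"].to_numpy() if endpoint == "binary" else None
        tr_idx, te_idx = train_test_split(
            n, test_fraction=test_fraction, seed=ds_seed, labels=labels
        )
        train, test = df.iloc[tr_idx], df.iloc[te_idx]
        for label, run in resolved:
            t0 = time.perf_counter()
            try:
                pred, cv_metric = run(train, test, endpoint, ds_seed)
                if endpoint == "binary":
                    metric = auc(test["target"].to_numpy(), pred)
                    clamped = metric
                else:
                    metric = r_squared(test["target"].to_numpy(), pred)
                    clamped = clamp_r_squared(metric)
            except Exception as exc:  # noqa: BLE001 — a failing arm must not stop the run
                warnings.warn(f"arm {label!r} failed on {ds['name']!r}: {exc}")
                metric = clamped = cv_metric = np.nan
            rows.append(
                {
                    "dataset": ds["name"],
                    "algorithm": label,
                    "endpoint": endpoint,
                    "cv_metric": cv_metric,
                    "test_metric": metric,
                    "test_metric_clamped": clamped,
                    "runtime_s": time.perf_counter() - t0,
                    "seed": ds_seed,
                }
            )
    return pd.DataFrame(rows)


def within_pct_of_best(results: pd.DataFrame, tolerance: float = 0.05, metric: str = "test_metric_clamped") -> pd.DataFrame:
    """Per-algorithm 'best %' and 'within tolerance of best %' summary.

    Expects results for a single endpoint type on a higher-is-better
    metric.  Ties credit every tied algorithm.
    """
    rows = []
    grouped = results.dropna(subset=[metric]).groupby("dataset")[metric]
    best = grouped.max()
    n_datasets = len(best)
    for alg, sub in results.groupby("algorithm"):
        sub = sub.dropna(subset=[metric]).set_index("dataset")[metric]
        b = best.loc[sub.index]
        n_best = int((sub >= b - 1e-12).sum())
        n_within = int((sub >= (1 - tolerance) * b).sum())
        rows.append(
            {
                "algorithm": alg,
                "pct_best": 100.0 * n_best / n_datasets,
                "pct_within": 100.0 * n_within / n_datasets,
                "n_datasets": n_datasets,
            }
        )
    return pd.DataFrame(rows).sort_values("algorithm", ignore_index=True)


@dataclass
class MetaModelResult:
    estimates: pd.DataFrame  # term, estimate, ci_low, ci_high, p_value
    random_intercept_var: float
    reference: str
    fallback_fixed_effects: bool = False

    def offset(self, algorithm: str) -> float:
        row = self.estimates.loc[self.estimates["term"] == algorithm]
        if row.empty:
            raise KeyError(algorithm)
        return float(row["estimate"].iloc[0])


def meta_analyze(results: pd.DataFrame, metric: str = "test_metric_clamped", reference: str = "srl") -> MetaModelResult:
    """Random-intercept meta-model: metric ~ algorithm + (1 | dataset).

    Fixed effects are expected metric changes relative to the reference
    algorithm; the intercept is the expected metric for the reference.
    Falls back to fixed dataset effects if the random-effect variance is
    singular.
    """
    import statsmodels.formula.api as smf

    data = results.dropna(subset=[metric]).copy()
    if data["algorithm"].nunique() < 2 or data["dataset"].nunique() < 3:
        raise ValueError("need >= 2 algorithms and >= 3 datasets")
    data = data.rename(columns={metric: "metric"})
    formula = f"metric ~ C(algorithm, Treatment('{reference}'))"

    fallback = False
    re_var = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, data, groups=data["dataset"]).fit(reml=True)
            re_var = float(fit.cov_re.iloc[0, 0])
            singular = not np.isfinite(re_var) or re_var < 1e-10
        except Exception:
            singular = True
    if singular:
        warnings.warn("singular random-intercept variance; using fixed dataset effects")
        fallback = True
        fit = smf.ols(formula + " + C(dataset)", data).fit()
        re_var = 0.0

    conf = fit.conf_int()
    rows = []
    prefix = "C(algorithm"
    for name in fit.params.index:
        if name == "Intercept":
            term = "(Intercept)"
        elif name.startswith(prefix):
            term = name.split("[T.")[1].rstrip("]")
        else:
            continue  # dataset fixed effects / variance component
        rows.append(
            {
                "term": term,
                "estimate": float(fit.params[name]),
                "ci_low": float(conf.loc[name, 0]),
                "ci_high": float(conf.loc[name, 1]),
                "p_value": float(fit.pvalues[name]),
            }
        )
    return MetaModelResult(
        estimates=pd.DataFrame(rows),
        random_intercept_var=re_var,
        reference=reference,
        fallback_fixed_effects=fallback,
    )
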