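"""Data preparation as a fit-on-train / apply-anywhere recipe.

The recipe mirrors the preparation used for benchmark tabular data: rare
categorical levels (below 10% frequency by default) are merged into a
single "other" class; categoricals are one-hot encoded against their most
frequent level; the candidate design (mains, interactions, polynomials)
is screened by a variance filter; and every surviving column is
standardized.  All statistics are learned on the training data and replayed
on new data, so no test-set information leaks into the preparation.

The variance filter runs on the *expanded* design, not just the raw
covariates.  Its default near-zero-variance (nzv) mode drops columns that
are almost constant — most-frequent / second-most-frequent value ratio
above 19 (a 95/5 split) together with fewer than 10% distinct values —
while the zero-variance (zv) mode drops only exactly-constant columns.
The distinction matters: on heavily skewed categorical data the nzv screen
can silently remove every candidate interaction before the supervised
step, whereas zv keeps any interaction with nonzero variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .terms import Covariate, TermSet, build_design_matrix, expand_terms

__all__ = [
    "RecipeConfig",
    "Recipe",
    "infer_covariates",
    "collapse_rare_levels",
    "encode_categoricals",
    "variance_filter",
    "standardize",
]

OTHER_LEVEL = "other"


@dataclass
class RecipeConfig:
    rare_threshold: float = 0.10
    filter_mode: str = "nzv"  # nzv | zv | none
    nzv_freq_ratio: float = 19.0  # 95/5
    nzv_unique_pct: float = 10.0
    standardize: bool = True

    def __post_init__(self):
        if not 0 <= self.rare_threshold < 0.5:
            raise ValueError("rare_threshold must be in [0, 0.5)")
        if self.nzv_freq_ratio < 1:
            raise ValueError("nzv_freq_ratio must be >= 1")
        if self.filter_mode not in ("nzv", "zv", "none"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")


def infer_covariates(data: pd.DataFrame) -> list:
    """Classify raw columns as continuous, binary or categorical."""
    out = []
    for name in data.columns:
        col = data[name]
        if (
            col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool
        ):
            levels = tuple(sorted(str(v) for v in col.dropna().unique()))
            out.append(Covariate(name, "categorical", levels=levels))
        else:
            nunique = col.nunique(dropna=True)
            kind = "binary" if nunique == 2 else "continuous"
            out.append(Covariate(name, kind))
    return out


def collapse_rare_levels(column: pd.Series, threshold: float):
    """Merge every level below ``threshold`` frequency into one class.

    Returns ``(mapped column, merge map)``.  The merged level is named
    "other", or "other_merged" if a literal "other" level already exists.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    col = column.astype(str)
    freq = col.value_counts(normalize=True)
    rare = freq.index[freq < threshold]
    if len(rare) == 0:
        return col, {}
    merged = OTHER_LEVEL if OTHER_LEVEL not in freq.index[freq >= threshold] else "other_merged"
    merge_map = {lvl: merged for lvl in rare}
    return col.replace(merge_map), merge_map


@dataclass
class _DummySpec:
    reference: str
    levels: list  # non-reference levels, each becoming one dummy column


def _dummy_name(cat: str, level: str) -> str:
    return f"{cat}={level}"


def encode_categoricals(data: pd.DataFrame, covariates=None):
    """One-hot encode categoricals against their most frequent level.

    Returns ``(encoded frame, encoded covariates, dummy spec map)``.  A
    categorical left with a single level is dropped with a warning.
    """
    covariates = covariates if covariates is not None else infer_covariates(data)
    frames, enc_covs, spec = {}, [], {}
    for cov in covariates:
        if cov.kind != "categorical":
            frames[cov.name] = pd.to_numeric(data[cov.name])
            enc_covs.append(cov)
            continue
        col = data[cov.name].astype(str)
        counts = col.value_counts()
        if len(counts) < 2:
            warnings.warn(
                f"categorical {cov.name!r} has a single level after collapsing; dropped"
            )
            spec[cov.name] = _DummySpec(reference=str(counts.index[0]) if len(counts) else "", levels=[])
            continue
        # reference = most frequent level (ties broken lexicographically)
        order = sorted(counts.index, key=lambda l: (-counts[l], l))
        reference, others = order[0], sorted(order[1:])
        spec[cov.name] = _DummySpec(reference=reference, levels=others)
        for lvl in others:
            dummy = _dummy_name(cov.name, lvl)
            frames[dummy] = (col == lvl).astype(float)
            enc_covs.append(Covariate(dummy, "binary", source=cov.name))
    encoded = pd.DataFrame(frames, index=data.index)
    return encoded, enc_covs, spec


def _column_profile(v: np.ndarray):
    """(freq ratio, percent unique) of one numeric column."""
    _, counts = np.unique(v, return_counts=True)
    n = v.size
    pct_unique = 100.0 * counts.size / n
    if counts.size < 2:
        return np.inf, pct_unique
    top2 = np.sort(counts)[-2:]
    return top2[1] / top2[0], pct_unique


def variance_filter(X: np.ndarray, ids, mode: str, config: RecipeConfig | None = None):
    """Partition design columns into retained and dropped.

    zv drops exactly-constant columns; nzv additionally drops columns with
    frequency ratio above ``nzv_freq_ratio`` and fewer than
    ``nzv_unique_pct`` percent distinct values; none drops nothing.
    Returns ``(kept ids, {dropped id: reason})``.
    """
    config = config or RecipeConfig()
    kept, dropped = [], {}
    for j, tid in enumerate(ids):
        v = X[:, j]
        if mode == "none":
            kept.append(tid)
            continue
        uniq = np.unique(v)
        if uniq.size <= 1:
            dropped[tid] = "zero variance"
            continue
        if mode == "nzv":
            ratio, pct_unique = _column_profile(v)
            if ratio > config.nzv_freq_ratio and pct_unique < config.nzv_unique_pct:
                dropped[tid] = "near-zero variance"
                continue
        kept.append(tid)
    return kept, dropped


def standardize(X: np.ndarray, stats=None):
    """Center and scale columns; returns ``(Xs, (means, scales), zero_scale)``.

    Scales are population standard deviations.  Exactly constant columns
    are centered only (scale forced to 1) and flagged so the variance
    filter can remove them.
    """
    X = np.asarray(X, dtype=float)
    if stats is None:
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        zero = scales == 0.0
        scales = np.where(zero, 1.0, scales)
    else:
        means, scales = stats
        zero = np.asarray(scales) == 1.0  # informational only on replay
    return (X - means) / scales, (means, scales), zero


class Recipe:
    """Fitted preparation pipeline: collapse, encode, expand, standardize, filter.

    ``fit`` learns everything from a training frame of raw covariates;
    ``transform`` replays the preparation on any frame with the same schema
    and returns the standardized, filtered design matrix.
    """

    def __init__(self, config: RecipeConfig | None = None, k: int = 1, poly: int = 2):
        self.config = config or RecipeConfig()
        self.k = k
        self.poly = poly
        self.fitted_ = False

    # -- fitting ---------------------------------------------------------
    def fit(self, data: pd.DataFrame) -> "Recipe":
        if data.isna().any().any():
            raise ValueError("missing values are not supported; impute or drop first")
        self.input_columns_ = list(data.columns)
        self.covariates_ = infer_covariates(data)

        self.merge_maps_ = {}
        work = data.copy()
        for cov in self.covariates_:
            if cov.kind == "categorical":
                mapped, mm = collapse_rare_levels(
                    work[cov.name], self.config.rare_threshold
                )
                work[cov.name] = mapped
                self.merge_maps_[cov.name] = mm

        encoded, enc_covs, self.dummy_spec_ = encode_categoricals(work, self.covariates_)
        self.encoded_covariates_ = enc_covs

        # reference values for effect profiles
        self.reference_values_ = {}
        self.ranges_ = {}
        self.training_levels_ = {}
        for cov in self.covariates_:
            if cov.kind == "categorical":
                self.reference_values_[cov.name] = work[cov.name].mode().iloc[0]
                self.training_levels_[cov.name] = sorted(work[cov.name].unique())
            else:
                col = pd.to_numeric(data[cov.name])
                self.reference_values_[cov.name] = float(col.median())
                self.ranges_[cov.name] = (float(col.min()), float(col.max()))

        # Continuous parents are centered before powers/products are formed
        # (conditioning); dummies stay raw 0/1 so the frequency-based
        # variance screen sees the true sparsity of interaction terms.
        # Every candidate column is standardized afterwards, which is what
        # makes the penalty weights comparable across term types.
        P = encoded.to_numpy(dtype=float)
        centers = np.array(
            [
                P[:, j].mean() if cov.kind == "continuous" else 0.0
                for j, cov in enumerate(enc_covs)
            ]
        )
        self.parent_stats_ = (centers, np.ones_like(centers))
        parents_ctr = pd.DataFrame(
            P - centers, columns=encoded.columns, index=encoded.index
        )
        self.parent_columns_ = list(encoded.columns)

        termset = expand_terms(enc_covs, k=self.k, poly=self.poly)
        D, ids = build_design_matrix(parents_ctr, termset)
        Ds, self.derived_stats_, _ = standardize(D)

        kept, dropped = variance_filter(Ds, ids, self.config.filter_mode, self.config)
        self.dropped_ = dropped
        self.full_termset_ = termset
        self.termset_ = termset.subset(kept)
        keep_mask = np.array([i in set(kept) for i in ids])
        self.keep_mask_ = keep_mask
        self.term_ids_ = [i for i in ids if i in set(kept)]
        self.fitted_ = True
        return self

    # -- application -----------------------------------------------------
    def parent_frame(self, data: pd.DataFrame) -> pd.DataFrame:
        """Collapse + encode new data into the numeric parent table (unstandardized)."""
        self._check_fitted()
        missing = [c for c in self.input_columns_ if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        if data[self.input_columns_].isna().any().any():
            raise ValueError("missing values are not supported")
        frames = {}
        for cov in self.covariates_:
            if cov.kind != "categorical":
                frames[cov.name] = pd.to_numeric(data[cov.name]).astype(float)
                continue
            spec = self.dummy_spec_[cov.name]
            if not spec.levels:
                continue
            col = data[cov.name].astype(str).replace(self.merge_maps_[cov.name])
            for lvl in spec.levels:
                frames[_dummy_name(cov.name, lvl)] = (col == lvl).astype(float)
        out = pd.DataFrame(frames, index=data.index)
        return out[self.parent_columns_]

    def transform(self, data: pd.DataFrame):
        """Return ``(design matrix, term ids)`` for new data."""
        self._check_fitted()
        parents = self.parent_frame(data)
        means, scales = self.parent_stats_
        Ps = (parents.to_numpy(dtype=float) - means) / scales
        parents_ctr = pd.DataFrame(Ps, columns=self.parent_columns_, index=parents.index)
        D, ids = build_design_matrix(parents_ctr, self.full_termset_)
        dmeans, dscales = self.derived_stats_
        Ds = (D - dmeans) / dscales
        return Ds[:, self.keep_mask_], list(self.term_ids_)

    def _check_fitted(self):
        if not self.fitted_:
            raise RuntimeError("recipe has not been fitted")
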