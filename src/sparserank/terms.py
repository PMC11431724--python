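"""Hierarchical term expansion and ranked-sparsity penalty weights.

The candidate model space is assembled from three blocks: the supplied
covariates themselves ("main effects", block A), products of distinct
covariates (interactions, block B), and integer powers of continuous
covariates (polynomials, block C).  The design matrix handed to the
penalized solver is ``X = [A B C]``.

Ranked sparsity calibrates per-term penalty weights by the size of the
block a term belongs to: with ``p`` mains there are ``p(p-1)/2`` pairwise
interactions, so interactions as a collection would otherwise contribute
far more prior model mass than the mains.  Setting ``w_j = p_j ** gamma``
(``p_j`` the group size, ``gamma = 0.5`` by default) equalizes that mass
and makes the fit more skeptical of complex terms without any extra tuning
parameter.  Polynomial terms of order ``m`` are weighted by the cumulative
number of candidate terms of polynomial order at most ``m`` (counting each
main as an order-1 term), so higher powers face monotonically higher
skepticism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "TermDescriptor",
    "TermSet",
    "PenaltyWeights",
    "expand_terms",
    "build_design_matrix",
    "assign_penalty_weights",
]

_KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class Covariate:
    """One input variable.

    ``source`` names the originating categorical for dummy columns; dummies
    that share a source are never multiplied together (their product is
    identically zero or duplicates one of them).
    """

    name: str
    kind: str = "continuous"
    levels: tuple = ()
    source: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    @property
    def effective_source(self) -> str:
        return self.source if self.source is not None else self.name


@dataclass(frozen=True)
class TermDescriptor:
    """One candidate model term.

    ``order`` is 1 for mains, the number of distinct parents minus one for
    interactions (so pairwise products are order 1), and the exponent for
    polynomial terms.
    """

    id: str
    kind: str  # main | interaction | polynomial
    parents: tuple
    order: int
    group_id: str


@dataclass
class TermSet:
    """Ordered collection of candidate terms with their grouping."""

    terms: list
    k: int
    poly: int
    covariates: tuple = ()

    @property
    def ids(self) -> list:
        return [t.id for t in self.terms]

    @property
    def group_sizes(self) -> dict:
        sizes: dict = {}
        for t in self.terms:
            sizes[t.group_id] = sizes.get(t.group_id, 0) + 1
        return sizes

    def __len__(self) -> int:
        return len(self.terms)

    def subset(self, keep_ids) -> "TermSet":
        keep = set(keep_ids)
        return TermSet(
            terms=[t for t in self.terms if t.id in keep],
            k=self.k,
            poly=self.poly,
            covariates=self.covariates,
        )


@dataclass
class PenaltyWeights:
    """Per-term multipliers of the overall shrinkage parameter lambda."""

    weights: dict
    gamma: float = 0.5
    unpenalized: set = field(default_factory=set)

    def as_vector(self, ids) -> np.ndarray:
        return np.array(
            [0.0 if i in self.unpenalized else self.weights[i] for i in ids],
            dtype=float,
        )


def interaction_id(names) -> str:
    return ":".join(sorted(names))


def polynomial_id(name: str, order: int) -> str:
    return f"{name}^{order}"


def expand_terms(covariates, k: int = 1, poly: int = 2) -> TermSet:
    """Expand covariates into mains, interactions and polynomials.

    Interactions are products of 2..k+1 covariates with pairwise-distinct
    sources; polynomials are powers 2..poly of continuous covariates only
    (a 0/1 dummy equals its own square).  Ordering is canonical: mains,
    then interactions, then polynomials, each block lexicographic by id.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if poly < 1:
        raise ValueError("poly must be >= 1")
    names = [c.name for c in covariates]
    if len(set(names)) != len(names):
        raise ValueError("duplicate covariate names")

    mains = [
        TermDescriptor(c.name, "main", (c.name,), 1, "main")
        for c in sorted(covariates, key=lambda c: c.name)
    ]

    interactions = []
    for size in range(2, k + 2):
        if size > len(covariates):
            break
        for combo in itertools.combinations(covariates, size):
            sources = [c.effective_source for c in combo]
            if len(set(sources)) != size:
                continue  # same-source dummies never multiplied
            parents = tuple(sorted(c.name for c in combo))
            interactions.append(
                TermDescriptor(
                    interaction_id(parents),
                    "interaction",
                    parents,
                    size - 1,
                    f"int{size - 1}",
                )
            )
    interactions.sort(key=lambda t: t.id)

    polynomials = []
    for c in covariates:
        if c.kind != "continuous":
            continue
        for order in range(2, poly + 1):
            polynomials.append(
                TermDescriptor(
                    polynomial_id(c.name, order),
                    "polynomial",
                    (c.name,),
                    order,
                    f"poly{order}",
                )
            )
    polynomials.sort(key=lambda t: t.id)

    return TermSet(
        terms=mains + interactions + polynomials,
        k=k,
        poly=poly,
        covariates=tuple(sorted(covariates, key=lambda c: c.name)),
    )


def build_design_matrix(data: pd.DataFrame, termset: TermSet):
    """Realize the expanded design on a numeric parent table.

    ``data`` holds one numeric column per parent covariate (categoricals
    already dummy-encoded upstream).  Returns ``(matrix, ids)`` with one
    column per term in canonical order.
    """
    needed = sorted({p for t in termset.terms for p in t.parents})
    missing = [p for p in needed if p not in data.columns]
    if missing:
        raise ValueError(f"parent covariates missing from data: {missing}")
    cols = {p: np.asarray(data[p], dtype=float) for p in needed}
    for p, v in cols.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"missing or non-finite values in covariate {p!r}")

    n = len(data)
    X = np.empty((n, len(termset.terms)), dtype=float)
    for j, t in enumerate(termset.terms):
        if t.kind == "main":
            X[:, j] = cols[t.parents[0]]
        elif t.kind == "interaction":
            col = cols[t.parents[0]].copy()
            for p in t.parents[1:]:
                col *= cols[p]
            X[:, j] = col
        else:  # polynomial
            X[:, j] = cols[t.parents[0]] ** t.order
    return X, termset.ids


def assign_penalty_weights(
    termset: TermSet, gamma: float = 0.5, poly_group_size=None
) -> PenaltyWeights:
    """Group-size-calibrated penalty weights ``w_j = p_j ** gamma``.

    Mains and each interaction order use their own group's size.  A
    polynomial of order ``m`` uses the cumulative count of candidate terms
    of polynomial order <= m, counting each main at order 1; pass
    ``poly_group_size(order, termset) -> int`` to swap in an alternative
    cumulative-dimension rule.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    sizes = termset.group_sizes
    n_main = sizes.get("main", 0)

    def cumulative_poly(order: int) -> int:
        total = n_main
        for m in range(2, order + 1):
            total += sizes.get(f"poly{m}", 0)
        return total

    size_fn = poly_group_size or (lambda order, ts: cumulative_poly(order))

    weights = {}
    for t in termset.terms:
        if t.kind == "polynomial":
            p_j = size_fn(t.order, termset)
        else:
            p_j = sizes[t.group_id]
        weights[t.id] = float(p_j) ** gamma
    return PenaltyWeights(weights=weights, gamma=gamma)
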