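"""Regulatory modules, regulons, fuzzy memberships, and label transfer.

A regulatory module is a set of RBPs sharing significant functional
interactions; modules are cut from a Ward tree built on cosine distances
between rows of the integrated map. A module's regulon is the set of RNA
features targeted by at least two of its member RBPs. Functional labels
are transferred to an RBP from its nearest neighbors in the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigError, DomainError
from .integrate import IntegratedMap
from .io import GeneSetCollection

logger = logging.getLogger("irimap")

__all__ = [
    "ModuleSet",
    "Regulon",
    "hierarchical_modules",
    "fuzzy_cmeans",
    "derive_regulon",
    "label_transfer",
]


@dataclass
class ModuleSet:
    """Hard partition of mapped RBPs into modules, with the linkage tree."""

    labels: pd.Series  # rbp -> module id (1-based ints)
    linkage: np.ndarray

    @property
    def modules(self) -> dict[int, tuple[str, ...]]:
        out: dict[int, tuple[str, ...]] = {}
        for module_id, grp in self.labels.groupby(self.labels):
            out[int(module_id)] = tuple(sorted(grp.index))
        return out

    def members(self, module_id: int) -> tuple[str, ...]:
        return self.modules[int(module_id)]


@dataclass
class Regulon:
    """RNA features jointly bound by at least ``min_rbps`` RBPs of one module."""

    module_rbps: frozenset[str]
    features: frozenset[str]
    support: dict[str, int]


def hierarchical_modules(irim: IntegratedMap, n_modules: int) -> ModuleSet:
    """Cut a Ward tree over the integrated map into ``n_modules`` modules.

    Rows of the combined-probability matrix are re-embedded via pairwise
    cosine distance between row profiles, then agglomerated with Ward's
    minimum-variance linkage (the squared-dissimilarity update, as in R's
    ward.D2 usage on a precomputed distance). Missing off-diagonal entries
    are imputed to the median of the defined entries (logged); the diagonal
    is treated as 0.
    """
    x = irim.values.to_numpy(dtype=float).copy()
    n = x.shape[0]
    if n_modules > n:
        raise DomainError(f"n_modules={n_modules} exceeds the {n} mapped RBPs")
    if n_modules < 1:
        raise DomainError("n_modules must be >= 1")
    np.fill_diagonal(x, 0.0)
    missing = ~np.isfinite(x)
    if missing.any():
        med = float(np.nanmedian(x[np.triu_indices(n, k=1)]))
        logger.info("imputing %d missing map entries to the median %.4g", int(missing.sum()), med)
        x[missing] = med
    d = pdist(x, metric="cosine")
    z = linkage(d, method="ward")
    labels = fcluster(z, t=n_modules, criterion="maxclust")
    return ModuleSet(pd.Series(labels, index=irim.rbps, name="module"), z)


def fuzzy_cmeans(
    profiles: pd.DataFrame | np.ndarray,
    c: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Fuzzy c-means memberships for the rows of ``profiles``.

    Standard alternating updates: memberships u_ik = 1 / sum_j (d_ik/d_jk)^
    (2/(m-1)), centroids as u^m-weighted means, iterated until the largest
    membership change drops below ``tol``. A point coincident with a centroid
    gets membership 1 there. Memberships per row sum to 1. Centroids are
    initialized from ``c`` distinct sampled rows.
    """
    if c < 2:
        raise DomainError("fuzzy c-means needs c >= 2 clusters")
    if fuzzifier <= 1:
        raise DomainError("fuzzifier must be > 1")
    index = profiles.index if isinstance(profiles, pd.DataFrame) else pd.RangeIndex(len(profiles))
    x = np.asarray(profiles, dtype=float)
    n = x.shape[0]
    if c > n:
        raise DomainError(f"c={c} exceeds the {n} points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # distinct-row init: unique rows to avoid coincident starting centroids
    uniq = np.unique(x, axis=0)
    if len(uniq) >= c:
        centroids = uniq[rng.choice(len(uniq), size=c, replace=False)]
    else:
        centroids = x[rng.choice(n, size=c, replace=False)].astype(float)
        centroids = centroids + 1e-9 * rng.standard_normal(centroids.shape)

    exponent = 2.0 / (fuzzifier - 1.0)
    u = np.full((n, c), 1.0 / c)
    for _ in range(max_iter):
        d = np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=2)
        u_new = np.empty_like(u)
        zero = d <= 0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-exponent)
            u_new = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            u_new[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        centroids_new = (u_new**fuzzifier).T @ x / (u_new**fuzzifier).sum(axis=0)[:, None]
        shift = float(np.max(np.abs(u_new - u)))
        u, centroids = u_new, centroids_new
        if shift < tol:
            break
    else:
        logger.warning("fuzzy c-means did not converge in %d iterations", max_iter)
    cols = [f"cluster_{j + 1}" for j in range(c)]
    return pd.DataFrame(u, index=index, columns=cols)


def derive_regulon(
    module: Iterable[str],
    calls: Mapping[str, frozenset[str] | set[str]],
    min_rbps: int = 2,
) -> Regulon:
    """Features that are called targets of at least ``min_rbps`` module members."""
    members = frozenset(module)
    if not members:
        raise ConfigError("module is empty")
    support: dict[str, int] = {}
    for rbp in members:
        for feat in calls.get(rbp, frozenset()):
            support[feat] = support.get(feat, 0) + 1
    features = frozenset(f for f, k in support.items() if k >= min_rbps)
    return Regulon(members, features, {f: support[f] for f in features})


def label_transfer(
    query: str,
    irim: IntegratedMap,
    annotations: GeneSetCollection,
    k: int = 3,
) -> list[tuple[str, int, float]]:
    """Rank annotation terms among the ``k`` nearest map neighbors of ``query``.

    ``annotations`` holds term -> set-of-RBPs. Terms are scored by how many
    of the k closest RBPs (smallest integrated value) carry them; ties break
    by the mean distance of the carrying neighbors (ascending), then term
    name. Returns (term, count, mean_distance) triples, best first.
    """
    if query not in irim.values.index:
        raise DomainError(f"query RBP {query!r} absent from the integrated map")
    row = irim.values.loc[query].drop(labels=[query]).dropna()
    if len(row) < k:
        raise DomainError(f"only {len(row)} neighbors available, need k={k}")
    # deterministic under distance ties: sort by (distance, id)
    order = sorted(row.items(), key=lambda item: (item[1], item[0]))[:k]
    neighbor_dist = dict(order)
    ranked: list[tuple[str, int, float]] = []
    for term, rbps in annotations.items():
        carriers = [r for r in neighbor_dist if r in rbps]
        if carriers:
            ranked.append((term, len(carriers), float(np.mean([neighbor_dist[r] for r in carriers]))))
    ranked.sort(key=lambda t: (-t[1], t[2], t[0]))
    return ranked
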