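"""Gene-set enrichment annotation of RBP neighborhoods.

Each RBP's feature scores (typically column z-scores of the target-score
matrix) are ranked descending and scanned with the classic weighted
Kolmogorov-Smirnov running sum: hits advance the sum in proportion to
|score|^weight, misses retreat it by 1/(N - n_hits), and the enrichment
score (ES) is the signed extremum. Significance comes from gene-sampling
permutations (random same-size sets), with NES = ES / mean(|ES*|) over
same-sign null scores and a +1-convention permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .io import GeneSetCollection

logger = logging.getLogger("irimap")

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "make_ranked_list",
    "gsea_es",
    "gsea_significance",
    "annotate_rbp",
    "heatmap_matrix",
    "annotation_score",
    "roc_auc",
]


@dataclass
class RankedList:
    """Features ordered by descending score; ties break by feature id."""

    features: np.ndarray  # dtype=object / str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise DomainError("features and scores must have equal length")
        if len(np.unique(self.features)) != len(self.features):
            raise DomainError("ranked list contains duplicate features")

    def __len__(self) -> int:
        return len(self.features)


def make_ranked_list(scores: pd.Series) -> RankedList:
    """Build a RankedList from a feature -> score Series (descending order)."""
    df = pd.DataFrame({"feature": scores.index.astype(str), "score": scores.to_numpy(dtype=float)})
    df = df.sort_values(["score", "feature"], ascending=[False, True], kind="mergesort")
    return RankedList(df["feature"].to_numpy(), df["score"].to_numpy())


@dataclass
class EnrichmentResult:
    """One (RBP, gene set) enrichment outcome."""

    rbp: str
    set_name: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: frozenset[str]


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    """Running-sum curve over the ranked list for one hit indicator vector."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise DomainError("gene set does not overlap the ranked list")
    w = np.abs(scores) ** weight
    hit_weight = np.where(hit_mask, w, 0.0)
    total = hit_weight.sum()
    if total == 0:
        # all hit scores are exactly zero: fall back to unweighted steps
        hit_weight = hit_mask.astype(float)
        total = hit_weight.sum()
    miss = n - n_hits
    steps = hit_weight / total
    if miss > 0:
        steps = steps - (~hit_mask) / miss
    return np.cumsum(steps)


def gsea_es(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and running sum for one gene set.

    Returns ``(es, running_sum)`` where ES is the running-sum value of
    maximal absolute deviation from zero (signed). A set with no overlap
    yields ``(nan, empty)`` -- an undefined-result marker, not 0.
    """
    members = frozenset(gene_set)
    hit_mask = np.fromiter((f in members for f in ranked.features), dtype=bool, count=len(ranked))
    if not hit_mask.any():
        return float("nan"), np.array([])
    curve = _running_sum(ranked.scores, hit_mask, weight)
    idx = int(np.argmax(np.abs(curve)))
    return float(curve[idx]), curve


def _null_es(
    ranked: RankedList, set_size: int, weight: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES scores from random same-size feature sets (vectorized)."""
    n = len(ranked)
    w = np.abs(ranked.scores) ** weight
    # random distinct positions per permutation via argpartition of random keys
    keys = rng.random((n_perm, n))
    hit_idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((n_perm, n), dtype=bool)
    rows = np.repeat(np.arange(n_perm), set_size)
    hits[rows, hit_idx.ravel()] = True
    hit_w = np.where(hits, w[None, :], 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0
    if degenerate.any():
        hit_w[degenerate] = hits[degenerate].astype(float)
        totals = hit_w.sum(axis=1, keepdims=True)
    steps = hit_w / totals
    miss = n - set_size
    if miss > 0:
        steps = steps - (~hits) / miss
    curves = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(curves), axis=1)
    return curves[np.arange(n_perm), idx]


def gsea_significance(
    ranked: RankedList,
    gene_set,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
    rbp: str = "",
    set_name: str = "",
    _null_cache: dict | None = None,
) -> EnrichmentResult:
    """Permutation p-value and NES for one gene set on one ranked list.

    The null samples random feature sets of equal size from the ranked
    universe. p = (#{same-sign |ES*| >= |ES|} + 1) / (n_same_sign + 1) and
    NES = ES / mean(|ES*| over same-sign nulls). With no same-sign nulls the
    result is p = 1 and NES = nan (undefined marker). ``q`` is filled by the
    caller (BH across sets); here it is initialized to ``p``.
    """
    if n_perm < 100:
        raise DomainError("n_perm must be >= 100 for a usable permutation null")
    members = frozenset(gene_set) & set(ranked.features.tolist())
    es, curve = gsea_es(ranked, gene_set, weight=weight)
    if not np.isfinite(es):
        return EnrichmentResult(rbp, set_name, float("nan"), float("nan"), 1.0, 1.0, frozenset())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = len(members)
    if _null_cache is not None and size in _null_cache:
        null = _null_cache[size]
    else:
        null = _null_es(ranked, size, weight, n_perm, rng)
        if _null_cache is not None:
            _null_cache[size] = null
    same_sign = null > 0 if es > 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        return EnrichmentResult(rbp, set_name, es, float("nan"), 1.0, 1.0, frozenset())
    extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
    p = (extreme + 1) / (n_same + 1)
    nes = es / float(np.mean(np.abs(null[same_sign])))
    # leading edge: hits at or before (after, for negative ES) the extremum
    hit_mask = np.fromiter((f in members for f in ranked.features), dtype=bool, count=len(ranked))
    idx = int(np.argmax(np.abs(curve)))
    if es >= 0:
        edge = ranked.features[: idx + 1][hit_mask[: idx + 1]]
    else:
        edge = ranked.features[idx:][hit_mask[idx:]]
    return EnrichmentResult(rbp, set_name, es, nes, float(p), float(p), frozenset(edge))


def annotate_rbp(
    scores: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
    rbp: str = "",
) -> list[EnrichmentResult]:
    """GSEA of one RBP's score profile against every set in a collection.

    ``scores`` is a feature -> score Series (z-scored by default upstream; a
    raw-score profile may be passed instead to avoid penalizing broad,
    generic sets). A constant profile carries no ranking information and is
    rejected. BH adjustment runs across the sets of the collection.
    """
    if len(sets) == 0:
        return []
    vals = scores.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        raise DomainError("constant score profile: ranking undefined")
    ranked = make_ranked_list(scores)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cache: dict[int, np.ndarray] = {}
    results = [
        gsea_significance(
            ranked, members, n_perm=n_perm, seed=rng, weight=weight,
            rbp=rbp, set_name=name, _null_cache=cache,
        )
        for name, members in sorted(sets.items())
    ]
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def heatmap_matrix(results: pd.DataFrame, nes_min: float = 2.0) -> pd.DataFrame:
    """Set x RBP NES matrix for plotting/clustering.

    Keeps sets whose maximum NES across RBPs exceeds ``nes_min`` and clamps
    negative NES values to 0. ``results`` needs columns rbp, set_name, nes.
    """
    if results.empty:
        return pd.DataFrame()
    wide = results.pivot_table(index="set_name", columns="rbp", values="nes", aggfunc="first")
    keep = wide.max(axis=1, skipna=True) > nes_min
    wide = wide.loc[keep]
    return wide.clip(lower=0.0).fillna(0.0)


def annotation_score(p: float, nes: float) -> float:
    """Signed annotation confidence ``-log10(p) * sign(nes)``."""
    if not (0.0 < p <= 1.0):
        raise DomainError(f"p outside (0, 1]: {p!r}")
    return float(-np.log10(p) * np.sign(nes))


def roc_auc(scores, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC for annotation scores against binary membership.

    AUC uses the rank (Mann-Whitney) formulation with midranks for ties,
    which coincides with the trapezoidal area under the threshold-sweep
    curve. Requires both classes present.
    """
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise DomainError("truth labels contain a single class")
    fpr, tpr, _ = roc_curve(y, s)
    from scipy.stats import rankdata

    ranks = rankdata(s, method="average")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return fpr, tpr, float(auc)
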