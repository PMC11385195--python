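"""Statistical validation of the integrated map.

Covers the quantile rule for significant pairs, permutation tests of the
overlap with external interaction references (value-shuffle null with the
+1 convention), column-shuffle robustness profiling, RNA-type enrichment
of target calls, and generic one-sided set-overlap tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .integrate import IntegratedMap
from .io import ReferenceInteractions, canonical_pair

logger = logging.getLogger("irimap")

__all__ = [
    "SignificantPairSet",
    "PermutationResult",
    "threshold_pairs",
    "mean_degree",
    "overlap_permutation_test",
    "overlap_permutation_tests",
    "robustness_shuffle",
    "rna_type_enrichment",
    "set_overlap_test",
    "benjamini_hochberg",
]


@dataclass
class SignificantPairSet:
    """Map pairs whose combined value falls strictly below a quantile threshold."""

    pairs: frozenset[tuple[str, str]]
    threshold: float
    quantile: float

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self.pairs


@dataclass
class PermutationResult:
    """Observed overlap fraction vs a value-shuffle null."""

    observed: float
    null_fractions: np.ndarray
    p: float
    q: float
    n_shuffles: int


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (statsmodels step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def threshold_pairs(irim: IntegratedMap, q: float = 0.25) -> SignificantPairSet:
    """Pairs with combined value strictly below the level-``q`` empirical quantile.

    The quantile interpolates linearly between order statistics (Hyndman-Fan
    type 7, the default of the common statistical environments), so with N
    distinct values and (N-1)*q integral the threshold lands exactly on an
    order statistic and exactly floor(q*N) pairs pass.
    """
    series = irim.pair_values()
    if len(series) < 2:
        raise DomainError("need at least 2 defined pairs")
    if not (0.0 <= q <= 1.0):
        raise DomainError(f"quantile level out of [0, 1]: {q}")
    thr = float(np.quantile(series.to_numpy(), q, method="linear"))
    passing = frozenset(series.index[series.to_numpy() < thr])
    return SignificantPairSet(passing, thr, q)


def mean_degree(pairs: SignificantPairSet, n_rbps: int) -> float:
    """Average number of contacts per RBP implied by a pair set: 2|E|/n."""
    if n_rbps <= 0:
        raise DomainError("n_rbps must be positive")
    return 2.0 * len(pairs) / n_rbps


def overlap_permutation_test(
    pairs: SignificantPairSet,
    ref: ReferenceInteractions,
    irim: IntegratedMap,
    n_shuffles: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Right-tailed permutation test of the overlap with a reference pair list.

    Observed statistic: the fraction of threshold-passing pairs present in
    the reference (restricted to map RBPs). Null: the pair -> value
    assignment of the map is permuted uniformly, the same quantile rule is
    re-applied, and the fraction recomputed. p = (#{null >= observed} + 1) /
    (n_shuffles + 1), never 0 and never above 1. ``q`` is initialized to p;
    use :func:`overlap_permutation_tests` for BH across references.
    """
    series = irim.pair_values()
    ref_r = ref.restricted_to(irim.rbps)
    if len(ref_r) == 0:
        raise DomainError("reference is empty after restriction to map RBPs")
    values = series.to_numpy()
    ref_mask = np.fromiter((p in ref_r.pairs for p in series.index), dtype=bool, count=len(series))
    thr = pairs.threshold
    obs_mask = values < thr
    n_pass = int(obs_mask.sum())
    if n_pass == 0:
        raise DomainError("no pairs pass the threshold")
    observed = float(ref_mask[obs_mask].sum() / n_pass)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(values)
        mask = perm < thr
        m = int(mask.sum())
        null[s] = ref_mask[mask].sum() / m if m else 0.0
    p = (int((null >= observed).sum()) + 1) / (n_shuffles + 1)
    return PermutationResult(observed, null, float(p), float(p), n_shuffles)


def overlap_permutation_tests(
    pairs: SignificantPairSet,
    refs: dict[str, ReferenceInteractions],
    irim: IntegratedMap,
    n_shuffles: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, PermutationResult]:
    """Overlap tests against several references, BH-adjusted across them."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = {
        name: overlap_permutation_test(pairs, ref, irim, n_shuffles=n_shuffles, seed=rng)
        for name, ref in sorted(refs.items())
    }
    qs = benjamini_hochberg([r.p for r in results.values()])
    for r, q in zip(results.values(), qs):
        r.q = float(q)
    return results


def robustness_shuffle(
    irim: IntegratedMap,
    fractions=(0.0, 0.05, 0.10, 0.25, 0.50, 0.75, 1.0),
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Column-shuffle robustness profile of the map.

    Per repeat and fraction f, ceil(f*n) columns are selected uniformly and
    the entries of each selected column are permuted independently (the
    matrix is deliberately left asymmetric). For every RBP the profile
    records the cosine distance between its original and perturbed column
    vector (displacement) and the min/median/max of its perturbed distances
    to partners, giving repeats x n estimates per fraction.
    """
    for f in fractions:
        if not (0.0 <= f <= 1.0):
            raise DomainError(f"shuffle fraction outside [0, 1]: {f}")
    x = irim.values.to_numpy(dtype=float).copy()
    n = x.shape[0]
    np.fill_diagonal(x, 0.0)
    if not np.all(np.isfinite(x)):
        med = float(np.nanmedian(x[np.triu_indices(n, k=1)]))
        x[~np.isfinite(x)] = med
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = irim.rbps
    off_diag = ~np.eye(n, dtype=bool)
    records = []
    for f in fractions:
        n_cols = math.ceil(f * n)
        for rep in range(repeats):
            perturbed = x.copy()
            if n_cols:
                cols = rng.choice(n, size=n_cols, replace=False)
                for c in cols:
                    perturbed[:, c] = rng.permutation(perturbed[:, c])
            for i in range(n):
                orig, pert = x[:, i], perturbed[:, i]
                displacement = _cosine_distance(orig, pert)
                partners = pert[off_diag[:, i]]
                records.append(
                    (f, rep, ids[i], displacement,
                     float(partners.min()), float(np.median(partners)), float(partners.max()))
                )
    return pd.DataFrame(
        records,
        columns=["fraction", "repeat", "rbp", "displacement", "min_dist", "median_dist", "max_dist"],
    )


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0 if nu == nv else 1.0
    return float(np.clip(1.0 - float(u @ v) / (nu * nv), 0.0, 2.0))


def rna_type_enrichment(
    calls: dict[str, frozenset[str]],
    background: frozenset[str] | set[str],
    types: dict[str, str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each RNA type among each RBP's targets.

    The 2x2 table per (RBP, type) splits the background into target vs
    non-target and type vs other; the alternative is 'greater' (enrichment).
    p-values are BH-adjusted within each RBP across the tested types. Types
    absent from the background are skipped with a warning.
    """
    background = frozenset(background)
    present = {t for f, t in types.items() if f in background}
    all_types = sorted({t for f, t in types.items()})
    usable = sorted(present)
    skipped = [t for t in all_types if t not in present]
    for t in skipped:
        logger.warning("RNA type %r absent from background; skipped", t)
    by_type = {t: frozenset(f for f in background if types.get(f) == t) for t in usable}
    rows = []
    for rbp in sorted(calls):
        targets = frozenset(calls[rbp]) & background
        non_targets = background - targets
        ps, ors = [], []
        for t in usable:
            members = by_type[t]
            a = len(targets & members)
            b = len(targets) - a
            c = len(non_targets & members)
            d = len(non_targets) - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            ps.append(p)
            ors.append(odds)
        qs = benjamini_hochberg(ps) if ps else []
        for t, odds, p, q in zip(usable, ors, ps, qs):
            rows.append((rbp, t, float(odds), float(p), float(q)))
    return pd.DataFrame(rows, columns=["rbp", "rna_type", "odds_ratio", "p", "q"])


def set_overlap_test(a, b, universe) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of the overlap of two sets.

    Returns ``(odds_ratio, p)`` for the 2x2 table of membership in ``a`` x
    membership in ``b`` over ``universe``.
    """
    universe = frozenset(universe)
    if not universe:
        raise DomainError("empty universe")
    a = frozenset(a) & universe
    b = frozenset(b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    odds, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="greater")
    return float(odds), float(p)
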