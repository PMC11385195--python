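"""From standardized target scores to the integrated RBP-RBP interaction map.

Each modality contributes a cosine-distance matrix over its panel, converted
to empirical left-tailed p-values by ranking all defined pairs within the
modality. Per RBP pair, the available modality p-values are aggregated with
the Mudholkar-George logit method into a single combined probability; small
values mean strong evidence of interaction. The map covers the RBPs measured
in at least ``min_modalities`` panels, recording per pair the number of
modalities (k) that actually covered it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .errors import DomainError
from .scores import TargetScoreMatrix

logger = logging.getLogger("irimap")

__all__ = [
    "DistanceMatrix",
    "EmpiricalPMatrix",
    "IntegratedMap",
    "cosine_distance_matrix",
    "empirical_left_p",
    "combine_logit",
    "build_irim",
    "leave_one_modality_out",
]


@dataclass
class DistanceMatrix:
    """Symmetric cosine distances in [0, 2] over one modality's panel."""

    values: pd.DataFrame
    modality: str

    @property
    def rbps(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(dtype=float), checks=False)


@dataclass
class EmpiricalPMatrix:
    """Symmetric empirical left-tailed p-values in (0, 1); diagonal undefined."""

    values: pd.DataFrame
    modality: str

    @property
    def rbps(self) -> list[str]:
        return list(self.values.index)


@dataclass
class IntegratedMap:
    """Combined interaction probabilities over the multi-modality RBP union.

    ``values`` is symmetric with NaN on the diagonal (and on pairs covered by
    no modality); ``k`` counts the modalities covering each pair. Smaller
    values mean stronger evidence of interaction.
    """

    values: pd.DataFrame
    k: pd.DataFrame = field(repr=False)

    @property
    def rbps(self) -> list[str]:
        return list(self.values.index)

    def pair_values(self) -> pd.Series:
        """Defined (off-diagonal, covered) pairs as a Series keyed by canonical pair."""
        ids = self.rbps
        vals = self.values.to_numpy(dtype=float)
        out = {}
        for i, j in itertools.combinations(range(len(ids)), 2):
            if np.isfinite(vals[i, j]):
                out[(ids[i], ids[j])] = vals[i, j]
        return pd.Series(out, dtype=float)

    def n_pairs(self) -> int:
        vals = self.values.to_numpy(dtype=float)
        iu = np.triu_indices(len(vals), k=1)
        return int(np.isfinite(vals[iu]).sum())


def cosine_distance_matrix(m: TargetScoreMatrix) -> DistanceMatrix:
    """Pairwise cosine distances ``1 - x.y/(|x||y|)`` between RBP rows.

    All-zero rows carry no direction; by convention they sit at distance 1
    (orthogonality) from every other RBP. The diagonal is 0.
    """
    x = m.values.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise DomainError("cosine distances require at least 2 RBPs")
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        logger.info("%d all-zero row(s); using the orthogonality convention (d=1)", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    d = 1.0 - unit @ unit.T
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(pd.DataFrame(d, index=m.values.index, columns=m.values.index), m.modality)


def empirical_left_p(d: DistanceMatrix) -> EmpiricalPMatrix:
    """Rank-based left-tailed p-values for pairwise similarity within a modality.

    For a pair with ascending rank r (1-based, average rank on ties) among the
    N defined pairs, p = r/(N+1) -- strictly inside (0, 1) so the values can be
    combined on the logit scale. Small p = unusually close pair.
    """
    cond = d.condensed()
    n = cond.size
    if n < 1:
        raise DomainError("empirical p-values require at least 2 RBPs (1 pair)")
    ranks = stats.rankdata(cond, method="average")
    p = ranks / (n + 1.0)
    mat = squareform(p, checks=False)
    np.fill_diagonal(mat, np.nan)
    return EmpiricalPMatrix(
        pd.DataFrame(mat, index=d.values.index, columns=d.values.index), d.modality
    )


_MG_DF_CACHE: dict[int, tuple[float, float]] = {}


def _mg_constants(k: int) -> tuple[float, float]:
    """Scale C and degrees of freedom for the Mudholkar-George t approximation."""
    if k not in _MG_DF_CACHE:
        c = float(np.sqrt(k * np.pi**2 * (5 * k + 2) / (3.0 * (5 * k + 4))))
        _MG_DF_CACHE[k] = (c, float(5 * k + 4))
    return _MG_DF_CACHE[k]


def combine_logit(ps) -> float:
    """Combine k p-values with the logit (Mudholkar-George) method.

    T = -sum(log(p_i/(1-p_i))) is referred to a Student t distribution with
    5k+4 degrees of freedom after scaling by C = sqrt(k*pi^2*(5k+2)/(3(5k+4))).
    Every p must lie strictly inside (0, 1). k = 1 is allowed and yields a
    monotone transform of the single p.
    """
    p = np.asarray(ps, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise DomainError("combine_logit expects a non-empty 1-d sequence of p-values")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise DomainError(f"p-values must be strictly inside (0, 1): {ps!r}")
    k = int(p.size)
    c, df = _mg_constants(k)
    t_stat = -np.sum(np.log(p / (1.0 - p))) / c
    return float(stats.t.sf(t_stat, df=df))


def _combine_logit_rows(pmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized row-wise logit combination of a (n_pairs x n_modalities) array.

    NaN marks a modality not covering the pair. Returns (combined, k); rows
    with k = 0 come back NaN.
    """
    finite = np.isfinite(pmat)
    k = finite.sum(axis=1)
    logits = np.where(finite, np.log(pmat / (1.0 - pmat), where=finite, out=np.zeros_like(pmat)), 0.0)
    t_num = -logits.sum(axis=1)
    combined = np.full(pmat.shape[0], np.nan)
    for kk in np.unique(k):
        if kk == 0:
            continue
        c, df = _mg_constants(int(kk))
        sel = k == kk
        combined[sel] = stats.t.sf(t_num[sel] / c, df=df)
    return combined, k.astype(int)


def build_irim(
    pmats: dict[str, EmpiricalPMatrix], min_modalities: int = 2
) -> IntegratedMap:
    """Aggregate per-modality empirical p-values into the integrated map.

    An RBP enters the map when it is measured in at least ``min_modalities``
    panels. Every pair of qualifying RBPs is combined over exactly the
    modalities in which both members were measured; the per-pair modality
    count k is recorded alongside the combined value. With the study's panel
    geometry (BioID and Perturb-seq panels nested in the eCLIP panel) this
    covers all n(n-1)/2 pairs of the two-modality union.
    """
    if len(pmats) < min_modalities:
        raise DomainError(
            f"need at least {min_modalities} modality matrices, got {len(pmats)}"
        )
    membership: dict[str, set[str]] = {}
    for modality, pm in pmats.items():
        for rbp in pm.rbps:
            membership.setdefault(rbp, set()).add(modality)
    ids = sorted(r for r, mods in membership.items() if len(mods) >= min_modalities)
    if len(ids) < 2:
        raise DomainError("fewer than 2 RBPs qualify for the integrated map")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    modalities = sorted(pmats)
    stacked = np.full((iu[0].size, len(modalities)), np.nan)
    for col, modality in enumerate(modalities):
        pm = pmats[modality]
        aligned = pm.values.reindex(index=ids, columns=ids).to_numpy(dtype=float)
        stacked[:, col] = aligned[iu]
    combined, k = _combine_logit_rows(stacked)

    vals = np.full((n, n), np.nan)
    kmat = np.zeros((n, n), dtype=int)
    vals[iu] = combined
    kmat[iu] = k
    vals[(iu[1], iu[0])] = combined
    kmat[(iu[1], iu[0])] = k
    logger.info(
        "integrated map: %d RBPs, %d covered pairs (of %d)",
        n, int(np.isfinite(combined).sum()), iu[0].size,
    )
    return IntegratedMap(
        pd.DataFrame(vals, index=ids, columns=ids),
        pd.DataFrame(kmat, index=ids, columns=ids),
    )


def leave_one_modality_out(
    pmats: dict[str, EmpiricalPMatrix], held_out: str, min_modalities: int = 2
) -> IntegratedMap:
    """Integrated map rebuilt from all modalities except ``held_out``."""
    if held_out not in pmats:
        raise DomainError(f"unknown modality {held_out!r}; have {sorted(pmats)}")
    remaining = {m: pm for m, pm in pmats.items() if m != held_out}
    return build_irim(remaining, min_modalities=min_modalities)
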