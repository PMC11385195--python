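"""Target-score matrices from per-modality differential statistics.

The common currency of the three assays is the signed significance score
TS = -log10(p) * sign(log2FC) per (RBP, feature) comparison. Columns are
then z-scored across RBPs so that modalities become comparable, target
calls follow a per-RBP Benjamini-Hochberg rule, and the Perturb-seq arm
provides guide assignment (Hamming-1 UMI collapse, >=5 UMIs, >80%
consensus) plus per-gene Welch t-test scoring of knockdown vs control.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DomainError, FormatError
from .io import DifferentialTable

logger = logging.getLogger("irimap")

__all__ = [
    "TargetScoreMatrix",
    "compute_target_score",
    "target_score_matrix",
    "standardize_columns",
    "cpm_filter",
    "call_targets",
    "collapse_umis_hamming1",
    "assign_guides",
    "two_group_scores",
    "perturbation_scores",
]


@dataclass
class TargetScoreMatrix:
    """RBP x feature matrix of signed significance scores for one modality."""

    values: pd.DataFrame
    modality: str
    standardized: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise FormatError("target-score matrix contains non-finite entries")

    @property
    def rbps(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def compute_target_score(p, log2fc):
    """Signed significance score ``-log10(p) * sign(log2fc)``.

    ``sign(0) = 0`` so a zero fold change always maps to a zero score.
    Accepts scalars or arrays; ``p`` must lie in (0, 1].
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0.0) | (p_arr > 1.0)):
        raise DomainError(f"p outside (0, 1]: {p!r}")
    ts = -np.log10(p_arr) * np.sign(np.asarray(log2fc, dtype=float))
    # -log10(1.0) can be -0.0; normalize so sign conventions stay clean
    ts = ts + 0.0
    return float(ts) if np.isscalar(p) or p_arr.ndim == 0 else ts


def target_score_matrix(table: DifferentialTable) -> TargetScoreMatrix:
    """Pivot a differential table into a dense RBP x feature TS matrix.

    Feature/RBP combinations absent from the table get TS = 0 (no evidence).
    """
    df = table.data.copy()
    df["ts"] = compute_target_score(df["p_value"].to_numpy(), df["log2fc"].to_numpy())
    mat = df.pivot(index="rbp", columns="feature", values="ts")
    mat = mat.sort_index(axis=0).sort_index(axis=1).fillna(0.0)
    return TargetScoreMatrix(mat, table.modality, standardized=False)


def standardize_columns(m: TargetScoreMatrix) -> TargetScoreMatrix:
    """Z-score every feature column across RBPs (population SD).

    Constant columns carry no ranking information and are mapped to all
    zeros. Requires at least two rows; a single-row z-score is undefined.
    """
    x = m.values.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise DomainError("z-scoring requires at least 2 RBPs")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mean[ok]) / sd[ok]
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return TargetScoreMatrix(out, m.modality, standardized=True)


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 2.0, min_samples: int = 2) -> list[str]:
    """Genes with counts-per-million >= ``min_cpm`` in >= ``min_samples`` samples.

    ``counts`` is sample x gene with non-negative entries. A sample with a
    zero library size cannot be normalized and is reported by name.
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise DomainError("counts must be non-negative")
    totals = arr.sum(axis=1)
    if np.any(totals == 0):
        bad = counts.index[int(np.flatnonzero(totals == 0)[0])]
        raise DomainError(f"sample {bad!r} has zero total counts")
    cpm = arr / totals[:, None] * 1e6
    keep = (cpm >= min_cpm).sum(axis=0) >= min_samples
    return [g for g, k in zip(counts.columns, keep) if k]


def call_targets(
    table: DifferentialTable, fdr_level: float = 0.05, lfc_min: float = 0.5
) -> dict[str, frozenset[str]]:
    """Reliable targets per RBP: BH-adjusted p < ``fdr_level`` AND log2fc > ``lfc_min``.

    The BH adjustment runs within each RBP separately, across that RBP's
    features only.
    """
    calls: dict[str, frozenset[str]] = {}
    if len(table) == 0:
        return calls
    for rbp, grp in table.data.groupby("rbp", sort=True):
        p = grp["p_value"].to_numpy(dtype=float)
        adj = multipletests(p, method="fdr_bh")[1]
        hit = (adj < fdr_level) & (grp["log2fc"].to_numpy(dtype=float) > lfc_min)
        calls[str(rbp)] = frozenset(grp.loc[hit, "feature"])
    return calls


# ---------------------------------------------------------------------------
# Perturb-seq guide assignment
# ---------------------------------------------------------------------------

def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > 1:
                return False
    return mismatches == 1


def collapse_umis_hamming1(umi_reads: Mapping[str, Counter]) -> dict[str, Counter]:
    """Greedily merge UMIs within Hamming distance 1 of each other.

    UMIs are visited in descending read-count order (ties broken
    lexicographically); each unabsorbed UMI becomes a sink that absorbs all
    remaining UMIs one substitution away. Absorbed UMIs do not chain. The
    result maps surviving UMIs to pooled per-guide read counts and is
    independent of input ordering.
    """
    order = sorted(umi_reads, key=lambda u: (-sum(umi_reads[u].values()), u))
    absorbed: set[str] = set()
    merged: dict[str, Counter] = {}
    for sink in order:
        if sink in absorbed:
            continue
        pooled = Counter(umi_reads[sink])
        for other in order:
            if other is sink or other in absorbed:
                continue
            if _hamming1(sink, other):
                pooled.update(umi_reads[other])
                absorbed.add(other)
        merged[sink] = pooled
    return merged


_VALID_BASES = frozenset("ACGTN")


def assign_guides(
    rows: pd.DataFrame, min_umis: int = 5, consensus_frac: float = 0.8
) -> dict[str, str | None]:
    """Cell -> guide assignment from (cell_barcode, umi, guide) read rows.

    Per cell, UMIs within Hamming distance 1 are first collapsed; each
    surviving UMI votes for its most-represented read-level guide. A cell is
    assigned iff it has at least ``min_umis`` distinct UMIs and strictly more
    than ``consensus_frac`` of them vote for the same guide; otherwise it maps
    to ``None``. Rows with malformed barcode or UMI characters are rejected
    with a log entry.
    """
    per_cell: dict[str, dict[str, Counter]] = defaultdict(lambda: defaultdict(Counter))
    n_rejected = 0
    for cell, umi, guide in rows[["cell_barcode", "umi", "guide"]].itertuples(index=False):
        cell, umi = str(cell), str(umi)
        if not (set(cell) <= _VALID_BASES and set(umi) <= _VALID_BASES):
            n_rejected += 1
            logger.warning("rejecting read with malformed barcode/UMI: %r / %r", cell, umi)
            continue
        per_cell[cell][umi][str(guide)] += 1
    if n_rejected:
        logger.info("rejected %d malformed read rows", n_rejected)

    assignment: dict[str, str | None] = {}
    for cell, umis in per_cell.items():
        merged = collapse_umis_hamming1(umis)
        if len(merged) < min_umis:
            assignment[cell] = None
            continue
        votes = Counter()
        for guide_counts in merged.values():
            # ties at the read level break lexicographically for determinism
            top = min(guide_counts, key=lambda g: (-guide_counts[g], g))
            votes[top] += 1
        winner = min(votes, key=lambda g: (-votes[g], g))
        if votes[winner] / len(merged) > consensus_frac:
            assignment[cell] = winner
        else:
            assignment[cell] = None
    return assignment


# ---------------------------------------------------------------------------
# Two-group differential scoring (Perturb-seq arms, BioID replicates)
# ---------------------------------------------------------------------------

def two_group_scores(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test per column of ``case`` (n1 x m) vs ``control`` (n2 x m).

    Returns ``(p, ts)`` where ts = -log10(p) * sign(mean(case) - mean(control)).
    Degenerate columns (zero variance in both groups, identical means) get
    p = 1 and ts = 0.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise DomainError("both groups need at least 2 observations")
    res = stats.ttest_ind(case, control, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    diff = case.mean(axis=0) - control.mean(axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    ts = compute_target_score(p, diff)
    return p, np.asarray(ts, dtype=float)


def perturbation_scores(
    counts: pd.DataFrame,
    assignment: Mapping[str, str | None],
    control_label: str,
) -> TargetScoreMatrix:
    """Per-(RBP, gene) Welch t scores of knockdown cells vs control cells.

    ``counts`` is cell x gene; ``assignment`` maps cell barcodes to guide
    labels (``control_label`` marks non-targeting cells, ``None`` means
    unassigned). Groups with fewer than 2 cells are skipped with a warning.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for cell, guide in assignment.items():
        if guide is not None and cell in counts.index:
            groups[guide].append(cell)
    control_cells = groups.pop(control_label, [])
    if len(control_cells) < 2:
        raise ConfigError(f"need >= 2 control cells labelled {control_label!r}, got {len(control_cells)}")
    control = counts.loc[control_cells].to_numpy(dtype=float)

    rows: dict[str, np.ndarray] = {}
    for guide in sorted(groups):
        cells = groups[guide]
        if len(cells) < 2:
            logger.warning("skipping guide %r: only %d assigned cell(s)", guide, len(cells))
            continue
        _, ts = two_group_scores(counts.loc[cells].to_numpy(dtype=float), control)
        rows[guide] = ts
    if not rows:
        raise ConfigError("no knockdown group has >= 2 cells")
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    return TargetScoreMatrix(mat.sort_index(), "perturbseq", standardized=False)
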