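"""Readers and writers for the tabular formats used across the pipeline.

All delimited files are tab-separated with a header row; identifiers are
opaque strings. Gene sets travel as standard GMT (name, description, then
members, one set per line). Reference protein-protein interactions are
two-column pair lists with an optional score column, canonicalized to
sorted unordered pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EmptyInputError, FormatError

logger = logging.getLogger("irimap")

MODALITIES = ("eclip", "bioid", "perturbseq")

DIFFERENTIAL_COLUMNS = ("rbp", "feature", "p_value", "log2fc")


# ---------------------------------------------------------------------------
# Differential tables
# ---------------------------------------------------------------------------

@dataclass
class DifferentialTable:
    """Per-modality differential statistics, one row per (RBP, feature).

    ``data`` holds columns ``rbp``, ``feature``, ``p_value`` in (0, 1] and a
    finite signed ``log2fc``. Duplicate (rbp, feature) keys are rejected.
    """

    data: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        missing = [c for c in DIFFERENTIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"differential table missing column(s): {', '.join(missing)}")
        df = self.data.loc[:, list(DIFFERENTIAL_COLUMNS)].reset_index(drop=True)
        p = df["p_value"].to_numpy(dtype=float)
        bad = np.flatnonzero(~((p > 0.0) & (p <= 1.0)))
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"p_value outside (0, 1] at row {i} "
                f"(rbp={df.at[i, 'rbp']!r}, feature={df.at[i, 'feature']!r}, p={p[i]!r})"
            )
        lfc = df["log2fc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lfc)):
            i = int(np.flatnonzero(~np.isfinite(lfc))[0])
            raise FormatError(f"non-finite log2fc at row {i} (rbp={df.at[i, 'rbp']!r})")
        if df.duplicated(subset=["rbp", "feature"]).any():
            dup = df[df.duplicated(subset=["rbp", "feature"])].iloc[0]
            raise FormatError(
                f"duplicate (rbp, feature) key: ({dup['rbp']!r}, {dup['feature']!r})"
            )
        self.data = df

    @property
    def rbps(self) -> list[str]:
        return sorted(self.data["rbp"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.data["feature"].unique())

    def __len__(self) -> int:
        return len(self.data)


def read_differential_table(path: str | Path, modality: str) -> DifferentialTable:
    """Read a tab-separated differential table; validates on construction."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty input file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"rbp": str, "feature": str})
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    table = DifferentialTable(df, modality)
    logger.info("read %d differential rows (%s) from %s", len(table), modality, path)
    return table


def write_differential_table(table: DifferentialTable, path: str | Path) -> None:
    out = table.data.sort_values(["rbp", "feature"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets within one namespace (e.g. BP/MF/CC-like)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    namespace: str = "default"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path, namespace: str = "default") -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members on a line are deduplicated; the description field is
    ignored for analysis but preserved for round-tripping.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has {len(fields)} field(s), expected >= 3")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: set {name!r} at line {lineno} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Reference interactions
# ---------------------------------------------------------------------------

def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferenceInteractions:
    """Unordered RBP pairs from an external gold-standard interaction list.

    Pairs are stored canonically sorted, without self-pairs or duplicates;
    ``scores`` carries the optional non-negative confidence per pair.
    """

    pairs: frozenset[tuple[str, str]]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise FormatError(f"self-pair in reference interactions: {a!r}")
            if a > b:
                raise FormatError(f"non-canonical pair order: ({a!r}, {b!r})")
        self.pairs = frozenset(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def restricted_to(self, rbps: Iterable[str]) -> "ReferenceInteractions":
        keep = set(rbps)
        pairs = frozenset(p for p in self.pairs if p[0] in keep and p[1] in keep)
        scores = {p: s for p, s in self.scores.items() if p in pairs}
        return ReferenceInteractions(pairs, scores)


def read_reference_interactions(path: str | Path, score_min: float = 0.0) -> ReferenceInteractions:
    """Read a pair list, dropping self-pairs (logged) and sub-threshold scores.

    Duplicate pairs (in either order) are merged keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two id columns")
    scored = df.shape[1] >= 3
    best: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            logger.warning("dropping self-pair %r in %s", a, path)
            continue
        score = float(row[2]) if scored else 0.0
        if score < 0:
            raise FormatError(f"{path}: negative score for pair ({a}, {b})")
        key = canonical_pair(a, b)
        best[key] = max(best.get(key, -np.inf), score)
    kept = {p: s for p, s in best.items() if s >= score_min}
    return ReferenceInteractions(frozenset(kept), kept if scored else {})


def write_reference_interactions(ref: ReferenceInteractions, path: str | Path) -> None:
    rows = []
    for a, b in sorted(ref.pairs):
        if ref.scores:
            rows.append((a, b, ref.scores.get((a, b), 0.0)))
        else:
            rows.append((a, b))
    cols = ["rbp_a", "rbp_b"] + (["score"] if ref.scores else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV with a stable float format."""
    df.to_csv(path, sep="\t", index=True, index_label="id", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide knobs: panel sizes, thresholds, permutation counts, seed.

    Defaults mirror the study conditions: panels of 120/50/68 RBPs with a
    two-modality union of 90, a 25% quantile threshold for significant pairs,
    5% FDR with log2FC > 0.5 for target calls, 10^4 map shuffles, and 10
    robustness repeats over the fraction grid.
    """

    seed: int = 0
    n_eclip: int = 120
    n_bioid: int = 50
    n_perturb: int = 68
    quantile: float = 0.25
    fdr_level: float = 0.05
    lfc_min: float = 0.5
    nes_min: float = 2.0
    n_shuffles: int = 10_000
    n_perm: int = 10_000
    n_modules: int = 6
    shuffle_fractions: tuple[float, ...] = (0.0, 0.05, 0.10, 0.25, 0.50, 0.75, 1.0)
    shuffle_repeats: int = 10

    def __post_init__(self) -> None:
        for name in ("n_eclip", "n_bioid", "n_perturb", "n_shuffles", "n_perm",
                     "n_modules", "shuffle_repeats"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("quantile", "fdr_level", "nes_min"):
            v = getattr(self, name)
            if not (0 < v) or (name != "nes_min" and not v < 1):
                raise ConfigError(f"{name} out of range: {v!r}")
        if any(not (0.0 <= f <= 1.0) for f in self.shuffle_fractions):
            raise ConfigError(f"shuffle_fractions must lie in [0, 1]: {self.shuffle_fractions!r}")
        self.shuffle_fractions = tuple(float(f) for f in self.shuffle_fractions)

    def derive_seed(self, stage: str) -> int:
        from ._seeds import derive_seed

        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "shuffle_fractions" in raw:
            raw["shuffle_fractions"] = tuple(raw["shuffle_fractions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["shuffle_fractions"] = list(self.shuffle_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
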