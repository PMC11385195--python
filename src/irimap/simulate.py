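"""Synthetic multimodal panels with planted ground truth.

The generator emulates the study's three-assay design over RNA-binding
proteins: an RNA-binding panel of 120 RBPs (binding scores per RNA), a
proximity-labeling panel of 50 RBPs nested inside it (enrichment per prey
protein), and a knockdown-screen panel of 68 RBPs also nested inside it,
sharing 28 RBPs with the proximity panel so that exactly 90 RBPs carry two
or more modalities. Regulatory structure is planted as disjoint modules:
RBPs of a module share a latent per-modality profile, mixed with private
noise as x = sqrt(rho) * profile + sqrt(1 - rho) * noise, so the expected
within-module cosine distance shrinks as the coherence rho grows. Each
module additionally receives a planted RNA regulon (strong positive binding
signal), a planted functional gene set among its proximity preys, and a
planted knockdown signature, giving every downstream stage recoverable
truth. Latent scores convert to (p, log2fc) pairs by treating the score as
a z-statistic, so the signed-significance transform downstream recovers a
monotone image of the latent geometry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed
from .errors import ConfigError
from .io import DifferentialTable, GeneSetCollection, ReferenceInteractions, canonical_pair

__all__ = [
    "SimParams",
    "PlantedTruth",
    "SingleCellSim",
    "plant_truth",
    "simulate_panel",
    "simulate_gene_sets",
    "rbp_annotation_sets",
    "reference_from_truth",
    "simulate_single_cell_counts",
    "simulate_guide_umi_table",
]

MODALITIES = ("eclip", "bioid", "perturbseq")


@dataclass
class SimParams:
    """Study-condition defaults for the synthetic panels.

    Panel sizes mirror the study (120 RNA-binding, 50 proximity, 68
    knockdown, 28 in both of the latter, union of multi-modality RBPs = 90).
    ``rho`` is the within-module profile correlation (coherence);
    ``noise_scale`` scales both shared and private latent components.
    Effect sizes are in z-units of the latent scores.
    """

    n_eclip: int = 120
    n_bioid: int = 50
    n_perturb: int = 68
    n_overlap: int = 28  # |bioid ∩ perturbseq|
    n_features: Mapping[str, int] = field(
        default_factory=lambda: {"eclip": 800, "bioid": 600, "perturbseq": 800}
    )
    n_modules: int = 6
    module_size: int = 8
    rho: float = 0.9
    noise_scale: float = 1.0
    regulon_size: int = 30
    regulon_effect: float = 6.0
    function_set_size: int = 25
    function_effect: float = 6.0
    signature_size: int = 30
    lfc_scale: float = 0.5
    n_decoy_sets: int = 6
    # single-cell arm
    cells_per_guide: int = 100
    control_cells: int = 100
    kd_log2fc: float = 1.0
    nb_dispersion: float = 0.3
    base_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigError(f"rho must lie in [0, 1], got {self.rho}")
        if self.noise_scale <= 0:
            raise ConfigError("noise_scale must be positive")
        if self.n_overlap > min(self.n_bioid, self.n_perturb):
            raise ConfigError("overlap exceeds a panel size")
        if self.n_union > self.n_eclip:
            raise ConfigError("bioid/perturbseq union exceeds the eclip panel")
        if self.n_modules * self.module_size > self.n_union:
            raise ConfigError(
                f"{self.n_modules} modules of size {self.module_size} exceed the "
                f"{self.n_union} multi-modality RBPs"
            )
        stride = self.n_union // self.module_size
        if self.n_modules > stride:
            raise ConfigError("module layout requires n_modules <= n_union // module_size")

    @property
    def n_union(self) -> int:
        """RBPs measured in >= 2 modalities (the mapped panel)."""
        return self.n_bioid + self.n_perturb - self.n_overlap


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    module_of: dict[str, int | None]
    modules: dict[int, tuple[str, ...]]
    regulons: dict[int, frozenset[str]]  # eclip feature space
    function_sets: dict[str, frozenset[str]]  # set name -> bioid features
    module_function: dict[int, str]
    signatures: dict[int, frozenset[str]]  # perturbseq feature space
    panels: dict[str, tuple[str, ...]]
    feature_ids: dict[str, tuple[str, ...]]
    true_pairs: frozenset[tuple[str, str]]

    def mapped_rbps(self, min_modalities: int = 2) -> list[str]:
        counts: dict[str, int] = {}
        for panel in self.panels.values():
            for rbp in panel:
                counts[rbp] = counts.get(rbp, 0) + 1
        return sorted(r for r, c in counts.items() if c >= min_modalities)

    def module_labels(self, rbps) -> np.ndarray:
        """Integer labels for ARI-style comparisons; background RBPs get 0."""
        return np.array([self.module_of.get(r) or 0 for r in rbps])


def plant_truth(params: SimParams) -> PlantedTruth:
    """Lay out panels, modules, regulons, function sets, and signatures.

    Deterministic given ``params.seed``. Modules are strided across the
    multi-modality union so every module spans all three panel regions
    (proximity-only, triple-overlap, knockdown-only).
    """
    rng = np.random.default_rng(derive_seed(params.seed, "truth"))
    width = max(3, len(str(params.n_eclip - 1)))
    rbps = tuple(f"RBP{i:0{width}d}" for i in range(params.n_eclip))
    bioid = rbps[: params.n_bioid]
    p_start = params.n_bioid - params.n_overlap
    perturb = rbps[p_start : p_start + params.n_perturb]
    panels = {"eclip": rbps, "bioid": bioid, "perturbseq": perturb}

    feature_ids = {
        m: tuple(f"{m[:3]}_f{j:04d}" for j in range(params.n_features[m]))
        for m in MODALITIES
    }

    n_union = params.n_union
    stride = n_union // params.module_size
    modules: dict[int, tuple[str, ...]] = {}
    module_of: dict[str, int | None] = {r: None for r in rbps}
    for m in range(1, params.n_modules + 1):
        idx = [(m - 1) + k * stride for k in range(params.module_size)]
        members = tuple(rbps[i] for i in idx)
        modules[m] = members
        for r in members:
            module_of[r] = m

    def sample_features(modality: str, size: int, taken: set[str]) -> frozenset[str]:
        pool = [f for f in feature_ids[modality] if f not in taken]
        chosen = rng.choice(len(pool), size=size, replace=False)
        picked = frozenset(pool[i] for i in chosen)
        taken |= picked
        return picked

    regulons, function_sets, module_function, signatures = {}, {}, {}, {}
    taken_e: set[str] = set()
    taken_b: set[str] = set()
    taken_p: set[str] = set()
    for m in range(1, params.n_modules + 1):
        regulons[m] = sample_features("eclip", params.regulon_size, taken_e)
        name = f"module{m:02d}_function"
        function_sets[name] = sample_features("bioid", params.function_set_size, taken_b)
        module_function[m] = name
        signatures[m] = sample_features("perturbseq", params.signature_size, taken_p)

    true_pairs = frozenset(
        canonical_pair(a, b)
        for members in modules.values()
        for a, b in itertools.combinations(members, 2)
    )
    return PlantedTruth(
        module_of, modules, regulons, function_sets, module_function,
        signatures, panels, feature_ids, true_pairs,
    )


def _latent_matrix(
    params: SimParams, truth: PlantedTruth, modality: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent target scores: sqrt(rho)*module_profile + sqrt(1-rho)*noise."""
    panel = truth.panels[modality]
    feats = truth.feature_ids[modality]
    n_feat = len(feats)
    feat_pos = {f: j for j, f in enumerate(feats)}

    planted = {"eclip": (truth.regulons, params.regulon_effect),
               "bioid": ({m: truth.function_sets[truth.module_function[m]]
                          for m in truth.modules}, params.function_effect),
               "perturbseq": (truth.signatures, params.function_effect)}
    effect_sets, effect = planted[modality]

    profiles = {}
    for m in truth.modules:
        g = rng.standard_normal(n_feat)
        boost = np.zeros(n_feat)
        boost[[feat_pos[f] for f in effect_sets[m] if f in feat_pos]] = effect
        profiles[m] = g + boost

    rows = np.empty((len(panel), n_feat))
    sq_rho, sq_noise = np.sqrt(params.rho), np.sqrt(1.0 - params.rho)
    for i, rbp in enumerate(panel):
        eps = rng.standard_normal(n_feat)
        m = truth.module_of[rbp]
        if m is None:
            rows[i] = eps
        else:
            rows[i] = sq_rho * profiles[m] + sq_noise * eps
    rows *= params.noise_scale
    return pd.DataFrame(rows, index=list(panel), columns=list(feats))


def _latent_to_differential(latent: pd.DataFrame, modality: str, lfc_scale: float) -> DifferentialTable:
    """Treat latent scores as z-statistics: p = two-sided normal tail, lfc ∝ z."""
    z = latent.to_numpy(dtype=float)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    lfc = lfc_scale * z
    long = pd.DataFrame({
        "rbp": np.repeat(latent.index.to_numpy(), latent.shape[1]),
        "feature": np.tile(latent.columns.to_numpy(), latent.shape[0]),
        "p_value": p.ravel(),
        "log2fc": lfc.ravel(),
    })
    return DifferentialTable(long, modality)


def simulate_panel(
    params: SimParams, truth: PlantedTruth | None = None
) -> tuple[dict[str, DifferentialTable], PlantedTruth]:
    """Generate the three per-modality differential tables plus planted truth.

    At rho = 1 with the shared profile dominating, within-module RBPs are
    colinear (cosine distance 0); at rho = 0 module membership is
    exchangeable with background.
    """
    if truth is None:
        truth = plant_truth(params)
    tables = {}
    for modality in MODALITIES:
        rng = np.random.default_rng(derive_seed(params.seed, f"panel:{modality}"))
        latent = _latent_matrix(params, truth, modality, rng)
        tables[modality] = _latent_to_differential(latent, modality, params.lfc_scale)
    return tables, truth


def simulate_gene_sets(
    truth: PlantedTruth,
    params: SimParams,
    namespace: str = "BP-like",
) -> GeneSetCollection:
    """Planted function sets plus size-matched decoy sets over the prey space.

    Decoys are sampled uniformly from the proximity-panel feature universe,
    so at default noise they should show no systematic enrichment for any
    RBP. An empty module list yields an empty collection.
    """
    if not truth.modules:
        return GeneSetCollection({}, namespace=namespace)
    rng = np.random.default_rng(derive_seed(params.seed, "gene_sets"))
    sets: dict[str, frozenset[str]] = dict(truth.function_sets)
    descriptions = {name: "planted module function" for name in sets}
    pool = np.array(truth.feature_ids["bioid"])
    sizes = itertools.cycle(sorted(len(s) for s in truth.function_sets.values()))
    for d in range(params.n_decoy_sets):
        size = next(sizes)
        name = f"decoy{d:02d}"
        sets[name] = frozenset(pool[rng.choice(pool.size, size=size, replace=False)])
        descriptions[name] = "size-matched decoy"
    return GeneSetCollection(sets, descriptions, namespace)


def rbp_annotation_sets(truth: PlantedTruth) -> GeneSetCollection:
    """Term -> RBP sets for label transfer: each module's function over its members."""
    sets = {
        truth.module_function[m]: frozenset(members)
        for m, members in truth.modules.items()
    }
    return GeneSetCollection(sets, namespace="rbp-functions") if sets else GeneSetCollection({}, namespace="rbp-functions")


def reference_from_truth(truth: PlantedTruth) -> ReferenceInteractions:
    """Planted within-module pairs as a gold-standard reference list."""
    return ReferenceInteractions(truth.true_pairs)


# ---------------------------------------------------------------------------
# Single-cell knockdown counts
# ---------------------------------------------------------------------------

@dataclass
class SingleCellSim:
    """Cell x gene counts with the cell -> guide truth and planted effects."""

    counts: pd.DataFrame
    cell_guides: dict[str, str]
    effect_genes: dict[str, frozenset[str]]
    control_label: str = "non-targeting"


def simulate_single_cell_counts(
    params: SimParams, truth: PlantedTruth | None = None
) -> SingleCellSim:
    """Negative-binomial counts for knockdown arms plus non-targeting controls.

    Guides target the knockdown-panel module RBPs; cells of a guide have the
    genes of that RBP's planted module signature shifted down by
    ``kd_log2fc`` log2 units (knockdown suppresses the genes the module
    sustains). Baseline means are log-normal around ``base_mean``;
    dispersion is the NB size parameter 1/``nb_dispersion``.
    """
    if params.control_cells <= 0:
        raise ConfigError("need at least one control cell")
    if truth is None:
        truth = plant_truth(params)
    rng = np.random.default_rng(derive_seed(params.seed, "single_cell"))
    genes = list(truth.feature_ids["perturbseq"])
    n_genes = len(genes)
    gene_pos = {g: j for j, g in enumerate(genes)}
    base = params.base_mean * np.exp(rng.normal(0.0, 0.8, size=n_genes))

    guides = [
        r for r in truth.panels["perturbseq"] if truth.module_of[r] is not None
    ]
    effect_genes = {
        r: truth.signatures[truth.module_of[r]] for r in guides
    }

    size = 1.0 / params.nb_dispersion

    def draw(mean_vec: np.ndarray, n_cells: int) -> np.ndarray:
        p = size / (size + mean_vec)
        return rng.negative_binomial(size, p, size=(n_cells, n_genes))

    blocks, barcodes, cell_guides = [], [], {}
    ctrl = draw(base, params.control_cells)
    for i in range(params.control_cells):
        bc = f"CTRL{i:05d}"
        barcodes.append(bc)
        cell_guides[bc] = "non-targeting"
    blocks.append(ctrl)
    for g_i, guide in enumerate(guides):
        mean_vec = base.copy()
        idx = [gene_pos[g] for g in effect_genes[guide]]
        mean_vec[idx] = mean_vec[idx] * 2.0 ** (-params.kd_log2fc)
        blocks.append(draw(mean_vec, params.cells_per_guide))
        for i in range(params.cells_per_guide):
            bc = f"KD{g_i:03d}C{i:04d}"
            barcodes.append(bc)
            cell_guides[bc] = guide
    counts = pd.DataFrame(np.vstack(blocks), index=barcodes, columns=genes)
    return SingleCellSim(counts, cell_guides, effect_genes)


# ---------------------------------------------------------------------------
# Guide/UMI read table
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _distinct_umis(rng: np.random.Generator, k: int, length: int, min_dist: int = 3) -> list[str]:
    """k UMIs pairwise at Hamming distance >= ``min_dist`` (rejection sampling).

    A gap of 3 guarantees that a 1-substitution sequencing error of one UMI
    can never sit within Hamming distance 1 of another UMI, so the injected
    duplicates collapse back onto their source unambiguously.
    """
    out: list[str] = []
    while len(out) < k:
        u = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(u, v)) >= min_dist for v in out):
            out.append(u)
    return out


def _mutate1(rng: np.random.Generator, umi: str) -> str:
    pos = int(rng.integers(0, len(umi)))
    alternatives = [b for b in "ACGT" if b != umi[pos]]
    return umi[:pos] + alternatives[int(rng.integers(0, 3))] + umi[pos + 1:]


def simulate_guide_umi_table(
    params: SimParams,
    n_clean: int = 30,
    n_low_umi: int = 5,
    n_ambiguous: int = 5,
    hamming_dup_rate: float = 0.3,
    umi_length: int = 8,
    barcode_length: int = 10,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Read-level (cell_barcode, umi, guide) rows with known assignment truth.

    Three cell classes are injected: clean cells (5-12 distinct UMIs, one
    guide, some UMIs duplicated at Hamming distance 1 which must collapse
    away), low-UMI cells (4 distinct UMIs, below the >= 5 rule), and
    ambiguous cells (10 UMIs split 8/2 between two guides -- exactly 80%,
    failing the strict > 80% consensus rule). Returns the rows and the
    expected cell -> guide (or None) assignment.
    """
    rng = np.random.default_rng(derive_seed(params.seed, "guide_umi"))
    guides = [f"guide_{g:02d}" for g in range(8)]
    rows = []
    expected: dict[str, str | None] = {}
    seen_barcodes: set[str] = set()

    def unique_barcode() -> str:
        while True:
            bc = _random_seq(rng, barcode_length)
            if bc not in seen_barcodes:
                seen_barcodes.add(bc)
                return bc

    for _ in range(n_clean):
        bc = unique_barcode()
        guide = guides[int(rng.integers(0, len(guides)))]
        n_umis = int(rng.integers(5, 13))
        umis = _distinct_umis(rng, n_umis, umi_length)
        for u in umis:
            for _ in range(int(rng.integers(1, 4))):
                rows.append((bc, u, guide))
            if rng.random() < hamming_dup_rate:
                rows.append((bc, _mutate1(rng, u), guide))
        expected[bc] = guide

    for _ in range(n_low_umi):
        bc = unique_barcode()
        guide = guides[int(rng.integers(0, len(guides)))]
        for u in _distinct_umis(rng, 4, umi_length):
            rows.append((bc, u, guide))
        expected[bc] = None

    for _ in range(n_ambiguous):
        bc = unique_barcode()
        g1, g2 = rng.choice(len(guides), size=2, replace=False)
        umis = _distinct_umis(rng, 10, umi_length)
        for u in umis[:8]:
            rows.append((bc, u, guides[g1]))
        for u in umis[8:]:
            rows.append((bc, u, guides[g2]))
        expected[bc] = None

    df = pd.DataFrame(rows, columns=["cell_barcode", "umi", "guide"])
    df = df.sample(frac=1.0, random_state=int(derive_seed(params.seed, "guide_umi_order")) % 2**32)
    return df.reset_index(drop=True), expected
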