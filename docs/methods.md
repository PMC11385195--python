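# Methods

## The model

`irimap` treats each assay modality as producing, per RBP, a vector of
differential statistics over that modality's feature space (RNAs bound,
prey proteins enriched, genes perturbed downstream). The working
hypothesis is geometric: RBPs that act in the same regulatory module have
correlated profiles in every modality that measures them, so their
standardized score vectors lie close in cosine distance. Because the three
feature spaces are incommensurable, distances are never compared across
modalities directly; instead each modality's N pairwise distances are
reduced to ranks and converted to empirical left-tailed p-values
p = r/(N+1) (average rank on ties). This rank convention deliberately
replaces the literal "fraction of pairs closer than the tested pair",
which would assign p = 0 to the closest pair and p ≥ 1/N to nothing
beyond the open unit interval that the logit combiner requires; it
preserves the ordering exactly and is invariant under any strictly
monotone transform of the distances.

Per pair, the modality p-values are combined with the logit
(Mudholkar–George) method: T = −Σ ln(pᵢ/(1−pᵢ)) referred to a Student t
with 5k+4 degrees of freedom after scaling by
C = √(k·π²·(5k+2)/(3·(5k+4))). The t reference is an approximation to the
sum-of-logistics null; at (0.01, 0.01, 0.01) its tail value is 8.9·10⁻⁵
against an exact convolution value of 7.6·10⁻⁵, i.e. accurate to well
under one order of magnitude deep in the tail and essentially exact in
the bulk. The combined value itself is used as the "integrated distance";
no further transform is applied, since smaller = closer is all the
downstream stages need.

### Map membership and per-pair k

An RBP enters the integrated map when it is measured in at least
`min_modalities` (default 2) panels; every pair of qualifying RBPs is
combined over exactly the modalities in which both members were measured,
and that count k ∈ {1, 2, 3} is recorded per pair. Under the default panel
geometry — proximity and knockdown panels nested inside the RNA-binding
panel, overlapping each other in 28 RBPs — the 90 qualifying RBPs form
4005 pairs, of which 880 (proximity-only × knockdown-only) are covered by
the RNA-binding modality alone. The alternative rule, dropping every pair
not co-measured in ≥2 modalities, would shrink the map to 3125 pairs and
break the n(n−1)/2 bookkeeping that the rest of the workflow (quantile
thresholding, mean degree) relies on; k is reported so users can filter
to k ≥ 2 if they prefer the stricter universe.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `quantile` | 0.25 | significance threshold on map values (Hyndman–Fan type 7 interpolation; pairs strictly below pass) |
| `fdr_level`, `lfc_min` | 0.05, 0.5 | per-RBP BH level and log2FC floor for target calls |
| `min_umis`, `consensus_frac` | 5, 0.8 | guide assignment: ≥5 distinct UMIs, strictly >80% consensus |
| `nes_min` | 2.0 | NES floor for the annotation heatmap; negative NES clamped to 0 |
| `n_shuffles` | 10⁴ | map shuffles for the overlap permutation test; p = (x+1)/(n+1) |
| `shuffle_fractions` | 0–1 grid | robustness: fraction of columns permuted; 10 repeats × n RBPs estimates per fraction |
| fuzzifier m, tol, max_iter | 2, 1e−6, 300 | fuzzy c-means; centroids initialized from distinct sampled rows |

Z-scoring uses the population SD across RBPs and maps constant columns to
zero. The two-group scorer is Welch's t (unequal variances), the safer
default for unequal arm sizes. BH adjustment always runs within the
natural family: per RBP across features (target calls), per RBP across
RNA types, per RBP across gene sets, across references for overlap tests.

## Numerical choices and degenerate inputs

- Cosine distance of an all-zero standardized row is defined as 1 to every
  other RBP (orthogonality convention) rather than dropping the RBP; the
  case is logged.
- Quantile thresholding takes pairs *strictly* below the interpolated
  threshold, so with (N−1)·q integral exactly ⌊qN⌋ distinct values pass
  (1001 of 4005 at q = 0.25); an all-tied map passes nothing.
- Hamming-1 UMI collapse is a greedy merge into the higher-count UMI, ties
  broken lexicographically, absorbed UMIs do not chain; the result is
  independent of row order.
- The permutation null for reference overlap permutes the pair→value
  assignment, preserving the value multiset and hence the passing count
  exactly; the empirical p uses the (x+1)/(n+1) convention and can never
  be 0.
- GSEA permutations sample random feature sets of matched size
  (gene-sampling); phenotype permutation is impossible with one profile
  per RBP. NES normalizes by the mean |ES| of same-sign nulls; with no
  same-sign null the NES is an explicit undefined marker, never 0. Null ES
  distributions are cached per set size within one ranked list.
- A constant score profile is rejected for ranking; a gene set with no
  overlap returns an undefined marker rather than ES = 0.
- Robustness shuffling permutes entries within selected columns and leaves
  the matrix asymmetric (no re-symmetrization); displacement is the cosine
  distance between original and perturbed column vectors, and min/median/
  max of perturbed partner distances are emitted alongside.

## The synthetic generator

`simulate_panel` plants M disjoint modules (default 6 × 8 RBPs) across the
multi-modality union, strided so every module spans the three panel
regions. Within a module, each member's latent profile is
√ρ·g_m + √(1−ρ)·ε with shared g_m and private ε (standard normal), so ρ is
exactly the within-module profile correlation and the expected
within-module cosine distance decreases monotonically in ρ; background
RBPs are pure noise. Planted structure rides on the shared profile: the
module's regulon (RNA features), function set (prey features), and
knockdown signature (gene features) receive a +6 z-unit offset in g_m.
Latent scores convert to (p, log2FC) by treating the score as a
z-statistic — p is the two-sided normal tail, log2FC = z/2 — which makes
the downstream signed-significance transform a monotone image of the
latent geometry.

Defaults mirror the study conditions: panels of 120/50/68 RBPs with a
28-RBP overlap (union 90), ρ = 0.9, unit noise scale, and feature spaces
of 800/600/800. Feature-space sizes, effect sizes, and noise are not
published quantities; they were fixed once by pilot simulation to the
values above — large enough that per-RBP BH target calling and NES > 2
annotation behave as in real data, small enough that the full pipeline
runs in seconds. The single-cell arm draws negative-binomial counts
(dispersion 0.3, log-normal baseline means around 20) with 100 cells per
arm and a 2-fold knockdown on signature genes; the guide/UMI table
injects Hamming-1 duplicates, sub-threshold (4-UMI) cells, and exactly-80%
consensus cells with known expected outcomes.

What the generator does *not* emulate: batch structure and normalization
artifacts, correlated (rather than independent) noise across features,
overlapping/nested modules, dropout and library-size variation in the
single-cell counts beyond the NB model, and real gene-set redundancy.
Passing tests therefore demonstrate that the statistical machinery is
implemented correctly and recovers planted structure under its own model
assumptions — not that the pipeline is robust to every artifact of real
multi-omic data.

## Scale of the shipped checks

The test suite and the acceptance script run the full geometry
(120/50/68 RBPs, 4005-pair map) for the bookkeeping and recovery checks,
reduced panels (24/10/12 RBPs) for replicated latent-geometry checks, 500
permutations per replicate for null-calibration checks (200 replicates),
10⁶ draws for the Monte-Carlo combination oracle, and 10³–10⁴
permutations for GSEA/overlap significance. These sizes are the package's
own verification budget; all thresholds (ARI ≥ 0.9, ≥80% sensitivity,
top-3 NES) were calibrated on pilot runs with seeds independent of the
shipped test seeds.

## Known limitations

- The rank-based empirical p-values make map values uniform *within* a
  modality by construction; the combined value is therefore a relative,
  not absolute, probability of interaction.
- With k varying per pair, combined values for k = 1 pairs are
  systematically less extreme than for k = 3 pairs; thresholding treats
  them on one scale, as the original workflow does.
- Ward linkage on cosine distances is a heuristic embedding of a
  probability matrix; module boundaries depend on the requested module
  count, which is a user parameter, not an inferred quantity.
- The NES normalization follows the gene-sampling scheme; it is a
  reimplementation validated on planted truth, not a numerical clone of
  any particular enrichment tool.
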