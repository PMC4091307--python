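# Methods

This note documents the models, parameters, and numerical choices behind
crequant, and what its synthetic validation does and does not demonstrate.

## The toy atlas

The reference atlas is a three-level ontology — a root, 12 major divisions
(acronyms Iso, OLF, HPF, CTsp, STR, PAL, TH, HY, MB, P, MY, CB), and a
configurable number of leaf structures per division (default 4, giving 48
leaves) — plus a 3D voxel-label volume. The mid-level partition used for all
quantification defaults to the division children (here the leaves), an
antichain whose leaf sets disjointly tile the brain; any valid antichain can
be designated instead, and `midlevel_partition` verifies the
disjoint-cover property by ancestor walk, naming the offending leaf on
failure.

Default geometry: 48 × 48 × 496 voxels at 25 µm (x = medio-lateral,
y = dorso-ventral, z = rostro-caudal), with a 8-voxel (200 µm) background
margin on every face — a 0.8 × 0.8 × 12 mm brain. Divisions are 1-mm
rostro-caudal slabs; leaves are 200-µm dorso-ventral blocks within each
slab. Two properties are deliberate:

- **Grid alignment.** Every structure boundary falls on a multiple of
  200 µm, so the default 200-µm analysis grid tiles structures exactly and
  per-structure energies have analytic ground truth. Real atlas borders do
  not align with grids; setting `jitter_voxels > 0` randomizes boundaries
  to study grid cells that straddle borders (grid-center assignment then
  attributes a straddling cell entirely to the structure under its center,
  the same coarseness the 200-µm unionization has on real data).
- **Realistic serial sampling.** The 12-mm rostro-caudal extent sampled
  every 200 µm yields ~60 sections, 5 per division slab, comparable to a
  real whole-brain series. Short toy brains (one slab per division) leave
  each structure's energy resting on a single 25-µm slab and Poisson
  sampling noise dominates rank recovery.

Voxel indexing is 0-based and every interval (voxels, grids, slabs) is
half-open `[lo, hi)`, so tilings never double-count.

## Synthetic histology

**Ground truth.** A line's ground truth is a density λ_s (expressing cells
per mm³) per mid-level structure. Pattern categories translate to densities
via multipliers of a base density λ0 (default 5000 cells/mm³): widespread
1.0, scattered 0.3, sparse 0.05 across a whole division; restricted 1.0 and
restricted-but-sparse 0.1 in a single structure; enriched 1.0 in the target
with 0.2 in its division siblings. The multipliers encode the qualitative
density ordering of the six visual pattern classes; no quantitative values
exist for them, so they are documented configuration, not estimates.

**Faithfulness modes for gene/Cre pairs.** Mode 1 copies the gene's
densities. Mode 2 adds ectopic structures drawn uniformly from
zero-density structures (default: half as many as the expressed set, at
their mean density). Mode 3 silences a random half of the expressed
structures, always keeping at least one. The 0.5 fractions are a design
choice: unfaithful lines in practice can gain or lose substantial parts of
their pattern, and smaller fractions make the categories statistically hard
to separate in small simulated cohorts.

**Cells and rendering.** Cell counts per structure are
Poisson(λ_s · V_s) with positions uniform in the structure's voxels and
per-cell amplitudes Normal(150, 20) clipped to [0, 255]. A section at
position p with thickness t (default 25 µm) renders every cell whose
sectioning-axis coordinate lies within p ± t/2 as an isotropic Gaussian
blob (σ = 10 µm) added onto a tissue background of mean b0 = 20 with
Gaussian texture σb = 5, on 10-µm pixels; out-of-tissue pixels are 0 and
intensities are rounded and clipped to 8-bit. Series sample every 200 µm
(coronal = fixed z, sagittal = fixed x, one hemisphere, no midline
mirroring), the first slab flush with the volume face, giving
`floor((extent − t)/spacing) + 1` sections. Images store *signal* intensity
(higher = more ISH product); real colorimetric scans are dark-on-light and
a loader for them would invert.

What the generator does **not** emulate: optical PSF and focus variation,
staining artifacts, tissue tears and folds, slide-level white balance,
registration error (section transforms are exact by construction), and any
cell morphology beyond a Gaussian blob. Passing tests therefore validate
the informatics — segmentation arithmetic, gridding, unionization,
statistics — under known truth; they do not certify detector performance
on real chromogenic ISH, where the upstream preprocessing and deformable
registration live.

## Segmentation

Per section, background level b is the median of in-tissue intensities and
spread s is 1.4826 × MAD (the SD-equivalent scaling). A pixel is expressing
iff it is in tissue and strictly above b + k · max(s, s_min), defaults
k = 3, s_min = 2 intensity units. The floor keeps the threshold meaningful
on noise-free images where the MAD collapses to zero. The mask is a pure
pointwise function: idempotent, monotone in k (raising k never adds
pixels), with no morphological cleanup.

Known limitation: the median background assumes expression occupies less
than half of a section's tissue. Sections where dense blobs cover the
majority of tissue inflate b and the threshold, suppressing detection —
visible in simulations above roughly 3 × 10⁴ cells/mm³ over whole
divisions. Background is estimated per section (not per series) to mirror
slide-level variation.

## Quantification

Grids are 200 µm (a positive integer multiple of the pixel size is
required; there is no resampling), tiled from the image origin with
half-open intervals; boundary cells may be partial and cells without tissue
are dropped. Each cell's center is mapped through the section's affine
transform to an atlas voxel and takes that voxel's mid-level structure
(grid-center lookup, one assignment per grid; centers outside the brain or
volume give an unassigned cell, excluded downstream).

Expression energy per structure is the pooled ratio
Σ detected intensity / Σ in-tissue pixels over the structure's assigned
grids; the denominator counts all tissue pixels of those grids, detected or
not, and never out-of-tissue pixels. Whole-brain energy pools the same sums
over all assigned grids, so it equals the pixel-weighted mean of structure
energies exactly. Division summaries pool the same raw sums per division,
keeping them consistent with the per-structure formula under unequal pixel
counts.

Structures sampled by no grid are reported **missing**, never zero:
serial sampling can miss small structures entirely, and conflating absence
of measurement with absence of expression would bias rank correlations.
Missing values propagate through correlations (pairwise structure drop) and
fold changes (missing F with a recorded reason).

## Analysis

- **Spearman ρ** uses average ranks for ties and demands ≥ 3 complete pairs
  and nonzero rank variance on both sides; degenerate inputs raise instead
  of silently returning 0.
- **Line correlation** averages ρ over all plane-matched cross pairs of
  replicates (sagittal with sagittal, coronal with coronal; no matched pair
  is an error). Averaging pairwise ρ — not correlating averaged profiles —
  matches how replicate-averaged coefficients are defined with 1–6
  replicates per dataset. Both the signed mean ρ and the mean ρ² are
  reported; ordering and binning use the signed mean.
- **Replicate baseline** is the mean over lines of the within-line mean
  pairwise replicate ρ; each line counts once regardless of replicate
  count.
- **Quartile bins** (high / mid / low / very-low) use inclusive
  linear-interpolation quartiles with boundary ties assigned upward (a
  value equal to Q3 is `high`); fewer than 4 lines are `unbinned`.
- **Fold change** F = E_s / W applies no expression floor, so a structure
  with trivially small energy can top a ranking — rankings should be read
  alongside absolute energy. Missing energies and W = 0 give missing F with
  a reason. Line ranking within a structure is descending F, missing last,
  ties broken lexically by line id.
- **Group comparison** is a two-tailed t-test: one-sample t on differences
  when paired, Welch's unequal-variance t otherwise (the safer default when
  group variances are unknown; switchable in principle to pooled t).
  Zero-variance data with equal means return t = 0, p = 1. No
  multiple-testing correction is applied anywhere.

## Pipeline reproducibility

A run is one `RunConfig` (YAML or JSON): atlas spec, line roster (pattern
assignments, faithfulness, 1–6 replicates, plane), segmentation and grid
parameters, and a single seed. Every stochastic stage derives its seed by
SHA-256 hashing of (seed, stage, line, probe, replicate), so replicates
differ while reruns are byte-identical; the manifest records SHA-256
checksums of every output table. Replicate counts outside 1–6 are rejected
at validation.

## Validation experiments and problem sizes

The experiments in `crequant.experiments` (also run by
`scripts/acceptance.py`) use sizes chosen to keep each run in seconds on
one CPU while leaving clear statistical margins:

- **Recovery**: one noiseless series over the default 48-structure atlas,
  densities logspace(10¹, 10⁴) cells/mm³ — three orders of magnitude
  bracketing λ0, with the top end inside the detector's operating regime
  (see segmentation limitation above). Recovered energy vs true density
  gives Spearman ρ ≈ 0.93 at seed 0; residual rank noise is Poisson
  sampling at the sparse end, where a structure's sections contain zero or
  one cell.
- **Conservation**: one noisy series; unionization residuals are exactly 0.
- **Enrichment**: 20 cohorts of 4 single-structure-restricted lines; the
  designed line ranks first by fold change in 100% of cohorts both
  noiseless and at default noise.
- **Faithfulness**: 10 gene/reporter pairs per category, 2 replicates per
  dataset at default noise. Mean ρ ordering is faithful > ectopic > subset
  (≈ 0.65 > 0.52 > 0.36 at seed 0) with the faithful mean within 0.01 of
  the replicate baseline (≈ 0.65). The baseline sits well below 1 because
  rank correlations over ~48 structures are dominated by noise-ranked
  non-expressing structures — the same reason replicate correlations of
  real whole-brain energy profiles are far from perfect.

These simulated cohorts share the generator's idealizations listed above;
none of the numbers is claimed to reproduce statistics measured on real
image datasets.
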