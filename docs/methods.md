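# Methods

## The social-space statistic

A settled group of flies in a triangular chamber is summarized by the
number of *other* flies within a counting radius of each focal fly; the
replicate (chamber) value is the mean of the per-fly counts. The radius
defaults to four body lengths with the adult body length fixed at
2.5 mm, i.e. 10 mm. The boundary is inclusive (`d ≤ r`): for continuous
coordinates ties are measure-zero, and inclusivity makes the statistic
deterministic on gridded test fixtures. Counts are computed from the
full Euclidean distance matrix (`scipy.spatial.distance.pdist`), and an
independent O(n²) double-loop oracle in the test suite checks exact
equality on hundreds of random configurations.

No edge correction is applied for flies near walls. This is a known
bias of the assay as practiced — the statistic is compared between
conditions measured in identical chambers, where the bias cancels — and
the tool deliberately reproduces it. Chambers with fewer than 12 or
more than 17 flies are analyzed but flagged with a warning: within that
range the statistic is insensitive to density, outside it the density
dependence is not calibrated. Replicates below the range are computed
rather than dropped, since escapes during loading are routine and the
decision to exclude belongs to the analyst.

## Arena geometry

The chamber is a triangle in mm with a wall-exclusion margin: flies
avoid walls, so all point operations act on the inner parallel body of
the triangle at distance `margin` (default 2 mm) from each edge. For a
triangle this inner body is computed exactly as the homothety of the
triangle about its incenter with ratio `(r − margin)/r`, `r` the
inradius — no polygon buffering approximations. Containment tests are
vectorised half-plane checks against the CCW edges with a small
distance-scaled tolerance. The default chamber is equilateral with
80 mm sides (area ≈ 2771 mm², eroded ≈ 2312 mm²), which comfortably
seats 16 flies at the default hardcore separation.

## The synthetic point process

No distributional model for settled fly positions is established in the
literature, so the generator uses a transparent statistical stand-in
rather than a behavioral model: a fixed-n pairwise-interaction Gibbs
process with unnormalised density

    f(x₁…xₙ) ∝ exp( β · Σ_{i<j} K(d_ij) ) · 1[all d_ij ≥ h] · 1[all xᵢ ∈ A]

where `K(d) = exp(−(d − d₀)²/2w²)` is a Gaussian bump centred at a
preferred inter-fly distance `d₀` (default 5 mm) with width `w`
(default 2 mm), `h` is a hardcore body-exclusion radius (default 2 mm)
and `β ≥ 0` (`attraction_strength`) controls clustering. `β = 0` is
complete spatial randomness given the hardcore; raising β plants a
monotone increase in the within-4BL count, standing in for
genotype/housing contrasts. Group size is fixed at n = 16 because the
experimenter fixes it; a birth–death process would be the wrong model.

Sampling: uniform triangle points via the barycentric fold rule (two
uniforms, folded when u+v > 1 — exact, no rejection); the hardcore
constraint by dart throwing with a cap of 10 000 retries per point and
an up-front densest-packing feasibility bound (≈90.7% coverage);
the interacting process by fixed-n Metropolis started from a CSR draw,
one sweep = n single-point Gaussian proposals with step sd `d₀/2`,
hard constraints enforced by rejection. Only the energy terms of the
moved point are recomputed per proposal. The returned configuration
carries overall and last-sweep acceptance rates; a sweep acceptance
below 1% emits a tuning warning. Default 50 sweeps; the heavy simulation
tests use 15–20 sweeps, which the zero-potential KS test and the
monotonicity grid show is enough burn-in at these parameter scales. All
samplers take integer seeds (or spawned `SeedSequence` children) and are
bit-reproducible.

## Image rendering and the detection pipeline

Rendered photographs place one filled ellipse per fly (major axis = one
body length, default aspect 0.35) at uniform random orientation on a
light background (fly 0.15, background 0.85 in [0,1]) with the arena
border traced and additive Gaussian pixel noise (default sd 0.03),
written as 8-bit grayscale. The default scale is 10 px/mm so a body is
25 px long. Pixel convention: 0-based, origin top-left, y down; every
mm↔px conversion goes through a single affine transform object. Ground
truth records each fly's pixel/mm centroid, orientation, and a
`touching` flag computed from actual rendered-mask adjacency (overlap or
8-adjacency), which marks the segmentation-hard cases.

Detection is global threshold (Otsu by default, with a half-histogram-bin
nudge so two-valued noiseless images binarise correctly; fixed threshold
optional; polarity configurable) → 8-connected components inside an
arena-interior mask polygon (excluding the drawn border) → area filter
(defaults 40–5000 px²) → optional splitting of merged blobs. A component
larger than 1.6× the median component area is treated as merged flies
and divided by a distance-transform watershed whose seeds are the top
`round(area/median-area)` local distance maxima; pieces smaller than
`min_area` are rejected and the blob kept whole if splitting fails. The
1.6 factor splits genuinely merged pairs but leaves elongated single
flies alone; capping the seed count prevents the ridge of a thin ellipse
from over-seeding. Centroids, axis lengths and orientations come from
binary region moments (`skimage.measure.regionprops`).

Calibration to mm uses an explicit px/mm scale when known (the
synthetic pipeline knows its render scale) or, for real photographs
without a ruler, sets the scale so that the median major-axis length of
unsplit detections equals 2.5 mm. Split halves are excluded from the
body-length estimate because watershed pieces are foreshortened.
Whether the original chamber analyses used a fixed 1 cm radius or a
per-image body-length radius is ambiguous in practice; both are
supported and fixed-radius (10 mm) is the default.

On the default preset, 100 seeded scenes round-trip with exact count
recovery and every matched centroid within 2 px (greedy one-to-one
nearest-pair matching, 5 px gate); the test suite asserts ≥ 95% within
2 px.

## Assay indices

- **Aggregation index** = sample variance (n−1 denominator) of
  per-compartment counts divided by their mean. The n−1 choice is fixed
  by the index's defining worked example: 16 flies in one of 8
  compartments must give variance 32 (population variance would give
  28) and hence index 16. Bounds are recomputed from `n_flies` and
  `n_compartments` rather than hard-coded, so non-standard chambers are
  handled.
- **Performance index** = `(n_air − n_dso)/n_total`. The denominator is
  all loaded responders including non-choosers, which shrinks |PI| when
  flies abstain; antisymmetric under vial swap.
- **Climbing percent** = `100·n_top/n_total`.
- **Aggression duration** sums each scored event's duration across both
  flies; simultaneous events both count (the measure is displayed
  behavior, not occupied wall-clock time). Filter labels outside the
  ethogram and absent from the log trigger a warning listing the known
  behaviors. Event logs are read in a minimal BORIS-style dialect
  (behavior/subject/start/stop columns, case-insensitive).
- **Activity summary** = total and per-minute mean of a 30-minute
  beam-crossing record; one fly is one replicate.

## Group comparison

Each factor-combination cell is Shapiro–Wilk tested at α = 0.05; any
rejection — or any cell that is constant or has fewer than three
values — routes the analysis to Kruskal–Wallis (tie-corrected) with
Dunn's pairwise z post hoc under Holm adjustment; otherwise a full
factorial ANOVA (1–3 factors, all interactions) with Type II sums of
squares is fitted, which handles the mildly unbalanced replicate counts
that real assay batches produce. Shapiro–Wilk is the standard small-n
normality test; Holm is uniformly more powerful than Bonferroni at the
same family-wise error control. Welch's t (Satterthwaite df) is
provided for two-group unequal-variance contrasts. ANOVA estimation is
delegated to statsmodels and elementary tests to scipy; Dunn's test is
implemented here (no installed library provides it) and cross-checked
against the exact two-group Kruskal–Wallis ↔ Mann–Whitney equivalence.
Degenerate inputs are defined, not exceptional: identical observations
give H = 0, p = 1; a design with empty cells or zero residual df raises
an error naming the inestimable interaction.

Calibration (asserted in the suite): the full gated procedure holds its
size at 0.05 ± 0.015 under three-group Gaussian nulls over 2 000
simulations, and a planted pure-interaction pattern of ±1 sd in a 2×2
design with 6 replicates per cell and unit noise (noncentrality 24) is
detected with power well above 0.8 — through the interaction term when
the gate selects ANOVA, through the omnibus rank test on the crossed
groups when it does not.

## Pipeline and reproducibility

`run_pipeline` executes the configured stages (points, images, detect,
socialspace, compare) in order, persisting every intermediate as
delimited text or PNG, and writes a manifest with the package version,
seed, a SHA-256 of the canonical configuration and per-stage output
hashes. Per-chamber seeds are spawned from the global seed via
`numpy.random.SeedSequence`, so a fixed configuration and seed reproduce
every artifact byte-for-byte. Configuration problems are reported by
`validate_config` as a diagnostics list (missing seed with stochastic
stages, unknown stages, inestimable designs, conflicting radius
options) before anything runs.

## Simulation sizes and known limitations

Distributional test sizes: 500 draws per level for the zero-potential
equivalence (KS, α = 0.01) and the attraction-monotonicity grid
{0, 1, 2, 5}; 10 000 draws for the CSR closed form (midpoint-rule
numeric integration of the disc∩triangle area on a 1 mm grid with
exactly clipped cells as the oracle); 2 000/400 simulations for
statistical size/power; 100 seeded runs for end-to-end effect-direction
recovery (9 chambers per condition, attraction 0 vs 5, 20 sweeps).

The synthetic layer emulates the *geometry* of settled groups, planted
clustering, and counting noise in the tabular assays. It does not
emulate behavioral dynamics over time, wall-following (beyond the
margin), body-size variation between flies, lighting gradients or
vignetting in photographs, or correlated non-choice in the binary
assays. Passing tests therefore demonstrate that the measurement
chain — detection, indices, statistics — is correct and calibrated
under known ground truth, not that the pair-potential is a model of fly
behavior. Real photographs with uneven illumination may need a fixed
threshold or preprocessing before segmentation; heavily overlapping
groups (more than ~2 flies per merged blob) can defeat the watershed
seed heuristic.
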