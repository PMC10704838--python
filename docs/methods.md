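# Methods

Quantitative conventions, model assumptions and numerical choices of the
`capimorph` package. Units are micrometres (µm) for tissue scenes and
nanometres (nm) for TEM contours unless stated otherwise.

## 1. Synthetic tissue model

### 1.1 Fiber mosaic

A muscle cross-section is modelled as a Voronoi mosaic: points are laid on a
jittered hexagonal lattice (jitter SD 0.28 of the spacing) and relaxed with
one Lloyd iteration; boundary-clipped cells are dropped. The lattice spacing
is chosen so that the *post-atrophy* mean cell area matches the configured
mean cross-sectional fiber area (MCSFA): the base cell area is
`mcsfa / w` with `w = p1 + p2a + p2b·(f·k + (1 − f))`, where `p·` are the
fiber-type proportions, `k` the type-2b atrophy area factor and `f` the
fraction of type-2b fibers it applies to.

Lloyd robustness: Qhull occasionally reports nominally finite border regions
with vertices at extreme coordinates; accepting such a centroid would fling a
point far outside the scene and degrade the next Voronoi's merge tolerance.
Updates that are non-finite or move a point by more than one lattice spacing
(which a valid relaxation step never does) are rejected.

Fiber types `1`, `2a`, `2b` are assigned i.i.d. with configured proportions.
Type-2b atrophy shrinks a configured *fraction* of 2b fibers about their
centroids by √k in linear scale (area factor k). Applying the factor to all
2b fibers instead would shift the whole 2b area distribution and make any
same-type-median atrophy detector blind by construction; the fraction is
therefore a first-class parameter (`type2b_atrophy_fraction`).

### 1.2 Capillaries and immune cells

Capillary profiles are points placed without replacement on fiber-junction
vertices (Voronoi vertices adjacent to at least one retained fiber), matching
the anatomical position of capillaries between fibers. The number placed is
`round(cf_true × n_fibers)`; requesting more capillaries than available
junctions raises an error naming the infeasible `cf_true`. Immune-cell
marker points (CD68, CD169, CD206, CD45, CD8) are scattered uniformly with
negative-binomial-like per-sample dispersion of the totals.

Known inhomogeneity: junction-per-fiber density is elevated near the mosaic
border, so a scene's guarded core can differ from its global capillary
census by a few percent. Estimator unbiasedness is therefore asserted on
spatially homogeneous (periodic) scenes in the tests, and generator-level
recovery on the *group difference* across many seeded runs, where shared
placement effects cancel.

### 1.3 TEM capillary profiles

A TEM profile is three nested closed contours in nm — lumen,
abluminal endothelial surface, and outer basement-membrane boundary — plus
pericyte arcs (angle intervals on the abluminal surface) and the generating
per-vertex capillary basement membrane (CBM) thickness field. The CBM field
is a smooth periodic harmonic series with configured mean and SD. Oblique
sectioning is emulated by an area-preserving affine stretch
`diag(√o, 1/√o)` plus a random rotation, so a caliper (Feret) aspect-ratio
measurement on the outer contour recovers the stretch `o`.

Per-sample CBM means are drawn as `max(50, N(cbm_mean, 0.8·cbm_sd))` with
within-profile SD `0.6·cbm_sd`, giving realistic between- and within-sample
variance components. The model has **no additional between-subject random
effect** beyond these draws; group-level variances are therefore somewhat
tighter than in real biopsy material.

### 1.4 Seeding

All randomness flows from the spec seed through per-sample substreams:
`SeedSequence([seed, sha256(sample_id)[:4]])`. Analysis-side randomness
(FOV placement, CBM site rotation) uses a separate stream derived from
`seed + 1_000_003`, so measuring a cohort never perturbs its generation.

## 2. Stereology

### 2.1 Counting frame and forbidden line

The unbiased counting frame counts a profile iff it intersects the closed
frame rectangle *and* does not touch the forbidden line — the left and
bottom edges extended: a polyline from `(x0, y1 + L)` down the left edge,
along the bottom edge, and down past the bottom-right corner to
`(x1, y0 − L)` with a large extension `L`. Touching is decided with a
symmetric tolerance of `1e-9` on shapely distances. Consequences, covered
exactly by tests: profiles tangent to the top or right edge are counted;
tangent to the left or bottom edge, the top-left corner, or either
extension are excluded; a tiling of frames counts every profile exactly
once.

### 2.2 Estimators

Per field of view (FOV), a square point grid (default 10 × 10, points at
subcell centres) yields `p_fiber / p_total`; the frame yields fiber- and
capillary-profile counts. Then

- `MCSFA = (p_fiber / p_total) · grid_area / n_fiber_profiles` (µm²),
- `capillary density = n_capillary_profiles / grid_area · 10⁶` (mm⁻²),
- `C/F = n_capillary_profiles / n_fiber_profiles`,

and the identity `density(mm⁻²) · MCSFA(mm²) = C/F` holds to machine
precision (asserted at 1e-9 in `estimate_all`). Sample-level aggregation
pools raw counts (ratio of sums), not per-FOV ratios.

### 2.3 Guard margin

Frame counts of extended profiles are exactly unbiased only if every frame
sees a fully populated neighbourhood. The mosaic border has a depopulated
band (clipped cells are dropped), so the pipeline samples FOVs with a guard
margin of 2.5 equivalent-circle fiber diameters (`guard_margin`), which
covers the band plus one fiber extent. This was validated from first
principles: a full tiling of frames reproduces the scene census exactly,
and guarded estimates on homogeneous scenes recover the true C/F.

## 3. TEM ultrastructure morphometry

### 3.1 Screening

Profiles are excluded, with a tagged reason, if

- the caliper aspect ratio (largest/smallest Feret diameter of the outer
  contour) is **strictly** greater than 1.2 ("oblique"; the conventional
  wording of the ratio as smallest-to-largest with a 1.2 threshold is
  impossible for a quantity ≤ 1 and is used here in the inverted form);
- the derived lumen radius exceeds 5000 nm ("large_vessel");
- pericyte coverage exceeds 80% of the circumference
  ("high_pericyte_coverage").

### 3.2 Contour morphometry

From contour perimeters `C` and areas `A` (TBIA-style formulas):
lumen radius `r = C_lumen / 2π`; a layer between contours in/out has mean
thickness `t = 2·ΔA / (C_in + C_out)`; pericyte coverage is
`100 · (arc length of pericyte arcs) / C_ec`. These closed-form measures
are validated against analytic concentric shapes (relative error ~1e-5)
and against dense outward-normal ray casting (within 5%).

### 3.3 Six-site CBM thickness

Per included capillary, six evenly spaced angular sites with a random
rotation offset; any site within 5° of a pericyte arc is re-drawn uniformly
from the pericyte-free domain (mirroring the protocol of omitting areas
near pericyte processes). Thickness at a site is the radial distance
between the endothelial and outer basement-membrane contours. If pericytes
leave less than 5% of the circumference free, the measurement errors out.
Single measurements above 350 nm are flagged (not removed) in aggregation.
Sample and group summaries report both the pooled single-measurement
distribution and the distribution of capillary means.

### 3.4 Pathology rubric (0–4)

Adjudicated in priority order, first match wins: 4 — endothelial
necrosis/debris/capillary remnants (required for a grade of 4);
3 — grade-2 findings, more pronounced; 2 — prominent irregular pericytes,
ensheathment, or prominent vesicles/mitochondria; 1 — ≥ 4 pericyte
processes, reduplication, single ensheathment, or slightly increased
vesicles/mitochondria; 0 — none of the above.

## 4. Histology

- **Cells per 10 HPF**: exactly ten per-field counts per marker, summed.
- **Type-2b atrophy (0–3)** with `f` = fraction of 2b fibers flagged
  atrophic: 0 if `f = 0`; 1 if `f < 0.15`; 2 if `0.15 ≤ f ≤ 0.60`;
  3 requires `f > 0.60` *and* "many" small fibers, operationalised as more
  than 30% of 2b fibers with minimal Feret diameter under 20 µm (otherwise
  grade 2). In synthetic mode the atrophy flag is derived as area below
  half the same-type median; on real annotations it is an input.
- **MHC-class-I**: 0 — no positive fibers; 1 — single fibers (< 20%),
  within normal range; 2 — ≥ 20% positive, judged significant.
- **Fiber-type composition**: percentages per type, with 2a and 2b also
  pooled as type 2.

## 5. Statistics

- **One-way ANOVA** by the standard sum-of-squares decomposition
  (`anova_f`), cross-checked against `scipy.stats.f_oneway`.
- **Tukey's HSD** for unequal group sizes (Tukey–Kramer), from raw values
  or from (mean, SD, n) summaries: `MSE = Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1)`,
  `SE = √(MSE/2 · (1/nᵢ + 1/nⱼ))`, `q = |x̄ᵢ − x̄ⱼ| / SE`, adjusted
  p-value from the studentized-range distribution
  (`scipy.stats.studentized_range.sf(q, k, df)`). The raw-value path and
  the summary path agree to machine precision; both are cross-checked
  against `statsmodels` and the null calibration is verified by
  Monte-Carlo (type-I error ≈ 0.05 at 20,000 replicates).
- **Pearson correlation** via `scipy.stats.pearsonr`.
- **ΔΔCT**: per sample and gene, replicate CT values above 40 cycles are
  dropped as not expressed before averaging; ΔCT = target mean CT −
  reference mean CT per sample; ΔΔCT = case-group mean ΔCT − control-group
  mean ΔCT; fold change = 2^−ΔΔCT. A target not expressed in either group
  is reported as such; a non-expressed reference gene is an error naming
  the sample.
- **Unit note**: CBM thickness is handled in nm throughout (capillary
  basement membranes are a few hundred nm; printing such values in µm is a
  common typographic slip this package deliberately avoids).

## 6. Pipeline and reproducibility

`run_pipeline(RunConfig)` simulates the cohort, measures every sample
(default: ten 250 µm FOVs per sample with the guard margin, 10 × 10 point
grid, 24-ish TEM capillaries screened and measured per sample), scores
histology, runs the group statistics, and writes TSV tables plus the exact
config and a manifest with SHA-256 checksums per output. Identical configs
produce identical outputs bit-for-bit; the config hash is recorded in the
manifest.

## 7. Known limitations

- No between-subject random effect beyond the configured sampling
  distributions; real biopsy cohorts are over-dispersed relative to the
  model.
- Capillaries are points at the scene scale (their ~5 µm extent is ignored
  by the counting frame), and immune cells are marker points without
  morphology.
- Synthetic TEM profiles carry no vesicle/necrosis content, so pathology
  flags beyond pericyte counts and ensheathment must be supplied by the
  caller in re-analysis mode.
- The mosaic border is depopulated and junction-dense; analyses must stay
  inside the guard margin (the pipeline does this by default).
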