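# Methods

## Geometry on voxel masks

A tumor model is a binary occupancy grid with physical spacing (mm); voxel
index `(i, j, k)` maps to world coordinates `origin + index·spacing`
(node-centered). Surfaces are extracted with marching cubes after smoothing
the binary field with a spacing-aware Gaussian (sigma = one voxel along the
finest axis). Meshing a raw binary grid produces staircase surfaces whose
area is biased high by ~9% on a sphere; smoothing removes the staircase but
shifts the nominal 0.5 iso-level inward on convex bodies (mean-curvature
bias, ~sigma²/r). The iso-level is therefore chosen *volume-matched*: the
number of field samples above the level equals the foreground voxel count.
On digitized balls of radius ≥ 10 voxels this yields volumes within ~1% and
areas within ~1% of the analytic values, and it keeps single-voxel or thin
structures from vanishing (the level adapts below the field maximum).
Duplicate mesh vertices are welded and collapsed faces dropped, which removes
zero-area slivers without opening the surface; faces are oriented so the
divergence-theorem volume is positive.

Principal axes are the eigenvalues (mm²) of the second central moment of
foreground voxel centers, with semi-axis = 2√λ (for a solid ball λ = r²/5, so
the semi-axis is 2r/√5 ≈ 0.894 r). This convention matters for SVR_N and is
the common radiomics one; a fitted-ellipsoid convention would scale all
semi-axes by √5/2.

The maximum 3D diameter is the largest pairwise vertex distance after
convex-hull reduction. The minimum enclosing sphere uses an active-set
scheme: keep a small support set, solve it exactly by enumerating boundary
subsets of size ≤ 4 (circumspheres via the Gram system), add the farthest
violator, repeat to tolerance 1e-9 of the bounding-box diagonal.

Volumes are reported in cm³ and areas in cm² (internal mm).

## Shape-feature conventions

All area/volume-based features use the mesh values; all moment-based features
use the voxel moments; the two conventions are never mixed inside one feature
vector. Compactness uses the "compactness-1" form `V/(√π·A^{3/2})`, which is
the monotone transform `sphericity^{3/2}/(6π)`; any scale-invariant
compactness variant is such a transform of sphericity, so Spearman-rank
analyses cannot distinguish them. VioS defaults to the maximum-diameter
reference sphere (`V / (π/6·d_max³)`), with the minimum-enclosing-sphere
reference available by option; the enclosing sphere is never smaller, so the
second mode never yields a larger VioS. By the isodiametric inequality VioS
≤ 1 for any shape.

## Plan indices

Index volumes are voxel-count based (dose and mask share a lattice, so the
digitization bias cancels in ratios); isodose thresholding is closed (≥) on
voxel-center dose. EI is the target integral dose over the integral dose
inside the half-prescription isodose region; a variant with the PIV as
denominator region is available (`ei_denominator="piv"`). For a single
isotropic Gaussian shot prescribed at 50% of its peak, GI is analytically
`(ln4/ln2)^{3/2} = 2^{3/2} ≈ 2.83`, which the voxel implementation reproduces
within 5% on a 0.4 mm grid — the main numerical oracle for the index code.

## Synthetic tumors

Boundary radius: `r(θ,φ) = r_ellipsoid(θ,φ)·(1 + a·s(θ,φ))` with `s` a
zero-mean random band-limited field (real part of a random complex
combination of spherical harmonics of degree 1..6), normalized to unit
maximum amplitude on a 2048-direction Fibonacci grid; `a` is the perturbation
amplitude (0 = exact ellipsoid, upper bound 0.6). Volume targeting rescales
the continuous shape using direction-grid quadrature of `(1/3)∮r³ dΩ`, which
keeps the digitized volume within 10% of the requested TV. Only voxels in the
shell `r_ell(1−a) < r ≤ r_ell(1+a)` evaluate the harmonic field. An
overlapping-spheres "lobes" mode generates multi-lobed shapes. The largest
6-connected component is kept and holes filled, so generated masks are single
closed solids. Everything is a pure function of (parameters, seed).

## Dose simulator

Shots are isotropic two-component kernels
`(1−f)·exp(−r²/2σ²) + f·exp(−r²/2(kσ)²)` with default `f = 0.15`, `k = 4`:
a pure Gaussian falls from 50% to 25% of its peak over ~0.49σ, far sharper
than measured radiosurgery profiles, and without the slow scatter/penumbra
component simulated plans show gradient indices near 1 and efficiency indices
near 1 for large targets — outside any clinically reported range. Collimator
sigmas (6.79, 3.40, 1.70 mm) give pure-Gaussian half-maximum radii of 8/4/2
mm, emulating the 16/8/4 mm collimators.

Packing is greedy: each shot is centered on the in-target voxel farthest from
the uncovered-region boundary (Euclidean distance transform with physical
sampling), using the largest collimator whose half-maximum radius fits that
distance (`spill_factor` relaxes the fit); a voxel counts as covered once it
lies within the half-maximum radius of a placed shot; packing stops at 95%
covered fraction or at the shot cap (100). Shot weights are then solved by
non-negative least squares so every shot center receives unit total dose —
without this balancing, kernel superposition inflates the maximum dose and
the 50%-of-maximum prescription collapses onto hotspots. The prescription is
set to 50% of the resulting maximum (so central dose = 2× margin dose) and
the grid is scaled to the margin dose in Gy.

The simulator is explicitly a stand-in for operator-driven planning: its
only contract is producing plans whose index distributions are realistic.
With the defaults, simulated cohorts have median CI ≈ 1.0, GI ≈ 2.5, EI ≈
0.3, and SI/PCI medians near 0.5 — coverage, gradient, and efficiency sit
where clinical cohorts report them, while selectivity runs lower than the
clinical median of ~0.8 (a greedy packer spills more than an experienced
operator). Known limitation: absolute SI/PCI levels should not be
interpreted clinically; rank relationships are the meaningful output.

## Synthetic cohorts

Per patient: a TV stratum drawn with weights 83:89:62 over (<1, 1–5, >5 cm³)
and log-uniform TV within the stratum (overall range 0.01–20.01 cm³, the
clinical spread); axis ratios uniform on [0.4, 1]; perturbation amplitude
uniform on [0, 0.5]. Larger strata draw proportionally smaller irregularity
(multipliers 1.0/0.7/0.45 on amplitude and on deviation of the axis ratios
from 1) because vestibular schwannomas grow by expansion and become more
spherical with size; this coupling makes VioS rise with TV (Spearman ≈ 0.6
in simulated cohorts) and is what gives the cohort-level VioS–index
correlations their clinical magnitude. Setting
`size_dependent_amplitude=False` removes the coupling, under which the pure
fixed-size shape effect on the indices is weak.

Voxel spacing adapts to tumor size (0.4–1.2 mm isotropic) so the smallest
tumors keep ≥ ~4 voxels per semi-axis while large grids stay tractable; grid
padding (6–12 mm) keeps the half-prescription isodose inside the grid.

Margin dose is drawn from {10.5, 11, 11.5, 12} Gy with probabilities
(0.10, 0.10, 0.15, 0.65) — median 12 Gy, range matching clinical practice;
central dose is twice the margin dose. Demographics: age uniform 18–89, sex
56% female, Koos grade and Gardner–Robertson class categorical with the
clinical frequencies; maximum cochlear dose log-normal (median 5.6 Gy,
clipped to [1.5, 16.1]); cochlea–target distance exponential (median ≈ 1.8
mm, clipped to [0, 10]).

Outcomes: 2-year growth control follows
`logit(p) = β₀ + 0.8·(margin dose − 12)`, with β₀ calibrated by root-finding
so the dose-mixture average equals 85.1%; hearing preservation is a constant
75.9% coin among patients with baseline serviceable hearing (GR I/II). No
shape or index covariate enters either outcome model, so TSI effects on
outcome are exactly null by construction — recovering that null (and the
planted dose effect) is what the Cox analysis is tested against. Event times
are exponential (mean 12 months) truncated to the 24-month horizon for
events, with administrative censoring at the end of follow-up (24 months
plus an exponential extension capped at 52) otherwise, keeping fixed-horizon
rates and Cox fits consistent.

What the generator does *not* emulate: real segmentation variability, MRI
resolution anisotropy of clinical contours, operator-specific planning
styles, cochlear-sparing constraints, dose-rate effects, and any true
biological link between shape and outcome. Passing tests therefore
demonstrate that the pipeline measures what it should on data with known
structure — not that the clinical effect sizes themselves are reproduced.

## Statistical analysis

- Volume groups: 1 (<1 cm³), 2 (1–5 cm³, boundaries included — the strict
  inequalities of the usual phrasing leave TV = 1 and 5 unassigned, so the
  closed middle interval is used), 3 (>5 cm³).
- Kruskal–Wallis is tie-corrected (scipy); all-identical samples return
  H = 0, p = 1 by convention. Dunn's post-hoc z-tests compare mean ranks with
  the tie-corrected variance and Bonferroni adjustment over pairs
  (implemented in-package and validated by type-I-error simulation).
  Significance thresholds: 0.05/12 ≈ 0.0041 for the Kruskal–Wallis family,
  0.05/40 = 0.00125 for the 8-feature × 5-response correlation family; the
  family sizes are configuration, not hard-coded.
- Outlier elimination before each Spearman correlation is per pair: robust
  Mahalanobis distances from a minimum-covariance-determinant fit (0.75
  support) on the 2-column slice, cut at the χ²₂ 0.975 quantile, with a
  classical-covariance fallback when the scatter is singular. Per-pair (not
  global) elimination is used so each correlation reports its own n; a
  global mode is a trivial composition of `remove_multivariate_outliers`
  with a column subset.
- Multicollinearity filter: greedy removal of |Spearman r| ≥ 0.9 pairs,
  dropping the member with the larger mean absolute correlation to the rest
  (lexicographic tie-break), deterministic.
- Lasso selection: per repeat a fresh 80/20 split, training-split
  standardization, a 50-point log grid from the training λ_max down four
  decades, λ by 3-fold cross-validated MSE (no one-standard-error rule),
  coefficients recorded at the chosen λ; the top feature maximizes the mean
  absolute coefficient over 100 repeats. Reproducible given (data, seed).
- Univariate regression: OLS with adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

## Machine learning

Labels: value ≥ cohort median (GI inverted: ≤ median), median computed on
the entire cohort before splitting — a deliberate, documented mild leakage
matching the retrospective design; `median_scope="train"` avoids it.
Features are z-scored with training statistics only. RFE ranks features by
recursively dropping the smallest absolute linear-SVM weight; the subset
size maximizes 3-fold CV accuracy (ties favor the smaller subset). Models:
LR, LDA, GB, SVM, RF with small fixed hyperparameter grids tuned by
stratified 3-fold CV on the training split; accuracy/sensitivity/specificity
are reported in percent with sensitivity on the high-quality class.

## Outcome analysis

Event rates are exact count ratios at the 24-month horizon. Cox models use
lifelines (Efron tie handling, Wald CIs); univariable mode fits each
covariate alone, multivariable jointly. Mann–Whitney is two-sided and
tie-corrected, exact for tie-free samples of ≤ 8 per group.

## Problem sizes used in tests and the acceptance script

Digitized oracles use balls of 10–15 voxel radius; the simulated cohort for
the correlation analysis has 200 tumors; planted-signal checks use 100 Lasso
repeats (n = 234), one RFE recovery at n = 300, and 200 Cox replicates at
n = 500; type-I rates use 1000–2000 null replicates; outcome-rate
calibration uses n = 10⁴ (tabular generation only — imaging is skipped, as
the outcome model depends only on the margin dose). These sizes give
sampling noise comfortably inside the asserted bands while keeping a full
run to a few minutes on one CPU.
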