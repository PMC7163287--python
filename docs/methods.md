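# Methods

## Signal model

Each voxel is modelled as a two-species (water/fat) complex gradient-echo
signal

    s(t) = (W + F · c(t)) · exp(i 2π ψ t) · exp(−R2* t),
    c(t) = Σₚ aₚ exp(i 2π fₚ t),

with non-negative amplitudes `W, F` (arbitrary units), field-map
off-resonance `ψ` in Hz, and a single decay rate `R2*` in 1/s shared by
water and fat (the standard CSE assumption; per-peak T2 relaxation is not
modelled — at echo times of 2–6 ms its influence is small). The fat
modulation `c(t)` uses an eight-peak triglyceride spectrum (methyl 0.90 ppm
through olefinic 5.29 ppm, amplitudes normalized to 1, offsets expressed
relative to water at 4.70 ppm and scaled linearly with field strength).
The spectrum is serializable to YAML so any published peak model can be
substituted. Echo times are stored in milliseconds (scanner convention)
and converted to seconds only inside the model.

`PDFF = F/(F+W)` is undefined where `F+W ≈ 0`; the denominator is floored
at `1e-9 × max(F+W)` and such voxels are flagged in a validity mask rather
than allowed to propagate NaN into segmentation.

## IDEAL reconstruction

Fitting is complex (not magnitude-based) throughout. For fixed `(ψ, R2*)`
the model is linear in `(W, F)`, so those are profiled out by a closed-form
2×2 least-squares solve (variable projection); `W` and `F` are extracted as
magnitudes of the complex solution, which makes PDFF invariant to a global
complex scaling of the input. The nonlinear pair is estimated per voxel by:

1. **Coarse ψ grid** at `R2* = 0` over ±150 Hz in 2 Hz steps. The ψ
   demodulation is unitary, so one fixed projection matrix serves every
   candidate and the search vectorizes over all voxels.
2. **In-plane 3×3 median smoothing** of the coarse map. Isolated voxels
   whose global residual minimum is a fat-water-swapped solution are pulled
   back to the neighborhood consensus; background is nearest-neighbor
   filled before filtering so mask-edge estimates are not dragged toward 0.
3. **Golden-section refinement** of ψ within ±3 Hz of the smoothed value.
4. **Alternating exact 1-D minimizations** of `R2*` (bracketed by a 21-point
   grid on [0, 400] s⁻¹ on the first pass) and ψ, both by vectorized
   golden-section search (32 iterations), until the per-voxel ψ update falls
   below 0.05 Hz or 40 alternations are reached. Converged voxels are
   frozen (active-set), so late iterations touch only the few voxels —
   typically low-signal boundary voxels — that are still moving; any voxel
   still active at the cap is reported in the log.

Only voxels whose first-echo magnitude exceeds 8 % of the robust (99th
percentile) maximum are processed; the rest are background.

Three-echo acquisitions (the protocol's first-year variant) give 3 complex
measurements for 4 real unknowns plus a common phase — marginally
determined for joint `R2*` — so with fewer than 4 echoes `R2*` is fixed at
a configurable prior (default 0), only `W, F, ψ` are estimated, and the
mode is recorded in the output metadata.

Coil combination estimates per-coil sensitivities from the (optionally
Gaussian-smoothed, σ = 1 voxel) first echo, normalizes them voxelwise to
unit root-sum-square, and combines as `Σ conj(Sc)·dc`. The residual
per-voxel phase factor is common to all echoes and is absorbed by the
complex `(W, F)` solution, so inter-echo phase evolution — all the
information IDEAL uses — is preserved exactly.

## Segmentation

Within the analyzed slab (20 contiguous slices centered on the femoral
head; ties of the even count break toward the lower index; the slab is
clipped to the volume):

* foreground = `F+W` above 5 % of its robust maximum, largest connected
  component;
* the PDFF map is binarized at 50 % (strict inequality; ties excluded, as
  for all depot thresholds) separating high-fat tissue from muscle;
* region-based active contours evolve the binarized map (C1) and its
  inverse (C2). The morphological Chan-Vese algorithm is used, 2-D per
  slice, 50 iterations; its curvature regularizer is an integer count of
  smoothing passes per iteration (default 1) rather than a continuous
  weight — the morphological variant is orders of magnitude faster per
  slice and satisfies the same fixed-point and curvature-shrinking
  behavior;
* mask algebra: M1 = C1, M2 = C2, M3 = ¬M2 within foreground, M4 = M1∖M2;
* depots: muscle = {PDFF < 0.50} ∩ M2, marrow = {PDFF > 0.50} ∩ M3,
  subcutaneous fat = {PDFF > 0.70} ∩ M4.

M3 and M4 both contain *all* high-fat tissue, so thresholds alone cannot
split marrow from the subcutaneous ring. Connectivity enforcement (2-D
8-connectivity, minimum component size 20 voxels) disambiguates by
topology: components of the high-fat set touching the background boundary
are subcutaneous fat, interior components (islands surrounded by muscle)
are marrow, at most two per slice (one per hip). The rules are idempotent:
re-running the assignment on its own output reproduces it exactly. The
femoral-head center slice comes from configuration (the phantom knows its
truth); an auto-centering heuristic is not attempted.

## Quantification

Per depot: mean PDFF and mean R2* over valid mask voxels, and the volume
ratio = mask voxels / voxels of the *analyzed slab* (not the full stack),
so masks and denominators always refer to the same sub-volume. R2* (1/s)
is the internal unit; `T2* = 1000/R2*` ms is provided for reporting.
Empty depots yield count 0 with NaN means, flagged rather than fatal.

## Statistics

* FRAX strata: `<10` LOW, `>20` HIGH, otherwise MOD. The published strict
  inequalities leave exactly 10 and 20 unassigned; both are mapped to MOD
  (configurable).
* Group comparisons: tie-corrected Kruskal-Wallis (χ², k−1 df) for
  demographics; for depot metrics both Welch's heteroscedastic ANOVA and
  the Brown-Forsythe F* are computed — the source protocol conflates the
  two — with Welch designated primary. Both are closed-form
  implementations cross-checked against independent references in the test
  suite. Degenerate inputs (groups constant to floating-point precision)
  short-circuit to F = 0, p = 1.
* Pearson matrices per group over the nine depot metrics plus age, height,
  weight, BMI and FRAX; p values from the t transform; the joint criterion
  |r| > 0.5 and p < 0.05 flags a correlation as significant. No
  multiple-testing correction is applied (matching the source analysis).
* Stepwise interaction regression: candidates are the z-scored
  (population SD) depot metrics and height/weight/age — BMI is excluded as
  collinear with height and weight — plus all pairwise products of the
  z-scores. Exactly collinear candidates are dropped (earlier-listed one
  kept). Selection is bidirectional from the intercept-only model under
  Gaussian AIC (`2k − 2logL`, statsmodels parameter convention; AICc
  optional). Because each step picks the best of m candidate additions, a
  raw "AIC decreased" acceptance admits a noise term almost surely once m
  is large (the best of m χ²(1) improvements easily beats the 2-point
  penalty); additions therefore must clear a Bonferroni-equivalent entry
  margin, `χ²₁.isf(0.05/m) − 2` on the AIC scale, while removals use the
  plain AIC comparison. This keeps the null model essentially empty while
  leaving genuine effects (which enter with AIC drops of hundreds)
  untouched. No strong-hierarchy constraint: an interaction may enter
  without its main effects, matching the published model's structure.
* Model structure is selected once on the full data; 5-fold
  cross-validation then refits the selected terms per training fold and
  reports per-fold test R² as a generalization diagnostic (the source does
  not state how CV interacted with selection; selecting inside folds would
  diagnose the selection procedure rather than the chosen model). Folds
  are a seeded permutation split; sizes differ by at most 1.
* Bland-Altman: bias = mean(pred − actual), limits of agreement
  bias ± 1.96 · SD(pred − actual).

## Synthetic data

The phantom is a stylized pelvis cross-section — subcutaneous ring
(PDFF 0.85, R2* 60 s⁻¹), muscle compartment (0.10, 40 s⁻¹), two circular
marrow regions (0.75, 100 s⁻¹) — constant through the slice stack, with a
constant / linear-ramp / smooth-polynomial field map (default ±30 Hz ramp).
Geometry is deliberately non-anatomical so ground truth is exact; the
segmentation operators only require the real data's contrast and topology.
Noise is independent complex Gaussian per voxel/echo/coil; SNR is the mean
foreground first-echo magnitude over the noise SD. Acquisition defaults
mirror the reference protocol (3 T, six echoes 2.1/2.8/3.5/4.5/5.2/5.9 ms,
128×128×40 matrix, 2.58×2.58×5 mm voxels). All randomness flows through a
single NumPy PCG64 generator seeded from the spec, so outputs are
bit-reproducible.

What the phantom does **not** emulate: partial-volume mixing beyond sharp
region boundaries, anatomical shape variability, cortical bone (a
no-signal rim), motion, eddy currents, bipolar-readout phase errors, or
spatially varying noise. Passing tests therefore demonstrate correctness
of the inversion, mask algebra and statistics under the stated model — not
robustness to every in-vivo artifact.

The cohort simulator draws demographics per stratum (n = 42/52/34) from
truncated normals matching the published per-group summaries (weight means
back-computed from the printed SD and CV cells, which are the cells that
survive table extraction unambiguously), and depot metrics from per-group
normals. Default between-group effects: marrow PDFF 72/74/77 % and muscle
PDFF 10.0/9.6/18.9 % across LOW/MOD/HIGH — the reported ~5-point marrow
and ~9-point muscle contrasts — with no group effect on R2* or volume
(none was observed). FRAX is generated from a planted
linear-plus-interaction model on the z-scored predictors around each
stratum's mean (coefficients: marrow PDFF 1.0, muscle PDFF 0.8, age 0.6,
marrow-PDFF×weight 0.5; noise SD 1.0), then clipped to the stratum
interval so labels and scores remain consistent.

## Problem sizes and numerical defaults

Recovery and fidelity checks run on a 64×64×8 phantom (≈22 k foreground
voxels, six echoes) — large enough for stable voxelwise error statistics
while keeping the whole validation under a minute per phantom; the
analysis drivers use 96×96×20 and the package handles the full 128×128×40
unchanged. Statistical calibration uses 2000-replicate nulls (Welch) and
500-replicate nulls (stepwise). Key defaults: ψ grid ±150 Hz / 2 Hz,
ψ tolerance 0.05 Hz, R2* search [0, 400] s⁻¹, outer cap 40, background
threshold 8 % (reconstruction) / 5 % (segmentation), contour iterations 50,
minimum component 20 voxels, depot thresholds 0.50/0.50/0.70, slab 20
slices, 5 CV folds. All are configuration fields, never constants buried
in logic.

## Known limitations

* Field-map smoothing is a per-slice median filter, not a full
  multi-resolution or graph-cut regularizer; severe (> ~150 Hz) or rapidly
  varying off-resonance would need the grid range extended and may swap.
* A single R2* per voxel biases PDFF when water and fat decay very
  differently (e.g. sclerotic marrow).
* The volume ratio depends on the slab definition; comparisons across
  protocols must use the same slab convention.
* The stepwise entry guard is conservative by construction: a true effect
  whose AIC improvement is smaller than the multiplicity margin
  (≈8 points at m = 36) will be missed; at the cohort's effect sizes this
  is immaterial, but weak-effect applications should lower `alpha_enter`
  consciously rather than rely on defaults.
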