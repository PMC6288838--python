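# Methods

## The measurement problem

A maternally deposited germline determinant (PIE-1, tagged with GFP)
becomes strongly enriched in the germline blastomeres of the early
*C. elegans* embryo.  Three mechanisms can contribute: preferential
inheritance at each asymmetric division, degradation in the somatic
sisters, and new translation in the germline lineage.  Separating them
requires absolute concentrations (fluorescence units differ between
sessions and instruments), cell volumes (amount = concentration ×
volume), and a way to observe synthesis directly (photobleaching the
pre-existing pool).  This package implements each measurement and the
mass-balance arithmetic that ties them together.

## Bath calibration

An embryo is imaged in a solution of purified GFP at known concentration
`C_bath` (150 nM for 1-cell embryos, 300 nM for 2- and 4-cell embryos,
the lower bath keeping the dimmer zygote on scale).  The estimator is

    C_in = C_bath * (I_in - bg - af) / (I_bath - bg)

with all intensities taken after flat-field correction: each image is
divided pixel-wise by the mean of ten bath-only images and rescaled by
that reference's maximum pixel.  `bg` is the camera offset measured from
a blank-buffer image — not from the region outside the embryo, which in
a calibration frame is bath and therefore fluorescent.  `af` is the
embryo autofluorescence in counts, measured once per imaging condition
as the background-corrected interior mean of untagged embryos in the same
bath; it is a single scalar, not a spatial map, and may be negative under
noise (propagated as-is).  Means are used throughout (not medians), and
pixels at the detector ceiling are excluded from means with a warning.

Order of operations matters: the flat-field reference includes the camera
offset, so correction distorts low-signal regions slightly.  Because the
tagged and untagged embryos are processed identically, this distortion
cancels in the subtraction and the estimator stays unbiased to well
within 2% at the default imaging conditions (verified by simulation in
the test suite; the ablation test shows the bias that appears when the
correction is skipped).

## Volumetrics

Cell volumes come from membrane-marker z-stacks (1 µm steps, sub-µm
pixels; anisotropic voxels are supported).  Volume = voxel count × voxel
volume, 1 pL = 1000 µm³.  Voxel assignment is winner-take-all, so
splitting a label conserves volume exactly.  When only the membrane
image is available, a seeded watershed on membrane intensity assigns
every voxel to the nearest seed's basin; an implicit background seed at
the stack corners claims the exterior, and two seeds that share a basin
(no membrane ridge between them, judged against an Otsu threshold) are
rejected by name rather than silently merged.

## Partitioning mass balance

For one division with daughter volumes `v_g, v_s` and (relative)
concentrations `c_g, c_s`, the germline daughter's share of the mother's
amount is `f = c_g v_g / (c_g v_g + c_s v_s)` — concentrations may be on
any common scale since the ratio is what matters.  Chained over
divisions, inheritance alone predicts a final concentration
`C_pred = C0 * phi * prod f_i`, with φ the zygote-to-final-cell volume
fold decrease, and the synthesized share of the observed signal is
`1 - C_pred / C_obs` (clamped to [0, 1] with a warning, since noise can
push the raw value outside).

Percentages are printed rounded half-up (the convention behind "58%",
"57%"); internal arithmetic keeps full precision.  φ is an explicit
input rather than being recomputed from daughter volumes: the measured
AB + P1 volumes give φ ≈ 5.9 while the conventional figure is 6.4, and
the package supports both (`reproduce` flags a non-6.4 φ as
"alternate").  "Just after division" is operationalized as the first
frame in which both daughter masks exist.

`PartitioningModel.fit()` averages replicate measurements per division
and returns a results object with fractions, their standard errors, the
prediction and a `summary()` table.

## FRAP synthesis analysis

Photobleaching erases the pre-existing fluorescent pool so that any
subsequent rise reports new synthesis (the bleach is an eraser here, not
a mobility probe — no recovery kinetics are modelled).  Traces are
per-cell background-corrected means; background comes from outside the
embryo, which is valid for these bath-free time-lapses.  Normalization
is either to the pre-bleach baseline (mean of the five frames before the
bleach) or to an unbleached control embryo's mean intensity (a single
first-frame scalar by default, with a per-timepoint option, since the
reference protocol does not specify which).  Synthesis is tested per
cell with a two-tailed paired t-test of the final versus first
post-bleach value across embryos; Welch's unpaired test is used for
between-genotype comparisons elsewhere.  Traces are not detrended for
acquisition photobleaching (none was applied in the reference protocol).

## Two-stage screen statistics

Each RNAi clone's per-embryo germline-blastomere means (background
subtracted using an outside-embryo region) are compared with the
empty-vector control by a pooled-variance Student t-test — stage 1 at
n ≥ 5, and stage-1 hits retested at n ≥ 11.  The retest is the
false-positive control: a null clone must clear two independent tests,
so the expected stage-2 false-discovery rate at α = 0.05 is roughly
α² × (null count) / (hit count).  No multiple-testing correction is
applied by default (a Benjamini–Hochberg option exists); clones below
the minimum n are flagged, never dropped.  Normalized effect sizes are
per-embryo (signal − bg) divided by the control mean.

## The synthetic generator

The generator emulates the study conditions with known ground truth:

- **Camera**: counts = Poisson(p·nM)·gain(x, y) + offset + N(0, σ_read),
  with p = 10 counts/nM/pixel, offset 100, σ_read 5, and a radial
  vignette (25% corner falloff).  p is a free parameter — real
  acquisitions never report the counts-per-concentration conversion — so
  all tests work on ratios, which p cancels out of.  Autofluorescence
  adds a 15 nM-equivalent interior signal in calibration scenes; trace
  simulations default it to zero (no bath, and the tagged-protein signal
  dominates the GFP channel).
- **Geometry**: a 2D midplane ellipse (48 × 28.8 µm at 0.3 µm/pixel) for
  intensity work; cells are anteroposterior intervals of the ellipse (so
  they tile it exactly) with nucleus ellipses inside; 3D ellipsoids for
  volume work.  This mirrors what each real measurement actually used.
- **Lineage**: zygote at 92 nM; divisions P0→(AB, P1) at 900 s after
  pronuclear meeting, AB→(ABa, ABp) at 1750 s, P1→(EMS, P2) at 1800 s;
  measured volumes 24.8/14.7/10.1/6.1/4.2 pL (P0 as the daughter sum);
  segregation fractions 0.58 and 0.57.  Between events each cell obeys
  dC/dt = k_syn − k_deg·C; divisions are instantaneous amount splits
  (mitotic intervals are not modelled).  Germline synthesis defaults to
  k_syn = 0.06 nM/s, the rate at which the simulated P2 endpoint lands
  near the observed ~424 nM; somatic degradation (ZIF-1 active) defaults
  to k_deg = 0.003 s⁻¹ in ABa/ABp, reproducing the observed decay of
  those traces while AB and EMS stay flat.  A maturation delay for newly
  synthesized protein is supported but defaults to 0 (its real value is
  unquantified; estimates of synthesis are therefore lower bounds).
- **Bleaching**: an 8 µm circle in the posterior cytoplasm; each
  repetition multiplies the matured amount inside the circle by the
  survival fraction and then lets the cell mix, so 25 short pulses
  deplete the whole zygote to ~40% even though the circle covers only
  ~4% of its area — `bleach_for_target` inverts this relation.  For a
  single pulse the immediately following frame renders the dark circle
  in place (amount-conserving); afterwards the cell is treated as well
  mixed.  For multi-pulse bleaches the next frame is rendered fully
  mixed, a fair approximation since the 0.5 s pulse train is short
  against the 15 s frame interval.
- **Screen**: per-embryo signals are Normal(m·µ, CV·m·µ) around the
  control mean with CV = 0.15 (a typical embryo-to-embryo spread for
  this kind of measurement); a clone's multiplier m = 1 is a true null.

All randomness derives from a single seed through numpy's splittable
`SeedSequence`, so every dataset is bit-reproducible.

### What the generator does not emulate

No optical sectioning/PSF, no cell-shape dynamics or mitotic rounding,
no transcript-level model, no spatial concentration gradients within a
cell (except the transient bleach hole), and no embryo-to-embryo
geometric variability.  Passing tests therefore demonstrate that the
estimators are correct under the stated noise and mass-balance model —
not that they are robust to segmentation error or optical artifacts in
real data, which would need real-image validation.

## Numerical choices and problem sizes

Frames are 128 × 192 pixels and simulations run at 15–30 s intervals
over 2100–2700 s — large enough that compartment means have sub-percent
noise, small enough that the full validation suite (estimator recovery
over 100 scenes, partitioning round-trips, 500-replicate power and
4000-replicate null simulations, 25 replicate screens) runs in a few
minutes on one core.  Ties in rounding go half-up; masks are half-open
rasters (each pixel belongs to exactly one compartment); saturated
pixels are excluded from means with a warning, and a fully saturated
compartment yields no estimate rather than a corrupt one; a bath whose
corrected intensity is ≤ 0 makes a scene uncalibratable and is rejected.

## Known limitations

- The calibration estimator inherits a small (<1% at defaults) bias from
  flat-fielding with an offset-containing reference; it cancels between
  the tagged and untagged measurements but would grow with stronger
  vignetting or offsets comparable to the bath signal.
- `fit_partitioning` takes the first frame where both daughters exist;
  with long frame intervals this lags the true division and, if
  degradation is active in the somatic daughter, biases the fraction
  upward slightly.
- The paired synthesis test assumes embryo-to-embryo independence and
  roughly Gaussian endpoint noise; its realized type-I rate at the
  default conditions is ~0.05 (measured at 0.0515 ± 0.0035 by
  simulation).
- Watershed volumes depend on the membrane shell being brighter than
  both interiors; very thin or dim membranes will leak basins.
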