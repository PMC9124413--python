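# Methods

## The TVE homogeneity statistic

TVE_p is a rank-based concentration measure on a 3D voxel grid. The
analysis window is the run of `window_length` consecutive slices (default
100) along the slice axis with the largest combined signal; ties in the
window search go to the smallest start index, and the search is exact
(cumulative-sum sliding window, equivalent to scanning every start). All
voxel values in the window are sorted in descending order and *k* is the
smallest prefix length whose sum **strictly** exceeds p% (default 30) of
the window total. TVE_p = k/N with N the count of all voxels in the
window, zeros included.

Properties the implementation guarantees and the suite verifies:

* **Scale invariance** — multiplying the volume by any positive scalar
  leaves k and TVE unchanged, so raw counts and calibrated activity give
  identical results.
* **Range** — 0 < TVE_p ≤ (⌊pN/100⌋+1)/N, the upper bound attained
  exactly by constant volumes.
* **Tie safety** — k depends only on the multiset of values; permuting
  equal voxels never changes it (stable descending sort is used anyway so
  intermediate outputs are reproducible).
* **Robin-Hood monotonicity** — transferring signal from a richer to a
  poorer voxel without reversing their order never decreases TVE.

Design choices where the definition is genuinely open:

* *Strict "exceeds".* At exact-boundary inputs (e.g. ten equal voxels at
  p = 30) strict `>` yields k = 4 where `>=` would give 3; the strict
  reading matches the statistic's name and is pinned by a test.
* *Denominator.* All voxels in the selected window are counted, zeros
  included; a `nonzero_only` option restricts the denominator to occupied
  voxels for sparse-background studies, off by default. The window — not
  the whole stack — is the denominator's domain; using the full stack
  instead is equivalent to rescaling by a constant for fixed geometry.
* *Degenerate input.* An all-zero window has no defined TVE (division by
  zero mass) and raises rather than returning a sentinel.

## Volume I/O

DICOM series are read with pydicom: frames are ordered by image
position projected on the slice normal when present, then by instance
number, with lexicographic filename order as a logged fallback; vendor
rescale slope/intercept are applied. Negative voxels (possible in
iterative reconstructions) are clamped to zero with a logged count,
since the ranking statistic requires a non-negative measure; clamping
never increases total signal. No resampling, registration, or smoothing
is performed — reconstructed voxels are analyzed as-is. The portable raw
container is a NumPy `.npz` (exact float64 round trip).

## Granulometry

The volume-weighted droplet-size distribution is modelled directly as
lognormal(x₅₀,₃, σ_g); no number↔volume weighting conversion is ever
performed because the instrument already reports volume weighting. The
`quantile` method uses exact normal quantiles (Φ⁻¹(0.84) = 0.9945, not
1), while the `x16_3`/`x84_3` convenience properties follow the
instrument convention x₅₀,₃/σ_g and x₅₀,₃·σ_g — the two agree to better
than 0.5% for any σ_g near the values seen in practice, and
σ_g = √(x₈₄,₃/x₁₆,₃) holds exactly in the property convention.

Binned histograms are fit in two stages. A probit regression —
Φ⁻¹(cumulative volume fraction) on ln(diameter) at interior bin edges,
closed-form least squares — provides the initial estimate; it is exactly
invertible when the grid spans the full support. Because a finite grid
(e.g. the 0.5–175 µm instrument range) clips tail mass and the
renormalized cumulative bends the probit line, the estimate is refined
by least squares against the truncated-renormalized CDF the histogram
actually represents. Noise-free binned input is then recovered to solver
precision for any grid, and the estimator matches a brute-force grid
search on the binned likelihood surface (verified in the suite).
At least three informative interior edges (cumulative strictly inside
(0,1)) are required; fewer raises "underdetermined fit".

Steadiness of a time-resolved measurement series can be summarized as
the coefficient of variation of x₅₀,₃ over consecutive fits; the package
treats each time slice as an independent `BinnedSizeData`.

## Dosimetry

* Residence time: τ = V/Q for a well-mixed single compartment, with the
  exact mL/(L·min⁻¹) → s factor of 60/1000. 130 mL at 2 L/min gives
  3.9 s.
* Deposition efficiency: 100·(deposited volume)/(loaded volume) in
  wt.-%, under the unit-density assumption appropriate for 0.9% saline.
  The activity-based fraction (deposited/loaded MBq) is reported
  separately and deliberately *not* reconciled with the volume-based
  one: decay timing and device dead volume affect them differently.
* Decay correction: A_ref = A·2^((t−t_ref)/T_half), half-life
  configurable (⁹⁹ᵐTc 6.0067 h default, ¹⁸F 1.8288 h constant
  provided). Correction composes as a group action and round-trips to
  1e−12 relative tolerance.

## Synthetic phantoms

The generator emulates a cylindrical capnoperitoneum phantom (a can of
~4.0 × 10.5 cm coated with a 1–2 mm agar layer) imaged as 250 slices of
92 × 92 voxels: a radius-40 cylinder spanning 210 slices by default, with
geometry scaling proportionally for other grid sizes. Three deposition
patterns model the three administration modes:

* **film** — uniform intensity on the cavity's inner boundary (lateral
  wall ring plus end caps, 2 voxels thick): aerosol coating all
  surfaces.
* **pool** — a compact ellipsoid in the gravitationally lowest band of
  the cylinder (vertical semi-axis 0.2 × radius, axial semi-axis 0.15 ×
  cavity length). The axial compactness is a deliberate choice: a
  1–2 mL instilled bolus pools near the injection site rather than
  running the cavity's full length, and an axially extended trough of
  equal volume fraction would occupy more of the analysis window than
  the film shell itself, contradicting the pattern's meaning.
* **depot** — a 3D Gaussian focus (σ = 3 voxels) truncated at 3σ: a
  liquid depot has an edge, and untruncated Gaussian tails would paint
  the entire cavity with fractional expectations that Poisson sampling
  turns into a diffuse speckle background.

The expected field is scaled to sum exactly to the requested total
counts; noise is voxelwise Poisson (the standard counting model), seeded
and reproducible, with replicate seeds spawned from one base seed. At
10⁶ counts and the canonical geometry, mean TVE30 separates the
patterns as film > pool > depot by far more than 5 replicate standard
deviations — the generator's discriminative-validity contract.

What the phantoms do **not** model: collimator response, scatter,
attenuation, and reconstruction smoothing. Real SPECT volumes are
blurred by reconstruction, which raises TVE values for all patterns;
synthetic TVE numbers are therefore meaningful ordinally (film vs. pool
vs. depot) but are not comparable numerically to scanner output, and
passing tests demonstrate correctness of the statistic and pipeline, not
calibration against in-vivo imaging.

## Group statistics

Shapiro–Wilk per group, one-way ANOVA omnibus across groups, pairwise
two-tailed t-tests; all p-values two-tailed and uncorrected by default
(Holm step-down available by flag). Arms contain distinct animals, so
the pairwise tests are unpaired by default; a paired mode exists for
matched designs because the two conventions appear interchangeably in
study descriptions and the package surfaces rather than resolves that
ambiguity. With every group constant the tests are undefined and the
comparison is returned flagged as skipped. For two groups the ANOVA F
equals the squared t statistic and the p-values coincide (tested to
1e−9); the simulated type-I error of the omnibus test at α = 0.05 lies
within [0.03, 0.07] over 1000 null replicates.

## Problem sizes and numerical choices

The suite and the acceptance script run the phantom study at the full
canonical grid (250 × 92 × 92, 10⁶ expected counts, 5–20 replicates per
arm) — one volume costs well under a second — while unit tests use
smaller grids where only correctness, not geometry proportions, is at
stake. The discriminative-validity check runs at full scale because the
depot focus has a fixed physical size in voxels and scaled-down grids
distort the pattern proportions. Window sums use cumulative sums (exact
argmax); voxel ranking uses a stable descending sort; the probit
refinement uses `scipy.optimize.least_squares` with tolerances at
1e−15. Seeds below 2³¹ are derived via `numpy.random.SeedSequence`.

## Known limitations

* No anatomical masking: TVE is computed over the full window volume,
  not a segmented peritoneal region.
* The lognormal model is monomodal; multimodal aerosols require a
  mixture the package does not provide.
* Dosimetry assumes unit density and a well-mixed cavity; impaction and
  sedimentation physics are out of scope.
* DICOM support covers single-frame series with standard ordering
  metadata; multi-frame objects are not parsed.
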