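# Methods

## The model

`srstcp` evaluates stereotactic-radiosurgery (SRS) dose distributions
radiobiologically rather than purely geometrically. The core quantity is the
Poisson tumour control probability over a voxelized dose grid:

    TCP = exp( − Σ_i ρ_i · V_i · SF(D_i) ),    SF(D) = exp(−αD − βD²)

where the sum runs over all voxels, ρ_i is the clonogenic-cell density
(cells/mm³), V_i the voxel volume (mm³, identical on a regular grid), D_i
the absorbed dose (Gy) and SF the linear-quadratic (LQ) surviving fraction.
The inner sum is the expected number of clonogens surviving the single
fraction; TCP is the probability that this Poisson-distributed count is
zero. Cell kill is assumed independent across clonogens and no
repopulation term is included — appropriate for single-fraction SRS.

Defaults: α = 0.24 Gy⁻¹, β = 0.03 Gy⁻², literature radiosensitivity values
for high-grade glioma, and 10⁶ clonogens in the target (a population giving
a TCP-curve slope typical of gliomas). The α/β ratio is a derived output
(0.24/0.03 = 8.0 Gy), never an input; the literature source these values
come from quotes α/β = 8.31 Gy from its own fit, which is deliberately not
enforced. We note that the LQ model's validity at the ~32 Gy maximum of an
SRS plan is debated, but the scientific weight of the evaluation rests on
the low-to-intermediate dose region around the target, where LQ is
uncontroversial.

## Infiltration scenarios

Invasive gliomas seed cells beyond the delineated target. Density fields
ρ(x) are built from the target mask and its Euclidean distance map d(x):

* **none** — ρ = ρ₀ inside the target, 0 outside, with
  ρ₀ = N / V_target (uniform in-target density is an explicit assumption).
* **continuous** — ρ = ρ₀·exp(−d/λ) for 0 < d ≤ d_max, 0 beyond. Defaults
  d_max = 10 mm (the average infiltration depth reported in
  autopsy-vs-MRI comparisons for high-grade glioma, range 6–14 mm) and
  λ = 1 mm. The literature never states the unit of the exponent's
  argument; taking it in millimetres is a modelling choice exposed as
  `decay_length_mm` because it controls the absolute infiltrating burden.
* **heterogeneous** — patchy infiltration: each outside voxel with
  0 < d ≤ d_max is independently occupied with probability exp(−d/λ);
  occupied voxels carry full density ρ₀. No spatial-correlation law for
  the patchiness is available, so independent Bernoulli occupancy is the
  minimal model whose expectation reproduces the continuous scenario voxel
  by voxel — which it provably does, and which the tests verify by
  averaging over seeds. One integer seed makes a realization fully
  deterministic.

Infiltrating cells are *additional* to the 10⁶ in-target clonogens: only
the in-target population is normalized, so the continuous scenario carries
roughly 1.23 × 10⁶ cells in total on the reference sphere. This affects
absolute TCP and is a deliberate choice (normalizing the grand total would
make the in-target burden depend on the scenario).

## Plan geometry

* **Distance map** — voxel-centre-to-nearest-target-voxel-centre Euclidean
  distance (scipy's exact EDT with anisotropic sampling), zero inside the
  target. Centre-to-centre (not surface) distance is well-defined on
  digitized masks and matches the resolution at which the TCP sum is
  evaluated; it is 1-Lipschitz in the voxel-centre metric.
* **Resampling** — dose grids are brought onto the structure grid by
  trilinear interpolation at structure voxel centres (exact for affine
  fields). Structure voxel centres outside the dose grid's centre hull get
  0 Gy with a logged count: SRS dose exports are spatially local and
  surrounding tissue genuinely receives negligible dose.
* **Conformity index** — coverage form: the fraction of the target volume
  receiving at least the prescription dose, with a closed threshold (a
  voxel at exactly 16 Gy counts as covered). Selectivity/gradient indices
  are out of scope.
* **Coordinates** — 0-based indices; the physical position of voxel
  (i, j, k) is `origin + index·spacing`, i.e. the origin is the *centre* of
  voxel (0, 0, 0). Arrays are indexed `[ix, iy, iz]`.

## Synthetic plans

Real plans are unavailable here, so `synthetic.py` generates
radiosurgery-like plans: targets as digitized ellipsoids (voxel centres
satisfying the ellipsoid inequality) and dose fields as weighted sums of
Gaussian shot kernels, max-normalized so the grid maximum equals
prescription/isodose-fraction (32 Gy for 16 Gy at the 50% isodose — the
same normalization a planning-system export carries). Gaussians reproduce
the steep-falloff, 50%-prescription character the framework probes and have
closed-form isodose radii (r_p = σ·√(2·ln(1/f)) at isodose fraction f),
which the tests exploit. `fit_shot_to_target` sizes a single isotropic shot
so the prescription isodose radius equals the target's equivalent-sphere
radius times a coverage factor: 1.0 is a tightly conformal plan, >1 adds
margin, <1 under-covers.

What the generator does **not** emulate: real collimator/sector beam
profiles, multi-shot interference lobes, irregular clinical target shapes,
tissue heterogeneity, or planning-system dose-calculation artifacts.
Passing tests therefore demonstrate the *formalism* — the TCP machinery,
its scenario contrast and its geometric primitives — on controlled inputs,
not agreement with any clinical dose matrix.

## Reference evaluation conditions

The headline scenario contrast is computed on a 10 mm-radius spherical
target digitized on a 1 mm isotropic 45³ grid (extent ±22 mm, enough to
contain the full 10 mm infiltration shell), single shot with coverage
factor 1.3 (minimum target dose ≈ 21.2 Gy). Under these conditions:
no-infiltration TCP rounds to 100% (expected survivors ~9 × 10⁻⁴) and the
continuous scenario rounds to 0% (expected survivors ≈ 17.7, almost all
outside the target); heterogeneous realizations average ≈ 26 survivors and
likewise round to 0%. A coverage factor of 1.4 (minimum target dose
≥ 22 Gy) leaves the no-infiltration row at 100% but softens the dose
gradient enough that the continuous scenario rises to ≈ 1% — the contrast
is steepest for tightly fitted plans, which is the point of the framework.
The margin-volume fact behind it: the 10 mm shell around a 2 cm-diameter
sphere holds ((20³ − 10³)/10³) = 7 times the target volume (the digitized
computation at 0.5 mm spacing lands within 2% of 7).

## Numerical choices

* The Poisson sum is accumulated with `math.fsum` (exact compensated
  summation): per-voxel survivor counts span ~20 orders of magnitude and a
  naive left-to-right sum would be at the mercy of ordering. Agreement with
  direct summation is tested to 1e-12 relative.
* `TCP = exp(−E)` maps E = 0 to exactly 1; for E > 745 the result is
  clamped to 0 before `exp` can underflow noisily.
* Degenerate inputs fail loudly: empty masks, negative doses or densities,
  mismatched grid geometries, all-zero synthetic dose fields and unknown
  scenario names raise `ValueError` with a specific message.
* Grid-geometry equality uses a 1e-9 mm tolerance on spacing and origin.
* Replicated heterogeneous evaluation uses seeds `seed + i`,
  i = 0..replicates−1, and reports mean ± sd of the TCP.

## Problem sizes

The reference grids are 45³ (1 mm) for scenario evaluation and 125³
(0.5 mm) for the margin-volume check; both evaluate in well under a second,
and the whole test suite in a few seconds. Larger grids change nothing
structurally — the pipeline is O(n) in voxels apart from the EDT's
O(n log n).

## Known limitations

* No DICOM RT support; interchange is NRRD (read/write) and NIfTI (read),
  axis-aligned grids only (a non-identity direction matrix is ignored with
  a warning).
* Uniform in-target density; imaging-derived heterogeneous density is out
  of scope.
* The heterogeneous scenario's spatial independence is an assumption, not
  biology; only its expectation structure is constrained by evidence.
* Plain LQ survival; no alternative high-dose models, no
  normal-tissue complication modelling, no fractionation or repopulation.
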