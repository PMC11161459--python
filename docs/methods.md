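# Methods

This note records the models, conventions and numerical choices behind
`ctstitch`, and what the synthetic validation does and does not establish.

## Stitching model

The pipeline assumes reconstructed scan volumes of the same specimen taken
at overlapping vertical positions, already on a common voxel grid up to an
integer XY translation and an affine grey-value distortion per scan
(brightness/contrast drift from the tube's heel effect). It performs no
rotational or sub-pixel registration and no blending: the join is a hard
cut at the fusion slice, which is how the workflow it reproduces operates.

**Fusion-slice selection.** The reference slice (bottom stack) and each
top-stack slice are normalised to zero mean and unit standard deviation;
the score of top slice k is the standard deviation of the difference
image, and the first argmin wins (deterministic tie-break). The original
workflow says only "normalize"; z-scoring was chosen because it makes the
residual exactly invariant under positive affine intensity maps — the same
distortion family the subsequent calibration removes — so selection and
calibration cannot disagree about what counts as a match. A constant slice
z-scores to all zeros rather than NaN. The heuristic confidence,
`1 − min/median` of the score profile clamped to [0, 1], exists only to
drive the abort-on-bad-match guard; it is not a calibrated probability.

**Intensity calibration.** Ordinary least squares through paired ROI mean
intensities on the matched slice pair, mapping top onto the bottom scale.
When no ROIs are given, a 4×4 grid of square patches over the central 80%
of the slice is used, dropping patches whose variance is at or below a
floor (default 0, i.e. exactly-flat background); an interactive user would
place ROIs by hand, and the automatic default exists to make the pipeline
scriptable. At least two ROIs with distinct top means are required.

**Crop convention.** The workflow description ("bottom between slice 1 and
the selected slice, top from the selected slice to the last slice") is
ambiguous about whether the fusion slice appears twice. Default: the
bottom stack contributes it, the top stack starts one slice later; the
duplicate convention is one flag (`duplicate_fusion_slice`). Indexing is
0-based in the library, 1-based in CLI output and logs, converted only at
the interface.

**Multi-scan folds.** `stitch_many` is a left fold of pairwise
concatenation, mirroring the repeat-the-macro-per-scan workflow; in manual
mode the bottom fusion index therefore refers to the volume stitched so
far (`ScanSimTruth.fusion_pairs_cumulative()` converts the simulator's
per-scan ground truth to this frame). All arithmetic is float64 from the
first concatenation on; quantisation to 8 bit is a separate final step,
as in the original processing chain.

## Synthetic data: the stated world

**Coral phantom.** A cylinder along z: dark organic core, then rings
alternating bright calcite (inner half of each ring period) and dark
organic. Grey levels default to background 10, organic 60, calcite 200 —
8-bit-like values with the calcite/organic contrast (140) dominating, as
in real skeletal slices where carbonate is bright and tissue dark. Two
geometric variations give every axial slice a unique texture, which the
fusion-slice search requires: the ring phase drifts 0.25 voxels per slice,
and the cross-section tapers conically by 0.002 per slice. The taper is
load-bearing: phase drift alone repeats every period/drift slices (an
axially periodic phantom defeats slice matching at exactly that lag, which
is also a fair warning about real specimens with periodic internodes).
Levels are exact constants so label-conditioned means are exact; noise
belongs to the scan simulator only.

**Scan simulator.** Distortion per scan: `v·g_i·(1 + h·z_local) + o_i`
(per-scan gain/offset plus a linear within-scan heel ramp), optional
integer XY shift, optional linear intensity roll-off over the outer k
slices standing in for cone-beam under-sampling, then additive Gaussian
noise — adequate for reconstructed grey values, not raw projections. This
is deliberately the exact distortion family the method assumes, plus the
roll-off for robustness checks; a green stitching test therefore
establishes correctness of the algorithm under its own model, not
robustness to nonlinear shading, scatter, or rotation misalignment, which
the simulator does not produce. Ground-truth fusion pairs point at the
middle slice of each overlap.

**Hourglass phantom.** One pair of equal spheres in contact per diameter
(defaults 3.000, 6.000, 9.525 mm), tangent along z, laid out along x, with
deterministic sub-voxel centre jitter so the rendering never aligns
specially with the grid. Surfaces are antialiased by 4³ subsampling of
boundary voxels (a binary mask would artificially degrade sub-voxel
metrology). Ground-truth centre distances equal the diameters exactly, by
construction, at any voxel size.

## Sphere metrology

"Threshold-independent" is implemented as an enforced property, not a
claim. Coarse stage: Otsu threshold, binary erosion (escalating 2→12
iterations until the expected component count appears — tangent spheres
bridge at the contact over a region that widens with sphere radius), and
connected-component centroids. Refinement: along 256 near-uniform ray
directions the surface is placed at the sub-voxel extremum of the radial
intensity derivative (parabolic interpolation, search window 0.5–1.5 of
the current radius estimate), then an algebraic least-squares sphere fit
with one 3·rms outlier trim discards rays that grazed the partner sphere
near the contact point; two such refine iterations. Stability check: the
coarse stage is rerun at ±10% of the threshold and a fit whose centre
drifts more than 0.1 voxel is flagged `threshold_stable=False`. On the
synthetic phantom at 50 µm the measured distances agree with truth to
under a micrometre, far inside the half-voxel default tolerance — but
that is on noiseless, artefact-free renderings; real scans add blur,
noise and beam hardening that this validation does not model.

## Beam hardening and density scaffold

The linearisation profile is p(x) = scale·(c₄x⁴+c₃x³+c₂x²+c₁x+c₀) applied
in normalised attenuation space x = v/normalisation_max, with the result
rescaled by normalisation_max; the shipped `nikon-preset-4` has
(c₀..c₄) = (0, 0.2, 0.8, 0, 0), scale 4.44, strictly increasing on [0, 1]
and anchored at 0 → 0. Two conventions here are package choices, since the
vendor's exact use of "Scale" is not public: scale is a plain multiplier
of the polynomial, and the transform acts on reconstructed values, not
projections. A numerical inverse (Brent root-finding per value) is
provided and round-trips to ≤ 1e-9. Density calibration is a scaffold
only: an affine map pinning an air ROI at 0 and a water ROI at 1, labelled
"relative density (water = 1)"; no absolute g/cm³ claim.

## Numerical conventions

- Rounding is half-away-from-zero everywhere quantisation occurs (8-bit
  conversion, physical-unit translations), for platform stability.
- 8-bit windowing defaults to min–max over the whole volume (the common
  viewer default), with percentile (0.05% tails) and explicit windows
  available; a degenerate window maps to zero with a warning rather than
  erroring. Whether the originally deposited volumes used a global or
  per-slice window is unknown; only global is offered.
- Voxel size: JSON sidecar wins over TIFF resolution tags (unit-ambiguous
  in the wild); with neither, an explicit argument is required.
- Seam-discontinuity measurements in the tests subtract the phantom's
  intrinsic slice-to-slice mean difference (known from ground truth),
  since the specimen itself varies along z; without that netting the
  metric saturates at the phantom's own axial variation.

## Known limitations

- No sub-pixel or rotational registration; XY alignment is integer
  translation from one landmark pair.
- Heel correction is an affine match at the seam; the ramp *within* each
  scan is left in place (as in the original workflow), so a stitched
  volume retains smooth axial intensity drift.
- The sphere detector assumes bright spheres on a darker background and
  at least ~4 voxels across the smallest sphere.
- Simulator omissions listed above (no nonlinear shading, scatter, rings,
  rotation, or projection-domain effects).
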