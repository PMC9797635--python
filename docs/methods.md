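# Methods

## The phantom model

The simulator reproduces the geometry of an anthropomorphic striatal
phantom: four fillable striatal wells inside a large brain-shaped background
compartment.  The digital analogue is a label volume on the acquisition grid
(default 128 × 128 × 96 voxels at 2.13 mm):

* **Brain shell** — an ellipsoid with semi-axes (62, 78, 55) mm (≈ 1.1 L),
  filled at the non-specific concentration `c_ns` and acting as the
  reference compartment.
* **Caudate wells** (4.7 / 4.6 mL right/left) — stadium-shaped (capsule)
  cross-sections, anterior and medial.
* **Putamen wells** (5.4 / 6.0 mL right/left) — lens-shaped elliptical
  cross-sections, lateral and slightly posterior, rotated 15° like the real
  structure.

All four wells are constant cross-section extrusions over the same ~42 mm
axial range, like the machined cavities of a physical phantom.  This is a
deliberate modeling choice with a useful consequence: inside the central
slices every image column through a well is "pure", so in the blur-free
noise-free limit the manual method recovers the true BPI exactly, which
pins down the entire quantification chain in tests.  The ~42 mm extent
yields a 19–20-slice composite (≈ 42 mm effective thickness) at 2.13 mm
slices.

Voxelization calibrates each well to within 2 % of its nominal capacity by
jointly searching the axial slice count (±2 around the target extent) and a
continuous in-plane scale factor; the in-plane search operates on each
pixel's "entry scale" (the smallest shape scale containing it), so the
calibration is exact up to the discreteness of the pixel lattice.  Degenerate
lattice ties are handled by thresholding between *distinct* entry scales.
The in-plane layout is sized so that the standardized TwoBox template
captures ≥ 95 % of each side's striatal composite counts at 11 mm PSF — the
design condition the physical template/phantom pairing is built around.

## Activity filling

`fill_activities` sets the shell to `c_ns` (1 count·mL⁻¹ in arbitrary
units; the simulator rescales globally) and every well to
`c_ns × ratio × ε`, where `ε` is a single lognormal preparation-error
factor with mean 1 and CV `jitter_cv` (default 0.10).  One factor is shared
by all four wells because a physical phantom is filled from one specific
solution.  The *achieved* ratio (post-jitter) is the ground truth recorded
per acquisition — the digital analogue of aliquot counting — and
`achieved_bpi = achieved_ratio − 1` exactly.  Nominal ratios 10–8, 7–5 and
4–2 form the high / intermediary / low activity-level groups.  The default
design allocates (3,2,3,3,2,3,3,2,2) replicates to ratios (10,…,2):
23 acquisitions, 8 high / 8 intermediary / 7 low.

## Acquisition surrogate

Projection-domain physics (collimator response, attenuation, scatter,
iterative reconstruction) is out of scope.  The chain is:

1. convolve the activity map with a stationary, sum-preserving Gaussian PSF
   (default FWHM 11 mm — typical of an LEHR collimator at a 20 cm orbit,
   folded with reconstruction blur);
2. rescale so the expected image sums to `expected_total_counts`
   (default 3·10⁶, a plausible brain-SPECT level);
3. draw independent Poisson counts per voxel;
4. apply a count-preserving Gaussian post-filter (default FWHM 6 mm,
   standing in for the post-reconstruction low-pass filter).

The phantom is padded ≥ 3 FWHM from the volume borders, so kernel leakage
is < 0.1 % of total counts.  The quantification biases the package studies —
partial-volume spill and count noise — are exactly the ones this surrogate
carries; what it cannot show is any effect of non-stationary resolution,
attenuation/scatter residuals or reconstruction nonlinearity, so passing
tests validate the ROI logic, not a full physics chain.

## Composite images

* `composite_top_k` (manual method): rank axial slices by counts inside the
  striatal mask, sum the top k (default 5), lower index wins ties.
* `composite_all_striatal` (template methods): sum every slice whose
  striatal-mask counts exceed 5 % of the per-slice maximum.  With the
  default geometry this selects the 20 well-bearing slices.

Simulation studies use the ground-truth striatal mask for slice selection;
a top-decile intensity fallback exists for mask-free use.  Note the
threshold rule can only ever select slices containing well voxels: counts
blurred axially *beyond* the wells (≈ 8 % of the specific signal at the
default resolution) are structurally outside any composite.  This is the
main accuracy ceiling of the composite-based methods here (see
Limitations).

## The five methods

**Manual (BPI).**  The operator's tracing is emulated deterministically:
each compartment ROI is the projection of its true label over the selected
slices, i.e. a perfect anatomical outline that captures in-boundary counts
but no spill-out — reproducing the PVE underestimation mechanism while
removing rater variance.  The reference ROI takes shell-projection pixels
(shell in *every* selected slice) at least 20 mm in-plane from any striatal
ROI pixel, restricted to the posterior third of the shell — an
occipital-like placement; ≥ 50 pixels are required.  CA/PU/ST values pool
counts over both sides' ROIs (not averages of per-side BPIs).

**TwoBox (SBR).**  Two isosceles trapezoids (bounding box 44.8 × 38.4 mm;
parallel sides anterior–posterior; medial/lateral side ratio 0.7, wider
side lateral) are centered on the per-side striatal count centroids,
symmetrized about the midline.  The reference pipeline follows the
semi-automated recipe exactly: zero the template regions, smooth the
remainder with a 3 × 3 mean filter applied three times, keep pixels ≥ 50 %
of the smoothed remainder's maximum; `c_ns` is then measured on the
*unsmoothed* composite over that mask (smoothing defines geometry only).
`SBR = (Ct/c_ns − V_ROI)/V_ST` per side with `V_ST` the side's nominal
CA+PU capacity and `V_ROI` = template area × composite thickness; the
striatal value pools sides by volume-weighted mean.

**ThreeBox (TBPI).**  Per side, a 44.8 × 38.4 mm rectangle on the striatal
centroid and an equal-area reference rectangle immediately posterior;
`TBPI = (Ct − c_ns·V_ns)/(c_ns·V_ns)/V_ST`, reported ×100 as a percent.
`V_ns` is taken as reference area × composite thickness.  The index is
implemented exactly as printed; its 1/volume scale makes its absolute
values and regression slope live on an arbitrary scale (the printed form of
the defining equation is dimensionally odd), so only its correlation
behavior is meaningful.

**Structural VOIs + GTM (BPI).**  Real structural imaging, segmentation and
rigid co-registration are replaced by construction in phantom space plus a
known, seeded perturbation: the MRI-like and CT-like variants apply a
global rigid shift of ≤ 1 voxel and random flips of one-voxel boundary
layers with a drawn net volume error ≤ ±3.5 % (segmentation differences of
physical phantoms are a few percent, below the SPECT resolution).  The GTM
is computed over the four well VOIs, the posterior reference VOI, and the
remaining shell as an explicit background region — without the background
region the non-specific spill-in around the wells would be unmodeled and
the correction could not recover the truth.  A `gtm_include_reference=False`
mode drops the reference VOI from the system (background absorbs it) and
reads the reference level directly off the image.  The model blur mirrors
the simulation chain (PSF stage then post-filter stage applied
sequentially), ensuring the noiseless exact-mask round trip is exact;
matrix conditioning is checked (error above 10⁸).  BPI uses the corrected
reference concentration; CA/PU/ST pool sides by volume-weighted mean
concentration.

## Statistics

Lin's CCC uses population (1/n) moments — the original definition — with a
Fisher-z confidence interval from Lin's asymptotic variance; a 1/(n−1)
variant is available via `bias="sample"` (the two differ noticeably at the
7–9 points per activity level).  Pearson r comes from `scipy.stats`, the
regression from `statsmodels` OLS with t-based 95 % CIs, ρ² = r².  Truth
pairing: SBR is regressed against the achieved ratio, BPI- and TBPI-type
indices against achieved ratio − 1.  Activity levels with fewer than three
points report an undefined (NaN) CCC rather than raising.

## Key parameters

| parameter | default | units | why |
| --- | --- | --- | --- |
| `voxel_size` | 2.13 | mm | acquisition pixel size of the emulated camera |
| `psf_fwhm` | 11 | mm | LEHR-class system resolution surrogate |
| `post_filter_fwhm` | 6 | mm | post-reconstruction smoothing surrogate |
| `expected_total_counts` | 3·10⁶ | counts | clinically plausible brain-SPECT total |
| `jitter_cv` | 0.10 | — | fill-preparation error; matches the spread of real achieved fills |
| `manual_top_k` | 5 | slices | manual-method composite depth |
| `composite_threshold` | 0.05 | — | per-slice striatal count threshold; yields ≈ 20 slices |
| trapezoid box | 44.8 × 38.4 | mm | standardized template dimensions |
| trapezoid side ratio | 0.7 | — | fixed shape of the template (unspecified upstream; chosen once) |
| reference margin | 20 | mm | keeps reference regions clear of striatal spill |
| `BOUNDARY_FLIP_P` | 0.12 | — | VOI boundary roughening intensity (sub-voxel scale) |

## Numerical choices

* Volume calibration tolerance 2 %; entry-scale bisection to 48 iterations;
  ties broken between distinct entry values.
* Slice-rank ties resolved toward the lower slice index (stable argsort).
* All seeds derive from a single master seed through `SeedSequence` spawning
  (31-bit children), making studies bit-reproducible; the two VOI variants
  get dedicated spawned seeds.
* Gaussian blurs use truncated (4σ) sampled kernels with zero-padding
  boundaries; GTM oracles in the tests rebuild the same kernels by hand and
  convolve via FFT.
* Degenerate inputs raise `ValueError` (empty masks/designs, non-positive
  reference levels, sub-voxel volume requests, overlapping or out-of-bounds
  templates, GTM condition number > 10⁸).

## Known limitations

* **Composite axial truncation.**  Mask-thresholded slice selection cannot
  include slices beyond the wells, so ≈ 8 % of the specific signal is
  blurred out of every composite at the default resolution.  Together with
  ≈ 95 % in-plane template capture this caps the TwoBox calibration slope
  at ≈ 0.87–0.88 in this simulator; an expert selecting slices on a real
  blurred image would include visible spill slices and recover part of
  this.  The TwoBox reference level also drifts slightly with the fill
  ratio (the 50 %-of-maximum threshold rises as spill elevates the smoothed
  background), which contributes a small ratio-dependent bias.
* **Structural-VOI optimism.**  With sub-voxel segmentation/registration
  perturbations the GTM-corrected methods are nearly unbiased (slope ≈ 1).
  Real co-registration of separately acquired modalities errs by more; the
  accuracy ranking between the VOI methods and the template methods in this
  simulator therefore favors the VOI methods more than physical experiments
  do.  The perturbation magnitude is a config-level choice, not a model of
  any specific registration algorithm.
* **TBPI scale.**  Implemented exactly as defined, the ThreeBox index is on
  an arbitrary scale (counts-ratio per mL); it is monotone and linear in
  the true uptake, so r and ρ² are meaningful, CCC and slope are not.
* No attenuation/scatter residuals, no non-stationary PSF, no rater
  variability, no decay correction — the simulator isolates ROI-geometry
  and PVE effects only.
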