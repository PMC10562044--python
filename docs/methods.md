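# Methods

`lu177planar` studies how far the scan time of a Lu-177 planar
scintigraphy acquisition can be reduced before organ-level activity
quantification degrades, and whether a convolutional denoiser restores
the reduced-count images well enough to keep ROI statistics and MIRD
dosimetry intact.  Everything is simulated: digital phantoms, an
analytic gamma-camera model, Poisson counting, binomial scan-time
reduction, CNN denoising, and the downstream statistics.

## Imaging model

The camera is a dual-head system with a medium-energy general-purpose
parallel-hole collimator (hole diameter 3.0 mm, septal thickness
1.05 mm, hole length 58 mm), 2.2 mm pixels on a 256x256 matrix
(540x400 mm useful field of view), planar system sensitivity
65 cps/MBq, system resolution 9.4 mm FWHM, and a 5-minute scan.

`projector.project_expected` is an *analytic surrogate* for photon
transport.  For each depth slab along the viewing axis the activity is
attenuated by the accumulated `exp(-sum mu dl)` of the overlying
material (half of the slab's own attenuation included), convolved with
a Gaussian PSF of FWHM

    R(z) = sqrt(R_int^2 + R_coll(z)^2),
    R_coll(z) = d_eff (l_eff + z) / l_eff,

and accumulated; the sum is scaled by sensitivity x scan time.
`R_int` is calibrated once so that `R(100 mm) = 9.4 mm`; the reference
distance of 100 mm is the customary system-resolution specification
depth and is configurable.  Scatter, septal penetration, the 20% energy
window and the crystal response are *not* modelled; their net effect on
count yield is folded into the measured sensitivity constant.  The
consequence (verified in the experiments): absolute ROI count levels
come out at roughly half the values a full Monte-Carlo transport
produces, uniformly across objects.  Patterns that depend on relative
counts (thinning ratios, significance structure) are unaffected; the
pixel t-tests simply operate at somewhat lower power.

Counting statistics: each pixel of the expected image receives an
independent Poisson draw.  A scan of fraction `f` of the time is
emulated by per-pixel binomial thinning (`p = f`), which for a Poisson
process is *exactly* a shorter scan.  Thinned series are nested (the
30% image is a photon subset of the 50% image), matching the list-mode
subsampling interpretation; the reduced-count images of later torso
time points reuse the first acquisition the same way.

Attenuation is water-equivalent everywhere (`mu = 0.0136 /mm` at
208 keV, NIST-interpolated); tissue-composition differences are reduced
to this single coefficient in the surrogate.

## Phantoms

* **Shepp-Logan** - the standard 10-ellipsoid head phantom, intensities
  mapped to activity, water attenuation inside the outer ellipsoid.
* **Brain-like surrogate** - the licensed Hoffman voxel phantom is not
  redistributable; a parametric stand-in provides the same *role*:
  a head-shaped support holding a folded two-compartment pattern
  (median-thresholded smooth random field) at a 4:1 grey:white activity
  ratio, deterministic under a seed.
* **Hot-rod (Derenzo-style) phantom** - 340 mm diameter, 78 mm tall,
  one rod per diameter in {10, 13, 17, 22, 28, 33} mm (the exact sector
  layout is not documented; rods sit on a ring, chosen only for
  non-overlap).  Rods at 10 MBq/kg, background at rods/TBR.  The voxel
  activity map is normalized so the phantom total equals the
  rounded-volume bookkeeping (180 cm^3 of rods in 7000 cm^3): 15.44 MBq
  at 5:1 and 5.21 MBq at 20:1.  The exact summed cylinder volume is
  178.6 cm^3.
* **Torso surrogate** - the licensed NCAT phantom is replaced by an
  elliptic-cylinder body with ellipsoidal liver, spleen and kidneys
  (liver superior-anterior, kidneys posterior-inferior with a small
  realistic projection overlap of the liver over the right kidney's
  upper pole).  Organ activities follow per-organ time-activity curves
  in percent injected activity sampled at 24/96/168 h with retention
  scaling 1.0 : 0.6 : 0.4 - the count-ratio structure the emulated
  study's tables exhibit across time points.  Default %IA at 24 h
  (liver 8, spleen 1.5, kidneys 1.2/1.0) with 700 MBq injected puts
  full-count organ pixels at the ~30-150 count level typical of a
  5-minute acquisition.
* **Training corpus** - each base phantom (Shepp-Logan, brain-like) is
  interpolated to `matrix x matrix x n_slices`; every axial slice is
  duplicated 30-fold along depth to a thin slab scene.  Two families of
  150 slices give 300 scenes at full scale, with per-scene total
  activities spaced evenly over 2.88-20.6 MBq (family A) and
  1.36-31 MBq (family B).

## Denoiser

The network follows the dense-skip-connection restoration lineage: one
low-level convolution, `n_blocks` dense blocks of `convs_per_block`
convolutions (each layer receives the concatenation of every preceding
feature map), a 1x1 bottleneck, two further stages standing in for the
super-resolution original's deconvolutions (input and output share
resolution here, so both are stride-1 - a transposed convolution at
stride 1 is an ordinary convolution with a flipped kernel, and the
kernels are learned), and a single-channel reconstruction layer.  The
full-scale recipe (8 blocks x 8 convs, 69 weighted layers) is shipped
as `PAPER_SPEC` but is GPU-class; the desk profile (`DESK_SPEC`,
2 blocks x 4 convs, growth 8, low-level 8, bottleneck 16) trains in
about 10 minutes on one CPU.

Training: 25x25 patch pairs cut on a stride-25 grid with a random
per-image offset (tiles never overlap, placement varies - our reading
of "randomly cropped with a stride of 25"); pairs whose full-count
label patch is all zero are discarded.  Loss is the RMSE between
output and label in normalized units; optimization is Adam (batch 32,
learning rate 1e-4, beta1 0.9, weight decay 1e-4).  The decay is
applied in decoupled (AdamW) form to convolution weights only: folding
L2 into Adam's adaptive step divides the penalty by the gradient scale,
which near convergence of an RMSE loss amplifies the nominal 1e-4 by
orders of magnitude and shrinks all output intensities by 1-2% - enough
to trip pixel t-tests over large ROIs.  Biases (zero-initialized per
the He/MSRA convention) are never decayed.  Weights are He-initialized.
One iteration is one batch.  Training is bit-deterministic under a
fixed seed.

**Intensity convention.**  A reduced-count image at fraction `f` is
divided by `f` before entering the network, so the network always
operates at full-count intensity scale and only removes noise; a single
model then serves every fraction.  This is forced by the reference
tables of the emulated study: the 96 h full-count image is
statistically identical to the 60%-count 24 h image, yet its denoised
reduced versions come out at the 96 h intensity level - impossible for
one network acting on raw counts (two inputs with near-identical
statistics would need outputs differing by 1.66x), consistent for one
network on fraction-scaled inputs.  The known acquisition fraction is
metadata, not a network input.  The remaining count-to-unit
normalization is a single constant stored with the model (99.9th
percentile of the training labels).

Inference runs the whole image through the stride-1 network (any size
is accepted), un-normalizes, and clamps negatives to zero; outputs stay
real-valued.

The conv-net engine itself (`nn.py`) is a small numpy implementation -
im2col/GEMM forward, hand-derived backward (input gradients as one
fat-K GEMM against the flipped kernel), verified against central finite
differences and scipy correlation oracles in the test suite.

## Metrics and ROI statistics

RMSE is computed over all pixels; PSNR is `20 log10(I_max / RMSE)` with
`I_max` the reference maximum (identical images return an infinity
sentinel).  SSIM is the *global* form - one value from whole-image
means, SDs (n-1) and covariance, with `C1 = (0.01 L)^2`,
`C2 = (0.03 L)^2`, `L = max(ref)`; a windowed variant (scikit-image) is
available behind a flag for cross-checks but is not the default.

Rod ROIs: Otsu's threshold (between-class variance on a 256-bin
histogram) computed on the full-count image within each rod's projected
footprint dilated by 2 px.  The tight neighbourhood makes the threshold
separate the rod core from its blur skirt; this reproduces the
character of the reference rod ROIs (relative SD 15-20% of the mean).
Masks are defined once on the full-count image and reused for every
reduced-count and denoised image, so comparisons are paired over
identical pixel sets.  Organ ROIs replace manual outlining: pixels
whose projected organ thickness exceeds half its maximum.

Significance: two-sample pooled-variance t-test (Welch behind a flag)
on the pixel intensities inside an ROI, test image vs full-count
reference, two-sided, alpha 0.01.  Pixels are treated as independent
samples - exactly what the emulated analysis does.  The caveat is
real: pixels are spatially correlated through the PSF, so the nominal
alpha is optimistic; since both the reference analysis and this one
share the convention, the comparison is like for like.

## Dosimetry

Conjugate-view activity: `A = F sqrt(I_A I_P / T) f / C` with
transmission `T` through the total thickness, calibration factor `C`
(counts/s per Bq; the system sensitivity), slab self-attenuation
`f = (mu t / 2) / sinh(mu t / 2)`, and a user-supplied background
factor `F` (default 1).  For a uniform slab source in water this is
exact; the noise-free recovery experiment confirms <0.1% error over
5-20 cm.  For organs, ROI count rates are additionally divided by a
recovery coefficient (the fraction of the organ's expected counts that
falls inside its ROI, computed from a noise-free projection of that
organ alone), correcting ROI truncation and blur spill.

Cumulated activity: trapezoids over the sampled time points, a
configurable rise from t=0 (linear default), and an exponential tail
from the last sample using the Lu-177 physical half-life (6.647 d,
not part of the emulated study's text; used only for the tail);
a mono-exponential fit rule is available.  Doses follow
`D_j = sum_k A~_k S(j<-k)`; S values are user-supplied (published
tabulations are not redistributed here), and the shipped 4-organ matrix
is an illustrative toy for exercising the arithmetic.

## Desk-scale study conditions

The full-scale study (300 scenes of 256x256, 69-layer network, 1e5
iterations on GPUs) is out of reach of a single CPU; the package's
experiments run a reduced edition, chosen once as the package's
standard conditions:

* training corpus: 30 scenes (15 slices x 2 families) of 96x96, 24
  duplicates deep; per-scene activities spaced over 4.5-45 MBq and
  3-50 MBq, preserving the wide (~10x and ~16x) brightness span of the
  full-scale corpus families so that full-count foregrounds cover
  ~10-160 counts/pixel - both the dim late-time-point organs and the
  bright rods fall inside the training intensity distribution (a
  network only calibrates its absolute intensity response within the
  brightness range it has seen);
* network: `DESK_SPEC` (2 blocks x 4 convolutions, growth 8), 2000 Adam
  iterations, batch 32 - about 10 minutes of training;
* count fractions {10, 30, 50, 70, 90}%;
* evaluation phantoms at their physical size (hot-rod 156x156 pixels at
  2.2 mm, torso 144x176), 20 held-out scenes for image metrics.

What passing the desk-scale experiments shows: the full chain -
simulation, thinning, scale-corrected denoising, paired ROI testing -
reproduces the *structure* of the reference results (all reduced-count
inputs significantly different; denoised images at >=30% counts
statistically indistinguishable for all rods >=13 mm and all organs,
i.e. a 70% scan-time reduction; percent differences of a few percent
for the 10 mm rods).  What it does not show: the reference's absolute
count values (they depend on full photon transport and GPU-scale
training) and behaviour on real patient data (registration errors,
anatomical variability, scatter tails and septal stars are all absent
from the surrogate).

Two power-related boundaries of the desk edition, both consequences of
its ~2x lower count levels: the 90%-count inputs on the small rods
(ROI n < 50 pixels) are genuinely not significant at alpha 0.01 (a 10%
count deficit inside a 20-pixel ROI is below the t-test's resolution at
~30 counts/pixel), so the universal-significance property is asserted
in the large-sample regime (n >= 50, mean >= 20 counts) at 90% and
everywhere for <=70%; and organ ROIs with thousands of pixels resolve
network biases below 1%, which is the regime where the desk-scale
network's calibration is at its limits.

## Numerical choices and degenerate inputs

* Gaussian blur uses zero-padding; point sources near the matrix edge
  lose tail counts (the experiments keep phantoms inside the matrix).
* `thin_counts` refuses to *increase* a fraction (counts cannot be
  created); `fraction == current` returns a copy.
* Identical images: RMSE 0, PSNR infinity sentinel, SSIM exactly 1;
  two constant equal samples: t = 0, p = 1 by convention.
* Otsu on a constant image raises; thresholds are bin centres, ties
  resolved toward the lowest threshold.
* The projector resamples in-plane to the pixel grid
  activity-conservingly (bilinear, then rescaled to the exact total).
* Workspace buffers inside the conv engine are reused across
  iterations; training memory stays under ~1 GB at desk scale.

## Known limitations

* No scatter/penetration transport: absolute counts are sensitivity-
  calibrated, not spectrum-faithful; background tails are cleaner than
  reality, which flatters Otsu segmentation.
* The anatomical surrogates are role-matched, not voxel-faithful;
  organ overlap in projection is milder than real anatomy.
* Pixel-level t-tests inherit the independence idealization discussed
  above.
* The desk-scale network is a capacity-limited stand-in; its residual
  ~1% intensity biases are visible to very large ROIs, and high-count
  fractions (>=70%) can come out slightly *worse* in PSNR than their
  already-clean inputs, while still improving every reduced-count
  condition the study targets.
* Intensity calibration below ~40 counts/pixel varies with the training
  seed (a few percent either way): dim pixels contribute little to the
  RMSE loss, so 2000 iterations on ~1200 patches leave them loosely
  constrained, and an unlucky training can push the late-time-point
  kidney ROIs (9-25 counts/pixel) over the significance threshold even
  after denoising.  Denoising *quality* (PSNR gain, RMSE monotonicity)
  is stable across seeds; absolute calibration at low counts is the
  fragile quantity.  The full-scale recipe (69 layers, 1e5 iterations,
  ~22.5k patches) is what buys uniform sub-percent calibration.
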