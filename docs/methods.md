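# Methods

This note records the models, numerical choices and limitations behind
`pulmoct`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from outside the code.

## Phantom model

The phantom is a voxelised scene on an isotropic grid (default 0.08 mm),
with a uniform lung background and a single "structure" HU level shared by
vessels and nodules. Defaults: background −580 HU, emulating a lung volume
filled with powdered polyamide as produced by selective laser sintering; an
air-like −875 HU is available for a patient-like background. Structures
default to −110 HU, the midpoint of the soft-tissue-like band [−130, −90] HU;
values outside that band are rejected at scene construction.

Nodules are spheres (benign-style) and spheres with conical spikes
(malignant-style, in the style of FDA lung-phantom inserts). A voxel belongs
to a sphere iff its centre lies within the radius. Spikes are cones whose
base circle (radius `spike_length · tan(base half-angle)`) sits on the
sphere surface and whose apex lies `spike_length` further out along the
spike direction. Published phantom descriptions do not pin down the spike
geometry numerically, so the defaults — 12 spikes (6 axis-aligned plus 6 in
seeded random directions), length 2.5 mm, base half-angle 20° — are declared
package choices, constrained so that sphere + spikes fit inside the
segmentation VOI of diameter d + 6.5 mm (this caps `spike_length` at
3.25 mm).

Real lungs provide connected tubular clutter around nodules; the package
substitutes a seeded recursive branching tree of capsules (per-level radius
and length decay, random branching angles within a configured range). It
plays the same statistical role — connected distractor structure that can
touch a nodule — without requiring patient data, and is bit-reproducible
per seed. It does not reproduce real airway/vessel anatomy, so tests passing
on it say nothing about anatomical realism, only about the measurement
chain.

Each nodule's *reference mask* is its exact digital shape plus any vessel
voxels 26-connected to it inside its VOI, mirroring what a segmenter
operating in that VOI can at best recover. Reference masks are single
26-connected components by construction.

## Acquisition model

Imaging is emulated purely in the image domain: convolution with a
separable Gaussian PSF, linear resampling to the reconstruction voxel size,
then optional i.i.d. Gaussian noise (in that order — noise lives in the
reconstruction domain). A system is characterised by its measured MTF
cutoff, inverted in closed form: σ = sqrt(−ln L / (2π²f²)) for MTF level L
at frequency f. The three presets are matched at the 50% cutoff (6.7, 6.1,
11.0 LP/cm for `ct`, `hrct`, `spcct`). A single Gaussian cannot match a
measured 50% and 10% cutoff pair whose ratio differs from
sqrt(ln 10 / ln 2) ≈ 1.82, and real reconstruction-filter MTFs are not
Gaussian, so the presets reproduce the 50% point exactly and the 10% point
only approximately; σ can instead be matched at the 10% cutoff where that
is the quantity of interest. Through-plane blur defaults to one slice
FWHM (σ_z = slice / 2.355). Projection physics, reconstruction filters,
photon statistics and spectral binning are out of scope.

Resampling preserves the physical field of view (whole voxel cells) to
within one voxel and keeps the voxel-centre convention: coordinates are
0-based indices, voxel (i,j,k) centred at origin + (i,j,k)·spacing, units mm
throughout.

## Wire phantom and MTF estimation

The wire renderer computes, per pixel, the exact area fraction covered by
the wire disk (piecewise-analytic chord integration with Gauss–Legendre
quadrature between branch points). Point sampling would alias badly — a
100 µm wire on a 130 µm grid can land entirely between pixel centres.

Rendering a sub-pixel wire *directly at the reconstruction pitch* is
still irreducibly aliased: the area-sampled disk spectrum extends far beyond
the sampling Nyquist, and the folded content (which depends on the wire's
sub-pixel position) perturbs a subsequent MTF estimate by a few percent for
a 100 µm wire at 0.13 mm pixels. `simulate_wire_acquisition` therefore
renders the wire on a grid 9× finer, blurs there (effectively continuum
resolution), and resamples to the reconstruction grid — the same
fine-phantom → blur → resample pattern as the lung simulation, and the
physically correct order (a scanner never has a pixelised intermediate
object). With an odd supersampling factor every output voxel centre lies on
a fine-grid node, so the final resampling is pure decimation.

Estimation chain: average slices → locate the wire (half-maximum centroid,
refined by iterating an intensity-weighted centroid inside a symmetric
circular window, which removes the lattice bias of thresholding) → subtract
the mean background outside 10 wire diameters → radial profile in
quarter-pixel bins → order-0 Hankel transform → finite-wire correction →
normalisation → cutoffs by linear interpolation on a 0–40 LP/cm grid in
0.1 LP/cm steps.

Two numerical choices matter at the percent level:

- *Bin abscissas.* Each radial bin is reported at the mean radius of its
  pixels, not the bin centre: near the centre the lattice provides only a
  few discrete radii, and bin-centre placement misassigns them by up to
  half a bin, biasing the transform's high-frequency end.
- *Quadrature.* For image-derived profiles the Hankel integral uses annular
  weights `n_bin · pixel_area` (equal to the 2-D Riemann sum over the pixel
  lattice), which is exact for a band-limited radial field; the trapezoidal
  rule over the sparse, irregular lattice radii loses several percent at
  high frequency. Analytic profiles (no pixel counts) use the trapezoidal
  rule with an r = 0 sample added by even quadratic extrapolation.

An optional square-pixel aperture correction (division by the angularly
averaged transform of the pixel aperture, exact for a radially averaged
measurement by the same argument as the wire correction) is provided for
images formed by area integration directly on the analysis grid; it is off
by default because `simulate_wire_acquisition` output is point-sampled
after continuum blurring. The absolute value of the Hankel output is taken
before normalisation, following the convention that a reported MTF is
non-negative. Profiles are truncated at the image's inscribed circle; a
tail above 5% of the peak triggers a truncation warning, as does a wire
correction evaluated at the disk transform's first null (those frequencies
are dropped).

With these choices the full chain recovers the analytic cutoff of a
noiseless Gaussian-blurred wire to well within 1% for both wire sizes and
all tested widths, at any sub-pixel wire position (see
`tests/test_acceptance.py` and `scripts/acceptance.py`).

## Segmentation

Two-cluster 1-D k-means is written out explicitly because its determinism
is part of the contract: Lloyd iteration initialised at the intensity
extremes, assignment by nearest centre (equivalently a midpoint split in
1-D), threshold reported as the midpoint of the final cluster means,
foreground the brighter cluster. This makes segmentation reproducible and
order-independent, and shift-equivariant by construction. Connectivity is
26-neighbourhood; where the centre voxel itself is background, the nearest
foreground voxel within one voxel is used, else the result is empty (valid,
logged). The triplicate repetition perturbs the centre by a uniform offset
within ± one voxel per axis (repeat 1 unperturbed), standing in for the
observer variability of manually selected centres of mass; downstream
volumes and Dice values average the repeats.

## Registration and statistics

Masks are compared on a common 0.14 mm isotropic grid (cubic interpolation
of the 0/1 field, re-binarised at 0.5 — the threshold choice for every mask
interpolation in the package). Rotation angles either come from
configuration or from a bounded search (±10° in 2° steps per axis); the
search runs as per-axis coordinate descent with two sweeps rather than the
full 11³ grid, which evaluates ~66 instead of ~1300 candidates and always
includes the identity. Translation is the integer shift maximising the 2-D
cross-correlation of the axial mid-slices, with ties broken toward the
smallest shift; the through-plane shift comes from 1-D correlation of
per-slice voxel counts and is applied first so the mid-slices correspond (an
extension — mid-slice correlation alone cannot fix z). A final guard keeps
the transformed mask only if it does not lower Dice, so registration never
hurts by construction.

Volumes are voxel counts × voxel volume. Regression is ordinary least
squares (statsmodels) with classical 95% t-intervals; RMSE is the root mean
squared residual. Bland–Altman limits are Δ ± 1.96δ with δ the n−1 sample
SD (used everywhere). The paired t-test is two-tailed with n−1 df; the KS
normality check standardises the differences and tests against N(0,1),
i.e. shape only — a Lilliefors-style correction is deliberately not
applied, and this interpretation is a documented choice.

## Default experiment and what it shows

The shipped scene holds six nodules (3/6/9 mm × sphere/spiked) on a 3 × 2
layout with 16 mm pitch in a 48 × 32 × 18 mm block at 0.08 mm — fine enough
that every reconstruction grid subsamples it, and small enough that the
whole study (three profiles, triplicate segmentation, registration, two
wire sizes) runs in about a minute on one CPU. All randomness derives from
one root seed through named CRC-based substreams, so a config reproduces
byte-identically.

On this scene the package asserts *directions*, not magnitudes: the
sharpest profile has the highest mean Dice; Dice rises with nodule size
within every profile; Bland–Altman mean differences are negative; regression
slopes are below 1. Physical-scanner magnitudes (RMSE in tens of mm³,
Dice means of 0.85–0.90) arise from manufacturing tolerances, positioning,
noise and non-Gaussian reconstruction filters that this image-domain
emulation does not model, so matching them is explicitly not a goal.

## Known limitations

- A single Gaussian PSF per system; measured 50%/10% cutoff pairs of real
  filters are not jointly matched.
- Noise is white Gaussian; CT noise is correlated and non-stationary.
- The vessel tree is statistical clutter, not anatomy; HU are piecewise
  constant before blur.
- Mask re-binarisation at 0.5 after interpolation loses sub-voxel detail;
  self-registration of a rotated voxelised shape plateaus near Dice 0.99.
- The z-translation handling in registration is an extension beyond
  mid-slice correlation and assumes roughly aligned slice stacks.
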