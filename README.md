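# pulmoct

Digital lung-phantom simulation and resolution analysis for pulmonary CT.

Small lung nodules sit at the edge of what clinical CT can resolve: whether a
6 mm lesion looks smooth or spiculated, and how accurately its volume can be
measured, depends directly on the scanner's in-plane resolution. `pulmoct` is
a library for studying that dependence end to end without a scanner. It
provides:

- **a digital lung phantom**: a powder-filled lung background (≈ −580 HU, an
  air-like −875 HU is configurable), a seeded procedural vessel tree, and
  parametric nodules in [−130, −90] HU — plain spheres (benign-style) and
  spheres with conical spikes (malignant-style) of 3, 6 and 9 mm;
- **an image-domain acquisition simulator**: each system is a Gaussian PSF
  whose width σ is set from a measured MTF cutoff via
  MTF(f) = exp(−2π²σ²f²), followed by resampling to the system's
  reconstruction voxel size and optional additive noise. Presets `ct`,
  `hrct` and `spcct` encode 50% cutoffs of 6.7, 6.1 and 11.0 LP/cm with
  0.13 × 0.13 × 0.625 mm (CT, HR-CT) and 0.13 × 0.13 × 0.25 mm (SPCCT)
  reconstruction grids;
- **nodule segmentation**: spherical VOI of diameter d + 1.5 mm (spheres) or
  d + 6.5 mm (spiked), two-cluster 1-D k-means thresholding, removal of
  components not 26-connected to the centre, repeated three times with a
  seeded centre perturbation;
- **rigid mask registration** to the digital reference (cubic upsampling to
  0.14 mm isotropic, rotation search, mid-slice cross-correlation shift) and
  **concordance statistics**: Dice = 2|A∩B|/(|A|+|B|), OLS volume regression
  with 95% CIs, Bland–Altman limits of agreement Δ ± 1.96δ, paired t-tests,
  KS normality check;
- **wire-phantom MTF estimation**: radial averaging around a thin wire,
  order-0 Hankel transform MTF(f) = |2π ∫ p(r) J₀(2πfr) r dr|, finite-wire
  (Nickoloff) correction by 2J₁(πdf)/(πdf), normalisation, and interpolated
  50%/10% cutoffs in LP/cm.

## Worked example

`examples/measure_mtf.py` images a 100 µm wire through a Gaussian system
whose true 50% cutoff is 11.0 LP/cm and recovers it:

```
Gaussian PSF sigma: 0.1704 mm (50% MTF at 11.0 LP/cm)
estimated 50% cutoff: 10.98 LP/cm  (true 11.00)
estimated 10% cutoff: 20.00 LP/cm  (true 20.05 for a Gaussian)
```

`examples/full_experiment.py` runs the whole six-nodule study (≈ 1 min):

```
Dice (mean of 3 repeats), nodule x profile:
               ct   hrct  spcct
3mm_sphere  0.921  0.912  0.960
3mm_spiked  0.868  0.862  0.922
6mm_sphere  0.961  0.961  0.980
6mm_spiked  0.939  0.937  0.967
9mm_sphere  0.969  0.966  0.981
9mm_spiked  0.964  0.965  0.977

Bland-Altman mean difference and limits of agreement (mm^3):
  profile  mean_diff_mm3  sd_diff_mm3  loa_low_mm3  loa_high_mm3
0      ct          -1.45         5.58       -12.39          9.48
1    hrct          -1.89         6.40       -14.43         10.66
2   spcct          -0.06         1.93        -3.85          3.72
```

Reading these numbers: the sharpest system (`spcct`) scores the highest Dice
for every nodule, Dice falls with nodule size within every profile, mean
volume differences are negative (blur plus thresholding loses a little
volume), and regression slopes sit just below 1 — the qualitative signature
of resolution-limited volumetry. The magnitudes are properties of this
synthetic scene, not of any physical scanner.

Other examples: `simulate_and_segment.py` (triplicate segmentation of one
nodule), `register_and_dice.py` (recovering a constructed rigid transform).

A thin CLI mirrors the library: `pulmoct run`, `build-phantom`, `simulate`,
`segment`, `register`, `evaluate`, `mtf` (see `pulmoct --help`).

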