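# Methods

This note documents the models, parameter choices and numerical conventions
of `dbpet-denoise`, and what the synthetic experiments do and do not show.

## Phantom and acquisition model

A phantom is a half-ellipsoidal breast attached to the chest-wall (row 0)
edge of the in-plane grid — the geometry of a prone breast hanging into a
ring detector — containing fibroglandular and fat tissue and optional
spherical lesions. Axis 0 of every volume is the axial (slice) direction.

* **Grid**: default 236×132 pixels at 0.78 mm isotropic voxels, the matrix
  of the clinical protocol this package emulates. The scaled-down
  experiment uses 64×64×40.
* **Tissue SUVs**: fibroglandular 1.18 (the typical background SUVmean of
  breast FDG-PET), fat 0.40 (a common fat uptake level; the exact value
  only needs to sit well below gland). The gland/fat pattern is a seeded
  Gaussian random field (default correlation length 3 mm; 5 mm in the
  scaled-down config so the blobs stay resolvable on the coarse grid)
  thresholded so that `gland_fraction` of the breast is gland. This gives
  background texture for ROI statistics without anatomical modelling.
* **Lesions**: uniform-SUV spheres ("focus" ≤ 10 mm, moderately avid;
  "mass" larger and hotter, SUVmax distributions centred at 2.84 ± 0.85 and
  12.61 ± 8.05 respectively, mixed ≈ 27 % / 73 %). No partial-volume blur
  by default (`edge_blur_mm` adds one). Random placement is
  clearance-aware: a distance transform of the breast mask guarantees the
  sphere fits, an in-plane margin guarantees the 10 mm SUVpeak circle of
  any lesion voxel stays on the grid, and a ≈ 3-voxel separation buffer
  keeps the measurement VOIs of distinct lesions disjoint. On small grids
  the upper mass diameter is clamped to the largest hostable size.
* **Noise**: scaled Poisson counts per voxel,
  `λ = SUV × minutes × s(z) × κ`, divided back by the scale factor. The
  simulated image is therefore unbiased for the activity, its CV scales as
  `1/√duration`, and it is noisier where the axial sensitivity `s(z)` is
  low. `κ` (`counts_per_suv_min`) defaults to 15.0, chosen once so a
  7-minute gland acquisition has voxel CV ≈ 9 %
  (`1/√(1.18·7·15) = 0.090`), the noise scale of a clinical full-count
  reference image; it is a calibration default, not a fit.
* **Axial sensitivity**: `s(z) = edge_min + (1 − edge_min)·sin(πz/(n−1))`
  (default), or a linear tent. 1 at the axial centre, `edge_min` (default
  0.3) at the first/last slice, symmetric and monotone. The real scanner's
  profile is not published; `edge_min` and the profile shape are free
  parameters, not estimates of any device.
* **Noise correlation**: none by default (independent voxels). Real
  reconstructed PET noise is spatially correlated;
  `noise_smoothing_mm > 0` smooths the noise field as a rough emulation.
  This is a knob, not a claim.

What the simulator does **not** model: list-mode data, iterative
reconstruction, scatter, attenuation, partial-volume effects, anatomy.
Passing tests therefore demonstrate that the pipeline recovers the right
orderings under duration-scaled, edge-elevated Poisson noise — not that it
would achieve any particular performance on clinical scans.

## Filters

* **Gaussian**: separable convolution with `σ = FWHM/(2√(2 ln 2)·voxel)`,
  unit-sum sampled kernel, default FWHM 1.17 mm. Applied in 3D by default
  (common PET post-smoothing practice; the protocol does not specify 2D vs
  3D), with a 2D in-plane option.
* **NLM**: slice-wise 2D, 3×3 patches compared over a 5×5 search window,
  weights `exp(−D²/h²)` where `D²` is the patch-size-normalised squared
  patch distance (a Gaussian-weighted patch distance is available as an
  option). The strength `h` is the pooled sample SD of the background
  fibroglandular ROIs of the low-count image — the simplest reproducible
  reading of "SD of the background tissue". The centre pixel's weight is
  its literal distance-zero value of 1 by default (`self_weight_rule =
  "self"`); the max-of-neighbours convention is available.
* **Boundaries**: whole-sample mirror padding (`np.pad(..., "reflect")`)
  for the NLM filter; scipy's reflect mode for the Gaussian. The protocol
  is silent on boundary handling.
* **SD convention**: sample SD (n−1 denominator) everywhere in the package.

## Residual denoiser

`n_conv_layers` (default 5) same-size convolutions with odd kernels
(default 15×15). Hidden layers have `n_filters` channels (default 128)
followed by batch normalization (eps 1e-5, momentum 0.1) and channel-wise
PReLU (initial slope 0.25); the final convolution projects to one channel
with no activation and its output is added to the input. The source
architecture leaves the output layer's width ambiguous ("128 filters per
layer" cannot end in a 1-channel image); this package uses
(n−1) hidden layers × n_filters plus a 1-filter projection.

Design contracts:

* **Identity at initialization**: the final convolution is zero-initialized
  (other layers seeded He-normal), so before training
  `denoise_volume(model, v) == v` to ≤ 1e-6 SUV. This makes the epochs=0
  pipeline a strict no-op — a testable baseline.
* **Raw SUV inputs**: slices are fed without rescaling by default; an
  optional per-slice max-normalization switch is recorded in the config.
* **Air-only slices are kept** in training (a flag can drop them).
* **Fully convolutional**: any slice size is accepted at inference even if
  training used another size.
* **Training**: MSE to the paired FC slice, Adam (lr 0.001, β 0.9/0.999),
  batch 16, shuffled by a seeded generator; validation split
  `round(val_fraction · n)` at slice level (at study scale, 10 % of 7,080
  slices is exactly 708). Minibatches of fewer than 2 samples are skipped
  (batch statistics are undefined). Inference uses running BN statistics
  and is deterministic.
* **Implementation**: the network is a self-contained numpy module
  (`dbpet.nn`) with FFT-domain convolution — for 15×15 kernels the Fourier
  route is far cheaper than patch extraction — and hand-written
  backpropagation, verified against finite differences and a direct
  convolution loop in the test suite. Float32 arithmetic throughout.

## Evaluation protocol

* **ROI placement** is automated and seeded (clinically it is manual):
  background ROIs are 8 mm circles fully inside gland tissue (pixel centre
  within radius defines membership — the pixelization of "8 mm diameter" is
  otherwise unstated), avoiding lesions; edge ROIs are rectangles whose
  near edge is exactly 5 px from the chest-wall image edge, confined to
  tissue. Each set uses n distinct slices with pairwise gap ≥ 5; a random
  greedy search with a deterministic fallback raises a descriptive error
  when the geometry is infeasible.
* **Edge ROIs and the axial noise profile**: the noise elevation is axial
  (slice-wise sensitivity) while the rectangles are anchored in-plane at
  the chest-wall edge. So that edge ROIs actually sample the noisy region,
  eligible slices are restricted to the first/last `edge_slice_fraction`
  of the axial range (default 20 %). On the 40-slice scaled grid the
  5-ROI / gap-5 protocol is only geometrically feasible with a wider band
  and a smaller rectangle, hence the scaled config's 6×16 px rectangles
  and 35 % band.
* **SUVmax** ties are broken toward the lowest (slice, row, col); the
  **SUVpeak** circle (10 mm) must fit on the grid or the measurement is an
  error, never silently clipped.
* **Bland–Altman**: bias = mean of `d`, and the protocol's "variance" —
  1.96 × SD of `d` — is labelled `limits` to avoid ambiguity.
* **Paired tests**: two-sided paired t or Wilcoxon signed-rank (scipy),
  Bonferroni-adjusted `min(1, m·p)` with m supplied by the pipeline
  (default 4 target-vs-reference comparisons); all-zero differences are
  flagged degenerate and non-significant rather than erroring.
* **MIP**: pixelwise maximum along the craniocaudal (axial) or mediolateral
  (column) axis; display maps SUV 0–4 to inverse grayscale.

## Scaled-down experiment

The default experiment is sized to run end-to-end in about two minutes on
one CPU: 64×64 slices, 40 slices/phantom, 8 training + 4 test phantoms
(≈ 320 training slices), 2 lesions per phantom, 16 filters, 7×7 kernels,
15 epochs. Train/test separation is at phantom level, mirroring
patient-level separation. The reference set applies the same 1.17 mm
Gaussian to the FC volume. Paper-scale settings (236×132, 128 filters,
15×15, 100 epochs, 15+13 phantoms) are available via `full_scale_config()`
and are intended for workstation runs.

All randomness flows from explicit named seeds (simulate / train / rois /
lesions); reruns with the same config are bit-identical, including CSV
outputs.

## Known limitations

* The phantom is geometric, not anatomical; absolute CV and bias values
  depend on the calibration `κ` and the sensitivity profile, which are
  package defaults rather than device measurements. Only orderings and
  scaling laws are meaningful.
* Uncorrelated voxel noise makes the NLM and Gaussian filters look better
  relative to clinical behaviour than they would on reconstructed noise.
* SUVpeak of small lesions is dominated by background dilution (the 10 mm
  circle is larger than a focus lesion), so peak agreement across image
  sets is noisier than SUVmax agreement — visible in the wide SUVpeak
  limits of the example runs.
* The numpy training loop is single-threaded CPU code; paper-scale training
  is possible but slow (hours, not minutes).
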