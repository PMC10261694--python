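# dbpet-denoise

Denoising for ring-type **dedicated breast PET (dbPET)** images acquired in
about half the usual emission time, using a large-kernel **residual
convolutional network**, with the conventional Gaussian and non-local-means
(NLM) post-filters as comparators and a full ROI / SUV / Bland–Altman
evaluation protocol. Because clinical scans are not redistributable, the
package ships a synthetic paired-acquisition phantom simulator that
reproduces the two noise behaviours the evaluation depends on: voxel noise
that shrinks with acquisition duration, and noise that rises toward the
axial edge of the field of view (FOV).

The package is aimed at researchers in PET image processing who want a
self-contained, reproducible re-implementation of this denoising and
evaluation pipeline that runs on one CPU.

## The model

Paired acquisitions of the same breast are simulated from a noise-free
activity map `a` (in SUV units): for duration `t` minutes and axial
sensitivity `s(z) ∈ (0, 1]`, each voxel draws

```
counts ~ Poisson(a · t · s(z) · κ),     image = counts / (t · s(z) · κ)
```

with calibration `κ` (counts per SUV-minute), so the image is unbiased for
`a` with voxel variance `a / (t · s(z) · κ)` — a 3-minute low-count (LC)
scan is `√(7/3) ≈ 1.53×` noisier than the 7-minute full-count (FC) scan.

The denoiser is a residual CNN: five same-size convolutions with 15×15
kernels (128 filters in the hidden layers), each hidden layer followed by
batch normalization and PReLU, a final 1-channel projection, and an
input-to-output skip connection, so the network learns the residual
`FC − LC`. It is trained slice-wise with mean squared error and Adam
(learning rate 0.001, batch size 16, 10 % of slices reserved for
validation). The final layer is zero-initialized, so the untrained network
is exactly the identity map.

Evaluation follows the clinical protocol: background coefficient of
variation `CV = σ / SUVmean × 100 (%)` from five 8 mm circular ROIs per
breast, edge-of-FOV CV from five 10×30-pixel rectangles placed 5 pixels
from the chest-wall image edge (each set on slices ≥ 5 apart), lesion
`SUVmax` over a 3D volume of interest and `SUVpeak` (mean of a fixed 10 mm
circle centred at the maximum), relative differences
`d = (SUVtgt − SUVref)/SUVref × 100 (%)` against the Gaussian-smoothed FC
reference, Bland–Altman bias (mean of `d`) and limits (1.96 × SD of `d`),
and Bonferroni-corrected paired t / Wilcoxon signed-rank tests.

## Worked example

`examples/05_full_experiment.py` runs the whole scaled-down experiment
(64×64 slices, 40 slices per phantom, 8 training + 4 test phantoms, 16
filters, 7×7 kernels, 15 epochs — a few minutes on one CPU):

```
$ python examples/05_full_experiment.py
Image-set evaluation (mean +/- SD over background ROIs)

  LC           SUVmean  1.185 +/- 0.018   background CV  15.34 +/-  2.30 %
  LC+Gaussian  SUVmean  1.165 +/- 0.025   background CV   5.89 +/-  1.96 %
  LC+NLM       SUVmean  1.182 +/- 0.015   background CV   6.90 +/-  2.68 %
  LC+DL        SUVmean  1.174 +/- 0.017   background CV   5.75 +/-  1.66 %
  FC+Gaussian  SUVmean  1.161 +/- 0.025   background CV   4.65 +/-  2.19 %
  ...
Background-noise ranking (lowest CV first):
  FC+Gaussian < LC+DL < LC+Gaussian < LC+NLM < LC

SUVmax agreement with the noise-free truth:
  LC    bias +16.64 %
  LC+DL bias +10.80 %  (closer to zero: the network suppresses the
                        noise-driven overestimate of SUVmax)
```

The five image sets mirror the clinical comparison: the raw low-count scan
(LC), its Gaussian- and NLM-filtered versions, the network output (LC+DL)
and the Gaussian-smoothed full-count reference. Training cuts the
background CV of the LC set by more than half — ranking LC+DL lowest among
the LC-derived sets — and moves lesion SUVmax closer to the noise-free
truth, the synthetic analogue of the clinical finding. The other example scripts exercise one capability each:
simulation, the two filters, training, and lesion measurement.

A thin CLI wraps the same functions: `dbpet simulate`, `dbpet filter`,
`dbpet train`, `dbpet denoise`, `dbpet run` (see `dbpet --help`).

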