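# dstripe

Removal of per-slice multiplicative intensity artefacts ("venetian blind"
stripes) from 4D diffusion MRI, using a small constrained convolutional
network trained without ground truth.

## The problem

Interleaved multiband EPI can leave neighbouring slices of a diffusion MRI
volume with inconsistent intensities — spin-history and slice-timing effects
modulate each slice by an unknown multiplicative factor. The artefact is
correlated within each temporally contiguous excitation block (here:
interleave 3, so slices *i* with *i* mod 3 = τ share a block), varies with
position, b-value and gradient direction, and is easily confused with genuine
anatomical through-plane contrast, which is one to two orders of magnitude
larger than the artefact. Target users are researchers processing multi-shell
neonatal or adult dMRI who see residual stripe patterns after motion
correction.

## The method

For each 3D volume S the network f<sub>Θ</sub> estimates a strictly positive
multiplicative field F on the grid of S; S ⊙ F is the corrected volume. The
architecture (18,109 trainable parameters) constrains F by construction:

* a **dynamic range constraint** T ↦ 2·σ(T) + 10⁻⁴ bounds the field logits to
  [1.0001, 2.0001] (σ is the logistic sigmoid; the preceding ReLU makes the
  input non-negative);
* in-plane, resolution is pooled down to a 16×16 grid, Gaussian-smoothed
  (σ = 1.5 voxels) in the log domain and bilinearly upsampled — the field is
  inherently smooth in-plane;
* through-plane, a high-pass (log-domain subtraction of a σ = 1 voxel Gaussian
  during training; an FFT Butterworth filter at inference) removes
  low-frequency field components, because slowly varying "modulations" cannot
  be distinguished from anatomy.

Training is self-supervised on volumes reoriented by random dihedral
transformations d (so each anatomical axis serves as the slice axis with
probability 1/3) and corrupted with simulated stripes m drawn from the
interleave-correlated distribution (mᵢ ~ N(μ<sub>τ</sub>, σ<sub>τ</sub>²),
squared, normalised to unit geometric mean; σ<sub>τ</sub>² = 0.05,
μ<sub>τ</sub> ~ U(0.9, 1.1)):

* along axes assumed stripe-free (AP, LR):
  J = J<sub>aug</sub> + J<sub>const</sub>, the masked MSE of undoing the
  simulated stripes plus the masked MSE of leaving clean data unchanged;
* along the acquisition axis (IS), where real stripes may be present, a
  Monte-Carlo **SURE** (Stein's Unbiased Risk Estimator) loss
  J<sub>SURE</sub> = (1/n<sub>M</sub>)‖S<sub>d,m</sub> − f<sub>Θ</sub>(S<sub>d,m</sub>)‖²<sub>M</sub> − σ² + (2σ²/n<sub>M</sub>)·|ρ|,
  with the divergence ρ estimated by a finite difference along a calibrated
  stripe-shaped perturbation P: ρ = ⟨P ⊙ (f<sub>Θ</sub>(S<sub>d,m</sub>+εP) −
  f<sub>Θ</sub>(S<sub>d,m</sub>))/ε⟩<sub>M</sub>, ε = 10⁻³.

At inference the field is refined iteratively,
F<sub>i+1</sub> ← h<sub>z</sub>(F<sub>i</sub> ⊙ f<sub>Θ</sub>(S ⊙ F<sub>i</sub>)),
where h<sub>z</sub> blends frequency bands with a brain-mask-derived
attention map and divides out the through-plane Butterworth low-pass
component (order 4, cutoff 21/32 of Nyquist — just below the interleave-3
stripe frequency at 2/3 Nyquist), followed by a final in-plane low-pass
(order 3, cutoff 2/32) against upsampling artefacts.

Stripiness is quantified by band-wise ℓ2-norms of real symmetric spherical
harmonics ‖S‖<sub>ℓ</sub> = √(Σ<sub>m</sub> (c<sub>ℓ</sub><sup>m</sup>)²),
local standard deviation in 1D patches of 7 voxels along each axis, and
diffusion-tensor fit residuals; estimated fields can be rank-reduced to
per-shell geometric means F<sub>b,x,y,z</sub> and per-slice factors
F<sub>b,z</sub>.

No GPU framework is required: the network, its gradients and the Adam/
triangular-learning-rate training loop are implemented directly on numpy.

## Worked example

```sh
dstripe simulate --out-prefix work/ph --seed 5 --shape 48 48 32
dstripe train --image work/ph.nii.gz --bvec work/ph.bvec --bval work/ph.bval \
              --mask work/ph_mask.nii.gz --checkpoint work/ckpt.zip \
              --epochs 40 --seed 3
dstripe apply --image work/ph.nii.gz --bvec work/ph.bvec --bval work/ph.bval \
              --mask work/ph_mask.nii.gz --checkpoint work/ckpt.zip \
              --out work/corrected.nii.gz --save-field work/field.nii.gz
dstripe metrics --image work/corrected.nii.gz --bvec work/ph.bvec \
              --bval work/ph.bval --mask work/ph_mask.nii.gz --out work/report.tsv
```

`simulate` writes a three-shell phantom (b = 0/1000/2600 s/mm², 8 volumes)
with known per-slice modulation factors in `ph_truth.tsv`, e.g.

```
volume	slice	factor
0	0	0.4465443131
0	1	0.6409009586
0	2	1.264341979
```

— slice 0 of volume 0 was dimmed to ~45%, slice 1 to ~64%, slice 2
brightened to ~126% (factors are squared normal draws, so occasional strong
outliers are expected).
`apply` writes the corrected series plus `corrected.nii.gz.field.tsv` with
the per-slice geometric mean of the estimated field; values above 1 brighten
a slice, values below 1 dim it, and multiplying each slice's truth factor by
its estimated field factor should move the product toward 1 for the
high-frequency part of the stripe pattern. `metrics` reports the masked mean
local SD per axis, shell and harmonic band (through-plane values drop after
correction while in-plane values stay put) and per-shell RMS diffusion-tensor
fit residuals. Every command writes a `*.provenance.json` sidecar recording
the seed and configuration.

## Layout

* `src/dstripe/dwi_io.py` — NIfTI/bvec/bval I/O, shell grouping, normalisation
* `src/dstripe/simulate.py` — stripe simulation, dihedral augmentation, phantoms
* `src/dstripe/layers.py`, `network.py` — numpy layer primitives with
  hand-written gradients; the constrained architecture
* `src/dstripe/training.py` — losses (incl. MC-SURE), Adam, LR schedule, loop
* `src/dstripe/inference.py` — iterative field updates, FFT filters, attention
* `src/dstripe/metrics.py` — SH band norms, local SD, DT fit, field reductions
* `src/dstripe/cli.py` — the `dstripe` command
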