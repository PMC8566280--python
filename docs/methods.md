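# Methods

## Model

Slice artefacts are modelled as a per-volume multiplicative field: the
observed volume is S = U ⊙ M where U is the artefact-free image and M a
field that is (i) strictly positive, (ii) smooth in-plane, and (iii)
dominated by high through-plane frequencies. The estimator returns F ≈ 1/M
so that S ⊙ F recovers U. Assumption (iii) is load-bearing: a slowly varying
through-plane modulation is unidentifiable from anatomy, so the method
*by design* does not attempt to recover it — both the training-time
log-domain Gaussian high-pass (σ = 1 voxel) and the inference-time
Butterworth step (h_z, order 4, cutoff 21/32 of Nyquist) remove sub-cutoff
field content. The cutoff sits just below the interleave-3 stripe
fundamental at 2/3 of Nyquist, so block-correlated stripe patterns pass
while anatomy-scale modulations are blocked.

The corrected image enters three losses. Along axes the data can be assumed
stripe-free (after dihedral reorientation), supervision is synthetic:
simulated stripes are applied and must be undone (J_aug) while clean inputs
must pass unchanged (J_const). Along the acquisition axis ground truth is
unavailable; an MC-SURE surrogate treats the simulated augmentation as the
noise process, with σ estimated as the masked SD of the augmentation change
and the divergence estimated by a finite difference along a calibrated
stripe-shaped perturbation. The SURE identity assumes i.i.d. homoscedastic
additive Gaussian noise; the stripe corruption is multiplicative and
structured, so the loss is a practically motivated surrogate rather than an
unbiased risk estimate. We keep the |ρ| clamp on the divergence term, which
bounds the loss from below.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| DRC scale / offset | 2.0 / 1e-4 | — | output range [1.0001, 2.0001] on the rectified domain |
| in-plane field grid | 16×16 | — | sets the spatial rank of the field in-plane |
| in-plane Gaussian | σ=1.5, 9×9×1 | voxels | fixed log-domain smoother inside the network |
| through-plane Gaussian | σ=1, 1×1×9 | voxels | training-time high-pass (subtracted blur); removed at inference |
| b1 Butterworth | order 4, cutoff 21/32, pad 17 | Nyquist=1, voxels | through-plane band split in h_z |
| final in-plane Butterworth | order 3, cutoff 2/32, pad 24 | Nyquist=1, voxels | kills bilinear-upsampling harmonics |
| F_lp,3D | σ=(5,5,11) | voxels | low-frequency background for attention blending |
| attention | 13 dilations, σ=9 in-plane, σ=3 z | voxels | mask-derived [0,1] weights gating high frequencies |
| modulation | interleave 3, στ²=0.05, μτ∼U(0.9,1.1) | — | stripe simulation; factors squared, unit geometric mean |
| schedule | Adam, batch 1, triangular LR [1,5]×10⁻⁴, 80 it/half-cycle | — | |
| SURE ε | 1e-3 | — | finite-difference step; one MC sample by default |
| normalisation | 0.99 percentile, joint per dataset | — | per-volume variant behind a flag |
| shell tolerance | 100 | s/mm² | gap threshold for shell grouping |

## Numerical choices

* **No GPU framework.** The network, all constraint layers and the full
  backward pass are implemented on numpy (depthwise convolutions via
  `scipy.ndimage.correlate`, z-dilation via z-decimation; weight gradients by
  explicit 27-offset reductions). Gradients are verified against central
  finite differences to ~1e-6 relative in float64; training runs in float32.
* **DRC form.** 2/(1+e^(−T)) + 10⁻⁴ — the unique sigmoid consistent with the
  stated output range on a rectified input.
* **Layers 10/11** are pointwise 1×1×1 convolutions (their parameter counts
  force this reading).
* **Pooling.** The first ConcatPool uses non-overlapping 2×2×1 windows (odd
  trailing rows dropped); adaptive pooling uses equal-as-possible contiguous
  bins; bilinear upsampling maps bin centres to voxel centres with constant
  extrapolation beyond the outer centres.
* **Batch normalisation** (batch of one) normalises per channel over the
  spatial extent; running statistics (momentum 0.1) are used at evaluation
  and are excluded from the trainable-parameter count.
* **Frequency conventions.** "Normalised frequency" means Nyquist = 1;
  Butterworth "padding" is a per-side edge-replication pad, which preserves
  constants exactly (DC gain 1). The final in-plane filter operates on log F,
  keeping the field positive.
* **Degenerate inputs.** Exact zeros in the modulation sampler are re-drawn;
  a perturbation modulation m̂ ≡ 1 is rejected (zero SD); all-zero datasets
  cannot be normalised; empty masks are rejected; slices without mask
  support give NaN in per-slice field summaries.
* **Determinism.** All sampling flows through one `numpy.random.Generator`;
  identical seeds give bit-identical phantoms, training logs and outputs.

## What the synthetic phantom does and does not emulate

The phantom is piecewise-smooth positive "anatomy" (Gaussian blobs) inside
an ellipsoidal mask, attenuated per shell (defaults 1.0/0.35/0.15 at
b = 0/1000/2600 s/mm², echoing the shell contrast of neonatal multi-shell
data), optionally modulated by a fixed-axis second-order angular profile,
plus additive Gaussian noise (σ = 0.01 of the b0 plateau, reflecting
complex-domain-denoised data). Stripes are applied per volume along z with
the interleave-correlated distribution above; the clean twin and the exact
factors are returned as ground truth.

Not emulated: spin-history physics, multiband unmixing, motion, Rician
bias, EPI distortion, and realistic white-matter orientation structure.
Passing the phantom tests therefore demonstrates that the estimator recovers
interleave-correlated multiplicative slice modulations superimposed on
smooth anatomy — not that it handles motion-scattered stripe patterns or
tissue-dependent artefact physics in vivo.

## Desk-scale experiment sizes

The recovery experiment trains on one 48×48×32 three-shell phantom
(2/3/3 volumes per shell) for 30 epochs — 240 iterations, about one and a
half triangular LR cycles, roughly ten minutes on one CPU — and evaluates on one
held-out phantom with independent stripes, using three inference
iterations. The full-scale regime this stands in for (20 datasets of 300 volumes at 99×99×64,
500 epochs) is three to four orders of magnitude more compute.

## Known limitations

* The through-plane band split caps what is recoverable: with the simulated
  modulation distribution, only ~14% of the stripe log-variance lies above
  the b1 cutoff (the within-block component is spectrally white, while the
  filter passes only the top third of the band). Slice-profile correlated,
  band-limited real artefacts are better matched to the filter than this
  worst-case white component. Consequences for the recovery statistics are
  quantified in the acceptance tests.
* Per-slice field summaries assume the slice axis is the third voxel axis
  after any reorientation (the CLI `--axis` flag handles the rest).
* Training assumes roughly isotropic grids (≥ 32 voxels per axis) so that
  dihedral reorientation keeps the in-plane extent large enough for the
  pooling stack.
* Source-space (per-excitation) destriping, which requires an external
  motion-correction/reconstruction framework, is out of scope; correction is
  applied in the reconstructed anatomical frame.
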