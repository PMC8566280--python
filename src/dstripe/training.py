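"""Self-supervised training of the destripe network.

Each training sample is one volume S_o, reoriented by a random dihedral
element d (stratified so every anatomical axis serves as the network slice
axis with probability 1/3) and corrupted along the new slice axis with a
simulated interleave-correlated modulation m: S_dm = d(S_o) ⊙ m.

The loss depends on which anatomical axis became the slice axis:

* AP or LR origin — the data can be assumed stripe-free along that axis, so
  supervision is direct:  J = J_aug + J_const with
  J_aug   = (1/n_M) ‖d(S_o) − f(S_dm)‖²_M   (undo the simulated stripes)
  J_const = (1/n_M) ‖d(S_o) − f(d(S_o))‖²_M (leave clean data alone)

* IS origin — real stripes may be present, so ground truth is unavailable;
  an MC-SURE surrogate is used instead:
  J_SURE = (1/n_M) ‖S_dm − f(S_dm)‖²_M − σ² + (2σ²/n_M)·|ρ|
  with σ the masked SD of the augmentation change S_dm − d(S_o), and ρ a
  Monte-Carlo divergence estimate from a calibrated stripe-structured
  perturbation P:  ρ = ⟨P ⊙ (f(S_dm + εP) − f(S_dm))/ε⟩_M.

Throughout, f denotes the corrected image S ⊙ F(S) (input times the
network field).  Optimisation: Adam, batch size 1, triangular cyclical
learning rate between 1e-4 and 5e-4 with 80 iterations per half-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi_io import BrainMask, DWIDataset, group_shells
from .network import DStripeNet, NetworkConfig
from .simulate import (
    DihedralElement,
    ModulationConfig,
    SliceModulation,
    apply_dihedral,
    apply_modulation,
    sample_dihedral,
    sample_modulation,
)

__all__ = [
    "TrainConfig",
    "LossTerms",
    "TrainingSample",
    "Adam",
    "lr_schedule",
    "corrected",
    "loss_aug",
    "loss_const",
    "sure_sigma",
    "perturbation",
    "rho_sure",
    "loss_sure",
    "select_loss",
    "make_training_sample",
    "train",
]

AXIS_NAMES = ("LR", "AP", "IS")  # anatomical label of original axes 0,1,2


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and hyper-parameters."""

    epochs: int = 500
    lr_low: float = 1e-4
    lr_high: float = 5e-4
    lr_half_cycle: int = 80  # iterations per half-cycle
    volumes_per_shell: int = 10
    percentile: float = 0.99
    sure_epsilon: float = 1e-3
    sure_samples: int = 1  # MC samples for the divergence
    seed: int = 0
    modulation: ModulationConfig = field(default_factory=ModulationConfig)

    def __post_init__(self):
        if not self.lr_low < self.lr_high:
            raise ValueError("learning-rate bounds must be ordered")
        if self.sure_epsilon <= 0:
            raise ValueError("SURE step ε must be positive")


@dataclass
class LossTerms:
    """Per-iteration loss bookkeeping (signal² units; σ in signal units)."""

    recipe: str  # 'aug+const' or 'sure'
    j_aug: float = np.nan
    j_const: float = np.nan
    j_sure: float = np.nan
    sigma_sure: float = np.nan
    rho_sure: float = np.nan

    @property
    def total(self) -> float:
        if self.recipe == "sure":
            return self.j_sure
        return self.j_aug + self.j_const


@dataclass
class TrainingSample:
    """One augmented training instance."""

    S_o: np.ndarray  # original volume (untransformed)
    d: DihedralElement
    m: SliceModulation
    S_d: np.ndarray  # d(S_o)
    S_dm: np.ndarray  # d(S_o) ⊙ m along network z
    mask: np.ndarray  # d-transformed brain mask
    slice_axis_origin: str  # 'AP' | 'LR' | 'IS'


def lr_schedule(iteration: int, low: float = 1e-4, high: float = 5e-4, half_cycle: int = 80) -> float:
    """Triangular cyclical learning rate; period is two half-cycles."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    phase = iteration % (2 * half_cycle)
    frac = phase / half_cycle
    if frac > 1.0:
        frac = 2.0 - frac
    return low + (high - low) * frac


class Adam:
    """Adaptive-moment gradient descent over a network's parameter list."""

    def __init__(self, net: DStripeNet, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in net.parameters()}
        self.v = {name: np.zeros_like(p) for name, p, _ in net.parameters()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p, g in self.net.parameters():
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# -- loss building blocks --------------------------------------------------


def corrected(net: DStripeNet, S: np.ndarray, train: bool = True, return_cache: bool = False):
    """Corrected image f(S) = S ⊙ F(S)."""
    if return_cache:
        F, cache = net.forward(S, train=train, return_cache=True)
        return S * F, (S, cache)
    return S * net.forward(S, train=train)


def _masked_mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    nM = int(mask.sum())
    if nM == 0:
        raise ValueError("empty mask")
    diff = (a - b)[mask]
    return float(np.dot(diff, diff) / nM)


def loss_aug(net: DStripeNet, sample: TrainingSample) -> float:
    """Masked MSE between d(S_o) and the network-corrected augmented image."""
    return _masked_mse(sample.S_d, corrected(net, sample.S_dm), sample.mask)


def loss_const(net: DStripeNet, sample: TrainingSample) -> float:
    """Masked MSE penalising any change to the (stripe-free) original."""
    return _masked_mse(sample.S_d, corrected(net, sample.S_d), sample.mask)


def sure_sigma(S_dm: np.ndarray, S_d: np.ndarray, mask: np.ndarray) -> float:
    """Masked population SD of the signal change due to augmentation."""
    nM = int(mask.sum())
    if nM < 2:
        raise ValueError("need at least 2 masked voxels")
    diff = (S_dm - S_d)[mask]
    return float(diff.std())


def perturbation(S_dm: np.ndarray, m_hat: SliceModulation, mask: np.ndarray, axis: int = 2) -> np.ndarray:
    """Calibrated stripe-structured perturbation with unit masked SD.

    P = (S_dm ⊙ m̂ − S_dm) / SD(S_dm ⊙ m̂ − S_dm)_M for an independent draw
    m̂ from the stripe modulation distribution.
    """
    delta = apply_modulation(S_dm, m_hat, axis=axis) - S_dm
    sd = float(delta[mask].std())
    if sd == 0.0:
        raise ValueError("degenerate perturbation modulation (m̂ ≡ 1)")
    return delta / sd


def rho_sure(
    f, S_dm: np.ndarray, P: np.ndarray, mask: np.ndarray, epsilon: float = 1e-3
) -> float:
    """Monte-Carlo divergence contraction ⟨P ⊙ (f(S_dm+εP) − f(S_dm))/ε⟩_M.

    ``f`` maps a volume to a corrected volume.  For a linear map v ↦ a·v the
    estimate is exact (a·‖P‖²_M) for any ε; for smooth nonlinear maps it
    converges first-order in ε to the true divergence contraction.
    """
    if epsilon <= 0:
        raise ValueError("ε must be positive")
    resp = (f(S_dm + epsilon * P) - f(S_dm)) / epsilon
    return float((P * resp)[mask].sum())


def loss_sure(S_dm: np.ndarray, f_S_dm: np.ndarray, sigma: float, rho: float, mask: np.ndarray) -> float:
    """MC-SURE loss: data term − σ² + (2σ²/n_M)·|ρ| (ρ clamped via |·|)."""
    nM = int(mask.sum())
    data = _masked_mse(S_dm, f_S_dm, mask)
    return data - sigma**2 + (2.0 * sigma**2 / nM) * abs(rho)


def select_loss(sample: TrainingSample) -> str:
    """AP/LR slice-axis origin → 'aug+const'; IS origin → 'sure'."""
    return "sure" if sample.slice_axis_origin == "IS" else "aug+const"


def make_training_sample(
    volume: np.ndarray, mask: np.ndarray, cfg: TrainConfig, rng: np.random.Generator
) -> TrainingSample:
    """Reorient a volume with a stratified dihedral element and add stripes."""
    d = sample_dihedral(rng)
    S_d = apply_dihedral(volume, d).copy()
    mask_d = apply_dihedral(mask, d).copy()
    m = sample_modulation(S_d.shape[2], cfg.modulation, rng)
    S_dm = apply_modulation(S_d, m, axis=2)
    return TrainingSample(
        S_o=volume,
        d=d,
        m=m,
        S_d=S_d,
        S_dm=S_dm,
        mask=mask_d,
        slice_axis_origin=AXIS_NAMES[d.slice_axis_origin],
    )


# -- gradient computation per recipe ---------------------------------------


def _step_aug_const(net: DStripeNet, sample: TrainingSample) -> LossTerms:
    """Forward+backward for the supervised recipe; grads accumulate in net."""
    mask = sample.mask
    nM = int(mask.sum())
    maskf = mask.astype(net.dtype)

    c_aug, (S1, cache1) = corrected(net, sample.S_dm, train=True, return_cache=True)
    c_const, (S2, cache2) = corrected(net, sample.S_d, train=True, return_cache=True)
    j_aug = _masked_mse(sample.S_d, c_aug, mask)
    j_const = _masked_mse(sample.S_d, c_const, mask)

    # d/dc of (1/nM)‖S_d − c‖²_M = (2/nM)(c − S_d)·M ; dc/dF = S
    d_aug = (2.0 / nM) * (c_aug - sample.S_d) * maskf * S1
    d_const = (2.0 / nM) * (c_const - sample.S_d) * maskf * S2
    net.backward(d_aug.astype(net.dtype), cache1)
    net.backward(d_const.astype(net.dtype), cache2)
    return LossTerms(recipe="aug+const", j_aug=j_aug, j_const=j_const)


def _step_sure(net: DStripeNet, sample: TrainingSample, cfg: TrainConfig, rng: np.random.Generator) -> LossTerms:
    """Forward+backward for the MC-SURE recipe; grads accumulate in net."""
    mask = sample.mask
    nM = int(mask.sum())
    maskf = mask.astype(net.dtype)
    eps = cfg.sure_epsilon
    sigma = sure_sigma(sample.S_dm, sample.S_d, mask)

    c0, (S0, cache0) = corrected(net, sample.S_dm, train=True, return_cache=True)

    rho_total = 0.0
    pert_caches = []
    for _ in range(cfg.sure_samples):
        m_hat = sample_modulation(sample.S_dm.shape[2], cfg.modulation, rng)
        P = perturbation(sample.S_dm, m_hat, mask)
        S_pert = sample.S_dm + eps * P
        c1, (S1, cache1) = corrected(net, S_pert, train=True, return_cache=True)
        rho_k = float((P * (c1 - c0) / eps)[mask].sum())
        rho_total += rho_k
        pert_caches.append((P, S1, cache1))
    rho = rho_total / cfg.sure_samples

    j = loss_sure(sample.S_dm, c0, sigma, rho, mask)

    # gradient wrt c0: data term + divergence term (through both passes)
    sgn = np.sign(rho) if rho != 0 else 0.0
    coeff = (2.0 * sigma**2 / nM) * sgn / (eps * cfg.sure_samples)
    d_c0 = (2.0 / nM) * (c0 - sample.S_dm) * maskf
    for P, S1, cache1 in pert_caches:
        d_c1 = coeff * P * maskf
        net.backward((d_c1 * S1).astype(net.dtype), cache1)
        d_c0 = d_c0 - d_c1
    net.backward((d_c0 * S0).astype(net.dtype), cache0)
    return LossTerms(recipe="sure", j_sure=j, sigma_sure=sigma, rho_sure=rho)


# -- training loop ----------------------------------------------------------


def _select_volumes(ds: DWIDataset, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """min(volumes_per_shell, available) volumes per shell, without replacement."""
    shells = group_shells(ds.gradients)
    chosen = []
    for s in range(shells.n_shells):
        vols = shells.volumes_in_shell(s)
        k = min(cfg.volumes_per_shell, len(vols))
        chosen.extend(rng.choice(vols, size=k, replace=False))
    if not chosen:
        raise ValueError("no volumes available after shell sampling")
    return np.asarray(sorted(chosen))


def train(
    datasets: list[tuple[DWIDataset, BrainMask]],
    cfg: TrainConfig = TrainConfig(),
    net: DStripeNet | None = None,
    progress: bool = False,
    checkpoint_dir=None,
    checkpoint_every: int = 0,
) -> tuple[DStripeNet, list[dict]]:
    """Train the destripe network; deterministic given ``cfg.seed``.

    Returns the trained network and a per-iteration loss log (dicts with
    iteration, recipe, J values, σ/ρ and learning rate).  With
    ``checkpoint_every`` = N > 0 a checkpoint archive is written to
    ``checkpoint_dir`` every N epochs.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    from .network import MIN_INPLANE

    for ds, _ in datasets:
        if min(ds.spatial_shape) < MIN_INPLANE:
            raise ValueError(
                f"training volumes must be ≥ {MIN_INPLANE} voxels along every axis "
                f"(dihedral augmentation rotates the slice axis in-plane); got {ds.spatial_shape}"
            )
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = DStripeNet(NetworkConfig(mode="train"), seed=int(rng.integers(2**31)))
    opt = Adam(net)

    # normalise each dataset jointly over its selected volumes
    pools = []
    for ds, bm in datasets:
        vols = _select_volumes(ds, cfg, rng)
        norm, _ = percentile_normalize_volumes(ds, vols, cfg.percentile)
        pools.append((norm, bm.mask, vols))

    log: list[dict] = []
    iteration = 0
    epoch_iter = range(cfg.epochs)
    if progress:
        from tqdm import tqdm

        epoch_iter = tqdm(epoch_iter, desc="train", unit="epoch")
    for epoch in epoch_iter:
        order = []
        for di, (sig, _, vols) in enumerate(pools):
            order.extend((di, vi) for vi in range(sig.shape[3]))
        rng.shuffle(order)
        for di, vi in order:
            sig, mask, _ = pools[di]
            sample = make_training_sample(sig[..., vi], mask, cfg, rng)
            lr = lr_schedule(iteration, cfg.lr_low, cfg.lr_high, cfg.lr_half_cycle)
            net.zero_grad()
            if select_loss(sample) == "sure":
                terms = _step_sure(net, sample, cfg, rng)
            else:
                terms = _step_aug_const(net, sample)
            opt.step(lr)
            log.append(
                {
                    "iteration": iteration,
                    "epoch": epoch,
                    "recipe": terms.recipe,
                    "j_aug": terms.j_aug,
                    "j_const": terms.j_const,
                    "j_sure": terms.j_sure,
                    "sigma_sure": terms.sigma_sure,
                    "rho_sure": terms.rho_sure,
                    "lr": lr,
                }
            )
            iteration += 1
        if checkpoint_every and checkpoint_dir is not None and (epoch + 1) % checkpoint_every == 0:
            from pathlib import Path

            d = Path(checkpoint_dir)
            d.mkdir(parents=True, exist_ok=True)
            net.save(d / f"epoch{epoch + 1:04d}.zip")
    return net, log


def percentile_normalize_volumes(ds: DWIDataset, vols: np.ndarray, percentile: float):
    """Joint percentile normalisation restricted to the selected volumes."""
    sig = ds.signal[..., vols]
    scale = float(np.quantile(sig, percentile))
    if scale <= 0:
        raise ValueError("percentile intensity is non-positive")
    return sig / scale, scale
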