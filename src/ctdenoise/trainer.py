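"""Reference denoising harness: a small residual CNN trained with a
configurable loss (per-pixel MAE baseline, WPLoss, HFLoss or the
hybrid).

The network is deliberately small — about five 3x3 convolution layers
with ReLU activations that predict the *noise residual*, so the output
is ``input - predicted_noise`` — because the subject of this package is
the loss function, not the architecture.  Forward and backward passes
are written directly in NumPy (im2col convolutions, analytic loss
gradients from :mod:`ctdenoise.losses`), and optimization follows the
reference protocol: Adam with beta1=0.5, beta2=0.9, learning rate
halved every 50 epochs, all kernels initialized from N(0, 0.01^2).

Patch weights of WPLoss enter the gradient as detached constants — the
gradient of the adaptive loss equals the gradient of the loss with
weights frozen at their current values, which is how the per-region
gradient modulation is realized without literal gradient masking.

Training runs in the normalized pixel domain; evaluation metrics are
computed in HU.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .imaging_core import (
    CTImage,
    Domain,
    NormalizationStats,
    denormalize,
    normalize,
    read_image,
)
from .losses import (
    FrequencyMask,
    HybridConfig,
    hf_loss,
    hf_loss_grad,
    hybrid_loss,
    hybrid_loss_grad,
    make_highpass_mask,
    wp_loss,
    wp_loss_grad,
)
from .metrics import psnr, ssim

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "DenoiserCNN",
    "PairedDataset",
    "build_denoiser",
    "train",
    "denoise",
    "ablation_run",
    "LOSS_VARIANTS",
]

LOSS_VARIANTS = ("mae", "wp", "hf", "hybrid")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

_OFFSETS = [(dy, dx) for dy in range(3) for dx in range(3)]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, H, W) -> (C*9, H*W) patch matrix for 3x3 same-padding conv."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = np.empty((c, 9, h, w))
    for k, (dy, dx) in enumerate(_OFFSETS):
        cols[:, k] = xp[:, dy : dy + h, dx : dx + w]
    return cols.reshape(c * 9, h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    c, h, w = shape
    dcols = dcols.reshape(c, 9, h, w)
    dxp = np.zeros((c, h + 2, w + 2))
    for k, (dy, dx) in enumerate(_OFFSETS):
        dxp[:, dy : dy + h, dx : dx + w] += dcols[:, k]
    return dxp[:, 1:-1, 1:-1]


class DenoiserCNN:
    """Residual denoiser: ``output = input - residual_net(input)``.

    ``n_layers`` 3x3 convolutions (1 -> channels -> ... -> 1) with ReLU
    between them.  Gaussian(0, init_std^2) kernel init, zero biases.
    """

    def __init__(self, seed: int = 0, init_std: float = 0.01, channels: int = 32, n_layers: int = 5):
        if n_layers < 2:
            raise ValueError("need at least 2 conv layers")
        rng = np.random.default_rng(seed)
        dims = [1] + [channels] * (n_layers - 1) + [1]
        self.weights = [
            rng.normal(0.0, init_std, size=(dims[i + 1], dims[i], 3, 3))
            for i in range(n_layers)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(n_layers)]
        self.channels = channels
        self.n_layers = n_layers

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = self.n_layers
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]

    def checksum(self) -> float:
        return float(sum(np.sum(p**2) for p in self.parameters()))

    def save(self, path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(str(path), channels=self.channels, n_layers=self.n_layers, **arrays)

    @classmethod
    def load(cls, path) -> "DenoiserCNN":
        data = np.load(str(path))
        model = cls(channels=int(data["channels"]), n_layers=int(data["n_layers"]))
        model.weights = [data[f"w{i}"] for i in range(model.n_layers)]
        model.biases = [data[f"b{i}"] for i in range(model.n_layers)]
        return model

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (H, W) normalized image -> (H, W) denoised image."""
        h, w = x.shape
        act = x[None]  # (1, H, W)
        cache = []
        for i, (W_, b) in enumerate(zip(self.weights, self.biases)):
            cols = _im2col(act)
            pre = (W_.reshape(W_.shape[0], -1) @ cols + b[:, None]).reshape(-1, h, w)
            if want_cache:
                cache.append((cols, act.shape, pre))
            act = np.maximum(pre, 0.0) if i < self.n_layers - 1 else pre
        residual = act[0]
        out = x - residual
        return (out, cache) if want_cache else out

    def backward(self, grad_out: np.ndarray, cache) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of a scalar loss w.r.t. parameters.

        ``grad_out`` is dLoss/dOutput; since output = input - residual,
        dLoss/dResidual = -grad_out.
        """
        h, w = grad_out.shape
        d_act = -grad_out[None]  # gradient w.r.t. last pre-activation
        dW: list[np.ndarray] = [None] * self.n_layers
        db: list[np.ndarray] = [None] * self.n_layers
        for i in range(self.n_layers - 1, -1, -1):
            cols, in_shape, pre = cache[i]
            if i < self.n_layers - 1:
                d_act = d_act * (pre > 0)  # ReLU mask
            d_flat = d_act.reshape(d_act.shape[0], -1)
            dW[i] = (d_flat @ cols.T).reshape(self.weights[i].shape)
            db[i] = d_flat.sum(axis=1)
            if i > 0:
                dcols = self.weights[i].reshape(self.weights[i].shape[0], -1).T @ d_flat
                d_act = _col2im(dcols, in_shape)
        return dW, db


def build_denoiser(seed: int = 0, init_std: float = 0.01, channels: int = 32, n_layers: int = 5) -> DenoiserCNN:
    """Construct the reference residual denoiser (deterministic per seed)."""
    return DenoiserCNN(seed=seed, init_std=init_std, channels=channels, n_layers=n_layers)


# ---------------------------------------------------------------------------
# Loss dispatch
# ---------------------------------------------------------------------------


class _LossFn:
    """Loss value + gradient for one generated/target pair (normalized)."""

    def __init__(self, name: str, config: HybridConfig):
        if name not in LOSS_VARIANTS:
            raise ValueError(f"unknown loss variant {name!r}; choose from {LOSS_VARIANTS}")
        self.name = name
        self.config = config
        self._mask_cache: dict[tuple[int, int], FrequencyMask] = {}

    def _mask(self, shape) -> FrequencyMask:
        if shape not in self._mask_cache:
            self._mask_cache[shape] = make_highpass_mask(
                shape, self.config.cutoff_fraction, self.config.filter_kind
            )
        return self._mask_cache[shape]

    def __call__(self, g: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.config
        if self.name == "mae":
            diff = g - t
            return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size
        if self.name == "wp":
            value, _ = wp_loss(g, t, cfg.weight_config)
            return value, wp_loss_grad(g, t, cfg.weight_config)
        if self.name == "hf":
            # HFLoss is blind below the cutoff, so on its own it leaves the
            # low-frequency content unconstrained; like the published
            # ablations it is trained on top of the per-pixel baseline.
            mask = self._mask(g.shape)
            diff = g - t
            value = float(np.mean(np.abs(diff))) + cfg.alpha2 * hf_loss(
                g, t, mask, cfg.hf_distance
            )
            grad = np.sign(diff) / diff.size + cfg.alpha2 * hf_loss_grad(
                g, t, mask, cfg.hf_distance
            )
            return value, grad
        report = hybrid_loss(g, t, cfg)
        return report.hybrid_loss, hybrid_loss_grad(g, t, cfg)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class PairedDataset:
    """In-memory NDCT/LDCT pairs split into train/val/test."""

    train: list[tuple[CTImage, CTImage]]
    val: list[tuple[CTImage, CTImage]]
    test: list[tuple[CTImage, CTImage]]
    stats: NormalizationStats

    @classmethod
    def from_manifest(cls, data_dir: str | Path) -> "PairedDataset":
        """Load pairs listed in ``data_dir/manifest.json``.

        Normalization stats are dataset-level, over the training NDCT
        images.
        """
        data_dir = Path(data_dir)
        manifest = json.loads((data_dir / "manifest.json").read_text())
        splits: dict[str, list] = {"train": [], "val": [], "test": []}
        for entry in manifest["entries"]:
            ndct = read_image(data_dir / entry["ndct"])
            ldct = read_image(data_dir / entry["ldct"])
            splits[entry["split"]].append((ndct, ldct))
        if not splits["train"]:
            raise ValueError("dataset has an empty training split")
        stats = NormalizationStats.from_images([p[0] for p in splits["train"]])
        return cls(train=splits["train"], val=splits["val"], test=splits["test"], stats=stats)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol of the reference harness.

    Adam(beta1=0.5, beta2=0.9), learning rate halved every
    ``lr_halving_interval`` epochs, Gaussian(0, init_std^2) kernel
    init.  ``loss`` selects the variant; ``hybrid_config`` carries the
    loss hyperparameters.
    """

    loss: str = "hybrid"
    hybrid_config: HybridConfig = field(default_factory=HybridConfig)
    learning_rate: float = 1e-4
    lr_halving_interval: int = 50
    epochs: int = 25
    batch_size: int = 4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    init_std: float = 0.01
    channels: int = 32
    n_layers: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in LOSS_VARIANTS:
            raise ValueError(f"unknown loss variant {self.loss!r}")


@dataclass
class TrainHistory:
    """Per-epoch curves plus the trained model."""

    train_loss: list[float]
    val_loss: list[float]
    val_psnr: list[float]
    val_ssim: list[float]
    model: DenoiserCNN


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: lr halves every ``lr_halving_interval`` epochs
    (0-based epoch index; epoch 100 under 50-epoch halving runs at lr/4)."""
    return config.learning_rate * 0.5 ** (epoch // config.lr_halving_interval)


class _Adam:
    def __init__(self, params: list[np.ndarray], beta1: float, beta2: float, eps: float = 1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _normalized_pairs(pairs, stats) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (normalize(ldct, stats).pixels, normalize(ndct, stats).pixels)
        for ndct, ldct in pairs
    ]


def train(model: DenoiserCNN, dataset: PairedDataset, config: TrainConfig) -> TrainHistory:
    """Train ``model`` in place on the dataset's training split.

    Returns per-epoch training loss, validation loss and validation
    PSNR/SSIM (computed in HU).  Fully reproducible given
    ``config.seed``.
    """
    if not dataset.train:
        raise ValueError("empty training split")
    loss_fn = _LossFn(config.loss, config.hybrid_config)
    stats = dataset.stats
    train_pairs = _normalized_pairs(dataset.train, stats)
    val_pairs = _normalized_pairs(dataset.val, stats) if dataset.val else []

    params = model.parameters()
    opt = _Adam(params, config.adam_beta1, config.adam_beta2)
    rng = np.random.default_rng(config.seed)

    hist = TrainHistory([], [], [], [], model)
    n = len(train_pairs)
    for epoch in range(config.epochs):
        lr = learning_rate_at(config, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = [np.zeros_like(p) for p in params]
            for idx in batch:
                x, y = train_pairs[idx]
                out, cache = model.forward(x, want_cache=True)
                value, grad_out = loss_fn(out, y)
                epoch_losses.append(value)
                dW, db = model.backward(grad_out, cache)
                for acc, g in zip(grads, dW + db):
                    acc += g
            for g in grads:
                g /= len(batch)
            opt.step(params, grads, lr)
        hist.train_loss.append(float(np.mean(epoch_losses)))

        if val_pairs:
            v_losses, v_psnr, v_ssim = [], [], []
            for (x, y), (ndct, ldct) in zip(val_pairs, dataset.val):
                out = model.forward(x)
                v_losses.append(loss_fn(out, y)[0])
                den = denormalize(CTImage(out, Domain.NORMALIZED, ndct.pixel_spacing), stats)
                v_psnr.append(psnr(den, ndct))
                v_ssim.append(ssim(den, ndct))
            hist.val_loss.append(float(np.mean(v_losses)))
            hist.val_psnr.append(float(np.mean(v_psnr)))
            hist.val_ssim.append(float(np.mean(v_ssim)))
        else:
            hist.val_loss.append(float("nan"))
            hist.val_psnr.append(float("nan"))
            hist.val_ssim.append(float("nan"))
    return hist


def denoise(model: DenoiserCNN, ldct: CTImage, stats: NormalizationStats) -> CTImage:
    """normalize -> forward -> denormalize; returns an HU image."""
    x = normalize(ldct, stats)
    out = model.forward(x.pixels)
    return denormalize(x.with_pixels(out), stats)


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------


def ablation_run(
    dataset: PairedDataset,
    base_config: TrainConfig,
    variants: tuple[str, ...] = LOSS_VARIANTS,
    out_csv: str | Path | None = None,
) -> list[dict]:
    """Train one model per loss variant (shared seed and data) and
    evaluate PSNR/SSIM on the test split.

    Returns rows ``{variant, psnr_mean, psnr_std, ssim_mean, ssim_std,
    n_test}`` and optionally writes them as CSV.
    """
    if not dataset.test:
        raise ValueError("empty test split")
    rows = []
    for variant in variants:
        config = replace(base_config, loss=variant)
        model = build_denoiser(config.seed, config.init_std, config.channels, config.n_layers)
        history = train(model, dataset, config)
        p_vals, s_vals = [], []
        for ndct, ldct in dataset.test:
            out = denoise(model, ldct, dataset.stats)
            p_vals.append(psnr(out, ndct))
            s_vals.append(ssim(out, ndct))
        rows.append(
            {
                "variant": variant,
                "psnr_mean": float(np.mean(p_vals)),
                "psnr_std": float(np.std(p_vals)),
                "ssim_mean": float(np.mean(s_vals)),
                "ssim_std": float(np.std(s_vals)),
                "n_test": len(p_vals),
                "train_loss_first": history.train_loss[0],
                "train_loss_last": history.train_loss[-1],
            }
        )
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows
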