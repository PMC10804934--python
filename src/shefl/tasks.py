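"""The two training recipes: volumetric phantom segmentation and 512-d
feature-bag biomarker classification.

Segmentation: 4-channel volumes are percentile-clipped and min-max normalized,
augmented (crop, flips with p=0.4, power-law intensity rescale with gain and
exponent uniform on 0.8-1.2, additive Gaussian noise sigma=0.03) and fed to a
3-D U-Net trained with the soft Dice loss, Adam at lr 1e-4, single-volume
batches.

Classification: per-patient bags of tile feature vectors inherit the patient's
binary label (weak labels), classes are equalized by random undersampling, and
a four-layer fully connected network is trained with cross-entropy, Adam at
lr 4e-5, batches of 124.  Patient-level scores are the mean of tile
positive-class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLPClassifier, UNet3D, soft_dice_loss

__all__ = [
    "UNetConfig",
    "MLPConfig",
    "AugmentConfig",
    "SegTrainConfig",
    "ClfTrainConfig",
    "normalize_volume",
    "augment_volume",
    "build_unet",
    "build_mlp",
    "dice_loss",
    "balance_by_undersampling",
    "patient_score",
]


@dataclass(frozen=True)
class UNetConfig:
    """U-Net topology. Reference scale: 4 levels, base 48, 128^3 input;
    default here is a desk-scale instance of the same topology."""

    levels: int = 2
    base_channels: int = 4
    in_channels: int = 4
    out_classes: int = 3
    spatial: tuple[int, int, int] = (16, 16, 16)

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass(frozen=True)
class MLPConfig:
    """Feature classifier: layer widths; last width = number of classes."""

    widths: tuple[int, ...] = (512, 256, 256, 128, 2)


@dataclass(frozen=True)
class AugmentConfig:
    flip_probability: float = 0.4
    gain_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    noise_sigma: float = 0.03
    crop: tuple[int, int, int] | None = None  # None = no crop

    def __post_init__(self):
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip probability must be in [0, 1]")
        for r in (self.gain_range, self.gamma_range):
            if r[0] > r[1]:
                raise ValueError("range must be ordered (lo, hi)")


@dataclass(frozen=True)
class SegTrainConfig:
    lr: float = 1e-4  # Adam, segmentation
    batch_size: int = 1  # single 3-D volume per step
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    use_augmentation: bool = True


@dataclass(frozen=True)
class ClfTrainConfig:
    lr: float = 4e-5  # Adam, feature classifier
    batch_size: int = 124
    balance: bool = True


# ---------------------------------------------------------------------------
# Preprocessing and augmentation
# ---------------------------------------------------------------------------


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Clip above the 99th percentile, shift to zero min, divide by max.

    For 4-D input (channels first) each channel is normalized independently,
    since each channel is a separately acquired image.  Constant input maps to
    all zeros; otherwise the output spans [0, 1].
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.size == 0:
        raise ValueError("empty volume")
    if vol.ndim == 4:
        return np.stack([normalize_volume(c) for c in vol])
    hi = np.percentile(vol, 99)
    clipped = np.minimum(vol, hi)
    shifted = clipped - clipped.min()
    peak = shifted.max()
    if peak == 0:
        return np.zeros_like(shifted)
    return shifted / peak


def augment_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    config: AugmentConfig = AugmentConfig(),
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic training augmentation; volume is (C, D, H, W), mask (D, H, W).

    Order: center-biased random crop, two independent flips (each with the
    configured probability, applied identically to the mask), power-law
    intensity rescale ``I <- g * I**gamma``, additive white Gaussian noise per
    channel.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    vol = np.asarray(volume, dtype=np.float64)
    msk = np.asarray(mask)
    if vol.shape[1:] != msk.shape:
        raise ValueError("volume and mask are not aligned")

    if config.crop is not None:
        cd, ch, cw = config.crop
        D, H, W = msk.shape
        if cd > D or ch > H or cw > W:
            raise ValueError("crop larger than volume")
        # center-biased: offset drawn from a binomial centered on the middle
        offs = []
        for extent, c in zip((D, H, W), (cd, ch, cw)):
            slack = extent - c
            offs.append(rng.binomial(slack, 0.5) if slack else 0)
        od, oh, ow = offs
        vol = vol[:, od:od + cd, oh:oh + ch, ow:ow + cw]
        msk = msk[od:od + cd, oh:oh + ch, ow:ow + cw]

    # medio-lateral and cranio-caudal flips
    for axis in (1, 2):  # volume axes (channel first); mask axis = axis - 1
        if rng.random() < config.flip_probability:
            vol = np.flip(vol, axis=axis + 1)
            msk = np.flip(msk, axis=axis)

    g = rng.uniform(*config.gain_range)
    gamma = rng.uniform(*config.gamma_range)
    vol = g * np.power(np.clip(vol, 0.0, None), gamma)

    if config.noise_sigma > 0:
        vol = vol + rng.normal(0.0, config.noise_sigma, size=vol.shape)

    return np.ascontiguousarray(vol), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def build_unet(config: UNetConfig, seed: int = 0) -> UNet3D:
    """He-initialized volumetric U-Net; raises if the spatial size cannot be
    pooled ``levels - 1`` times."""
    return UNet3D(
        levels=config.levels,
        base_channels=config.base_channels,
        in_channels=config.in_channels,
        out_classes=config.out_classes,
        spatial=config.spatial,
        seed=seed,
    )


def build_mlp(config: MLPConfig, seed: int = 0) -> MLPClassifier:
    """He-initialized fully connected classifier with ReLU activations."""
    return MLPClassifier(widths=config.widths, seed=seed)


def mlp_parameter_count(widths) -> int:
    """sum(in*out + out) over consecutive widths."""
    return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


def dice_loss(pred_probs: np.ndarray, target_onehot: np.ndarray,
              eps: float = 1e-5) -> float:
    """Soft Dice loss over foreground (non-first) classes on probabilities.

    ``1 - mean_c (2 sum(p_c t_c) + eps) / (sum p_c + sum t_c + eps)``.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target_onehot, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    terms = []
    for c in range(1, p.shape[1]):
        num = 2.0 * (p[:, c] * t[:, c]).sum() + eps
        den = p[:, c].sum() + t[:, c].sum() + eps
        terms.append(num / den)
    return 1.0 - float(np.mean(terms))


# ---------------------------------------------------------------------------
# Weak-label bag handling
# ---------------------------------------------------------------------------


def balance_by_undersampling(
    features: np.ndarray, labels: np.ndarray, seed=0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly undersample every class to the minority-class tile count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires at least two classes present")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return features[keep], labels[keep]


def patient_score(tile_probabilities: np.ndarray) -> float:
    """Patient-level score: mean of the tiles' positive-class probabilities."""
    p = np.asarray(tile_probabilities, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty tile bag")
    return float(p.mean())


def one_hot_mask(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """(D, H, W) integer mask -> (1, C, D, H, W) one-hot float array."""
    out = np.zeros((1, n_classes) + mask.shape)
    for c in range(n_classes):
        out[0, c] = mask == c
    return out
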