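"""Synthetic multi-site datasets with controlled heterogeneity.

Two generators stand in for the multi-centre cohorts the protocol is meant to
train on, so every pipeline stage is exercisable without any download:

* ``generate_phantom_site`` — 4-channel 3-D volumes containing an ellipsoidal
  lesion (core + rim) on a constant background, with per-site intensity gain,
  offset, channel-contrast jitter and noise level emulating scanner/site
  variation in multi-site MRI.
* ``generate_feature_site`` — per-patient bags of tile feature vectors with a
  binary patient label, emulating features extracted from histopathology
  tiles: positives are shifted by a class-effect vector on a subset of
  dimensions, and each site adds its own random offset vector (batch effect).

Both are pure functions of (config, site_id, seed).  Per-site parameters are
drawn from (seed, site_id), so a held-out site automatically has gain/offset/
prevalence disjoint from every training site.  Default magnitudes are set so
that single-site models generalize measurably worse to a held-out site than a
model trained on the pooled sites — the regime in which federation helps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomConfig",
    "FeatureBagConfig",
    "PhantomSiteData",
    "FeatureSiteData",
    "ScenarioData",
    "generate_phantom_site",
    "generate_feature_site",
    "partition_scenario",
]

# class-mean intensity per (class, channel): background, rim, core across the
# 4 channels (emulating the four MR sequences' differing tissue contrasts)
_CLASS_MEANS = np.array(
    [
        [0.20, 0.25, 0.30, 0.20],
        [0.55, 0.45, 0.60, 0.70],
        [0.90, 0.80, 0.75, 0.95],
    ]
)


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (16, 16, 16)
    channels: int = 4
    # lesion large enough that foreground is a workable fraction of a 16^3
    # volume — tiny structures put the soft-Dice loss in its vanishing-gradient
    # regime at desk scale
    radius_range: tuple[float, float] = (4.5, 6.5)
    core_fraction: float = 0.7  # core radii as a fraction of lesion radii
    patients_per_site: int = 6
    test_patients: int = 12
    gain_range: tuple[float, float] = (0.7, 1.3)
    offset_range: tuple[float, float] = (-0.1, 0.1)
    noise_sigma_range: tuple[float, float] = (0.02, 0.06)
    contrast_jitter: float = 0.35  # per-channel scaling of class contrasts

    def __post_init__(self):
        if self.radius_range[1] * 2 >= min(self.shape):
            raise ValueError("lesion radius does not fit inside the volume")
        if self.gain_range[0] <= 0:
            raise ValueError("gains must be positive")


@dataclass(frozen=True)
class FeatureBagConfig:
    dim: int = 512
    tiles_per_patient: int = 150
    n_active: int = 32  # dimensions carrying the class effect
    effect_size: float = 0.12  # shift per active dimension for positives
    site_offset_scale: float = 0.30  # sd of the per-site batch-effect vector
    prevalence: float = 0.5
    patients_per_site: int = 8
    test_patients: int = 60  # held-out cohort size (external test cohorts are
    # typically much larger than any single training site)

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_active > self.dim:
            raise ValueError("n_active cannot exceed the feature dimension")


@dataclass
class PhantomSiteData:
    site_id: int
    volumes: list[np.ndarray]  # each (C, D, H, W)
    masks: list[np.ndarray]  # each (D, H, W), values {0 bg, 1 rim, 2 core}

    @property
    def n_patients(self) -> int:
        return len(self.volumes)


@dataclass
class FeatureSiteData:
    site_id: int
    features: np.ndarray  # (n_patients, tiles_per_patient, dim)
    labels: np.ndarray  # (n_patients,) in {0, 1}

    @property
    def n_patients(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class ScenarioData:
    train_sites: list
    test_site: object
    site_params: list = field(default_factory=list)


def _phantom_site_params(config: PhantomConfig, site_id: int, seed: int):
    rng = np.random.default_rng([int(seed), 1009, int(site_id)])
    gain = rng.uniform(*config.gain_range)
    offset = rng.uniform(*config.offset_range)
    sigma = rng.uniform(*config.noise_sigma_range)
    jitter = rng.uniform(
        1.0 - config.contrast_jitter, 1.0 + config.contrast_jitter,
        size=config.channels,
    )
    return {"gain": gain, "offset": offset, "noise_sigma": sigma, "contrast": jitter}


def generate_phantom_site(
    config: PhantomConfig, site_id: int, seed: int
) -> PhantomSiteData:
    """Generate one site's phantom volumes and voxel label masks.

    Each patient volume contains an ellipsoidal lesion (rim around a core) at
    a random position and size.  Channel intensity = site contrast profile for
    the voxel's class, times the site gain, plus the site offset, plus white
    Gaussian noise at the site's noise level.
    """
    params = _phantom_site_params(config, site_id, seed)
    rng = np.random.default_rng([int(seed), 2003, int(site_id)])
    D, H, W = config.shape
    grid = np.stack(
        np.meshgrid(np.arange(D), np.arange(H), np.arange(W), indexing="ij")
    ).astype(np.float64)

    # site-specific class means: background anchored, contrasts scaled
    base = _CLASS_MEANS[:, : config.channels]
    contrast = params["contrast"][None, :]
    means = base[0:1] + (base - base[0:1]) * contrast
    means = means * params["gain"] + params["offset"]

    volumes, masks = [], []
    for _ in range(config.patients_per_site):
        radii = rng.uniform(*config.radius_range, size=3)
        margin = radii + 1.0
        center = np.array(
            [rng.uniform(m, e - 1 - m) for m, e in zip(margin, (D, H, W))]
        )
        dist = np.sqrt(
            sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        )
        core = dist <= config.core_fraction
        rim = (dist <= 1.0) & ~core
        mask = np.zeros((D, H, W), dtype=np.int64)
        mask[rim] = 1
        mask[core] = 2
        vol = means[mask].transpose(3, 0, 1, 2).astype(np.float64)
        vol = vol + rng.normal(0.0, params["noise_sigma"], size=vol.shape)
        volumes.append(vol)
        masks.append(mask)
    return PhantomSiteData(site_id=site_id, volumes=volumes, masks=masks)


def _feature_site_params(config: FeatureBagConfig, site_id: int, seed: int):
    rng = np.random.default_rng([int(seed), 3001, int(site_id)])
    offset = rng.normal(0.0, config.site_offset_scale, size=config.dim)
    # prevalence jittered around the configured value, clipped to (0.15, 0.85)
    prevalence = float(
        np.clip(config.prevalence + rng.uniform(-0.15, 0.15), 0.15, 0.85)
    )
    return {"offset": offset, "prevalence": prevalence}


def _effect_vector(config: FeatureBagConfig, seed: int) -> np.ndarray:
    """Class-effect direction shared by all sites: delta on n_active dims."""
    rng = np.random.default_rng([int(seed), 4001])
    active = rng.choice(config.dim, size=config.n_active, replace=False)
    v = np.zeros(config.dim)
    v[active] = config.effect_size
    return v


def generate_feature_site(
    config: FeatureBagConfig, site_id: int, seed: int
) -> FeatureSiteData:
    """Generate one site's patient feature bags with weak binary labels.

    Patient label ~ Bernoulli(site prevalence); each tile feature vector
    ~ Normal(site offset + label * effect vector, I).  Every tile inherits its
    patient's label.
    """
    params = _feature_site_params(config, site_id, seed)
    effect = _effect_vector(config, seed)
    rng = np.random.default_rng([int(seed), 5003, int(site_id)])
    n, t, d = config.patients_per_site, config.tiles_per_patient, config.dim
    labels = (rng.random(n) < params["prevalence"]).astype(np.int64)
    # guarantee both classes at desk-scale cohort sizes
    if labels.sum() == 0:
        labels[0] = 1
    elif labels.sum() == n:
        labels[0] = 0
    features = rng.normal(size=(n, t, d)) + params["offset"][None, None, :]
    features += labels[:, None, None] * effect[None, None, :]
    return FeatureSiteData(site_id=site_id, features=features, labels=labels)


def partition_scenario(
    config, n_train_sites: int, seed: int, task: str = "feature-classification"
) -> ScenarioData:
    """Build ``n_train_sites`` training sites plus one held-out test site.

    The test site uses ``site_id = n_train_sites`` and therefore draws its own
    gain/offset/prevalence, disjoint from every training site — an external
    validation cohort in miniature.
    """
    if n_train_sites < 1:
        raise ValueError("need at least one training site")
    if task == "feature-classification":
        gen, pfun = generate_feature_site, _feature_site_params
    elif task == "phantom-segmentation":
        gen, pfun = generate_phantom_site, _phantom_site_params
    else:
        raise ValueError(f"unknown task: {task}")
    from dataclasses import replace as _replace

    train = [gen(config, s, seed) for s in range(n_train_sites)]
    test_cfg = _replace(config, patients_per_site=config.test_patients)
    test = gen(test_cfg, n_train_sites, seed)
    params = [pfun(config, s, seed) for s in range(n_train_sites + 1)]
    return ScenarioData(train_sites=train, test_site=test, site_params=params)


# ---------------------------------------------------------------------------
# On-disk forms: NIfTI volumes, delimited feature tables
# ---------------------------------------------------------------------------


def write_phantom_site(data: PhantomSiteData, out_dir):
    """Write volumes/masks as NIfTI files; returns the written paths."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, (vol, mask) in enumerate(zip(data.volumes, data.masks)):
        # channels-last spatial image, identity affine
        img = nib.Nifti1Image(vol.transpose(1, 2, 3, 0), np.eye(4))
        seg = nib.Nifti1Image(mask.astype(np.int16), np.eye(4))
        vp = os.path.join(out_dir, f"site{data.site_id}_patient{i}_image.nii")
        sp = os.path.join(out_dir, f"site{data.site_id}_patient{i}_mask.nii")
        nib.save(img, vp)
        nib.save(seg, sp)
        paths.extend([vp, sp])
    return paths


def feature_site_to_frame(data: FeatureSiteData):
    """Long-form table: patient_id, tile_id, label, f0..f{dim-1}."""
    import pandas as pd

    n, t, d = data.features.shape
    flat = data.features.reshape(n * t, d)
    frame = pd.DataFrame(flat, columns=[f"f{j}" for j in range(d)])
    frame.insert(0, "patient_id", np.repeat(np.arange(n), t))
    frame.insert(1, "tile_id", np.tile(np.arange(t), n))
    frame.insert(2, "label", np.repeat(data.labels, t))
    return frame


def feature_site_from_frame(frame, site_id: int = 0) -> FeatureSiteData:
    """Inverse of :func:`feature_site_to_frame`."""
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    patients = np.sort(frame["patient_id"].unique())
    feats, labels = [], []
    for p in patients:
        sub = frame[frame["patient_id"] == p].sort_values("tile_id")
        feats.append(sub[fcols].to_numpy(dtype=np.float64))
        labels.append(int(sub["label"].iloc[0]))
    return FeatureSiteData(
        site_id=site_id, features=np.stack(feats), labels=np.asarray(labels)
    )
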