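"""Synthetic cohort generator: group-dependent ROI texture, covariates, cognition.

Each subject receives one volume holding four ellipsoidal hippocampal-
subregion ROIs (left/right x caudal/head; the masks are fixed across
subjects). ROI texture is a smoothed Gaussian random field whose
correlation length (smoothing sigma, in voxels) depends on the diagnostic
group — longer correlation mimics the loss of fine gray-level
heterogeneity — plus a group intensity shift. Covariates follow the
clinical cohort structure the analysis assumes: age and gender are
group-balanced, while MMSE and the four AVLT scores are noisy monotone
transforms of a latent disease severity ordered NC < aMCI < AD.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import (
    MASK_COLUMNS,
    CohortSubject,
    ROIPatch,
    patch_from_arrays,
    save_volume,
)
from .registry import SUBREGIONS

#: Default group sizes follow the discovery cohort the pipeline targets.
DEFAULT_N = {"NC": 45, "aMCI": 33, "AD": 38}
#: Latent severity per group (arbitrary units, NC < aMCI < AD).
SEVERITY = {"NC": 0.0, "aMCI": 1.0, "AD": 2.0}


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Generator knobs. All group-keyed dicts must cover NC, aMCI, AD.

    smoothing_sigma: Gaussian-field correlation length in voxels per group.
    heterogeneity_sd: sd of ROI intensities about the base mean.
    intensity_shift: additive group offset of the ROI mean intensity.
    roi_semi_axes: ellipsoid semi-axes (voxels) per subregion ROI.
    """

    n_per_group: dict[str, int] = dataclasses.field(default_factory=lambda: dict(DEFAULT_N))
    roi_semi_axes: tuple[float, float, float] = (7.0, 5.0, 4.0)
    base_mean: float = 100.0
    heterogeneity_sd: float = 10.0
    smoothing_sigma: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"NC": 1.0, "aMCI": 1.3, "AD": 1.6}
    )
    intensity_shift: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"NC": 0.0, "aMCI": -3.0, "AD": -6.0}
    )
    age_mean: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"NC": 68.2, "aMCI": 70.6, "AD": 71.7}
    )
    age_sd: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"NC": 6.9, "aMCI": 8.2, "AD": 8.3}
    )
    male_fraction: float = 0.5
    #: between-subject variability of the ROI mean (additive, intensity units)
    subject_mean_sd: float = 2.0
    #: between-subject variability of the ROI sd (lognormal sigma)
    subject_sd_jitter: float = 0.1
    mmse_intercept: float = 28.6
    mmse_slope: float = 5.5  # MMSE = intercept - slope * severity + noise
    mmse_noise_sd: float = 1.5
    severity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2, got {n}")
        if min(self.heterogeneity_sd, self.mmse_noise_sd, self.severity_sd,
               self.subject_mean_sd, self.subject_sd_jitter) < 0:
            raise ValueError("all standard deviations must be >= 0")
        if any(s < 0 for s in self.smoothing_sigma.values()):
            raise ValueError("smoothing sigmas must be >= 0")


@dataclasses.dataclass
class SyntheticCohort:
    subjects: list[CohortSubject]
    masks: dict[str, np.ndarray]  # per subregion, within the shared volume grid
    volumes: dict[str, np.ndarray]  # per subject id
    config: CohortConfig


def _ellipsoid(semi: tuple[float, float, float]) -> np.ndarray:
    shape = tuple(int(2 * np.ceil(s)) + 3 for s in semi)
    center = [(n - 1) / 2 for n in shape]
    grids = np.indices(shape)
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return (d2 <= 1.0).astype(np.uint8)


def _layout_masks(config: CohortConfig) -> tuple[dict[str, np.ndarray], tuple[int, int, int]]:
    """Place the four subregion ellipsoids side by side in one volume grid."""
    ell = _ellipsoid(config.roi_semi_axes)
    ex, ey, ez = ell.shape
    pad = 2
    vol_shape = (4 * (ex + pad) + pad, ey + 2 * pad, ez + 2 * pad)
    masks = {}
    for i, sr in enumerate(SUBREGIONS):
        m = np.zeros(vol_shape, dtype=np.uint8)
        x0 = pad + i * (ex + pad)
        m[x0 : x0 + ex, pad : pad + ey, pad : pad + ez] = ell
        masks[sr] = m
    return masks, vol_shape


def _textured_field(
    shape: tuple[int, int, int],
    mask: np.ndarray,
    sigma: float,
    mean: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smoothed white noise rescaled to the requested mean/sd over the ROI.

    The smoothing sigma sets the field's correlation length: larger sigma
    means smoother texture (lower GLCM contrast/entropy). Rescaling uses
    the foreground voxels, so the ROI's marginal moments match the config
    exactly and texture and intensity effects stay separable knobs.
    """
    noise = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(noise, sigma) if sigma > 0 else noise
    fg = field[mask > 0]
    s = fg.std()
    if s > 0:
        field = (field - fg.mean()) / s
    return mean + sd * field


def make_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate an in-memory cohort fully determined by (config, seed)."""
    rng = np.random.default_rng(config.seed)
    masks, vol_shape = _layout_masks(config)
    subjects: list[CohortSubject] = []
    volumes: dict[str, np.ndarray] = {}
    sid_counter = 0
    for group in ("NC", "aMCI", "AD"):
        n = config.n_per_group.get(group, 0)
        for _ in range(n):
            sid = f"S{sid_counter:04d}"
            sid_counter += 1
            severity = SEVERITY[group] + rng.normal(0.0, config.severity_sd)
            age = rng.normal(config.age_mean[group], config.age_sd[group])
            gender = "M" if rng.random() < config.male_fraction else "F"
            mmse = np.clip(
                config.mmse_intercept
                - config.mmse_slope * severity
                + rng.normal(0.0, config.mmse_noise_sd),
                0.0,
                30.0,
            )
            # AVLT subscores: noisy monotone transforms of the same severity,
            # anchored at healthy-control means of the target cohort structure
            avlt_ir = np.clip(5.6 - 1.3 * severity + rng.normal(0, 1.2), 0, 10)
            avlt_dr = np.clip(5.6 - 2.5 * severity + rng.normal(0, 1.5), 0, 10)
            avlt_rp = np.clip(9.4 - 1.6 * severity + rng.normal(0, 1.3), 0, 10)
            avlt_rn = np.clip(9.8 - 1.5 * severity + rng.normal(0, 1.3), 0, 10)

            vol = np.zeros(vol_shape)
            for sr in SUBREGIONS:
                # subject-level jitter of the ROI's marginal moments: real
                # cohorts vary between subjects even within a group
                roi_mean = (
                    config.base_mean
                    + config.intensity_shift[group]
                    + rng.normal(0.0, config.subject_mean_sd)
                )
                roi_sd = config.heterogeneity_sd * np.exp(
                    rng.normal(0.0, config.subject_sd_jitter)
                )
                field = _textured_field(
                    vol_shape,
                    masks[sr],
                    config.smoothing_sigma[group],
                    roi_mean,
                    roi_sd,
                    rng,
                )
                vol = np.where(masks[sr] > 0, field, vol)
            volumes[sid] = vol
            patches = {sr: _patch(vol, masks[sr], sr) for sr in SUBREGIONS}
            cov = pd.Series(
                {
                    "group": group,
                    "age": float(age),
                    "gender": gender,
                    "mmse": float(mmse),
                    "avlt_ir": float(avlt_ir),
                    "avlt_dr": float(avlt_dr),
                    "avlt_rp": float(avlt_rp),
                    "avlt_rn": float(avlt_rn),
                }
            )
            subjects.append(CohortSubject(subject_id=sid, patches=patches, covariates=cov))
    return SyntheticCohort(subjects=subjects, masks=masks, volumes=volumes, config=config)


def _patch(volume: np.ndarray, mask: np.ndarray, label: str) -> ROIPatch:
    return patch_from_arrays(volume, mask, label=label)


def null_cohort(n: int = 10, seed: int = 0, **overrides) -> SyntheticCohort:
    """Cohort with all group effects zero: the three groups are exchangeable.

    Used for type-I-error calibration and permutation-style null checks.
    """
    config = CohortConfig(
        n_per_group={"NC": n, "aMCI": n, "AD": n},
        smoothing_sigma={"NC": 1.0, "aMCI": 1.0, "AD": 1.0},
        intensity_shift={"NC": 0.0, "aMCI": 0.0, "AD": 0.0},
        age_mean={"NC": 70.0, "aMCI": 70.0, "AD": 70.0},
        age_sd={"NC": 7.5, "aMCI": 7.5, "AD": 7.5},
        seed=seed,
        **overrides,
    )
    return make_cohort(config)


def separable_cohort(n: int = 10, seed: int = 0, **overrides) -> SyntheticCohort:
    """Extreme texture + intensity effects: AD vs NC separable in few features."""
    config = CohortConfig(
        n_per_group={"NC": n, "aMCI": n, "AD": n},
        smoothing_sigma={"NC": 0.5, "aMCI": 1.5, "AD": 2.5},
        intensity_shift={"NC": 0.0, "aMCI": -12.0, "AD": -25.0},
        seed=seed,
        **overrides,
    )
    return make_cohort(config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes, the four shared masks, and the manifest CSV.

    Returns the manifest path; the layout matches what ``load_cohort``
    consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sr in SUBREGIONS:
        save_volume(cohort.masks[sr], out_dir / f"mask_{sr}.nii.gz")
    rows = []
    for s in cohort.subjects:
        vol_name = f"{s.subject_id}.nii.gz"
        save_volume(cohort.volumes[s.subject_id], out_dir / vol_name)
        row = {"subject_id": s.subject_id, **s.covariates.to_dict(), "vol_path": vol_name}
        for sr, col in MASK_COLUMNS.items():
            row[col] = f"mask_{sr}.nii.gz"
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
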