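"""Volume/mask I/O and masked bounding-box extraction of ROI patches.

The pipeline consumes spatially pre-aligned T1 volumes (NIfTI-1) plus four
binary hippocampal-subregion masks per subject (left/right x caudal/head).
No registration or reslicing is done here: volume and mask must already
share a grid, and only shape agreement is checked.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .registry import SUBREGIONS

#: Minimum foreground voxels for a usable ROI: 3x3x3 neighbourhood, the
#: smallest region on which 3-D texture statistics are not degenerate.
MIN_ROI_VOXELS = 27

GROUPS = ("NC", "aMCI", "AD")

MASK_COLUMNS = {
    "left_caudal": "mask_lc",
    "left_head": "mask_lh",
    "right_caudal": "mask_rc",
    "right_head": "mask_rh",
}

COVARIATE_COLUMNS = ("group", "age", "gender", "mmse")
AVLT_COLUMNS = ("avlt_ir", "avlt_dr", "avlt_rp", "avlt_rn")


@dataclasses.dataclass(frozen=True)
class IntensityVolume:
    """A 3-D scalar image with voxel spacing (mm) and grid-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D with all dims >= 1, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            raise ValueError(
                f"volume contains a non-finite voxel at index {tuple(int(i) for i in bad[0])}"
            )


@dataclasses.dataclass(frozen=True)
class ROIMask:
    """Binary subregion mask sharing the companion volume's grid."""

    data: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in SUBREGIONS:
            raise ValueError(f"unknown subregion label {self.label!r}; expected one of {SUBREGIONS}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be binary 0/1, found {vals[:5]}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass(frozen=True)
class ROIPatch:
    """Bounding-box crop of a masked subregion.

    ``values`` is the intensity grid cropped to the tight bounding box of
    the mask's foreground; ``mask`` is carried alongside so that every
    downstream statistic is computed over foreground voxels only, never the
    zero-filled background.
    """

    values: np.ndarray
    mask: np.ndarray
    label: str
    n_voxels: int

    def foreground(self) -> np.ndarray:
        """Foreground intensities as a flat array (the analysis sample)."""
        return self.values[self.mask.astype(bool)]


def load_volume(path: str | Path) -> IntensityVolume:
    """Read a NIfTI-1 volume; error on missing file, non-3-D data or NaNs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def load_mask(path: str | Path, label: str) -> ROIMask:
    """Read a binary NIfTI mask; values are binarised by > 0.5."""
    vol = load_volume(path)
    data = (vol.data > 0.5).astype(np.uint8)
    return ROIMask(data=data, label=label)


def save_volume(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def bounding_box(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Tight half-open bounding box [lo, hi) per axis of the foreground."""
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    boxes = []
    for axis in range(mask.ndim):
        proj = mask.any(axis=tuple(a for a in range(mask.ndim) if a != axis))
        idx = np.flatnonzero(proj)
        boxes.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(boxes)


def extract_roi(volume: IntensityVolume, mask: ROIMask) -> ROIPatch:
    """Crop a subregion to its mask's tight bounding box.

    The mask travels with the patch: background voxels inside the box are
    excluded from every downstream statistic, not merely zeroed.
    """
    if volume.data.shape != mask.data.shape:
        raise ValueError(
            f"volume shape {volume.data.shape} does not match mask shape {mask.data.shape}"
        )
    n = mask.n_voxels
    if n == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    if n < MIN_ROI_VOXELS:
        raise ValueError(
            f"mask {mask.label!r} has {n} foreground voxels; "
            f"at least {MIN_ROI_VOXELS} are required for 3-D texture statistics"
        )
    box = bounding_box(mask.data)
    sl = tuple(slice(lo, hi) for lo, hi in box)
    return ROIPatch(
        values=np.ascontiguousarray(volume.data[sl], dtype=np.float64),
        mask=np.ascontiguousarray(mask.data[sl], dtype=np.uint8),
        label=mask.label,
        n_voxels=n,
    )


def patch_from_arrays(values: np.ndarray, mask: np.ndarray, label: str = "left_caudal") -> ROIPatch:
    """Build a patch directly from in-memory arrays (synthetic/test path)."""
    vol = IntensityVolume(
        data=np.asarray(values, dtype=np.float64), spacing=(1.0, 1.0, 1.0), affine=np.eye(4)
    )
    return extract_roi(vol, ROIMask(data=np.asarray(mask, dtype=np.uint8), label=label))


@dataclasses.dataclass
class CohortSubject:
    subject_id: str
    patches: dict[str, ROIPatch]
    covariates: pd.Series


def load_cohort(manifest: str | Path) -> list[CohortSubject]:
    """Load a cohort from a manifest CSV.

    Expected columns: subject_id, group, age, gender, mmse, the four
    AVLT scores (optional), vol_path and one mask path per subregion.
    Paths are resolved relative to the manifest's directory.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    required = {"subject_id", "vol_path", *COVARIATE_COLUMNS, *MASK_COLUMNS.values()}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicated subject id in manifest: {dup!r}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        raise ValueError(f"unknown group label {df.loc[bad_group, 'group'].iloc[0]!r}")

    root = manifest.parent
    has_avlt = all(c in df.columns for c in AVLT_COLUMNS)
    subjects: list[CohortSubject] = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        volume = load_volume(root / row["vol_path"])
        patches: dict[str, ROIPatch] = {}
        for label, col in MASK_COLUMNS.items():
            mpath = root / str(row[col])
            if pd.isna(row[col]) or not mpath.exists():
                raise ValueError(f"subject {sid!r}: missing {label} mask file {row[col]!r}")
            patches[label] = extract_roi(volume, load_mask(mpath, label))
        cov_cols = list(COVARIATE_COLUMNS) + (list(AVLT_COLUMNS) if has_avlt else [])
        subjects.append(
            CohortSubject(subject_id=sid, patches=patches, covariates=row[cov_cols].copy())
        )
    return subjects
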