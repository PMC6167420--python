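"""Assembly of per-subregion (423) and per-subject (1692) feature vectors.

Column order is the deterministic product (subregion LC, LH, RC, RH) x
(band orig, LLL..HHH) x (registry order: 14 intensity, 22 GLCM, 11 GLRLM),
named ``<subregion>__<band>__<family>__<feature>``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry
from .image_io import AVLT_COLUMNS, COVARIATE_COLUMNS, CohortSubject, ROIPatch
from .texture import base_features
from .wavelet import dwt3


@dataclasses.dataclass(frozen=True)
class ExtractionConfig:
    """Tunable knobs of the feature-extraction stage.

    ng: gray levels for quantization (per patch, per sub-band).
    glcm_distance: co-occurrence offset length in voxels.
    wavelet / boundary_mode: decomposition filter and boundary handling.
    excess_kurtosis: report kurtosis - 3 instead of the non-excess moment.
    """

    ng: int = 64
    glcm_distance: int = 1
    wavelet: str = "sym4"
    boundary_mode: str = "periodization"
    excess_kurtosis: bool = False


DEFAULT_CONFIG = ExtractionConfig()


def _cell_values(patch: ROIPatch, config: ExtractionConfig) -> np.ndarray:
    blocks = base_features(
        patch,
        ng=config.ng,
        glcm_distance=config.glcm_distance,
        excess_kurtosis=config.excess_kurtosis,
    )
    return np.concatenate(
        [blocks["intensity"].values, blocks["glcm"].values, blocks["glrlm"].values]
    )


def extract_subregion_features(
    patch: ROIPatch, config: ExtractionConfig = DEFAULT_CONFIG
) -> pd.Series:
    """423 features of one subregion: 47 base features on the original patch
    plus 47 on each of the 8 wavelet sub-bands, in fixed order."""
    values = [_cell_values(patch, config)]
    for band in dwt3(patch, wavelet=config.wavelet, mode=config.boundary_mode):
        band_patch = ROIPatch(
            values=band.values,
            mask=band.mask,
            label=patch.label,
            n_voxels=int(band.mask.sum()),
        )
        values.append(_cell_values(band_patch, config))
    out = pd.Series(
        np.concatenate(values), index=registry.subregion_columns(patch.label), dtype=np.float64
    )
    if not np.isfinite(out.to_numpy()).all():
        bad = out.index[~np.isfinite(out.to_numpy())][0]
        raise ValueError(f"non-finite feature value for {bad}")
    return out


def extract_subject_features(
    patches: dict[str, ROIPatch] | list[ROIPatch], config: ExtractionConfig = DEFAULT_CONFIG
) -> pd.Series:
    """1692 features of one subject: the four subregion blocks concatenated
    in canonical label order (order is fixed by label, not argument order)."""
    if not isinstance(patches, dict):
        patches = {p.label: p for p in patches}
    labels = sorted(patches)
    if sorted(registry.SUBREGIONS) != labels:
        raise ValueError(
            f"expected one patch per subregion {registry.SUBREGIONS}, got labels {labels}"
        )
    parts = [extract_subregion_features(patches[sr], config) for sr in registry.SUBREGIONS]
    return pd.concat(parts)


@dataclasses.dataclass
class FeatureTable:
    """Cohort feature matrix (subjects x 1692) with its covariate side table."""

    features: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        expected = registry.subject_columns()
        if list(self.features.columns) != expected:
            raise ValueError(
                f"feature table has {len(self.features.columns)} columns; "
                f"expected the {len(expected)} registry columns in canonical order"
            )
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing cells")
        if not self.features.index.equals(self.covariates.index):
            raise ValueError("feature rows and covariate rows must share subject order")


def extract_cohort_features(
    subjects: list[CohortSubject], config: ExtractionConfig = DEFAULT_CONFIG
) -> FeatureTable:
    rows = {s.subject_id: extract_subject_features(s.patches, config) for s in subjects}
    features = pd.DataFrame.from_dict(rows, orient="index")
    features = features[registry.subject_columns()]
    features.index.name = "subject_id"
    cov_cols = [c for c in (*COVARIATE_COLUMNS, *AVLT_COLUMNS) if c in subjects[0].covariates.index]
    covariates = pd.DataFrame(
        {s.subject_id: s.covariates[cov_cols] for s in subjects}
    ).T
    covariates.index.name = "subject_id"
    for col in covariates.columns:
        if col not in ("group", "gender"):
            covariates[col] = pd.to_numeric(covariates[col])
    return FeatureTable(features=features, covariates=covariates)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write features to ``path`` and covariates to ``<stem>.covariates.csv``
    at full decimal precision (lossless round trip)."""
    path = Path(path)
    table.features.to_csv(path, float_format="%.17g")
    table.covariates.to_csv(path.with_suffix(".covariates.csv"))


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    features = pd.read_csv(path, index_col="subject_id")
    expected = registry.subject_columns()
    if list(features.columns) != expected:
        raise ValueError(
            f"{path}: found {len(features.columns)} feature columns, expected {len(expected)} "
            "in canonical registry order"
        )
    cov_path = path.with_suffix(".covariates.csv")
    covariates = pd.read_csv(cov_path, index_col="subject_id")
    features.index = features.index.astype(str)
    covariates.index = covariates.index.astype(str)
    return FeatureTable(features=features.astype(np.float64), covariates=covariates)
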