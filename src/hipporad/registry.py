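"""Feature-name registries and the feature-column naming grammar.

The full per-subject radiomic profile is the deterministic product

    (subregion: LC, LH, RC, RH) x (band: orig, LLL..HHH) x (family registry)

where each (subregion, band) cell carries 14 first-order, 22 GLCM and
11 GLRLM features: 47 per cell, 423 per subregion, 1692 per subject.
Column names follow the grammar ``<subregion>__<band>__<family>__<feature>``
and are parseable back into their four components.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

#: Hippocampal subregion labels in canonical order (left/right x caudal/head).
SUBREGIONS: tuple[str, ...] = ("left_caudal", "left_head", "right_caudal", "right_head")

#: Short display codes used in reports and heat maps.
SUBREGION_CODES: dict[str, str] = {
    "left_caudal": "LC",
    "left_head": "LH",
    "right_caudal": "RC",
    "right_head": "RH",
}

#: Wavelet sub-band codes in fixed order; ``orig`` is the unfiltered image.
WAVELET_BANDS: tuple[str, ...] = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
BANDS: tuple[str, ...] = ("orig",) + WAVELET_BANDS

#: First-order (intensity histogram) features, fixed order.
INTENSITY_FEATURES: tuple[str, ...] = (
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "mean_absolute_deviation",
    "median",
    "minimum",
    "range",
    "root_mean_square",
    "skewness",
    "standard_deviation",
    "uniformity",
    "variance",
)

#: Gray-level co-occurrence matrix features (Haralick-style), fixed order.
GLCM_FEATURES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
)

#: Gray-level run-length matrix features, fixed order.
GLRLM_FEATURES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

FAMILIES: dict[str, tuple[str, ...]] = {
    "intensity": INTENSITY_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
}

N_FEATURES_PER_CELL = len(INTENSITY_FEATURES) + len(GLCM_FEATURES) + len(GLRLM_FEATURES)
N_FEATURES_PER_SUBREGION = N_FEATURES_PER_CELL * len(BANDS)
N_FEATURES_PER_SUBJECT = N_FEATURES_PER_SUBREGION * len(SUBREGIONS)


class ColumnName(NamedTuple):
    subregion: str
    band: str
    family: str
    feature: str


def make_column(subregion: str, band: str, family: str, feature: str) -> str:
    return f"{subregion}__{band}__{family}__{feature}"


def parse_column(name: str) -> ColumnName:
    """Split a feature-column name into (subregion, band, family, feature)."""
    parts = name.split("__")
    if len(parts) != 4:
        raise ValueError(f"malformed feature column name: {name!r}")
    subregion, band, family, feature = parts
    if subregion not in SUBREGIONS:
        raise ValueError(f"unknown subregion in column {name!r}")
    if band not in BANDS:
        raise ValueError(f"unknown band in column {name!r}")
    if family not in FAMILIES or feature not in FAMILIES[family]:
        raise ValueError(f"unknown family/feature in column {name!r}")
    return ColumnName(subregion, band, family, feature)


def cell_feature_names() -> list[tuple[str, str]]:
    """(family, feature) pairs for one (subregion, band) cell, in order."""
    return [(fam, feat) for fam in ("intensity", "glcm", "glrlm") for feat in FAMILIES[fam]]


def subregion_columns(subregion: str) -> list[str]:
    """The 423 column names of one subregion, in canonical order."""
    return [
        make_column(subregion, band, fam, feat)
        for band in BANDS
        for fam, feat in cell_feature_names()
    ]


def subject_columns() -> list[str]:
    """All 1692 per-subject column names, in canonical order."""
    cols: list[str] = []
    for subregion in SUBREGIONS:
        cols.extend(subregion_columns(subregion))
    return cols


def registry_table() -> pd.DataFrame:
    """Machine-readable registry (name, family, formula id) fixing column order."""
    rows = []
    for fam, feats in FAMILIES.items():
        for i, feat in enumerate(feats):
            rows.append({"name": feat, "family": fam, "formula_id": f"{fam}.{i:02d}"})
    return pd.DataFrame(rows, columns=["name", "family", "formula_id"])
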