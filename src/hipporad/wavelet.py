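"""Single-level 3-D discrete wavelet decomposition of ROI patches.

Each patch is decomposed with the separable Symlet-4 filter pair into the
8 sub-bands LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH (L = low-pass,
H = high-pass, one letter per axis), decimated by 2 per axis. Boundary
handling is periodization, which yields exactly ceil(n/2) coefficients per
axis and preserves orthogonality, so the sum of sub-band energies equals
the input energy on full-mask patches.

Background voxels are zero-filled before filtering; a 2x2x2 max-pooled
companion mask marks which sub-band coefficients draw on any foreground
voxel, and sub-band feature extraction uses those coefficients only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

from .image_io import ROIPatch
from .registry import WAVELET_BANDS

#: band letter -> pywt coefficient key letter (a = approximation/low-pass)
_LETTER = {"L": "a", "H": "d"}


@dataclasses.dataclass(frozen=True)
class SubbandPatch:
    """One wavelet sub-band of a patch, with its downsampled mask."""

    values: np.ndarray
    mask: np.ndarray
    band: str
    label: str


def subband_mask(mask: np.ndarray) -> np.ndarray:
    """2x2x2 max-pool of a binary mask (any-of-8 reduction), matching the
    ceil(n/2) sub-band grid of the decimated transform."""
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("mask is empty")
    padded = np.zeros(tuple(-(-n // 2) * 2 for n in mask.shape), dtype=mask.dtype)
    padded[tuple(slice(0, n) for n in mask.shape)] = mask
    pooled = padded.reshape(
        padded.shape[0] // 2, 2, padded.shape[1] // 2, 2, padded.shape[2] // 2, 2
    ).max(axis=(1, 3, 5))
    if not pooled.any():
        raise ValueError("pooled sub-band mask is empty")
    return pooled.astype(np.uint8)


def dwt3(patch: ROIPatch, wavelet: str = "sym4", mode: str = "periodization") -> list[SubbandPatch]:
    """Decompose a patch into its 8 sub-bands, in fixed band order."""
    if min(patch.values.shape) < 2:
        raise ValueError(f"every axis must have length >= 2, got shape {patch.values.shape}")
    data = patch.values * patch.mask  # zero-fill background before filtering
    coeffs = pywt.dwtn(data, wavelet, mode=mode)
    pooled = subband_mask(patch.mask)
    bands = []
    for band in WAVELET_BANDS:
        key = "".join(_LETTER[c] for c in band)
        values = np.asarray(coeffs[key], dtype=np.float64)
        if values.shape != pooled.shape:
            raise ValueError(
                f"sub-band shape {values.shape} does not match pooled mask {pooled.shape}; "
                f"use mode='periodization' for ceil(n/2) sub-band grids"
            )
        bands.append(SubbandPatch(values=values, mask=pooled, band=band, label=patch.label))
    return bands


def idwt3(bands: list[SubbandPatch], wavelet: str = "sym4", mode: str = "periodization") -> np.ndarray:
    """Inverse transform (synthesis filter bank) of the 8 sub-bands."""
    coeffs = {
        "".join(_LETTER[c] for c in b.band): b.values for b in bands
    }
    return np.asarray(pywt.idwtn(coeffs, wavelet, mode=mode))
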