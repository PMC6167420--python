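"""First-order, GLCM and GLRLM texture features of one ROI patch.

All statistics are computed over foreground (mask == 1) voxels only.
Gray-level quantization uses Ng equal-width bins spanning the foreground
min-max range, with the top bin closed so the maximum maps to level Ng.
Texture matrices are accumulated in the 13 unique 3-D direction offsets
(26-connectivity modulo point symmetry); features are evaluated per
direction and averaged over the non-empty directions. Entropy-type
features use log base 2 with the 0*log(0) = 0 convention.

Degenerate (zero-variance) inputs are mapped to finite values: first-order
skewness and kurtosis are 0, GLCM correlation is 0. Kurtosis is non-excess
(a Gaussian histogram scores 3); the excess variant is a config flag.
"""

from __future__ import annotations

import dataclasses
import functools
import logging

import numpy as np

from .image_io import ROIPatch
from .registry import GLCM_FEATURES, GLRLM_FEATURES, INTENSITY_FEATURES

logger = logging.getLogger(__name__)

#: The 13 unique 3-D offsets: 26-neighbourhood modulo point symmetry.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclasses.dataclass(frozen=True)
class QuantizedPatch:
    """ROI patch with foreground intensities discretized to levels 1..Ng."""

    levels: np.ndarray  # int grid; 1..Ng on foreground, 0 on background
    ng: int
    bin_edges: np.ndarray  # Ng + 1 monotone thresholds

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


@dataclasses.dataclass(frozen=True)
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    P: np.ndarray  # Ng x Ng probabilities
    direction: tuple[int, int, int]
    distance: int
    empty: bool = False


@dataclasses.dataclass(frozen=True)
class GLRLM:
    """Gray-level run-length matrix: R[g-1, l-1] counts runs of level g, length l."""

    R: np.ndarray
    direction: tuple[int, int, int]
    n_runs: int


@dataclasses.dataclass(frozen=True)
class FeatureBlock:
    names: tuple[str, ...]
    values: np.ndarray
    family: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, (float(v) for v in self.values)))


def quantize(patch: ROIPatch, ng: int) -> QuantizedPatch:
    """Equal-width gray-level quantization of the foreground intensities."""
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    fg = patch.mask.astype(bool)
    x = patch.values[fg]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(patch.values.shape, dtype=np.int32)
    if hi == lo:
        logger.warning("constant patch (%s): all foreground voxels map to level 1", patch.label)
        levels[fg] = 1
        edges = np.linspace(lo, lo + 1.0, ng + 1)
        return QuantizedPatch(levels=levels, ng=ng, bin_edges=edges)
    edges = np.linspace(lo, hi, ng + 1)
    # floor((x - lo)/width * Ng) + 1, with the top bin closed at the maximum
    lv = np.floor((patch.values[fg] - lo) / (hi - lo) * ng).astype(np.int32) + 1
    np.clip(lv, 1, ng, out=lv)
    levels[fg] = lv
    return QuantizedPatch(levels=levels, ng=ng, bin_edges=edges)


# ---------------------------------------------------------------------------
# first-order features


def intensity_features(patch: ROIPatch, ng: int = 64, excess_kurtosis: bool = False) -> FeatureBlock:
    """The 14 histogram/first-order features of the foreground intensities."""
    x = patch.foreground().astype(np.float64)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance, matching the moment-ratio definitions
    sd = np.sqrt(var)
    if var > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
        if excess_kurtosis:
            kurt -= 3.0
    else:
        skew = 0.0
        kurt = 0.0
        logger.debug("zero-variance patch: skewness/kurtosis set to 0")
    # histogram probabilities over the quantization grid
    q = quantize(patch, ng)
    counts = np.bincount(q.levels[q.levels > 0], minlength=ng + 1)[1:]
    p = counts / counts.sum()
    p_nz = p[p > 0]
    values = np.array(
        [
            float(np.sum(x**2)),  # energy
            float(-(p_nz * np.log2(p_nz)).sum()),  # entropy
            kurt,
            float(x.max()),
            float(mean),
            float(np.mean(np.abs(x - mean))),  # mean absolute deviation
            float(np.median(x)),
            float(x.min()),
            float(x.max() - x.min()),
            float(np.sqrt(np.mean(x**2))),  # root mean square
            skew,
            float(sd),
            float(np.sum(p**2)),  # uniformity
            float(x.var(ddof=1)) if n > 1 else 0.0,  # variance
        ]
    )
    return FeatureBlock(names=INTENSITY_FEATURES, values=values, family="intensity")


# ---------------------------------------------------------------------------
# GLCM


def compute_glcm(
    qpatch: QuantizedPatch, direction: tuple[int, int, int], distance: int = 1
) -> GLCM:
    """Count co-occurring foreground level pairs at ``distance * direction``.

    Pairs are accumulated symmetrically (each ordered pair counted in both
    orders) and normalized to probabilities.
    """
    direction = tuple(int(d) for d in direction)
    if direction not in DIRECTIONS_13:
        raise ValueError(f"direction {direction} is not one of the 13 canonical offsets")
    lv = qpatch.levels
    ng = qpatch.ng
    off = tuple(d * distance for d in direction)
    src, dst = [], []
    for axis, o in enumerate(off):
        n = lv.shape[axis]
        if abs(o) >= n:
            return GLCM(P=np.zeros((ng, ng)), direction=direction, distance=distance, empty=True)
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    a = lv[tuple(src)]
    b = lv[tuple(dst)]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return GLCM(P=np.zeros((ng, ng)), direction=direction, distance=distance, empty=True)
    i = a[valid].astype(np.int64) - 1
    j = b[valid].astype(np.int64) - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T
    P = counts / counts.sum()
    return GLCM(P=P, direction=direction, distance=distance, empty=False)


@functools.lru_cache(maxsize=8)
def _glcm_grids(ng: int):
    i = np.arange(1, ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    sum_idx = (I + J).astype(np.int64)  # 2 .. 2Ng
    diff_idx = np.abs(I - J).astype(np.int64)  # 0 .. Ng-1
    return i, I, J, sum_idx, diff_idx


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_feature_values(glcm: GLCM) -> np.ndarray:
    """Evaluate the 22 GLCM features of one normalized symmetric matrix."""
    P = glcm.P
    ng = P.shape[0]
    i, I, J, sum_idx, diff_idx = _glcm_grids(ng)

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    p_sum = np.bincount(sum_idx.ravel(), weights=P.ravel(), minlength=2 * ng + 1)[2:]
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_diff = np.bincount(diff_idx.ravel(), weights=P.ravel(), minlength=ng)
    k_diff = np.arange(ng, dtype=np.float64)

    HXY = _entropy2(P.ravel())
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    HXY1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    HXY2 = _entropy2(pxpy.ravel())
    HX = _entropy2(px)
    HY = _entropy2(py)

    autocorrelation = float((I * J * P).sum())
    cp_base = I + J - mu_x - mu_y
    cluster_prominence = float((cp_base**4 * P).sum())
    cluster_shade = float((cp_base**3 * P).sum())
    cluster_tendency = float((cp_base**2 * P).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 0.0
    difference_entropy = _entropy2(p_diff)
    dissimilarity = float((np.abs(I - J) * P).sum())
    energy = float((P**2).sum())
    entropy = HXY
    homogeneity1 = float((P / (1.0 + np.abs(I - J))).sum())
    homogeneity2 = float((P / (1.0 + (I - J) ** 2)).sum())
    denom = max(HX, HY)
    imc1 = (HXY - HXY1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))
    idmn = float((P / (1.0 + (I - J) ** 2 / ng**2)).sum())
    idn = float((P / (1.0 + np.abs(I - J) / ng)).sum())
    offdiag = diff_idx > 0
    inverse_variance = float((P[offdiag] / (I - J)[offdiag] ** 2).sum())
    maximum_probability = float(P.max())
    sum_average = float((k_sum * p_sum).sum())
    sum_entropy = _entropy2(p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    variance = float(((I - mu_x) ** 2 * P).sum())  # GLCM variance about the marginal mean

    return np.array(
        [
            autocorrelation,
            cluster_prominence,
            cluster_shade,
            cluster_tendency,
            contrast,
            correlation,
            difference_entropy,
            dissimilarity,
            energy,
            entropy,
            homogeneity1,
            homogeneity2,
            imc1,
            imc2,
            idmn,
            idn,
            inverse_variance,
            maximum_probability,
            sum_average,
            sum_entropy,
            sum_variance,
            variance,
        ]
    )


def glcm_features(qpatch: QuantizedPatch, distance: int = 1) -> FeatureBlock:
    """The 22 GLCM features, averaged over the non-empty 13 directions."""
    per_dir = []
    for direction in DIRECTIONS_13:
        g = compute_glcm(qpatch, direction, distance)
        if not g.empty:
            per_dir.append(glcm_feature_values(g))
    if not per_dir:
        raise ValueError("all 13 GLCM directions are empty; ROI too small or fragmented")
    values = np.mean(per_dir, axis=0)
    return FeatureBlock(names=GLCM_FEATURES, values=values, family="glcm")


# ---------------------------------------------------------------------------
# GLRLM


@functools.lru_cache(maxsize=256)
def _line_order(shape: tuple[int, int, int], direction: tuple[int, int, int]):
    """Voxel ordering that concatenates all rasters in ``direction``.

    Returns (order, line_id) where ``order`` indexes the flattened grid so
    that voxels of each line are contiguous and in walking order, and
    ``line_id`` labels the line of each ordered voxel.
    """
    idx = np.indices(shape)
    steps_back = np.full(shape, np.iinfo(np.int64).max, dtype=np.int64)
    for axis, d in enumerate(direction):
        if d == 1:
            np.minimum(steps_back, idx[axis], out=steps_back)
        elif d == -1:
            np.minimum(steps_back, shape[axis] - 1 - idx[axis], out=steps_back)
    start = [idx[a] - steps_back * direction[a] for a in range(3)]
    line_id = np.ravel_multi_index(start, shape).ravel()
    order = np.lexsort((steps_back.ravel(), line_id))
    return order, line_id[order]


def compute_glrlm(qpatch: QuantizedPatch, direction: tuple[int, int, int]) -> GLRLM:
    """Maximal same-level runs along rasters in ``direction``.

    Runs are broken by background voxels and by the patch boundary.
    """
    direction = tuple(int(d) for d in direction)
    if direction not in DIRECTIONS_13:
        raise ValueError(f"direction {direction} is not one of the 13 canonical offsets")
    lv = qpatch.levels
    ng = qpatch.ng
    lmax = max(lv.shape)
    order, line_id = _line_order(lv.shape, direction)
    seq = lv.ravel()[order]

    # run starts: first voxel overall, a new line, or a level change
    change = np.empty(seq.size, dtype=bool)
    change[0] = True
    change[1:] = (seq[1:] != seq[:-1]) | (line_id[1:] != line_id[:-1])
    starts = np.flatnonzero(change)
    lengths = np.diff(np.append(starts, seq.size))
    levels = seq[starts]
    keep = levels > 0
    levels, lengths = levels[keep], lengths[keep]

    R = np.zeros((ng, lmax), dtype=np.int64)
    np.add.at(R, (levels - 1, lengths - 1), 1)
    return GLRLM(R=R, direction=direction, n_runs=int(R.sum()))


def glrlm_feature_values(glrlm: GLRLM, n_voxels: int) -> np.ndarray:
    """Evaluate the 11 run-length features of one matrix."""
    R = glrlm.R.astype(np.float64)
    nr = R.sum()
    g = np.arange(1, R.shape[0] + 1, dtype=np.float64)  # gray level
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)  # run length
    r_g = R.sum(axis=1)
    r_l = R.sum(axis=0)
    G, L = g[:, None], l[None, :]
    sre = float((R / L**2).sum() / nr)
    lre = float((R * L**2).sum() / nr)
    gln = float((r_g**2).sum() / nr)
    rln = float((r_l**2).sum() / nr)
    rp = float(nr / n_voxels)
    lglre = float((R / G**2).sum() / nr)
    hglre = float((R * G**2).sum() / nr)
    srlgle = float((R / (G**2 * L**2)).sum() / nr)
    srhgle = float((R * G**2 / L**2).sum() / nr)
    lrlgle = float((R * L**2 / G**2).sum() / nr)
    lrhgle = float((R * G**2 * L**2).sum() / nr)
    return np.array([sre, lre, gln, rln, rp, lglre, hglre, srlgle, srhgle, lrlgle, lrhgle])


def glrlm_features(qpatch: QuantizedPatch) -> FeatureBlock:
    """The 11 GLRLM features, averaged over the 13 directions."""
    n_vox = qpatch.n_voxels
    if n_vox == 0:
        raise ValueError("empty foreground")
    per_dir = []
    for direction in DIRECTIONS_13:
        m = compute_glrlm(qpatch, direction)
        if m.n_runs > 0:
            per_dir.append(glrlm_feature_values(m, n_vox))
    values = np.mean(per_dir, axis=0)
    return FeatureBlock(names=GLRLM_FEATURES, values=values, family="glrlm")


def base_features(patch: ROIPatch, ng: int = 64, glcm_distance: int = 1,
                  excess_kurtosis: bool = False) -> dict[str, FeatureBlock]:
    """All 47 base features (14 intensity + 22 GLCM + 11 GLRLM) of a patch."""
    q = quantize(patch, ng)
    return {
        "intensity": intensity_features(patch, ng=ng, excess_kurtosis=excess_kurtosis),
        "glcm": glcm_features(q, distance=glcm_distance),
        "glrlm": glrlm_features(q),
    }
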