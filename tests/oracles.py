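"""Independent brute-force oracles used to check the implementation.

Everything here is written as naive enumeration / direct formula
evaluation, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def glcm_pair_enumeration(levels: np.ndarray, direction, distance: int, ng: int) -> np.ndarray:
    """Exhaustive ordered-pair counting, symmetric accumulation, normalized."""
    C = np.zeros((ng, ng))
    off = tuple(int(d) * distance for d in direction)
    for idx in np.ndindex(levels.shape):
        jdx = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= j < n for j, n in zip(jdx, levels.shape)):
            a, b = levels[idx], levels[jdx]
            if a > 0 and b > 0:
                C[a - 1, b - 1] += 1
                C[b - 1, a - 1] += 1
    total = C.sum()
    return C / total if total else C


def glrlm_run_enumeration(levels: np.ndarray, direction, ng: int, lmax: int) -> np.ndarray:
    """Walk every raster line in ``direction`` and count maximal runs."""
    R = np.zeros((ng, lmax))
    d = np.array(direction)
    shape = np.array(levels.shape)
    starts = []
    for idx in np.ndindex(levels.shape):
        prev = np.array(idx) - d
        if not all(0 <= p < n for p, n in zip(prev, shape)):
            starts.append(np.array(idx))
    for start in starts:
        line = []
        pos = start.copy()
        while all(0 <= p < n for p, n in zip(pos, shape)):
            line.append(levels[tuple(pos)])
            pos = pos + d
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            R[line[i] - 1, j - i - 1] += 1
            i = j
    return R


def oneway_f(groups: list[np.ndarray]) -> float:
    """Classical between/within sum-of-squares F statistic."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_x) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    return (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation via midranks and the Pearson formula on ranks."""

    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2
            i = j
        return ranks

    rx, ry = midrank(np.asarray(x, float)), midrank(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


def auc_pair_counting(scores: np.ndarray, positive: np.ndarray) -> float:
    """Exhaustive positive/negative pair comparison with half credit for ties."""
    pos = np.asarray(scores)[np.asarray(positive, bool)]
    neg = np.asarray(scores)[~np.asarray(positive, bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def maxpool_any_of_8(mask: np.ndarray) -> np.ndarray:
    out_shape = tuple(-(-n // 2) for n in mask.shape)
    out = np.zeros(out_shape, dtype=np.uint8)
    for idx in np.ndindex(out_shape):
        block = mask[
            idx[0] * 2 : idx[0] * 2 + 2,
            idx[1] * 2 : idx[1] * 2 + 2,
            idx[2] * 2 : idx[2] * 2 + 2,
        ]
        out[idx] = 1 if block.any() else 0
    return out


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)
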