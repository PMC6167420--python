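"""Nested leave-one-out RBF-SVM classification with t-test feature ranking.

The classifier follows the standard nested-LOOCV protocol: for every outer
fold, an inner leave-one-out loop over the outer-training rows performs
min-max normalization, Welch-t feature ranking and top-k selection on the
inner-training rows only, scores every (C, gamma) candidate pair, and the
pair with the best inner accuracy (ties: smallest C, then smallest gamma)
is refit on the full outer-training set to predict the held-out subject.
Normalization parameters, ranking statistics and hyperparameters in any
fold are therefore computable from that fold's training rows alone — no
information from a test row ever reaches its own training pipeline.

Welch ranking statistic: T = (mu_1 - mu_2) / sqrt(s1^2/n1 + s2^2/n2) with
sample variances (denominator n - 1); features are ordered by descending
|T|. At most 200 features are ever selected.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps
from sklearn.svm import SVC

try:  # low-overhead libsvm entry point for the inner grid search hot loop
    from sklearn.svm import _libsvm as _fast_libsvm

    _fast_libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - fall back to the estimator API
    _fast_libsvm = None


@dataclasses.dataclass(frozen=True)
class SVMGridConfig:
    """Geometric (C, gamma) candidate grids and the ranked-feature cap.

    Default grids are the canonical powers-of-two search of RBF-SVM
    practice: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2.
    """

    c_values: tuple[float, ...] = tuple(float(2.0**e) for e in range(-5, 16, 2))
    g_values: tuple[float, ...] = tuple(float(2.0**e) for e in range(-15, 4, 2))
    max_features: int = 200

    def __post_init__(self) -> None:
        if self.max_features > 200:
            raise ValueError("at most 200 ranked features may be selected")


DEFAULT_GRID = SVMGridConfig()

#: A deliberately small grid for quick experiments and simulation studies.
SMALL_GRID = SVMGridConfig(c_values=(1.0, 32.0), g_values=(2.0**-7, 2.0**-3))


@dataclasses.dataclass(frozen=True)
class NormalizationParams:
    xmin: np.ndarray
    xmax: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        span = self.xmax - self.xmin
        out = np.zeros_like(X, dtype=np.float64)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.xmin[ok]) / span[ok]
        return out  # constant training features map to 0; test rows are not clipped


def minmax_fit(train: np.ndarray) -> NormalizationParams:
    if train.shape[0] < 2:
        raise ValueError("min-max normalization needs at least 2 training rows")
    return NormalizationParams(xmin=train.min(axis=0), xmax=train.max(axis=0))


def minmax_fit_apply(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, NormalizationParams]:
    """Learn per-feature min/max on the training rows only and apply to both."""
    params = minmax_fit(train)
    return params.apply(train), None if test is None else params.apply(test), params


@dataclasses.dataclass(frozen=True)
class WelchRankResult:
    t: np.ndarray
    order: np.ndarray  # feature indices by descending |T|, ties by index

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def welch_t_statistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """T = (mu_1 - mu_2) / sqrt(s1^2/n1 + s2^2/n2), class order by label sort."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("both classes need at least 2 rows for the Welch statistic")
    se2 = a.var(axis=0, ddof=1) / a.shape[0] + b.var(axis=0, ddof=1) / b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    # zero scale: no information if means agree (T=0), infinite separation otherwise
    with np.errstate(invalid="ignore"):
        t = np.where(se2 == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    return t


def welch_rank(X: np.ndarray, y: np.ndarray) -> WelchRankResult:
    t = welch_t_statistic(X, y)
    order = np.lexsort((np.arange(t.size), -np.abs(t)))
    return WelchRankResult(t=t, order=order)


@dataclasses.dataclass
class CVResult:
    """Out-of-fold predictions and summary metrics of a nested LOOCV run."""

    decision_values: np.ndarray
    predicted: np.ndarray
    true: np.ndarray
    positive_label: str
    acc: float
    sen: float
    spe: float
    auc: float
    k_features: int
    fold_params: list[tuple[float, float]]
    selection_frequency: np.ndarray  # fraction of outer folds selecting each feature


def roc_auc(decision_values: np.ndarray, labels: np.ndarray, positive_label) -> tuple[float, np.ndarray]:
    """AUC by the Mann-Whitney rank formulation with midrank ties, plus the
    (FPR, TPR) staircase points of the empirical ROC curve."""
    y = np.asarray(labels) == positive_label
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    r = sps.rankdata(decision_values)
    auc = (r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-decision_values, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    curve = np.column_stack(
        [np.concatenate([[0], fps / n_neg]), np.concatenate([[0], tps / n_pos])]
    )
    return float(auc), curve


def _prep_fold(X_tr: np.ndarray, y_tr: np.ndarray, k: int):
    """Train-side pipeline of one fold: normalize, rank, select top-k."""
    params = minmax_fit(X_tr)
    Xn = params.apply(X_tr)
    sel = welch_rank(Xn, y_tr).top(k)
    return params, sel, Xn[:, sel]


def _fit_predict_one(Xs: np.ndarray, ys: np.ndarray, xt: np.ndarray, c: float, g: float) -> float:
    """Fit an RBF C-SVC and predict one row (numeric class codes).

    Uses scikit-learn's low-level libsvm binding when available: the inner
    grid search fits the same model thousands of times on tiny samples, and
    the estimator wrapper's per-fit overhead dominates there. Fit results
    are identical to ``SVC(C=c, gamma=g)``.
    """
    if _fast_libsvm is not None:
        model = _fast_libsvm.fit(Xs, ys, svm_type=0, kernel="rbf", C=c, gamma=g)
        return float(
            _fast_libsvm.predict(xt, *model[:7], svm_type=0, kernel="rbf", gamma=g)[0]
        )
    clf = SVC(C=c, gamma=g, kernel="rbf")  # pragma: no cover
    clf.fit(Xs, ys)
    return float(clf.predict(xt)[0])


def _choose_cg(X_tr, y_tr, grid: SVMGridConfig, k: int) -> tuple[float, float]:
    """Inner LOOCV grid search on the outer-training rows.

    Each inner fold re-normalizes and re-ranks on its own training rows;
    accuracy per (C, gamma) is pooled over inner folds. Ties resolve to the
    smallest C, then the smallest gamma.
    """
    n = X_tr.shape[0]
    y_codes = np.unique(y_tr, return_inverse=True)[1].astype(np.float64)
    hits = np.zeros((len(grid.c_values), len(grid.g_values)), dtype=np.int64)
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y_tr[tr]).size < 2:
            raise ValueError("an inner training fold lost a class; group too small")
        params, sel, Xs = _prep_fold(X_tr[tr], y_tr[tr], k)
        Xs = np.ascontiguousarray(Xs)
        ys = np.ascontiguousarray(y_codes[tr])
        xt = np.ascontiguousarray(params.apply(X_tr[i : i + 1])[:, sel])
        for ci, c in enumerate(grid.c_values):
            for gi, g in enumerate(grid.g_values):
                hits[ci, gi] += int(_fit_predict_one(Xs, ys, xt, c, g) == y_codes[i])
    best = np.unravel_index(np.argmax(hits), hits.shape)  # argmax: first = smallest c, g
    return grid.c_values[best[0]], grid.g_values[best[1]]


def _decision_for(clf: SVC, X: np.ndarray, positive_label) -> np.ndarray:
    """Signed distance from the hyperplane, oriented positive-class-positive."""
    d = clf.decision_function(X)
    return d if clf.classes_[1] == positive_label else -d


def nested_loocv(
    X: np.ndarray,
    y: np.ndarray,
    grid: SVMGridConfig = DEFAULT_GRID,
    k_features: int = 200,
    positive_label=None,
) -> CVResult:
    """Nested leave-one-out cross-validation of the ranked-feature RBF-SVM."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, d = X.shape
    if n < 6:
        raise ValueError("nested LOOCV needs at least 6 subjects")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected 2 classes, got {classes}")
    if positive_label is None:
        patient = [c for c in classes if str(c) != "NC"]
        positive_label = patient[0] if len(patient) == 1 else classes[1]
    k = min(k_features, grid.max_features, d)

    decisions = np.empty(n)
    predicted = np.empty(n, dtype=y.dtype)
    fold_params: list[tuple[float, float]] = []
    sel_counts = np.zeros(d)
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y[tr]).size < 2:
            raise ValueError("an outer training fold lost a class")
        c, g = _choose_cg(X[tr], y[tr], grid, k)
        params, sel, Xs = _prep_fold(X[tr], y[tr], k)
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(Xs, y[tr])
        xt = params.apply(X[i : i + 1])[:, sel]
        predicted[i] = clf.predict(xt)[0]
        decisions[i] = _decision_for(clf, xt, positive_label)[0]
        fold_params.append((c, g))
        sel_counts[sel] += 1

    pos = y == positive_label
    tp = int(((predicted == positive_label) & pos).sum())
    tn = int(((predicted != positive_label) & ~pos).sum())
    fp = int(((predicted == positive_label) & ~pos).sum())
    fn = int(((predicted != positive_label) & pos).sum())
    auc, _ = roc_auc(decisions, y, positive_label)
    return CVResult(
        decision_values=decisions,
        predicted=predicted,
        true=y.copy(),
        positive_label=str(positive_label),
        acc=(tp + tn) / n,
        sen=tp / (tp + fn) if tp + fn else float("nan"),
        spe=tn / (tn + fp) if tn + fp else float("nan"),
        auc=auc,
        k_features=k,
        fold_params=fold_params,
        selection_frequency=sel_counts / n,
    )


def select_feature_count(
    X: np.ndarray,
    y: np.ndarray,
    grid: SVMGridConfig = DEFAULT_GRID,
    counts: tuple[int, ...] = (10, 25, 50, 100, 163, 200),
    positive_label=None,
) -> tuple[int, CVResult, dict[int, CVResult]]:
    """Run nested LOOCV per candidate feature count, return the best.

    The count is tuned on the outer accuracy itself (ties: smaller k), so
    the winning accuracy carries the usual optimistic selection bias; the
    per-count results are returned for transparent reporting.
    """
    counts = tuple(sorted(set(int(c) for c in counts)))
    if not counts or counts[0] < 1 or counts[-1] > grid.max_features:
        raise ValueError(f"counts must lie in [1, {grid.max_features}]")
    results = {
        k: nested_loocv(X, y, grid=grid, k_features=k, positive_label=positive_label)
        for k in counts
    }
    best_k = max(counts, key=lambda k: (results[k].acc, -k))
    return best_k, results[best_k], results


def hyperplane_score_correlation(
    decision_values: np.ndarray, scores: np.ndarray, subset: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of out-of-fold decision values with a cognitive
    score (e.g. MMSE) over an optional subject subset."""
    d = np.asarray(decision_values, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        d, s = d[subset], s[subset]
    if d.size < 5:
        raise ValueError("need at least 5 subjects for the correlation")
    r, p = sps.pearsonr(d, s)
    return float(r), float(p)


def _stratified_holdout(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Pick k test indices round-robin across classes (keeps folds stratified)."""
    classes = np.unique(y)
    pools = [rng.permutation(np.flatnonzero(y == c)) for c in classes]
    pools = [list(p) for p in pools]
    test: list[int] = []
    ci = 0
    while len(test) < k:
        pool = pools[ci % len(pools)]
        if pool:
            test.append(pool.pop())
        ci += 1
        if all(not p for p in pools):  # pragma: no cover
            break
    return np.array(sorted(test))


def repeated_leave_k_out(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 4,
    reps: int = 1000,
    seed: int = 0,
    grid: SVMGridConfig = DEFAULT_GRID,
    k_features: int = 200,
    positive_label=None,
) -> dict[str, float]:
    """Repeated leave-k-subjects-out validation of the same train-side pipeline.

    Each repetition holds out k stratified random subjects, runs the full
    training pipeline (normalize, rank, inner-LOOCV grid search, fit) on
    the rest and scores the holdout. Returns mean +/- sd of ACC/SEN/SPE.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = X.shape[0]
    if n <= k:
        raise ValueError("need more subjects than the holdout size")
    classes = np.unique(y)
    if positive_label is None:
        patient = [c for c in classes if str(c) != "NC"]
        positive_label = patient[0] if len(patient) == 1 else classes[1]
    kf = min(k_features, grid.max_features, X.shape[1])
    rng = np.random.default_rng(seed)
    accs, sens, spes = [], [], []
    skipped = 0
    for _ in range(reps):
        test = _stratified_holdout(y, k, rng)
        tr = np.setdiff1d(np.arange(n), test)
        if np.unique(y[tr]).size < 2 or min(np.bincount(np.searchsorted(classes, y[tr]))) < 3:
            skipped += 1
            continue
        c, g = _choose_cg(X[tr], y[tr], grid, kf)
        params, sel, Xs = _prep_fold(X[tr], y[tr], kf)
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(Xs, y[tr])
        pred = clf.predict(params.apply(X[test])[:, sel])
        pos = y[test] == positive_label
        hit = pred == y[test]
        accs.append(hit.mean())
        if pos.any():
            sens.append(hit[pos].mean())
        if (~pos).any():
            spes.append(hit[~pos].mean())
    return {
        "acc_mean": float(np.mean(accs)),
        "acc_sd": float(np.std(accs)),
        "sen_mean": float(np.mean(sens)),
        "sen_sd": float(np.std(sens)),
        "spe_mean": float(np.mean(spes)),
        "spe_sd": float(np.std(spes)),
        "reps_used": len(accs),
        "reps_skipped": skipped,
    }
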