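"""Covariate adjustment, mass-univariate screening and cognition correlations.

The screening stage mirrors a standard neuroimaging case-control workflow:
every feature is residualized on age and gender by OLS over all subjects,
then tested with a one-way fixed-effects ANOVA across the three diagnostic
groups (NC, aMCI, AD) at a Bonferroni-corrected threshold alpha / N
(alpha = 0.01, N = number of features, 1692 for the full table). Post hoc
two-sample tests (Welch by default) compare each pair of groups, and
Spearman rank correlations relate features to cognition (MMSE at the
corrected threshold over pooled AD+aMCI subjects; AVLT at P < 0.05).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import registry

GROUP_PAIRS = (("aMCI", "NC"), ("AD", "NC"), ("AD", "aMCI"))

P_FLOOR = 1e-300  # before -log10, keeps heat-map output finite


@dataclasses.dataclass
class AdjustedTable:
    """Residualized feature matrix plus the fitted nuisance coefficients."""

    features: pd.DataFrame  # residual + grand mean, same shape as input
    coefficients: pd.DataFrame  # rows: intercept/age/gender, cols: features
    groups: pd.Series
    covariates: pd.DataFrame


def _encode_gender(g: pd.Series) -> np.ndarray:
    vals = g.astype(str).str.upper()
    mapping = {"M": 0.0, "F": 1.0, "0": 0.0, "1": 1.0, "0.0": 0.0, "1.0": 1.0}
    try:
        return vals.map(mapping).to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:  # pragma: no cover
        raise ValueError(f"gender must be binary-coded (M/F or 0/1): {exc}") from exc


def adjust_covariates(features: pd.DataFrame, covariates: pd.DataFrame) -> AdjustedTable:
    """Residualize every feature on [1, age, gender] by OLS over all subjects.

    Fitting pools all subjects jointly (never per group), so genuine group
    differences are not absorbed into the nuisance fit. Returns residuals
    plus the grand mean, keeping features on their original scale.
    Constant covariate columns are dropped with a warning.
    """
    age = pd.to_numeric(covariates["age"]).to_numpy(dtype=np.float64)
    gender = _encode_gender(covariates["gender"])
    cols = [np.ones(len(features))]
    names = ["intercept"]
    for name, col in (("age", age), ("gender", gender)):
        if np.ptp(col) == 0:
            warnings.warn(f"covariate {name!r} is constant and was dropped from the adjustment")
            continue
        cols.append(col)
        names.append(name)
    X = np.column_stack(cols)
    Y = features.to_numpy(dtype=np.float64)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid + Y.mean(axis=0, keepdims=True)
    coef = pd.DataFrame(beta, index=names, columns=features.columns)
    return AdjustedTable(
        features=pd.DataFrame(adjusted, index=features.index, columns=features.columns),
        coefficients=coef,
        groups=covariates["group"].astype(str),
        covariates=covariates,
    )


def _oneway_f(groups_data: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way fixed-effects ANOVA over feature columns.

    Returns (F, P). Columns with zero between- and within-group variance
    follow the convention F = 0, P = 1.
    """
    k = len(groups_data)
    ns = np.array([g.shape[0] for g in groups_data])
    n = ns.sum()
    all_data = np.vstack(groups_data)
    grand = all_data.mean(axis=0)
    means = np.vstack([g.mean(axis=0) for g in groups_data])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = np.vstack([((g - m) ** 2).sum(axis=0) for g, m in zip(groups_data, means)]).sum(
        axis=0
    )
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    F = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), F)
    P = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isfinite(F), F, 0.0), df_b, df_w))
    P = np.where(F == 0, 1.0, P)
    return F, P


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch two-sample t with Satterthwaite degrees of freedom."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    zero = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero, np.where(ma == mb, 0.0, np.inf * np.sign(ma - mb)), t)
    df = np.where(zero | ~np.isfinite(df), 1.0, df)
    P = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df))
    P = np.where((t == 0) & zero, 1.0, P)
    return t, P


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se2 = sp2 * (1 / na + 1 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    zero = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero, np.where(ma == mb, 0.0, np.inf * np.sign(ma - mb)), t)
    P = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df))
    P = np.where((t == 0) & zero, 1.0, P)
    return t, P


def spearman_rho_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho (midrank ties) with the t-approximation P."""
    n = X.shape[0]
    rx = sps.rankdata(X, axis=0)
    ry = sps.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
    rho = np.where(denom == 0, 0.0, np.clip(rho, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    P = np.where(np.abs(rho) == 1.0, 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), n - 2))
    return rho, P


@dataclasses.dataclass
class ScreenResult:
    """Per-feature screening statistics with corrected significance flags."""

    table: pd.DataFrame  # indexed by feature column name
    alpha: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    def neg_log10_p(self, column: str = "p_anova") -> pd.Series:
        return -np.log10(self.table[column].clip(lower=P_FLOOR))


def anova_screen(
    adjusted: AdjustedTable, alpha: float = 0.01, n_tests: int | None = None
) -> ScreenResult:
    """One-way three-group ANOVA per feature with Bonferroni correction."""
    groups = adjusted.groups
    group_names = [g for g in ("NC", "aMCI", "AD") if (groups == g).any()]
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    data = []
    for g in group_names:
        block = adjusted.features.loc[groups.to_numpy() == g].to_numpy(dtype=np.float64)
        if block.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        data.append(block)
    F, P = _oneway_f(data)
    n_tests = n_tests if n_tests is not None else adjusted.features.shape[1]
    table = pd.DataFrame(
        {"F": F, "p_anova": P, "sig_anova": P < alpha / n_tests},
        index=adjusted.features.columns,
    )
    return ScreenResult(table=table, alpha=alpha, n_tests=n_tests)


def posthoc_pairwise(
    adjusted: AdjustedTable, screen: ScreenResult, variant: str = "welch"
) -> ScreenResult:
    """Two-sample post hoc tests for all three group pairs.

    Statistics and P values are reported for every feature; significance
    flags are raised only where the omnibus ANOVA is itself significant,
    at the same corrected threshold.
    """
    test = {"welch": _welch_t, "pooled": _pooled_t}[variant]
    groups = adjusted.groups.to_numpy()
    X = adjusted.features.to_numpy(dtype=np.float64)
    for a, b in GROUP_PAIRS:
        t, P = test(X[groups == a], X[groups == b])
        key = f"{a.lower()}_{b.lower()}"
        screen.table[f"t_{key}"] = t
        screen.table[f"p_{key}"] = P
        screen.table[f"sig_{key}"] = screen.table["sig_anova"] & (P < screen.threshold)
    return screen


def spearman_screen(
    adjusted: AdjustedTable,
    scores: pd.Series,
    screen: ScreenResult,
    subset: np.ndarray | None = None,
    score_name: str = "mmse",
    alpha: float | None = None,
    corrected: bool = True,
) -> ScreenResult:
    """Spearman correlation of every feature with a cognitive score.

    ``subset`` restricts to a boolean subject mask (default: pooled AD and
    aMCI patients, the symptomatic groups). MMSE uses the corrected
    threshold at alpha = 0.01; AVLT screens conventionally use
    alpha = 0.05 uncorrected (``corrected=False``).
    """
    if subset is None:
        subset = adjusted.groups.isin(["AD", "aMCI"]).to_numpy()
    subset = np.asarray(subset, dtype=bool)
    if subset.sum() < 5:
        raise ValueError("need at least 5 subjects for a rank correlation screen")
    X = adjusted.features.to_numpy(dtype=np.float64)[subset]
    y = pd.to_numeric(scores).to_numpy(dtype=np.float64)[subset]
    rho, P = spearman_rho_p(X, y)
    alpha = alpha if alpha is not None else screen.alpha
    thr = alpha / screen.n_tests if corrected else alpha
    screen.table[f"rho_{score_name}"] = rho
    screen.table[f"p_{score_name}"] = P
    screen.table[f"sig_{score_name}"] = P < thr
    return screen


@dataclasses.dataclass
class MultiRegionSummary:
    """Which base features are flagged in which subregions."""

    by_feature: pd.DataFrame  # index: base feature id, columns: 4 subregions (bool)
    per_subregion: pd.Series
    n_multi: int  # base features significant in more than one subregion


def summarize_multiregion(screen: ScreenResult, flag_column: str = "sig_anova") -> MultiRegionSummary:
    """Group flags by base (band, family, feature) identity across subregions.

    A base feature counts as significant in a subregion if any of that
    subregion's columns sharing the base identity is flagged.
    """
    flags = screen.table[flag_column]
    parsed = [registry.parse_column(c) for c in screen.table.index]
    base_ids = [f"{p.band}__{p.family}__{p.feature}" for p in parsed]
    subregions = [p.subregion for p in parsed]
    df = pd.DataFrame(
        {"base": base_ids, "subregion": subregions, "flag": flags.to_numpy()}
    )
    pivot = df.pivot_table(index="base", columns="subregion", values="flag", aggfunc="any")
    pivot = pivot.reindex(columns=list(registry.SUBREGIONS), fill_value=False).fillna(False)
    pivot = pivot.astype(bool)
    per_subregion = pivot.sum(axis=0)
    n_multi = int((pivot.sum(axis=1) > 1).sum())
    return MultiRegionSummary(by_feature=pivot, per_subregion=per_subregion, n_multi=n_multi)
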