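"""Statistical analysis of a cohort table.

Volume subgrouping, group comparisons (chi-square, Kruskal-Wallis + Dunn),
Spearman correlation with per-pair robust multivariate outlier elimination and
Bonferroni control, multicollinearity filtering, repeated cross-validated
Lasso feature selection, and univariate linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.covariance import EmpiricalCovariance, MinCovDet
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold, train_test_split

from .shape_features import TSI_FEATURES

#: dose-plan responses correlated against shape features (Table-2 layout)
RESPONSES = ["si", "gi", "ei", "pci", "tv_cm3"]

#: significance threshold conventions: 0.05/40 for the 8x5 correlation
#: family, 0.05/12 for the Kruskal-Wallis family
KRUSKAL_ALPHA = 0.0041


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (0.05, 40) -> 0.00125."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def assign_volume_group(tv_cm3: float) -> int:
    """Volume stratum: 1 if TV < 1 cm^3, 2 if 1 <= TV <= 5, 3 if TV > 5.

    Boundary volumes (exactly 1 or 5 cm^3) go to the middle group.
    """
    if tv_cm3 <= 0:
        raise ValueError("tumor volume must be positive")
    if tv_cm3 < 1.0:
        return 1
    if tv_cm3 <= 5.0:
        return 2
    return 3


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    dunn_p: dict = field(default_factory=dict)  # (group_i, group_j) -> adjusted p
    significant: bool = False
    dunn_significant: dict = field(default_factory=dict)


def kruskal_dunn(
    values,
    groups,
    alpha_kw: float = KRUSKAL_ALPHA,
    alpha_dunn: float = 0.05,
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis omnibus test plus Dunn's post-hoc z-tests.

    Dunn's pairwise tests compare mean ranks with the tie-corrected variance
    and Bonferroni adjustment over all pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")

    if np.all(values == values[0]):
        # all observations identical: no evidence against the null
        res = GroupTestResult(statistic=0.0, p_value=1.0)
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        res.dunn_p = {p: 1.0 for p in pairs}
        res.dunn_significant = {p: False for p in pairs}
        return res

    h, p = stats.kruskal(*samples)

    # Dunn's z-tests on mean ranks
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: float(ranks[groups == g].mean()) for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    m = len(pairs)
    dunn_p = {}
    for gi, gj in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        dunn_p[(gi, gj)] = min(1.0, m * p_raw)

    return GroupTestResult(
        statistic=float(h),
        p_value=float(p),
        dunn_p=dunn_p,
        significant=bool(p < alpha_kw),
        dunn_significant={k: bool(v < alpha_dunn) for k, v in dunn_p.items()},
    )


def chi_square(contingency) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a counts table."""
    table = np.asarray(contingency, dtype=float)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# correlation analysis
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    feature: str
    index: str
    r: float
    p: float
    n_used: int
    n_outliers_removed: int
    significant: bool


def remove_multivariate_outliers(
    X, chi2_quantile: float = 0.975, support_fraction: float = 0.75
) -> np.ndarray:
    """Kept-row mask from robust (MCD) Mahalanobis distances.

    Rows whose squared robust distance exceeds the chi-square(p) quantile are
    flagged as multivariate outliers.  Falls back to the classical covariance
    when the MCD scatter is singular.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 rows for outlier elimination")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov = MinCovDet(support_fraction=support_fraction, random_state=0).fit(X)
        d2 = cov.mahalanobis(X)
        if not np.all(np.isfinite(d2)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("MCD scatter singular; falling back to classical covariance",
                      stacklevel=2)
        cov = EmpiricalCovariance().fit(X)
        d2 = cov.mahalanobis(X)
    cutoff = stats.chi2.ppf(chi2_quantile, df=p)
    return d2 <= cutoff


def spearman_pair(
    x, y, eliminate_outliers: bool = True
) -> tuple[float, float, int, int]:
    """Spearman r and p for one pair after robust outlier elimination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.ones(len(x), dtype=bool)
    if eliminate_outliers:
        keep = remove_multivariate_outliers(np.column_stack([x, y]))
    xs, ys = x[keep], y[keep]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), float("nan"), int(keep.sum()), int((~keep).sum())
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue), int(keep.sum()), int((~keep).sum())


def spearman_matrix(
    table: pd.DataFrame,
    features: list[str] = TSI_FEATURES,
    responses: list[str] = RESPONSES,
    alpha: float = 0.05,
    eliminate_outliers: bool = True,
) -> list[CorrelationResult]:
    """All feature-response Spearman correlations with Bonferroni control.

    Outlier elimination is per pair (robust Mahalanobis on the 2-column
    slice), so each correlation may use a different subset of rows, as when a
    correlation table reports pair-specific n.
    """
    m = len(features) * len(responses)
    threshold = bonferroni_threshold(alpha, m)
    results = []
    for feat in features:
        for resp in responses:
            sub = table[[feat, resp]].dropna()
            if len(sub) < 10:
                raise ValueError(f"need >= 10 complete rows for {feat} vs {resp}")
            r, p, n_used, n_removed = spearman_pair(
                sub[feat].to_numpy(), sub[resp].to_numpy(), eliminate_outliers
            )
            results.append(
                CorrelationResult(
                    feature=feat, index=resp, r=r, p=p,
                    n_used=n_used, n_outliers_removed=n_removed,
                    significant=bool(np.isfinite(p) and p < threshold),
                )
            )
    return results


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# multicollinearity and Lasso feature selection
# ---------------------------------------------------------------------------


def drop_multicollinear(
    table: pd.DataFrame, features: list[str], r_cut: float = 0.9
) -> list[str]:
    """Greedy removal of |Spearman r| >= r_cut feature pairs.

    While any pair exceeds the cut, the member of the worst pair with the
    larger mean absolute correlation to the remaining features is dropped
    (ties broken lexicographically), so the result is deterministic.
    """
    if len(features) < 2:
        return list(features)
    kept = sorted(features)
    corr = table[kept].corr(method="spearman").abs()
    while len(kept) > 1:
        sub = corr.loc[kept, kept].copy()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.stack().idxmax()
        if sub.loc[worst] < r_cut:
            break
        a, b = sorted(worst)
        mean_a = sub.loc[a].drop([a, b]).mean() if len(kept) > 2 else 0.0
        mean_b = sub.loc[b].drop([a, b]).mean() if len(kept) > 2 else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # lexicographic tie-break
        kept.remove(drop)
    return [f for f in features if f in kept]


@dataclass
class LassoSelectionResult:
    top_feature: str
    mean_abs_coef: pd.Series
    coefficients: pd.DataFrame  # repeats x features
    alphas: pd.Series  # chosen regularization per repeat


def lasso_select(
    table: pd.DataFrame,
    features: list[str],
    response: str,
    split: float = 0.8,
    folds: int = 3,
    repeats: int = 100,
    seed: int = 0,
    n_alphas: int = 50,
) -> LassoSelectionResult:
    """Repeated cross-validated Lasso: the top feature over random splits.

    Per repeat: a fresh train/test split, a log-spaced regularization grid
    from the training lambda_max down four decades, lambda chosen by k-fold
    cross-validated mean squared error, coefficients recorded at the chosen
    lambda refit on the training split.  The top feature has the largest mean
    absolute standardized coefficient over repeats.
    """
    X = table[features].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    rng = np.random.default_rng(seed)
    coefs = np.zeros((repeats, len(features)))
    alphas_used = np.zeros(repeats)
    for rep in range(repeats):
        rep_seed = int(rng.integers(2**31))
        X_tr, _, y_tr, _ = train_test_split(
            X, y, train_size=split, random_state=rep_seed
        )
        # standardize within the training split
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X_tr - mu) / sd
        yc = y_tr - y_tr.mean()
        lam_max = np.max(np.abs(Z.T @ yc)) / len(yc)
        grid = np.logspace(np.log10(lam_max), np.log10(lam_max) - 4.0, n_alphas)
        cv = KFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        model = LassoCV(alphas=grid, cv=cv, max_iter=10000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z, yc)
        coefs[rep] = model.coef_
        alphas_used[rep] = model.alpha_
    mean_abs = pd.Series(np.abs(coefs).mean(axis=0), index=features)
    return LassoSelectionResult(
        top_feature=str(mean_abs.idxmax()),
        mean_abs_coef=mean_abs,
        coefficients=pd.DataFrame(coefs, columns=features),
        alphas=pd.Series(alphas_used),
    )


# ---------------------------------------------------------------------------
# univariate regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def univariate_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with adjusted R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    r2 = float(model.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        adjusted_r_squared=adj,
        p_value=float(model.pvalues[1]),
        n=n,
    )
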