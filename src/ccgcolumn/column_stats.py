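"""Quantitative relationships over significant pairs: binned curves, fits,
distance matching, standardized regressions and composition tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    target: str
    predictor_names: list
    coefficients: np.ndarray
    intercept: float
    r_squared: float
    cost: str
    n: int


def binned_relationship(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 10,
    stat: str = "mean",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantile-binned summary of y against x with bootstrap 95% CIs.

    Bins are deciles of ``x`` by default; tied quantile edges are merged with
    a warning.  Returns columns bin_center, stat, ci_lo, ci_hi, n.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < n_bins:
        raise ValueError("fewer points than bins")
    statfun = {"mean": np.mean, "median": np.median}[stat]
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        logger.warning("binned_relationship: tied quantile edges merged")
    edges = uniq
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        yb = y[sel]
        center = float(np.mean(x[sel]))
        val = float(statfun(yb))
        boots = np.array(
            [statfun(yb[rng.integers(0, len(yb), len(yb))]) for _ in range(n_boot)]
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(dict(bin_center=center, stat=val, ci_lo=float(lo), ci_hi=float(hi), n=int(sel.sum())))
    return pd.DataFrame(rows)


def fit_linear(x, y, cost: str = "MSE"):
    """Least-cost straight line; returns (slope, intercept, pearson_r)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (no spread)")
    slope, intercept = np.polyfit(x, y, 1)
    if cost == "MAE":
        res = optimize.minimize(
            lambda p: np.abs(y - (p[0] * x + p[1])).mean(),
            x0=[slope, intercept],
            method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000),
        )
        slope, intercept = res.x
    elif cost != "MSE":
        raise ValueError(f"unknown cost {cost!r}")
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    return float(slope), float(intercept), r


def fit_exponential_decay(x, y, cost: str = "MAE"):
    """Fit y ≈ a·exp(−x/λ); returns (amplitude, lambda, half_distance, r).

    The decay constant λ is the e-fold distance; the half distance λ·ln 2 is
    reported alongside.  A fit driving λ beyond 100× the x-range is flagged
    as no-decay (λ = inf).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (y <= 0).any():
        raise ValueError("exponential fit requires positive y")
    # log-linear initialisation
    b, log_a = np.polyfit(x, np.log(y), 1)
    lam0 = np.inf if b >= 0 else -1.0 / b
    a0 = float(np.exp(log_a))
    if not np.isfinite(lam0):
        return float(np.mean(y)), np.inf, np.inf, 0.0
    costfun = {"MAE": lambda r: np.abs(r).mean(), "MSE": lambda r: (r**2).mean()}[cost]
    res = optimize.minimize(
        lambda p: costfun(y - p[0] * np.exp(-x / p[1])),
        x0=[a0, lam0],
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-14, maxiter=10000),
    )
    a, lam = res.x
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    if lam > 100 * max(np.ptp(x), 1e-12):
        logger.warning("fit_exponential_decay: no decay detected")
        return float(a), np.inf, np.inf, r
    return float(a), float(lam), float(lam * np.log(2)), r


def distance_match(pairs: pd.DataFrame, tolerance_um: float = 2.0) -> dict:
    """Adjacent pairing of distance-sorted significant CCGs.

    Sorts by ``distance_um``, pairs ranks (1,2), (3,4), …; an odd leftover is
    dropped.  Returns the matched table, the fraction of matches whose
    distance difference is below ``tolerance_um``, and the correlations of
    Δ|peak lag| and Δefficacy against Δr_ori.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 significant pairs")
    s = pairs.sort_values("distance_um", kind="mergesort").reset_index(drop=True)
    n = len(s) - (len(s) % 2)
    if n < len(s):
        logger.info("distance_match: dropping odd leftover pair")
    a = s.iloc[0:n:2].reset_index(drop=True)
    b = s.iloc[1:n:2].reset_index(drop=True)
    matched = pd.DataFrame(
        dict(
            d_distance=(b["distance_um"] - a["distance_um"]).abs(),
            d_abs_lag=b["peak_lag_ms"].abs() - a["peak_lag_ms"].abs(),
            d_efficacy=b["peak_efficacy"] - a["peak_efficacy"],
            d_r_ori=b["r_ori"] - a["r_ori"] if "r_ori" in b else np.nan,
        )
    )
    frac_close = float((matched["d_distance"] < tolerance_um).mean())
    out = dict(matched=matched, n_matches=len(matched), frac_within_tolerance=frac_close)
    if "r_ori" in b:
        ok = matched[["d_abs_lag", "d_efficacy", "d_r_ori"]].notna().all(axis=1)
        m = matched[ok]
        out["corr_dlag_drori"] = float(np.corrcoef(m["d_abs_lag"], m["d_r_ori"])[0, 1])
        out["corr_defficacy_drori"] = float(np.corrcoef(m["d_efficacy"], m["d_r_ori"])[0, 1])
    return out


def _iqr_mask(y: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    return (y >= q1 - k * iqr) & (y <= q3 + k * iqr)


def fit_standardized_regression(
    pairs: pd.DataFrame,
    target: str = "peak_lag",
    predictors=("distance_um", "r_ori"),
    remove_outliers: bool = True,
) -> RegressionResult:
    """OLS of |peak lag| or peak efficacy on z-scored predictors.

    Predictors are standardized so coefficients read as change per 1 SD;
    target outliers beyond 1.5·IQR of the quartiles are removed first.
    """
    if target == "peak_lag":
        y = pairs["peak_lag_ms"].abs().to_numpy(float)
    elif target == "peak_efficacy":
        y = pairs["peak_efficacy"].to_numpy(float)
    else:
        y = pairs[target].to_numpy(float)
    X = pairs.loc[:, list(predictors)].to_numpy(float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    if len(y) < 10:
        raise ValueError("need at least 10 pairs")
    if remove_outliers:
        keep = _iqr_mask(y)
        y, X = y[keep], X[keep]
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    corr = np.corrcoef(Xz, rowvar=False)
    if np.any(np.abs(corr[np.triu_indices_from(corr, k=1)]) >= 1 - 1e-12):
        raise ValueError("collinear predictors")
    A = np.column_stack([np.ones(len(y)), Xz])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(
        target=target,
        predictor_names=list(predictors),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        r_squared=r2,
        cost="MSE",
        n=len(y),
    )


def one_proportion_ztest(successes: int, n: int, p0: float = 0.5):
    """Normal-approximation test of a proportion against p0; returns (z, p)."""
    if n == 0:
        return np.nan, np.nan
    phat = successes / n
    se = np.sqrt(p0 * (1 - p0) / n)
    z = (phat - p0) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def class_composition_tests(pairs: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Within/between-layer composition per class plus cross-class tests.

    Per class: proportion of pairs with both units in the same layer, with a
    one-proportion z-test against 0.5.  Across classes: a class × layer-pairing
    chi-squared contingency test and Wilcoxon rank-sum tests of distance and
    r_ori between every pair of classes.  Bonferroni correction is applied
    within each family; tests with expected counts below 5 are flagged.
    """
    if "class_label" not in pairs or "layer_ref" not in pairs:
        raise ValueError("pairs must carry class labels and layer pairings")
    df = pairs.dropna(subset=["class_label"]).copy()
    df["within_layer"] = df["layer_ref"] == df["layer_target"]
    classes = sorted(df["class_label"].unique())

    within_rows = []
    for c in classes:
        sub = df[df["class_label"] == c]
        n = len(sub)
        k = int(sub["within_layer"].sum())
        z, p = one_proportion_ztest(k, n)
        within_rows.append(
            dict(
                class_label=c,
                n=n,
                within_proportion=k / n if n else np.nan,
                z=z,
                p=p,
                p_bonferroni=min(1.0, p * len(classes)) if np.isfinite(p) else np.nan,
                unreliable=n * 0.5 < 5,
            )
        )
    within = pd.DataFrame(within_rows)

    table = pd.crosstab(df["class_label"], df["within_layer"])
    if table.size and (table.shape[0] > 1 and table.shape[1] > 1):
        chi2, chi_p, dof, expected = stats.chi2_contingency(table)
        chi = dict(
            chi2=float(chi2),
            p=float(chi_p),
            dof=int(dof),
            unreliable=bool((expected < 5).any()),
        )
    else:
        chi = dict(chi2=np.nan, p=np.nan, dof=0, unreliable=True)

    rank_rows = []
    metrics = [m for m in ("distance_um", "r_ori") if m in df]
    n_comparisons = len(metrics) * len(classes) * (len(classes) - 1) // 2
    for metric in metrics:
        for i, c1 in enumerate(classes):
            for c2 in classes[i + 1 :]:
                a = df.loc[df["class_label"] == c1, metric].dropna()
                b = df.loc[df["class_label"] == c2, metric].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                u, p = stats.ranksums(a, b)
                rank_rows.append(
                    dict(
                        metric=metric,
                        class_a=c1,
                        class_b=c2,
                        statistic=float(u),
                        p=float(p),
                        p_bonferroni=min(1.0, p * max(n_comparisons, 1)),
                    )
                )
    return dict(
        within_between=within,
        chi_squared=chi,
        rank_sums=pd.DataFrame(rank_rows),
        alpha=alpha,
        bonferroni_families=dict(
            within_between=len(classes), rank_sums=max(n_comparisons, 1)
        ),
    )


def layer_logistic_regression(
    pairs: pd.DataFrame,
    class_label: str | list,
    distance_range: tuple[float, float] = (86.0, 310.0),
) -> pd.DataFrame:
    """Logistic regression of class membership on distance and same-layer flag.

    Restricted to pairs inside ``distance_range``; outcome is membership in
    ``class_label`` (a label or list of labels).  Falls back to an L2-penalised
    fit under complete separation.
    """
    import statsmodels.api as sm

    labels = [class_label] if isinstance(class_label, str) else list(class_label)
    df = pairs.dropna(subset=["class_label"]).copy()
    lo, hi = distance_range
    df = df[(df["distance_um"] > lo) & (df["distance_um"] < hi)]
    if len(df) < 20:
        raise ValueError(f"fewer than 20 pairs in distance range {distance_range}")
    y = df["class_label"].isin(labels).astype(int).to_numpy()
    X = sm.add_constant(
        np.column_stack(
            [
                df["distance_um"].to_numpy(float),
                (df["layer_ref"] == df["layer_target"]).astype(float).to_numpy(),
            ]
        )
    )
    names = ["intercept", "distance", "same_layer"]
    flagged = False
    try:
        fit = sm.Logit(y, X).fit(disp=0)
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
    except Exception:
        flagged = True
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
        params = np.asarray(fit.params)
        bse = np.full_like(params, np.nan)
        pvalues = np.full_like(params, np.nan)
        logger.warning("layer_logistic_regression: separation, penalised fallback")
    return pd.DataFrame(
        dict(
            predictor=names,
            coefficient=np.asarray(params),
            std_error=np.asarray(bse),
            p_value=np.asarray(pvalues),
            separation_flag=flagged,
        )
    )


def simple_complex_direction_test(pairs: pd.DataFrame, cell_class: pd.Series) -> dict:
    """Forward vs reverse composition among simple→complex pairs.

    Restricts to significant pairs whose reference unit is simple and target
    unit complex, then z-tests the F_async share of asynchronous pairs
    against 0.5.
    """
    df = pairs.dropna(subset=["class_label"]).copy()
    ref_class = df["ref_unit"].map(cell_class)
    tgt_class = df["target_unit"].map(cell_class)
    sc = df[(ref_class == "simple") & (tgt_class == "complex")]
    counts = sc["class_label"].value_counts()
    n_f = int(counts.get("F_async", 0))
    n_r = int(counts.get("R_async", 0))
    if n_f + n_r == 0:
        return dict(n_pairs=len(sc), counts=counts.to_dict(), z=np.nan, p=np.nan)
    z, p = one_proportion_ztest(n_f, n_f + n_r)
    return dict(
        n_pairs=len(sc),
        counts=counts.to_dict(),
        forward_proportion=n_f / (n_f + n_r),
        z=z,
        p=p,
    )
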