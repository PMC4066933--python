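"""Integrative regression of module gene significance on connectivity and
module-QTL correlations.

Observations here are module probes, not samples: each probe contributes
its gene significance for WHO grade (GS), its module membership (kME),
its intramodular connectivity (kIN), and one GSmQTL column per selected
mQTL SNP (the Spearman correlation of the probe's expression with that
SNP's allele count).  Responses are rank-inverse-normal transformed;
models are ordinary least squares with stepwise AIC selection; the
significant GSmQTL columns are aggregated by coefficient sign into
"risk" (positive) and "protective" (negative) sums, which together with
kME form the final three-regressor model.  Model-level VIF is
1/(1 - R^2); per-predictor VIFs diagnose multicollinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionReport",
    "gsmqtl_matrix",
    "rank_inverse_normal",
    "fit_linear",
    "stepwise_aic",
    "aggregate_risk_protective",
    "final_model",
    "dichotomize_groups",
]


@dataclass
class RegressionReport:
    response: str
    predictors: list
    coefficients: pd.Series  # includes "intercept"
    std_errors: pd.Series
    p_values: pd.Series  # two-sided t-test
    r_squared: float
    adjusted_r_squared: float
    aic: float
    model_vif: float
    predictor_vifs: pd.Series
    shapiro_w: float
    shapiro_p: float
    n_obs: int
    fitted: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    residuals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "se": self.std_errors,
                "p": self.p_values,
            }
        )


def gsmqtl_matrix(expr_module, geno, mqtl_ids) -> pd.DataFrame:
    """Per-probe Spearman correlation with each mQTL genotype.

    ``expr_module`` is an ExpressionMatrix restricted to module probes;
    missing genotypes are dropped pairwise.  Monomorphic SNPs are rejected.
    """
    ids = list(mqtl_ids)
    missing = [s for s in ids if s not in set(geno.snp_ids)]
    if missing:
        raise ValueError(f"mQTL ids not in genotype matrix: {missing[:5]}")
    samples = list(expr_module.sample_ids)
    out = pd.DataFrame(index=expr_module.probe_ids, columns=ids, dtype=float)
    for snp in ids:
        g = geno.calls.loc[samples, snp].to_numpy(dtype=float)
        ok = ~np.isnan(g)
        if np.unique(g[ok]).size < 2:
            raise ValueError(f"mQTL {snp!r} is monomorphic")
        gr = stats.rankdata(g[ok])
        vals = expr_module.values.loc[:, samples].to_numpy(dtype=float)[:, ok]
        ranks = np.apply_along_axis(stats.rankdata, 1, vals)
        out[snp] = [np.corrcoef(r, gr)[0, 1] for r in ranks]
    return out


def rank_inverse_normal(x) -> np.ndarray:
    """z_i = Phi^-1((r_i - 0.5)/n) with average ranks for ties."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if np.unique(arr).size < 2:
        raise ValueError("constant input has no rank-normal transform")
    r = stats.rankdata(arr)
    return stats.norm.ppf((r - 0.5) / arr.size)


def _aic(rss: float, n: int, n_coef: int) -> float:
    # RSS form with constant terms omitted; only AIC differences matter
    return n * np.log(rss / n) + 2 * (n_coef + 1)


def fit_linear(response, predictors: pd.DataFrame, response_name: str = "y") -> RegressionReport:
    """Ordinary least squares with the report fields used downstream.

    AIC = n ln(RSS/n) + 2(p+1) with p the number of coefficients including
    the intercept; model VIF = 1/(1 - R^2); per-predictor VIFs come from
    regressing each predictor on the others.  Residual normality is
    summarized by the Shapiro-Wilk W and p.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.to_numpy(dtype=float) if isinstance(predictors, pd.DataFrame) else np.atleast_2d(np.asarray(predictors, dtype=float))
    names = list(predictors.columns) if isinstance(predictors, pd.DataFrame) else [f"x{i}" for i in range(X.shape[1])]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n_rows > n_predictors + 1")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased = _aliased_columns(design, names)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    dof = n - k - 1
    sigma2 = rss / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    coef_names = ["intercept"] + names
    vifs = {}
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            vifs[name] = 1.0
            continue
        d2 = np.column_stack([np.ones(n), others])
        b2, _, _, _ = np.linalg.lstsq(d2, X[:, j], rcond=None)
        res2 = X[:, j] - d2 @ b2
        tss2 = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        r2j = 1.0 - float(res2 @ res2) / tss2 if tss2 > 0 else 0.0
        vifs[name] = 1.0 / max(1.0 - r2j, 1e-12)
    if n >= 3 and np.ptp(resid) > 0:
        sw, sp = stats.shapiro(resid)
    else:
        sw, sp = np.nan, np.nan
    return RegressionReport(
        response=response_name,
        predictors=names,
        coefficients=pd.Series(beta, index=coef_names),
        std_errors=pd.Series(se, index=coef_names),
        p_values=pd.Series(pvals, index=coef_names),
        r_squared=r2,
        adjusted_r_squared=adj_r2,
        aic=_aic(max(rss, 1e-300), n, k + 1),
        model_vif=1.0 / max(1.0 - r2, 1e-12),
        predictor_vifs=pd.Series(vifs, dtype=float),
        shapiro_w=float(sw),
        shapiro_p=float(sp),
        n_obs=n,
        fitted=fitted,
        residuals=resid,
    )


def _aliased_columns(design: np.ndarray, names: list) -> list:
    aliased = []
    kept = [0]  # intercept
    for j in range(1, design.shape[1]):
        trial = design[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j - 1])
    return aliased


def _aic_of_subset(y: np.ndarray, X: np.ndarray, cols: tuple) -> float:
    n = y.size
    design = np.ones((n, 1)) if not cols else np.column_stack([np.ones(n), X[:, list(cols)]])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = max(float(resid @ resid), 1e-300)
    return _aic(rss, n, design.shape[1])


def stepwise_aic(response, predictors: pd.DataFrame, direction: str = "both",
                 response_name: str = "y") -> RegressionReport:
    """Stepwise model selection minimizing AIC, starting from the full model.

    At each step every single-predictor addition and removal is evaluated
    and the move with the largest AIC decrease is applied; selection stops
    when no move decreases AIC.  Ties prefer removal, then the
    lexicographically first predictor.  Deterministic.
    """
    if direction not in ("both", "backward", "forward"):
        raise ValueError(f"unknown direction {direction!r}")
    y = np.asarray(response, dtype=float)
    names = list(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    design = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"aliased predictor columns: {_aliased_columns(design, names)}"
        )
    current = set(range(len(names))) if direction != "forward" else set()
    cur_aic = _aic_of_subset(y, X, tuple(sorted(current)))
    while True:
        moves = []  # (aic, prefer_removal_rank, name, new_set)
        if direction in ("both", "backward"):
            for j in sorted(current, key=lambda j: names[j]):
                new = current - {j}
                moves.append((_aic_of_subset(y, X, tuple(sorted(new))), 0, names[j], new))
        if direction in ("both", "forward"):
            for j in sorted(set(range(len(names))) - current, key=lambda j: names[j]):
                new = current | {j}
                moves.append((_aic_of_subset(y, X, tuple(sorted(new))), 1, names[j], new))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best = moves[0]
        if best[0] < cur_aic - 1e-10:
            cur_aic = best[0]
            current = best[3]
        else:
            break
    # guard: never report a model with higher AIC than the empty model
    if _aic_of_subset(y, X, ()) < cur_aic - 1e-10:
        current = set()
    chosen = [names[j] for j in sorted(current)]
    if chosen:
        return fit_linear(y, predictors[chosen], response_name=response_name)
    return _intercept_only_report(y, response_name)


def _intercept_only_report(y: np.ndarray, response_name: str) -> RegressionReport:
    n = y.size
    resid = y - y.mean()
    rss = max(float(resid @ resid), 1e-300)
    sw, sp = stats.shapiro(resid) if n >= 3 and np.ptp(resid) > 0 else (np.nan, np.nan)
    return RegressionReport(
        response=response_name,
        predictors=[],
        coefficients=pd.Series({"intercept": float(y.mean())}),
        std_errors=pd.Series({"intercept": float(np.std(resid, ddof=1) / np.sqrt(n))}),
        p_values=pd.Series({"intercept": np.nan}),
        r_squared=0.0,
        adjusted_r_squared=0.0,
        aic=_aic(rss, n, 1),
        model_vif=1.0,
        predictor_vifs=pd.Series(dtype=float),
        shapiro_w=float(sw),
        shapiro_p=float(sp),
        n_obs=n,
        fitted=np.full(n, y.mean()),
        residuals=resid,
    )


def aggregate_risk_protective(report: RegressionReport, gsmqtl: pd.DataFrame,
                              p_threshold: float = 0.01):
    """Sum significant GSmQTL columns by coefficient sign.

    Risk = rowwise sum of columns entering the model with a positive
    coefficient and p < threshold; Protective = likewise for negative
    coefficients.  Returns (risk Series, protective Series).
    """
    risk_cols, prot_cols = [], []
    for name in report.predictors:
        if name not in gsmqtl.columns:
            continue
        if report.p_values[name] < p_threshold:
            if report.coefficients[name] > 0:
                risk_cols.append(name)
            elif report.coefficients[name] < 0:
                prot_cols.append(name)
    if not risk_cols and not prot_cols:
        warnings.warn("no significant GSmQTL variables; risk/protective are zero")
    zero = pd.Series(0.0, index=gsmqtl.index)
    risk = gsmqtl[risk_cols].sum(axis=1) if risk_cols else zero.copy()
    prot = gsmqtl[prot_cols].sum(axis=1) if prot_cols else zero.copy()
    return risk.rename("GSmQTLRisk"), prot.rename("GSmQTLProtective")


def final_model(gs, kme, protective, risk) -> tuple[RegressionReport, pd.Series, float]:
    """OLS of rank-inverse-normal(GS) on kME, protective and risk sums.

    Returns (report, fitted values, Spearman rho between fitted and the
    observed untransformed GS).  A constant regressor (e.g. an all-zero
    protective sum) is dropped, collapsing to the smaller model.
    """
    idx = kme.index
    preds = pd.DataFrame(
        {"kME": kme, "GSmQTLProtective": protective, "GSmQTLRisk": risk}, index=idx
    )
    keep = [c for c in preds.columns if preds[c].nunique() > 1]
    gs_arr = np.asarray(gs, dtype=float)
    report = fit_linear(rank_inverse_normal(gs_arr), preds[keep], response_name="GS_WHO_Grade")
    fitted = pd.Series(report.fitted, index=idx, name="fitted_GS")
    rho = float(stats.spearmanr(fitted, gs_arr).statistic)
    return report, fitted, rho


def dichotomize_groups(kme, risk, protective, gs) -> pd.DataFrame:
    """Median splits of kME (K), risk (R) and protective (P) vs gene significance.

    Probes strictly above the median go to the "+" group; values at or
    below the median go to "-".  Returns one row per K/R/P combination with
    the group size and the GS mean/median/quartiles.
    """
    kme = pd.Series(kme)
    risk = pd.Series(risk, index=kme.index)
    prot = pd.Series(protective, index=kme.index)
    gs = pd.Series(gs, index=kme.index)
    labels = {}
    for tag, vec in (("K", kme), ("R", risk), ("P", prot)):
        med = vec.median()
        if vec.nunique() < 2:
            warnings.warn(f"constant vector for {tag} split; all probes in {tag}-")
        labels[tag] = np.where(vec > med, "+", "-")
    rows = []
    for ktag in ("+", "-"):
        for rtag in ("+", "-"):
            for ptag in ("+", "-"):
                mask = (labels["K"] == ktag) & (labels["R"] == rtag) & (labels["P"] == ptag)
                sub = gs[mask]
                rows.append(
                    {
                        "group": f"K{ktag}R{rtag}P{ptag}",
                        "n": int(mask.sum()),
                        "gs_mean": float(sub.mean()) if len(sub) else np.nan,
                        "gs_median": float(sub.median()) if len(sub) else np.nan,
                        "gs_q1": float(sub.quantile(0.25)) if len(sub) else np.nan,
                        "gs_q3": float(sub.quantile(0.75)) if len(sub) else np.nan,
                    }
                )
    return pd.DataFrame(rows).set_index("group")
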