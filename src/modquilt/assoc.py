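"""SNP association scans: module-QTL mapping, stage association, genomic control.

Following the snpStats "SNP as outcome" convention, each genotype (an
allele count out of 2) is modelled as a binomial-logistic response with
the module summaries (eigengene, PC2, PC1+PC2) or the binary tumor stage
as regressors; p-values come from a likelihood-ratio test against the
base model (intercept-only unless covariates are held fixed).  A score
test is available as an asymptotically equivalent option.  Hits are
tiered: "significant" at p <= 1e-6, "suggestive" at p < 1e-4.  Genomic
control reports lambda = median(chi2_1 quantiles of p) / 0.4549364.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats

__all__ = [
    "AssociationRecord",
    "LambdaReport",
    "genotype_outcome_test",
    "mqtl_scan",
    "classify_tier",
    "dedup_by_gene",
    "stage_scan",
    "genomic_lambda",
    "replicate_overlap",
    "TIER_SIGNIFICANT_P",
    "TIER_SUGGESTIVE_P",
]

TIER_SIGNIFICANT_P = 1e-6
TIER_SUGGESTIVE_P = 1e-4
CHI2_1_MEDIAN = 0.4549364


@dataclass
class AssociationRecord:
    snp_id: str
    model: str
    effect: float
    se: float
    p_value: float
    tier: str = "none"
    gene: str = ""
    note: str = ""
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "model": self.model,
            "effect": self.effect,
            "se": self.se,
            "p": self.p_value,
            "tier": self.tier,
            "gene": self.gene,
            "note": self.note,
            "n": self.n,
        }


@dataclass
class LambdaReport:
    n_tests: int
    lambda_gc: float


def _binomial_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # y in {0,1,2} successes of 2 trials; constant binom(2, y) term included
    pi = 1.0 / (1.0 + np.exp(-eta))
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    const = np.where(y == 1, np.log(2.0), 0.0)
    return float(np.sum(const + y * np.log(pi) + (2 - y) * np.log(1 - pi)))


def _fit_binomial_logit(y: np.ndarray, X: np.ndarray, ridge: float = 0.0,
                        maxiter: int = 50, tol: float = 1e-10):
    """Newton-Raphson fit of logit(pi) = X b with y ~ Binomial(2, pi).

    Returns (beta, cov, loglik, converged).  ``ridge`` adds an L2 penalty on
    the non-intercept coefficients (used as a fallback under separation).
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.zeros(p)
    pen[1:] = ridge
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = 2.0 * pi * (1.0 - pi)
        grad = X.T @ (y - 2.0 * pi) - pen * beta
        info = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, None, -np.inf, False
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
        if np.max(np.abs(beta)) > 1e4:
            break
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = 2.0 * pi * (1.0 - pi)
    info = (X * w[:, None]).T @ X + np.diag(pen)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = None
    return beta, cov, _binomial_loglik(y, eta), converged


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.column_stack([np.ones(n), cov])


def _score_test(y: np.ndarray, X_base: np.ndarray, X_add: np.ndarray) -> tuple[float, float]:
    """GLM score test of the added covariates at the base-model fit."""
    beta0, _, _, _ = _fit_binomial_logit(y, X_base)
    eta = X_base @ beta0
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = 2.0 * pi * (1.0 - pi)
    u = X_add.T @ (y - 2.0 * pi)
    i_aa = (X_add * w[:, None]).T @ X_add
    i_ab = (X_add * w[:, None]).T @ X_base
    i_bb = (X_base * w[:, None]).T @ X_base
    v = i_aa - i_ab @ np.linalg.solve(i_bb, i_ab.T)
    stat = float(u @ np.linalg.solve(v, u))
    df = X_add.shape[1]
    return stat, float(stats.chi2.sf(stat, df))


def genotype_outcome_test(
    genotype_vec,
    covariates,
    base_covariates=None,
    snp_id: str = "",
    model: str = "ME",
    method: str = "lrt",
) -> AssociationRecord:
    """Binomial-logistic association test with the SNP as outcome.

    ``covariates`` are the regressors added on top of ``base_covariates``;
    the p-value is a likelihood-ratio (or score) test of the addition, with
    as many degrees of freedom as added columns.  Missing genotypes are
    dropped pairwise.  Monomorphic or sparse genotypes are skipped; under
    separation/non-convergence a ridge-penalized refit is used and flagged.
    """
    y_full = np.asarray(genotype_vec, dtype=float)
    add = np.atleast_2d(np.asarray(covariates, dtype=float))
    if add.shape[0] != y_full.shape[0]:
        add = add.T
    base = None
    if base_covariates is not None:
        base = np.atleast_2d(np.asarray(base_covariates, dtype=float))
        if base.shape[0] != y_full.shape[0]:
            base = base.T
    ok = ~np.isnan(y_full)
    ok &= ~np.isnan(add).any(axis=1)
    if base is not None:
        ok &= ~np.isnan(base).any(axis=1)
    y = y_full[ok]
    if y.size < 10:
        return AssociationRecord(snp_id, model, np.nan, np.nan, np.nan, "none", note="skip:too_few", n=int(y.size))
    if np.unique(y).size < 2:
        return AssociationRecord(snp_id, model, np.nan, np.nan, np.nan, "none", note="skip:monomorphic", n=int(y.size))
    X_add = add[ok]
    X_base = _design(base[ok] if base is not None else None, y.size)
    X_full = np.column_stack([X_base, X_add])
    df = X_add.shape[1]

    if method == "score":
        stat, p = _score_test(y, X_base, X_add)
        return AssociationRecord(snp_id, model, np.nan, np.nan, _clip_p(p), classify_tier(_clip_p(p)), n=int(y.size))
    if method != "lrt":
        raise ValueError(f"unknown method {method!r}")

    bf, cov_f, ll_f, conv_f = _fit_binomial_logit(y, X_full)
    bb, _, ll_b, conv_b = _fit_binomial_logit(y, X_base)
    note = ""
    big = np.max(np.abs(bf)) > 50
    if not (conv_f and conv_b) or big or cov_f is None or ll_f < ll_b:
        # separation or non-convergence: penalized refit with the same ridge
        # in both models so the LRT stays comparable
        bf, cov_f, ll_f, _ = _fit_binomial_logit(y, X_full, ridge=1e-2)
        bb, _, ll_b, _ = _fit_binomial_logit(y, X_base, ridge=1e-2)
        note = "penalized"
    lr = max(0.0, 2.0 * (ll_f - ll_b))
    p = _clip_p(float(stats.chi2.sf(lr, df)))
    j = X_base.shape[1]  # first added coefficient
    se = float(np.sqrt(cov_f[j, j])) if cov_f is not None else np.nan
    return AssociationRecord(
        snp_id, model, float(bf[j]), se, p, classify_tier(p), note=note, n=int(y.size)
    )


def _clip_p(p: float) -> float:
    return float(min(max(p, 5e-324), 1.0))


def classify_tier(p: float) -> str:
    """"significant" at p <= 1e-6, "suggestive" at 1e-6 < p < 1e-4."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if p <= TIER_SIGNIFICANT_P:
        return "significant"
    if p < TIER_SUGGESTIVE_P:
        return "suggestive"
    return "none"


def _scan(geno, covariates, base, model, gene_map=None, method="lrt") -> pd.DataFrame:
    records = []
    for snp in geno.snp_ids:
        rec = genotype_outcome_test(
            geno.calls[snp].to_numpy(dtype=float),
            covariates,
            base,
            snp_id=snp,
            model=model,
            method=method,
        )
        if gene_map is not None:
            rec.gene = gene_map.get(snp, "")
        elif "gene" in geno.snp_meta.columns:
            rec.gene = str(geno.snp_meta.loc[snp, "gene"])
        records.append(rec.as_dict())
    return pd.DataFrame.from_records(records).set_index("snp_id")


def mqtl_scan(geno, me, pc2, method: str = "lrt") -> dict:
    """The three module-QTL scans.

    A: genotype ~ ME; B: improvement of adding PC2 over the ME base model
    (1-df LRT); C: genotype ~ (PC1 + PC2) as a single summed regressor.
    Returns {"ME": table, "ME_plus_PC2_improvement": table, "PC1plusPC2": table}.
    """
    me_v = np.asarray(me, dtype=float)
    pc2_v = np.asarray(pc2, dtype=float)
    return {
        "ME": _scan(geno, me_v, None, "ME", method=method),
        "ME_plus_PC2_improvement": _scan(geno, pc2_v, me_v, "ME_plus_PC2_improvement", method=method),
        "PC1plusPC2": _scan(geno, me_v + pc2_v, None, "PC1plusPC2", method=method),
    }


def dedup_by_gene(table: pd.DataFrame, snp_to_gene: dict | None = None) -> pd.DataFrame:
    """Keep only the most significant SNP per gene.

    Unmapped SNPs pass through.  Ties on p break lexicographically by snp_id.
    """
    tab = table.copy()
    if snp_to_gene is not None:
        tab["gene"] = [snp_to_gene.get(s, "") for s in tab.index]
    tab["_snp"] = tab.index
    tab = tab.sort_values(["p", "_snp"], kind="stable")
    mapped = tab["gene"].astype(str) != ""
    kept_mapped = tab[mapped].loc[~tab[mapped].duplicated("gene")]
    out = pd.concat([kept_mapped, tab[~mapped]])
    out = out.loc[table.index.intersection(out.index)]  # original order
    return out.drop(columns="_snp")


def stage_scan(geno, stage_binary, method: str = "lrt") -> pd.DataFrame:
    """Genotype-vs-stage scan: each SNP regressed on the binary stage."""
    stage = np.asarray(stage_binary, dtype=float)
    classes = np.unique(stage[~np.isnan(stage)])
    if classes.size < 2:
        raise ValueError("both stage classes must be present")
    return _scan(geno, stage, None, "stage", method=method)


def genomic_lambda(p_values) -> LambdaReport:
    """Genomic-control inflation factor from a vector of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must be in (0, 1]")
    q = stats.chi2.isf(p, df=1)
    return LambdaReport(n_tests=int(p.size), lambda_gc=float(np.median(q) / CHI2_1_MEDIAN))


def replicate_overlap(tables: dict, gene_maps: dict, proxy_maps: dict | None = None,
                      tiers=("significant", "suggestive")) -> dict:
    """Gene overlaps across tiered association tables.

    ``tables`` maps a table name to an AssociationTable (with a ``tier``
    column); ``gene_maps`` maps table name -> {snp_id: gene or [genes]};
    ``proxy_maps`` optionally adds proxy genes (e.g. via user-supplied LD
    lists), reported with provenance "proxy".  Returns per-pair overlaps and
    the genes present in >= 2 lists under key "duplicates".
    """
    proxy_maps = proxy_maps or {}
    gene_sets: dict[str, dict] = {}
    for name, tab in tables.items():
        selected = tab[tab["tier"].isin(tiers)]
        provenance: dict[str, str] = {}
        gmap = gene_maps.get(name, {})
        pmap = proxy_maps.get(name, {})
        for snp in selected.index:
            for g in _as_list(gmap.get(snp)):
                provenance.setdefault(g, "direct")
            for g in _as_list(pmap.get(snp)):
                provenance.setdefault(g, "proxy")
        gene_sets[name] = provenance
    names = sorted(tables)
    out: dict = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = sorted(set(gene_sets[a]) & set(gene_sets[b]))
            out[(a, b)] = [
                {"gene": g, "provenance_a": gene_sets[a][g], "provenance_b": gene_sets[b][g]}
                for g in shared
            ]
    counts: dict[str, int] = {}
    for prov in gene_sets.values():
        for g in prov:
            counts[g] = counts.get(g, 0) + 1
    out["duplicates"] = sorted(g for g, c in counts.items() if c >= 2)
    return out


def _as_list(v):
    if v is None:
        return []
    if isinstance(v, str):
        return [v]
    return list(v)
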