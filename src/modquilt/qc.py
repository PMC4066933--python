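"""Genotype and expression quality control.

SNPs must pass three filters, all inclusive: minor allele frequency >= 5%,
call rate >= 95%, and a Hardy-Weinberg equilibrium p-value >= 0.01.
Expression probes are kept when they show at least a 1.8-fold change from
the probe median in at least 10% of samples; because intensities arrive
log2-transformed, the fold-change rule is |x - median| >= log2(1.8).
Probes annotated to a dropped chromosome (Y by default) are removed.
Missing expression values are imputed by k-nearest-neighbour averaging
over probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .dataio import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "minor_allele_frequency",
    "call_rate",
    "hwe_test",
    "hwe_exact_test",
    "filter_snps",
    "variance_filter",
    "drop_chromosome",
    "knn_impute",
]


@dataclass
class QcThresholds:
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.01
    fold_change: float = 1.8
    sample_fraction: float = 0.10
    knn_k: int = 10

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "sample_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def minor_allele_frequency(calls) -> float:
    """Folded allele frequency min(p, 1-p) from 0/1/2 calls (NaN = missing)."""
    arr = np.asarray(calls, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("all calls missing; MAF undefined")
    p = arr.sum() / (2 * arr.size)
    return float(min(p, 1 - p))


def call_rate(calls) -> float:
    arr = np.asarray(calls, dtype=float)
    if arr.size == 0:
        raise ValueError("no calls")
    return float((~np.isnan(arr)).sum() / arr.size)


def _genotype_counts(calls) -> tuple[int, int, int]:
    arr = np.asarray(calls, dtype=float)
    arr = arr[~np.isnan(arr)]
    return int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum())


def hwe_test(counts) -> tuple[float, float]:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    ``counts`` is (n_AA, n_Aa, n_aa).  Expected counts are n(1-p)^2,
    2np(1-p), np^2 with p the observed alternate-allele frequency; no
    continuity correction is applied.
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype counts")
    p = (n_ab + 2 * n_bb) / (2 * n)
    if p in (0.0, 1.0):
        raise ValueError("monomorphic counts; HWE undefined")
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(counts) -> float:
    """Exact Hardy-Weinberg test (Wigginton-style mid-less p), optional
    alternative to the chi-square; sums the probabilities of heterozygote
    counts no more likely than the observed one."""
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb  # minor-allele copies, folded below
    if n_b > n:
        n_b = 2 * n - n_b
        obs_het = n_ab
    else:
        obs_het = n_ab
    if n == 0:
        raise ValueError("no genotype counts")
    # enumerate heterozygote counts with the observed allele counts
    hets = np.arange(n_b % 2, n_b + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    n_a = 2 * n - n_b
    for i, h in enumerate(hets):
        hom_b = (n_b - h) // 2
        hom_a = n - h - hom_b
        logp[i] = (
            gammaln(n + 1)
            - gammaln(hom_a + 1)
            - gammaln(h + 1)
            - gammaln(hom_b + 1)
            + h * np.log(2)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == obs_het][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def filter_snps(
    geno: GenotypeMatrix, thresholds: QcThresholds | None = None, exact_hwe: bool = False
):
    """Apply the three SNP filters to the original matrix (not sequentially).

    Returns (filtered GenotypeMatrix, report DataFrame).  The report holds
    each SNP's MAF, call rate, HWE p-value, kept flag, and the failing
    rule(s) as a comma-separated string.
    """
    th = thresholds or QcThresholds()
    rows = []
    for snp in geno.snp_ids:
        calls = geno.calls[snp].to_numpy(dtype=float)
        cr = call_rate(calls)
        nonmiss = calls[~np.isnan(calls)]
        if nonmiss.size == 0:
            rows.append((snp, np.nan, cr, np.nan, False, "maf,call_rate,hwe"))
            continue
        maf = minor_allele_frequency(calls)
        counts = _genotype_counts(calls)
        if maf == 0.0:
            hwe_p = np.nan  # monomorphic: undefined, but MAF filter removes it
        elif exact_hwe:
            hwe_p = hwe_exact_test(counts)
        else:
            hwe_p = hwe_test(counts)[1]
        reasons = []
        if maf < th.maf_min:
            reasons.append("maf")
        if cr < th.call_rate_min:
            reasons.append("call_rate")
        if not np.isnan(hwe_p) and hwe_p < th.hwe_p_min:
            reasons.append("hwe")
        rows.append((snp, maf, cr, hwe_p, not reasons, ",".join(reasons)))
    report = pd.DataFrame(
        rows, columns=["snp_id", "maf", "call_rate", "hwe_p", "kept", "reasons"]
    ).set_index("snp_id")
    kept = report.index[report["kept"]].tolist()
    return geno.subset_snps(kept), report


def variance_filter(expr: ExpressionMatrix, thresholds: QcThresholds | None = None):
    """Keep probes with >= ``fold_change``-fold deviation from the probe
    median in >= ``sample_fraction`` of samples (log2 scale, inclusive)."""
    th = thresholds or QcThresholds()
    vals = expr.values.to_numpy(dtype=float)
    cut = np.log2(th.fold_change)
    medians = np.nanmedian(vals, axis=1, keepdims=True)
    frac = (np.abs(vals - medians) >= cut).mean(axis=1)
    keep = frac >= th.sample_fraction
    return expr.subset_probes(np.asarray(expr.probe_ids)[keep])


def drop_chromosome(expr: ExpressionMatrix, chromosome: str = "Y") -> ExpressionMatrix:
    """Remove probes annotated to ``chromosome``; unannotated probes stay."""
    chrom = expr.probe_meta["chrom"].astype(str)
    keep = expr.probe_meta.index[chrom != str(chromosome)]
    return expr.subset_probes(keep)


def knn_impute(expr: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing cells from the k nearest probes.

    Distances are Euclidean over the samples both probes observe; a missing
    cell becomes the mean of the neighbours' values at that sample.
    """
    vals = expr.values.to_numpy(dtype=float)
    if not np.isnan(vals).any():
        return expr
    if np.isnan(vals).all(axis=1).any():
        bad = np.asarray(expr.probe_ids)[np.isnan(vals).all(axis=1)][0]
        raise ValueError(f"probe {bad!r} has no observed values")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(vals)
    out = pd.DataFrame(filled, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.probe_meta.copy())
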