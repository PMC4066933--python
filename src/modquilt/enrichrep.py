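"""Gene-set enrichment, PPI interaction enrichment, and replication statistics.

Enrichment is the hypergeometric upper tail of the query/term overlap in a
fixed gene universe, BH-adjusted across terms, with a coverage filter (the
fraction of the query matched by the term).  PPI enrichment compares the
observed within-set edge count with a permutation null of random node
subsets.  The replication statistics are a Welch t-test per probe between
stage groups (BH-flagged at q < 0.05), a location-scale batch adjustment,
and a Wilcoxon/permutation comparison of module membership (kME) between
the differentially expressed probes and the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, GeneSetCollection, PpiEdgeList

__all__ = [
    "hypergeom_enrichment",
    "bh_fdr",
    "ppi_enrichment",
    "batch_adjust",
    "stage_de",
    "connectivity_shift",
    "PpiEnrichment",
    "ConnectivityShift",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    query,
    sets: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.001,
    coverage_min: float = 0.10,
    coverage_mode: str = "query",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query.

    p = P(X >= x) with X ~ Hypergeometric(N, K, n) where N is the universe
    size, K the in-universe term size, n the in-universe query size and x
    the overlap.  ``coverage`` is x over the in-universe query size
    (``coverage_mode="query"``) or over the term size (``"term"``); a term
    passes iff BH q < ``fdr_threshold`` and coverage >= ``coverage_min``.
    """
    uni = frozenset(universe)
    q = frozenset(query) & uni
    if not q:
        raise ValueError("query and universe do not intersect")
    n_uni, n_query = len(uni), len(q)
    rows = []
    for term, (desc, genes) in sets.items():
        in_uni = genes & uni
        if not in_uni:
            continue
        overlap = q & in_uni
        x, big_k = len(overlap), len(in_uni)
        p = float(stats.hypergeom.sf(x - 1, n_uni, big_k, n_query))
        denom = n_query if coverage_mode == "query" else big_k
        rows.append(
            {
                "term": term,
                "description": desc,
                "universe_size": n_uni,
                "term_size": big_k,
                "query_size": n_query,
                "overlap": x,
                "coverage": x / denom,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    tab = pd.DataFrame(rows).set_index("term")
    if len(tab):
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        tab["pass"] = (tab["q"] < fdr_threshold) & (tab["coverage"] >= coverage_min)
        tab = tab.sort_values(["p", "term"], kind="stable")
    return tab


@dataclass
class PpiEnrichment:
    observed: int
    expected: float
    p_value: float
    n_permutations: int
    set_size: int
    null_quantiles: dict


def ppi_enrichment(gene_set, ppi: PpiEdgeList, b: int = 10000, seed: int = 0) -> PpiEnrichment:
    """Permutation test for excess protein-protein interactions within a set.

    The null draws ``b`` uniform random node subsets of the same size from
    the PPI node universe; p = (1 + #{null >= observed}) / (b + 1).
    """
    if b < 100:
        raise ValueError("need at least 100 permutations")
    nodes = sorted(ppi.nodes)
    members = sorted(set(gene_set) & set(nodes))
    if len(members) < 2:
        raise ValueError("fewer than 2 query genes are in the PPI universe")
    adj = {n: set() for n in nodes}
    for e in ppi.edges:
        a_node, b_node = tuple(e)
        adj[a_node].add(b_node)
        adj[b_node].add(a_node)

    def count_edges(subset) -> int:
        s = set(subset)
        return sum(len(adj[n] & s) for n in s) // 2

    observed = count_edges(members)
    rng = np.random.default_rng(seed)
    node_arr = np.asarray(nodes, dtype=object)
    null = np.empty(b, dtype=float)
    m = len(members)
    for i in range(b):
        null[i] = count_edges(rng.choice(node_arr, size=m, replace=False))
    p = (1 + int((null >= observed).sum())) / (b + 1)
    qs = {f"q{int(100 * q)}": float(np.quantile(null, q)) for q in (0.5, 0.95, 0.99)}
    return PpiEnrichment(observed, float(null.mean()), float(p), b, m, qs)


def batch_adjust(expr: ExpressionMatrix, batch_labels) -> ExpressionMatrix:
    """Location-scale batch adjustment.

    Per probe and batch, values are centred and scaled by the batch mean
    and sd, then rescaled to the probe's pooled mean and sd.  A batch with
    a single sample cannot be scaled and is rejected.
    """
    batches = pd.Series(batch_labels, index=expr.values.columns)
    vals = expr.values.to_numpy(dtype=float)
    out = np.empty_like(vals)
    pooled_mean = vals.mean(axis=1, keepdims=True)
    pooled_sd = vals.std(axis=1, ddof=1, keepdims=True)
    pooled_sd[pooled_sd == 0] = 1.0
    for b in batches.unique():
        cols = (batches == b).to_numpy()
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        sub = vals[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        out[:, cols] = (sub - mu) / sd * pooled_sd + pooled_mean
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        expr.probe_meta.copy(),
    )


def stage_de(expr: ExpressionMatrix, stage_binary, q_threshold: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per probe between stage groups, BH-adjusted.

    Constant probes get missing statistics and are excluded from the BH
    adjustment.  Returns a table with t, p, q and the DE flag at
    q < ``q_threshold``.
    """
    stage = np.asarray(pd.Series(stage_binary, index=expr.values.columns), dtype=float)
    g1 = expr.values.to_numpy(dtype=float)[:, stage == 1]
    g0 = expr.values.to_numpy(dtype=float)[:, stage == 0]
    if g1.shape[1] < 2 or g0.shape[1] < 2:
        raise ValueError("each stage group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g0, axis=1, equal_var=False)
    tab = pd.DataFrame({"t": t, "p": p}, index=expr.probe_ids)
    ok = tab["p"].notna()
    tab["q"] = np.nan
    if ok.any():
        tab.loc[ok, "q"] = bh_fdr(tab.loc[ok, "p"].to_numpy())
    tab["de"] = tab["q"] < q_threshold
    return tab


@dataclass
class ConnectivityShift:
    wilcoxon_stat: float
    wilcoxon_p: float
    mean_diff: float  # mean kME(flagged) - mean kME(unflagged)
    permutation_p: float
    n_permutations: int
    seed: int
    null_quantiles: dict


def connectivity_shift(kme_values, de_flags, b: int = 10000, seed: int = 0) -> ConnectivityShift:
    """Do differentially expressed probes sit deeper in the module?

    Two-sided Wilcoxon rank-sum of kME between flagged and unflagged
    probes, plus a permutation background: ``b`` random relabelings of the
    flag vector give the null distribution of the flagged-minus-unflagged
    mean kME difference; the empirical p is two-sided on |difference|.
    """
    kme = np.asarray(kme_values, dtype=float)
    flags = np.asarray(de_flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("need at least one flagged and one unflagged probe")
    stat, p = stats.ranksums(kme[flags], kme[~flags])
    obs = kme[flags].mean() - kme[~flags].mean()
    rng = np.random.default_rng(seed)
    null = np.empty(b)
    for i in range(b):
        perm = rng.permutation(flags)
        null[i] = kme[perm].mean() - kme[~perm].mean()
    perm_p = (1 + int((np.abs(null) >= abs(obs)).sum())) / (b + 1)
    qs = {f"q{int(100 * q)}": float(np.quantile(null, q)) for q in (0.5, 0.95, 0.99)}
    return ConnectivityShift(float(stat), float(p), float(obs), float(perm_p), b, seed, qs)
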