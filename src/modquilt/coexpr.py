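"""Weighted co-expression network construction and module statistics.

The adjacency between probes i and j is |cor(x_i, x_j)|^beta with a soft
thresholding power beta (default 6).  Scale-free topology is assessed by
binning the connectivity distribution into 10 equal-width bins and
regressing log10 p(k) on log10 k.  Modules come from average-linkage
hierarchical clustering of the topological-overlap dissimilarity with a
static cut; each module is summarized by its eigengene (first principal
component of the standardized module expression).  Per-probe module
statistics follow the field's definitions: kIN is the sum of absolute
Spearman correlations with the other module probes, kME (module
membership) is the Spearman correlation with the eigengene, and GS (gene
significance) is the Spearman correlation with a trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataio import ExpressionMatrix, PhenotypeTable

__all__ = [
    "Network",
    "ScaleFreeFit",
    "ModuleAssignment",
    "ModuleEigengenes",
    "ModuleProfile",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlations",
    "module_profile",
]

UNASSIGNED = "unassigned"


@dataclass
class Network:
    probe_ids: list
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray | None = None

    def validate(self) -> None:
        a = self.adjacency
        if not np.allclose(a, a.T):
            raise ValueError("adjacency not symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency out of [0, 1]")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("adjacency diagonal must be 1")


@dataclass
class ScaleFreeFit:
    n_bins: int
    bin_k: np.ndarray  # mean connectivity per non-empty bin
    bin_p: np.ndarray  # empirical probability per non-empty bin
    r_squared: float
    pearson_cor: float
    slope: float


@dataclass
class ModuleAssignment:
    labels: pd.Series  # probe_id -> module label, "unassigned" reserved

    def modules(self) -> list:
        out = [m for m in self.labels.unique() if m != UNASSIGNED]
        return sorted(out, key=lambda m: (-(self.labels == m).sum(), m))

    def members(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])


@dataclass
class ModuleEigengenes:
    me: pd.DataFrame  # samples x modules, unit variance
    pc2: pd.DataFrame  # samples x modules
    variance_explained: pd.DataFrame | None = None


@dataclass
class ModuleProfile:
    """Per-probe statistics of one module: kIN, kME, GS per trait, sd."""

    table: pd.DataFrame  # index probe_id; columns kin, kme, sd, gs_<trait>...
    module: str = ""


def _cor_matrix(vals: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        vals = np.apply_along_axis(stats.rankdata, 1, vals)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = vals.std(axis=1)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance probe(s) at rows {np.where(sd == 0)[0][:5].tolist()}"
        )
    return np.corrcoef(vals)


def adjacency(expr: ExpressionMatrix, beta: float = 6.0, cor_method: str = "pearson") -> Network:
    """Unsigned soft-thresholded adjacency a_ij = |cor|^beta, a_ii = 1."""
    vals = expr.values.to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if np.isnan(vals).any():
        raise ValueError("expression contains missing values; impute first")
    cor = _cor_matrix(vals, cor_method)
    adj = np.abs(np.clip(cor, -1, 1)) ** beta
    np.fill_diagonal(adj, 1.0)
    net = Network(list(expr.probe_ids), beta, adj)
    net.validate()
    return net


def connectivity(network: Network) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = network.adjacency
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=network.probe_ids, name="k")


def scale_free_fit(k_values, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width intervals spanning
    [min k, max k]; each non-empty bin contributes its mean connectivity and
    its share of values, and log10 p(k) is regressed on log10 k.
    """
    k = np.asarray(k_values, dtype=float)
    if np.unique(k).size < n_bins:
        raise ValueError("need at least n_bins distinct connectivity values")
    if k.min() == k.max():
        raise ValueError("all connectivity values identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    bin_k, bin_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        bin_k.append(members.mean())
        bin_p.append(members.size / k.size)
    if len(bin_k) < 3:
        raise ValueError("fewer than 3 non-empty bins; fit undefined")
    bin_k = np.asarray(bin_k)
    bin_p = np.asarray(bin_p)
    res = stats.linregress(np.log10(bin_k), np.log10(bin_p))
    return ScaleFreeFit(
        n_bins=n_bins,
        bin_k=bin_k,
        bin_p=bin_p,
        r_squared=float(res.rvalue**2),
        pearson_cor=float(res.rvalue),
        slope=float(res.slope),
    )


def tom_similarity(network: Network) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    network.tom = tom
    return tom


def _eigengene_of(vals: np.ndarray) -> np.ndarray:
    """First sample-space principal component of standardized rows, unit sd."""
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    if np.corrcoef(me, z.mean(axis=0))[0, 1] < 0:
        me = -me
    return me


def detect_modules(
    tom: np.ndarray,
    expr: ExpressionMatrix,
    min_module_size: int = 30,
    cut_height: float = 0.995,
    merge_threshold: float = 0.75,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` become "unassigned"; modules
    whose eigengenes correlate above ``merge_threshold`` are merged
    iteratively.  Labels M1, M2, ... are ordered by decreasing module size
    (ties by first probe).  The expression matrix is needed for the
    eigengene-based merge step.
    """
    probe_ids = list(expr.probe_ids)
    if tom.shape != (len(probe_ids), len(probe_ids)):
        raise ValueError("TOM shape does not match expression probes")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    vals = expr.values.to_numpy(dtype=float)
    groups: dict[int, np.ndarray] = {}
    for c in np.unique(raw):
        idx = np.where(raw == c)[0]
        if idx.size >= min_module_size:
            groups[int(c)] = idx

    # iterative eigengene merge
    merged = True
    while merged and len(groups) > 1:
        merged = False
        keys = sorted(groups)
        mes = {c: _eigengene_of(vals[groups[c]]) for c in keys}
        best = None
        for i, ci in enumerate(keys):
            for cj in keys[i + 1 :]:
                r = abs(np.corrcoef(mes[ci], mes[cj])[0, 1])
                if r > merge_threshold and (best is None or r > best[0]):
                    best = (r, ci, cj)
        if best is not None:
            _, ci, cj = best
            groups[ci] = np.sort(np.concatenate([groups[ci], groups.pop(cj)]))
            merged = True

    ordered = sorted(groups.values(), key=lambda idx: (-idx.size, idx[0]))
    labels = pd.Series(UNASSIGNED, index=probe_ids, name="module", dtype=object)
    for rank, idx in enumerate(ordered, start=1):
        labels.iloc[idx] = f"M{rank}"
    return ModuleAssignment(labels)


def module_eigengene(expr: ExpressionMatrix, member_probes, n_components: int = 2):
    """Eigengene (and PC2) of one module.

    Probes are standardized across samples; the returned components are the
    right-singular directions over samples scaled to unit variance.  The
    eigengene's sign is chosen so it correlates non-negatively with the mean
    standardized module expression; PC2 is signed so its largest-magnitude
    sample weight is positive.
    """
    members = list(member_probes)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 probes")
    vals = expr.values.loc[members].to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance probe in module")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-0 module")
    comps = []
    for c in range(min(n_components, vt.shape[0])):
        vec = vt[c]
        vec = vec / vec.std(ddof=1)
        if c == 0:
            if np.corrcoef(vec, z.mean(axis=0))[0, 1] < 0:
                vec = -vec
        else:
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
        comps.append(vec)
    idx = expr.values.columns
    me = pd.Series(comps[0], index=idx, name="ME")
    pc2 = pd.Series(
        comps[1] if len(comps) > 1 else np.zeros(len(idx)), index=idx, name="PC2"
    )
    var_expl = float(s[0] ** 2 / (s**2).sum())
    return me, pc2, var_expl


def eigengenes_for(expr: ExpressionMatrix, assignment: ModuleAssignment) -> ModuleEigengenes:
    """Eigengene/PC2 table for every assigned module."""
    mes, pc2s, ve = {}, {}, {}
    for mod in assignment.modules():
        me, pc2, v = module_eigengene(expr, assignment.members(mod))
        mes[mod] = me
        pc2s[mod] = pc2
        ve[mod] = v
    return ModuleEigengenes(
        me=pd.DataFrame(mes),
        pc2=pd.DataFrame(pc2s),
        variance_explained=pd.DataFrame({"variance_explained": ve}),
    )


def module_trait_correlations(
    eigengenes: ModuleEigengenes, pheno: PhenotypeTable
) -> pd.DataFrame:
    """Spearman correlation of every eigengene with every phenotype trait.

    Missing trait values are dropped pairwise; constant traits are reported
    with missing rho/p.
    """
    me = eigengenes.me
    traits = pheno.traits().apply(pd.to_numeric, errors="coerce")
    shared = me.index.intersection(traits.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples")
    rows = []
    for mod in me.columns:
        for trait in traits.columns:
            x = me.loc[shared, mod].to_numpy(dtype=float)
            y = traits.loc[shared, trait].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 4 or np.unique(y[ok]).size < 2:
                rows.append((mod, trait, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append((mod, trait, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["module", "trait", "spearman_rho", "p"])


def module_profile(
    expr: ExpressionMatrix, member_probes, me: pd.Series, traits: pd.DataFrame | None = None
) -> ModuleProfile:
    """kIN, kME, GS and expression sd for the probes of one module.

    All correlations are Spearman with average ranks for ties; kIN excludes
    the probe's self-correlation.
    """
    members = list(member_probes)
    vals = expr.values.loc[members].to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    cor = np.corrcoef(ranks)
    kin = np.abs(cor).sum(axis=1) - 1.0  # drop self
    me_rank = stats.rankdata(me.loc[expr.values.columns].to_numpy(dtype=float))
    kme = np.array([np.corrcoef(r, me_rank)[0, 1] for r in ranks])
    out = pd.DataFrame({"kin": kin, "kme": kme}, index=members)
    out["sd"] = vals.std(axis=1, ddof=1)
    if traits is not None:
        tnum = traits.apply(pd.to_numeric, errors="coerce")
        for trait in tnum.columns:
            y = tnum.loc[expr.values.columns, trait].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 3 or np.unique(y[ok]).size < 2:
                out[f"gs_{trait}"] = np.nan
                continue
            yr = stats.rankdata(y[ok])
            gs = [np.corrcoef(stats.rankdata(v[ok]), yr)[0, 1] for v in vals]
            out[f"gs_{trait}"] = gs
    return ModuleProfile(out)
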