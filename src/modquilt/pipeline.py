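"""End-to-end orchestration: qc -> coexpr -> centrality -> assoc -> integrate
(-> enrichment/replication when inputs are provided).

A run is driven by a :class:`PipelineConfig` (loadable from YAML), executes
the stages on an aligned cohort, writes every tabular output as TSV into
the output directory, and records a JSON manifest with the config
snapshot, derived seeds and a SHA-256 checksum per output file.  The only
nondeterminism allowed is the master seed: re-running with the same config
and seed reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, centrality, coexpr, enrichrep, integrate, qc
from .dataio import (
    align_cohort,
    read_expression,
    read_genotypes,
    read_phenotypes,
    write_expression,
    write_genotypes,
    write_phenotypes,
)
from .synthdata import SimulationParams, simulate_cohort, simulate_replication

__all__ = ["PipelineConfig", "RunManifest", "select_target_module", "run_pipeline", "RECOVERY_CONFIG"]

log = logging.getLogger("modquilt")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the study's thresholds."""

    # inputs: either file paths or a simulation block
    genotype_path: str | None = None
    genotype_format: str = "tsv_dosage"
    expression_path: str | None = None
    expression_meta_path: str | None = None
    phenotype_path: str | None = None
    simulate: dict | None = None  # SimulationParams fields; used when no paths
    out_dir: str = "modquilt_out"
    seed: int = 0

    # qc
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.01
    fold_change: float = 1.8
    sample_fraction: float = 0.10
    knn_k: int = 10
    drop_chromosome: str = "Y"

    # coexpr
    beta: float = 6.0
    cor_method: str = "pearson"
    n_bins: int = 10
    min_module_size: int = 30
    cut_height: float = 0.995
    merge_threshold: float = 0.75
    target_trait: str = "who_grade"

    # centrality
    edge_threshold: float = 0.1
    hub_degree_min: float = 250
    hub_betweenness_min: float = 2500

    # assoc / integrate
    suggestive_p: float = 1e-4
    significant_p: float = 1e-6
    gsmqtl_p_threshold: float = 0.01

    # enrichment / replication
    gene_sets_path: str | None = None
    ppi_path: str | None = None
    fdr_threshold: float = 0.001
    coverage_min: float = 0.10
    de_q_threshold: float = 0.05
    n_permutations: int = 10000
    run_replication: bool = False
    record_timestamps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "sample_fraction",
                     "coverage_min", "fdr_threshold", "de_q_threshold"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} out of (0, 1]")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if not (0 < self.edge_threshold <= 1):
            raise ValueError("edge_threshold out of (0, 1]")
        if self.simulate is None:
            for pth, name in (
                (self.genotype_path, "genotype_path"),
                (self.expression_path, "expression_path"),
                (self.phenotype_path, "phenotype_path"),
            ):
                if pth is None:
                    raise ValueError(f"{name} required when no simulation block is given")
                if not Path(pth).exists():
                    raise FileNotFoundError(f"{name}: {pth} does not exist")


# Parameters used for the planted-signal demonstration runs: a cohort large
# enough (n=200) for the module and its mQTLs to be recoverable, and a
# dendrogram cut suited to the weaker correlations of the synthetic module.
RECOVERY_CONFIG = dict(
    simulate=dict(n_samples=200, n_probes=1000, module_size=100, n_snps=300,
                  genotype_missing_rate=0.0),
    cut_height=0.9995,
    edge_threshold=0.02,
    hub_degree_min=10,
    hub_betweenness_min=0,
)


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    stage_counts: dict
    checksums: dict = field(default_factory=dict)
    timestamps: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def select_target_module(module_trait: pd.DataFrame, assignment, trait: str = "who_grade",
                         mean_abs_gs: pd.Series | None = None) -> str:
    """Module whose eigengene best correlates (absolutely) with the trait.

    Ties go to the larger module.  ``module_trait`` is the output of
    :func:`modquilt.coexpr.module_trait_correlations`.
    """
    sub = module_trait[module_trait["trait"] == trait].dropna(subset=["spearman_rho"])
    if sub.empty:
        raise ValueError(f"no module-trait correlations for trait {trait!r}")
    sizes = {m: len(assignment.members(m)) for m in sub["module"]}
    sub = sub.assign(abs_rho=sub["spearman_rho"].abs(), size=sub["module"].map(sizes))
    sub = sub.sort_values(["abs_rho", "size", "module"], ascending=[False, False, True], kind="stable")
    if (sub["p"] > 0.5).all():
        log.warning("no module correlates with %s (all p > 0.5); returning best anyway", trait)
    return str(sub.iloc[0]["module"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_name: str | None = None) -> None:
    out = df.copy()
    if index_name:
        out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, write outputs under ``config.out_dir``, return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "assoc", "permutation"),
            np.random.SeedSequence(config.seed).spawn(3),
        )
    }
    counts: dict = {}
    truth = None

    # ---- inputs -----------------------------------------------------------
    if config.simulate is not None:
        params = SimulationParams(**{**config.simulate, "seed": seeds["simulate"]})
        geno, expr, pheno, truth = simulate_cohort(params)
        write_genotypes(geno, out / "genotypes.tsv")
        write_expression(expr, out / "expression.tsv", out / "expression_meta.tsv")
        write_phenotypes(pheno, out / "phenotypes.tsv")
        _write_tsv(truth.to_frame().set_index("id"), out / "ground_truth.tsv")
    else:
        geno = read_genotypes(config.genotype_path, config.genotype_format)
        expr = read_expression(config.expression_path, config.expression_meta_path)
        pheno = read_phenotypes(config.phenotype_path)
    geno, expr, pheno = align_cohort(geno, expr, pheno)
    counts["samples"] = len(pheno.sample_ids)
    counts["snps_in"] = len(geno.snp_ids)
    counts["probes_in"] = len(expr.probe_ids)
    log.info("aligned cohort: %d samples, %d SNPs, %d probes",
             counts["samples"], counts["snps_in"], counts["probes_in"])

    # ---- qc ---------------------------------------------------------------
    thresholds = qc.QcThresholds(
        maf_min=config.maf_min,
        call_rate_min=config.call_rate_min,
        hwe_p_min=config.hwe_p_min,
        fold_change=config.fold_change,
        sample_fraction=config.sample_fraction,
        knn_k=config.knn_k,
    )
    geno, snp_report = qc.filter_snps(geno, thresholds)
    _write_tsv(snp_report, out / "snp_qc_report.tsv")
    expr = qc.drop_chromosome(expr, config.drop_chromosome)
    if expr.has_missing():
        expr = qc.knn_impute(expr, thresholds.knn_k)
    expr = qc.variance_filter(expr, thresholds)
    if len(expr.probe_ids) < 3:
        raise RuntimeError("stage qc: fewer than 3 probes survive the variance filter")
    counts["snps_kept"] = len(geno.snp_ids)
    counts["probes_kept"] = len(expr.probe_ids)
    log.info("qc: %d SNPs and %d probes kept", counts["snps_kept"], counts["probes_kept"])

    # ---- coexpr -----------------------------------------------------------
    net = coexpr.adjacency(expr, beta=config.beta, cor_method=config.cor_method)
    k = coexpr.connectivity(net)
    try:
        sf = coexpr.scale_free_fit(k.to_numpy(), n_bins=config.n_bins)
        sf_frame = pd.DataFrame(
            {"bin_k": sf.bin_k, "bin_p": sf.bin_p}
        ).assign(r_squared=sf.r_squared, pearson_cor=sf.pearson_cor, slope=sf.slope)
    except ValueError as exc:
        log.warning("scale-free fit unavailable: %s", exc)
        sf_frame = pd.DataFrame()
    _write_tsv(sf_frame, out / "scale_free_fit.tsv")
    tom = coexpr.tom_similarity(net)
    assignment = coexpr.detect_modules(
        tom,
        expr,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_threshold=config.merge_threshold,
    )
    _write_tsv(assignment.labels.to_frame(), out / "module_assignment.tsv", "probe_id")
    modules = assignment.modules()
    counts["modules"] = len(modules)
    if not modules:
        raise RuntimeError("stage coexpr: no modules detected")
    eig = coexpr.eigengenes_for(expr, assignment)
    _write_tsv(eig.me, out / "module_eigengenes.tsv", "sample_id")
    traits = pheno.table.loc[expr.values.columns]
    mt = coexpr.module_trait_correlations(eig, pheno)
    _write_tsv(mt.set_index("module"), out / "module_trait_correlations.tsv")
    target = select_target_module(mt, assignment, trait=config.target_trait)
    counts["target_module"] = target
    members = assignment.members(target)
    me = eig.me[target]
    pc2 = eig.pc2[target]
    profile = coexpr.module_profile(expr, members, me, traits)
    _write_tsv(profile.table, out / "module_profile.tsv", "probe_id")
    log.info("coexpr: %d modules; target %s with %d probes", len(modules), target, len(members))

    # ---- centrality -------------------------------------------------------
    graph = centrality.build_graph(net, members, edge_threshold=config.edge_threshold)
    cent = centrality.centrality_table(
        graph, degree_min=config.hub_degree_min, betweenness_min=config.hub_betweenness_min
    )
    _write_tsv(cent, out / "centrality.tsv", "probe_id")
    hubs = centrality.select_hubs(cent, config.hub_degree_min, config.hub_betweenness_min)
    counts["hubs"] = len(hubs)

    # ---- assoc ------------------------------------------------------------
    scans = assoc.mqtl_scan(geno, me.to_numpy(), pc2.to_numpy())
    for name, tab in scans.items():
        _write_tsv(tab, out / f"mqtl_{name}.tsv")
    stage_tab = assoc.stage_scan(geno, pheno.stage_binary.to_numpy())
    _write_tsv(stage_tab, out / "stage_scan.tsv")
    lam = assoc.genomic_lambda(stage_tab["p"].dropna().to_numpy())
    (out / "lambda_report.json").write_text(
        json.dumps({"n_tests": lam.n_tests, "lambda": lam.lambda_gc}, indent=2)
    )
    counts["lambda_stage"] = round(lam.lambda_gc, 4)
    mqtl_hits = scans["ME"][scans["ME"]["tier"].isin(["significant", "suggestive"])]
    mqtl_hits = assoc.dedup_by_gene(mqtl_hits)
    counts["mqtl_hits_ME"] = int(len(mqtl_hits))
    log.info("assoc: %d ME-scan mQTL hits; stage-scan lambda %.3f",
             len(mqtl_hits), lam.lambda_gc)

    # ---- integrate --------------------------------------------------------
    mqtl_ids = list(mqtl_hits.index)
    final_rep = None
    if mqtl_ids:
        module_expr = expr.subset_probes(members)
        gsm = integrate.gsmqtl_matrix(module_expr, geno, mqtl_ids)
        _write_tsv(gsm, out / "gsmqtl_matrix.tsv", "probe_id")
        gs = profile.table[f"gs_{config.target_trait}"]
        step = integrate.stepwise_aic(
            integrate.rank_inverse_normal(gs.to_numpy()), gsm, response_name="GS_WHO_Grade"
        )
        _write_tsv(step.to_frame(), out / "stepwise_gsmqtl_model.tsv", "term")
        risk, prot = integrate.aggregate_risk_protective(
            step, gsm, p_threshold=config.gsmqtl_p_threshold
        )
        report, fitted, rho = integrate.final_model(
            gs.to_numpy(), profile.table["kme"], prot, risk
        )
        final_rep = report
        _write_tsv(report.to_frame(), out / "final_model.tsv", "term")
        summary = pd.DataFrame(
            {
                "value": {
                    "adjusted_r_squared": report.adjusted_r_squared,
                    "r_squared": report.r_squared,
                    "model_vif": report.model_vif,
                    "spearman_fitted_vs_gs": rho,
                }
            }
        )
        _write_tsv(summary, out / "final_model_summary.tsv", "stat")
        groups = integrate.dichotomize_groups(
            profile.table["kme"], risk, prot, gs
        )
        _write_tsv(groups, out / "dichotomized_groups.tsv")
        counts["final_model_adj_r2"] = round(report.adjusted_r_squared, 4)
    else:
        log.warning("integrate: no mQTL hits; integration stage skipped")

    # ---- enrichment -------------------------------------------------------
    if config.gene_sets_path:
        from .dataio import read_gene_sets

        sets = read_gene_sets(config.gene_sets_path)
        universe = [str(g) for g in expr.probe_meta["gene"]]
        query = [str(expr.probe_meta.loc[p, "gene"]) for p in members]
        enr = hypergeom = enrichrep.hypergeom_enrichment(
            query, sets, universe,
            fdr_threshold=config.fdr_threshold, coverage_min=config.coverage_min,
        )
        _write_tsv(enr, out / "enrichment.tsv")
        counts["enriched_terms"] = int(enr["pass"].sum()) if len(enr) else 0
    if config.ppi_path:
        from .dataio import read_ppi

        ppi = read_ppi(config.ppi_path)
        genes = [str(expr.probe_meta.loc[p, "gene"]) for p in members]
        try:
            pe = enrichrep.ppi_enrichment(
                genes, ppi, b=config.n_permutations, seed=seeds["permutation"]
            )
            (out / "ppi_enrichment.json").write_text(
                json.dumps(dataclasses.asdict(pe), indent=2)
            )
        except ValueError as exc:
            log.warning("ppi enrichment skipped: %s", exc)

    # ---- replication ------------------------------------------------------
    if config.run_replication and config.simulate is not None:
        rep_expr, batches, rep_pheno = simulate_replication(params, truth)
        rep_expr = enrichrep.batch_adjust(rep_expr, batches)
        de = enrichrep.stage_de(
            rep_expr, rep_pheno.stage_binary.to_numpy(), q_threshold=config.de_q_threshold
        )
        _write_tsv(de, out / "replication_de.tsv", "probe_id")
        shared = [p for p in members if p in set(de.index)]
        flags = de.loc[shared, "de"].to_numpy(dtype=bool)
        if flags.any() and not flags.all():
            shift = enrichrep.connectivity_shift(
                profile.table.loc[shared, "kme"].to_numpy(),
                flags,
                b=config.n_permutations,
                seed=seeds["permutation"],
            )
            (out / "connectivity_shift.json").write_text(
                json.dumps(dataclasses.asdict(shift), indent=2)
            )
            counts["replicated_de_fraction"] = round(float(flags.mean()), 4)

    # ---- manifest ---------------------------------------------------------
    # out_dir is where the run lands, not what it computes: leaving it out of
    # the snapshot keeps same-seed manifests byte-identical across locations
    config_snapshot = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
    }
    manifest = RunManifest(
        config=config_snapshot,
        version=_version(),
        seeds=seeds,
        stage_counts=counts,
    )
    if config.record_timestamps:
        import datetime

        manifest.timestamps = {"finished": datetime.datetime.now().isoformat()}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest.checksums[f.name] = _sha256(f)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
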