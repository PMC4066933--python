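# modquilt

Weighted co-expression network analysis with genotype integration for
tumor-grade genomics: module discovery, module-QTL (mQTL) mapping,
hub-gene centrality, SNP–stage association with genomic control, and an
integrative regression that decomposes module gene significance into
risk and protective genotype contributions.

## Who this is for

Groups analysing matched tumor expression and genotype cohorts (e.g.
meningioma series with WHO grades I–III) who want a reproducible,
scriptable version of the classic WGCNA-plus-QTL workflow — and a
synthetic-cohort generator with planted ground truth to validate every
stage before touching real data.

## The method

1. **QC.** SNPs must pass three inclusive filters: minor allele
   frequency ≥ 5 %, call rate ≥ 95 %, Hardy–Weinberg equilibrium
   (Pearson 1-df χ², p ≥ 0.01). Expression probes are kept when
   |x − median| ≥ log₂(1.8) in ≥ 10 % of samples; Y-chromosome probes
   are dropped; missing values are kNN-imputed over probes.
2. **Network.** Unsigned soft-thresholded adjacency
   `a_ij = |cor(x_i, x_j)|^β` with β = 6; scale-free topology is
   assessed by regressing log₁₀ p(k) on log₁₀ k over 10 equal-width
   connectivity bins. Modules come from average-linkage clustering of
   the topological-overlap dissimilarity (1 − TOM) with a static cut,
   small-cluster pruning and eigengene-based merging. Each module is
   summarised by its eigengene (ME, first PC of the standardized module
   expression); per-probe statistics are kIN (Σ|Spearman ρ| within the
   module), kME (Spearman ρ with the ME) and GS (Spearman ρ with a
   trait such as WHO grade).
3. **Hubs.** The target module is binarised at an adjacency threshold;
   hubs are nodes with degree ≥ 250 and raw Brandes betweenness
   ≥ 2 500 (both configurable).
4. **Association.** Each SNP (allele count out of 2) is modelled as a
   binomial-logistic outcome: `genotype ~ ME`, the PC2-over-ME
   improvement (1-df LRT), `genotype ~ PC1+PC2`, and `genotype ~ stage`
   (grade I vs II/III). Hits are tiered (suggestive p < 1e-4,
   significant p ≤ 1e-6), deduplicated per gene, and the stage scan is
   summarised by the genomic-control inflation factor
   λ = median(χ²₁)/0.4549.
5. **Integration.** Per-probe Spearman correlations with each mQTL
   genotype (GSmQTL) enter a stepwise-AIC regression of
   rank-inverse-normal GS; significant columns are summed by
   coefficient sign into GSmQTL-Risk/-Protective, and the final model
   `RIN(GS) ~ kME + Protective + Risk` is reported with R², adjusted
   R², model VIF = 1/(1 − R²), per-predictor VIFs and residual
   normality; median splits of kME/Risk/Protective give the eight-group
   GS summary.
6. **Enrichment & replication.** Hypergeometric gene-set
   over-representation with BH-FDR and coverage filters, a permutation
   test for excess PPI edges, location-scale batch adjustment, Welch-t
   differential expression between stages, and a Wilcoxon/permutation
   comparison of kME between DE and non-DE module probes.

## Worked example

Run the full pipeline on a synthetic cohort with a planted 100-probe
module and two planted mQTLs (the packaged "recovery" conditions:
200 samples, 1 000 probes, 300 SNPs):

```python
from modquilt.pipeline import RECOVERY_CONFIG, PipelineConfig, run_pipeline

cfg = PipelineConfig(**{**RECOVERY_CONFIG, "out_dir": "demo", "seed": 1})
manifest = run_pipeline(cfg)
print(manifest.stage_counts)
```

which prints (seed 1):

```
{'samples': 200, 'snps_in': 300, 'probes_in': 1000,
 'snps_kept': 294, 'probes_kept': 1000, 'modules': 1,
 'target_module': 'M1', 'hubs': 62, 'lambda_stage': 1.078,
 'mqtl_hits_ME': 1, 'final_model_adj_r2': 0.0936}
```

Reading: 294/300 SNPs survive the three filters; module detection finds
exactly one module (M1, the planted one — compare
`demo/module_assignment.tsv` against `demo/ground_truth.tsv`); the
stage scan shows no systematic inflation (λ ≈ 1.08 on 294 null SNPs);
one planted mQTL reaches the suggestive tier in the eigengene scan, and
the integrative model explains a modest share of GS variance at this
single-mQTL signal strength. All tables land in `demo/` as TSV, with a
`manifest.json` of seeds and SHA-256 checksums; re-running with the
same seed reproduces every file byte-identically.

The same run is available from the shell:

```
modquilt run --config config.yaml --seed 1
```

with `config.yaml` holding any `PipelineConfig` field; individual
stages are exposed as `modquilt simulate|qc|network|hubs|assoc|enrich|replicate`.

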