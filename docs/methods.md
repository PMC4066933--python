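# Methods

This note documents the models, defaults and numerical choices behind
modquilt, and what the synthetic-data tests do and do not establish
about real cohorts.

## Synthetic cohort model

The generator emulates a tumor study with matched genotypes and
expression. For sample *s*, SNP *j* and module probe *g*:

- genotypes: minor-allele frequency m_j ~ Uniform(maf_range), calls
  ~ Binomial(2, m_j), independently masked missing at a configurable
  rate (default 2 %);
- grades: the configured proportions (default 39/15/5 for WHO I/II/III,
  the discovery-template composition) are apportioned exactly by
  largest remainder and shuffled, so the default 59-sample cohort
  always contains 39/15/5 — the cohort composition is a design
  constant, not a draw;
- latent module factor: f_s = γ·grade_s + Σ_j δ_j·g_js + N(0, 1), with
  γ = 0.5 and two mQTL SNPs at δ = 0.8 by default;
- module probes: x_gs = u_g·f_s + N(0, σ_e), u_g ~ Uniform(0.5, 1),
  σ_e = 1; background probes are independent N(0, 1).

γ = 0.5 makes grade a visible but not dominant driver of the factor
(about 12 % of factor variance at the default grade mix); δ = 0.8 at
MAF ≈ 0.3 gives the association scans ~100 % power at n = 200 and
little at n = 59, which mirrors the intended contrast between
discovery-scale and desk-scale runs. One RNG stream per matrix
(genotypes, phenotypes, expression, replication), all spawned from the
master seed, so changing the probe count never perturbs the genotypes.

The replication generator reuses the probe universe, shifts a chosen
set of module probes by `de_effect` (default 2 residual sd) between
stage groups, and applies per-batch location/scale distortions.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, copy-number events, probe cross-hybridisation, and microarray
mean–variance structure. The last omission matters for one qualitative
observation on real data — there, lowly connected module genes are
*more* variable; under x = u·f + ε with fixed residual sd, the loading
u raises connectivity and total sd together, so the synthetic model
shows the opposite (and our tests assert the model's true direction).
Passing tests therefore validate the statistical machinery, not that
real tumor data will show any particular sd–connectivity relation.

## Quality control

All thresholds are inclusive ("minimum … of"): MAF ≥ 0.05 (folded,
computed on non-missing calls), call rate ≥ 0.95, HWE p ≥ 0.01. HWE is
a Pearson 1-df χ² against p², 2pq, q² without continuity correction; an
exact (Wigginton-style) test is available but off by default. The three
SNP rules are applied to the original matrix, never sequentially, so
the report attributes every failure. The 1.8-fold expression filter is
interpreted on the log₂ scale (|x − row median| ≥ log₂ 1.8 ≈ 0.848 in
≥ 10 % of samples) because intensities arrive log₂-transformed and a
fold change "according to the median" is multiplicative; a linear-scale
reading is not offered. Imputation is k-nearest-neighbour over probes
(k = 10), with neighbour distances computed on shared observed samples
(delegated to scikit-learn's KNNImputer, which implements exactly this
scheme).

## Network and modules

Adjacency uses Pearson correlation raised to β = 6 (unsigned), the
conventional soft threshold; kIN/kME/GS deliberately use Spearman with
average ranks, matching how the module statistics are defined. The
scale-free fit bins connectivities into 10 equal-width intervals over
[min k, max k] ("bins of equal size" read as equal width, the standard
fit index; equal-count binning is exposed as an alternative reading via
the `n_bins`/binning knobs), drops empty bins, and regresses log₁₀ p(k)
on log₁₀ k; `r_squared` is the squared Pearson correlation of that
regression, identically.

Module detection is a deliberately simple, fully deterministic stand-in
for dynamic tree cutting: average-linkage clustering of 1 − TOM, a
static cut (default height 0.995), pruning of clusters below 30 probes
to "unassigned", then iterative merging of modules whose eigengenes
correlate above 0.75, largest pair first. Labels M1, M2, … are ordered
by decreasing size. The static cut is the one knob that genuinely needs
per-dataset tuning: strongly correlated blocks (pairwise r ≈ 0.8)
separate cleanly at the default, while the weaker planted module of the
recovery conditions (pairwise r ≈ 0.2–0.5 after β = 6 powering) needs a
higher cut; the packaged `RECOVERY_CONFIG` uses 0.9995, chosen from the
TOM scale of the planted model, and recovers the module at Jaccard 1.0
across seeds. Eigengenes are right-singular vectors of the
standardized module matrix scaled to unit variance (ddof = 1),
sign-aligned to correlate non-negatively with the mean standardized
module expression; PC2's sign makes its largest-magnitude weight
positive. Both conventions are arbitrary but fixed, which is what
determinism requires.

## Centrality

The module graph is unweighted: edge iff a_ij ≥ edge_threshold.
Because β-powered adjacencies are small, the default threshold (0.1)
must be tuned per dataset for the paper-scale hub cutoffs
(degree ≥ 250, raw betweenness ≥ 2 500) to be meaningful; hub calling
is the inclusive conjunction of both. Betweenness is raw (unnormalised)
Brandes via networkx — unordered pairs counted once, endpoints
excluded — validated in the tests against an exhaustive
all-shortest-paths enumerator.

## Association

Genotypes are treated as binomial outcomes with two trials
(additive allelic model): logit π = Xb, y ~ Binomial(2, π), fitted by
Newton–Raphson; p-values are likelihood-ratio tests of the added
regressors over the base model (intercept-only unless the eigengene is
held as base, as in the PC2-improvement scan). A score test is
available as an option and agrees with the LRT to Spearman ρ ≥ 0.99
under the null. Under separation or non-convergence both models are
refitted with a small L2 ridge (1e-2 on non-intercept terms) and the
record is flagged "penalized"; the LRT remains comparable because the
same penalty enters both likelihoods. SNPs with fewer than 10
non-missing calls, or monomorphic after pairwise deletion, are skipped
with a reason. Tiers formalise "order of 10⁻⁵ or less" as p < 1e-4
(suggestive) and "significant" as p ≤ 1e-6; both constants are
configurable. Genomic control uses the exact χ²₁ median 0.4549364.
Gene-level deduplication keeps the minimum-p SNP per gene with a
lexicographic tie-break; replication overlap accepts user-supplied
SNP→gene maps and optional proxy maps (e.g. from LD lists computed
elsewhere — LD itself is out of scope) and reports provenance
(direct/proxy) per overlapping gene.

## Integrative regression

Observations are module probes. Responses are rank-inverse-normal
transformed, z_i = Φ⁻¹((r_i − 0.5)/n) with average ranks; predictors
enter raw. OLS reports use AIC = n·ln(RSS/n) + 2(p + 1) — the constant
terms are omitted consistently, so only differences matter and results
are implementation-independent. Stepwise selection starts from the full
model and greedily applies the single addition/removal with the largest
AIC decrease (ties prefer removal, then lexicographic order); a final
guard returns the intercept-only model if it beats the greedy optimum,
so the reported model never has higher AIC than either endpoint. Note
that AIC-based selection admits an independent noise predictor with
probability P(χ²₁ > 2) ≈ 0.16 — exact recovery of a single true
predictor among four noise columns therefore happens in only about half
of runs, which the tests assert as the attainable guarantee. The model
VIF is 1/(1 − R²) (a single number even for one-regressor models,
consistent with the convention that pairs R² = 0.51 with VIF = 2.04);
per-predictor VIFs from regressing each predictor on the others
diagnose multicollinearity. Risk/Protective sums collect the GSmQTL
columns with t-test p < 0.01, split by coefficient sign. Median
dichotomisation assigns values equal to the median to the lower ("−")
group; ties are documented and configurable.

## Enrichment and replication statistics

Enrichment is the hypergeometric upper tail P(X ≥ x) with the universe
fixed to the analysed probes' genes; BH-FDR is applied across tested
terms, and coverage (overlap over in-universe query size by default;
the term-size reading is a flag) must reach the configured minimum
(0.10 for module analyses, 0.03 for mQTL gene lists). PPI enrichment
replaces an analytic expected-edge model with an explicit permutation
null: B random same-size node subsets of the PPI universe, expected =
null mean, p = (1 + #{null ≥ obs})/(B + 1), so p can never fall below
1/(B + 1). Batch adjustment is a location-scale standardisation per
probe and batch rescaled to the pooled moments — a transparent stand-in
for empirical-Bayes batch correction, adequate for additive/scale batch
effects but not for batch-covariate confounding. Differential
expression uses Welch's t with BH (q < 0.05), a documented deviation
from moderated-t approaches; the kME comparison between DE and other
module probes reports both the two-sided Wilcoxon rank-sum test and a
B = 10 000 permutation null of the mean-kME difference (two-sided on
|difference|).

## Pipeline and determinism

The pipeline is single-process and in-memory (the intended scale —
≤ ~1e5 SNPs, ~1e4 probes, a few hundred samples — does not warrant
more). Every stochastic stage consumes a seed spawned from the master
seed; outputs are TSV with a fixed float format, and the manifest
records the config snapshot (minus the output directory, which is
where a run lands rather than what it computes), derived seeds,
per-stage counts and SHA-256 checksums. Wall-clock timestamps are
recorded only on request, keeping same-seed manifests byte-identical.
The target module is the one whose eigengene has the largest
|Spearman ρ| with the chosen trait, ties to the larger module.

## Problem sizes used in tests and the acceptance script

Calibration checks use 2 000–4 000 null simulations at n = 200 and
100 000 uniform p-values for λ; recovery checks use the planted
conditions (1 000 probes, module 100, n = 200, σ_e = 1, u ∈ [0.5, 1];
mQTL δ = 0.8 at MAF 0.3 over 200 replicates; 100 final-model
replicates at 300 probes). These sizes give the binomial/empirical
bands quoted in the tests comfortable margins while keeping the whole
suite fast.

## Known limitations

- Module detection is a static-cut stand-in; datasets with nested or
  weak modules may need the cut height and minimum size tuned.
- The binomial-logistic scans assume additive allelic effects and no
  population stratification adjustment.
- The batch stand-in cannot recover signal confounded with batch.
- The generator's distributional choices (normal noise, uniform
  loadings, linear grade coding) are stand-ins; all are configurable,
  and conclusions about real data require real data.
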