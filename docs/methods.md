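# Methods

## Screen phenotype model

An sgRNA's phenotype γ is its log2 enrichment between screen start and
end, per population doubling, on a scale anchored by non-targeting
negative controls. Per replicate, counts are normalized to reads per
million (rpm), a pseudocount ψ is added *on the rpm scale*, and

    raw_i = log2(rpm_i^TEND + ψ) − log2(rpm_i^T0 + ψ)
    γ_i   = (raw_i − median over negative-control raws) / D

with D the number of population doublings. Applying ψ after
normalization means multiplying any sample column by a constant leaves
every γ exactly unchanged (to float precision) — sequencing depth is a
nuisance parameter, not a signal. The NC-median subtraction removes both
depth offsets and the bulk-fitness renormalization of a growing
population (depleted sgRNAs dilute into everyone else's share; controls
absorb the common shift). Replicates are combined by unweighted mean —
appropriate for technical duplicates of equal design depth — and the
combined scores are re-centered once more so that the NC median is
*exactly* zero, which downstream statistics assume.

Assumptions: one transcription start site per gene (one sgRNA set per
gene); a single global doubling count (no per-replicate growth-rate
correction); independent sgRNA counts (no UMI/jackpot structure).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `doublings` | 8 | population doublings T0→TEND (screen design) |
| `pseudocount` | 1 | rpm added before the log-ratio; damps dropout noise |
| `min_t0_reads` | 25 | raw T0 reads below which an sgRNA is excluded (low-coverage sgRNAs dominate variance) |
| `gene_score_mode` / `n_top` | `top_n_abs`, 3 | gene phenotype = mean of the 3 most extreme of 5 sgRNAs; tolerant of inert guides. `mean_all` uses every passing sgRNA |
| `pseudogene_size` / `n_pseudogenes` | 5 / 2000 | null genes assembled from random NC sgRNAs, matching the library's sgRNAs/gene |
| `target_fdr` | 0.05 | empirical false-discovery target of hit calling |

## Hit calling

Gene significance is a two-sided Mann–Whitney test of the gene's sgRNA
γ's against the pooled NC γ's (exact by enumeration for tie-free samples
of ≤ 8 per group; otherwise normal approximation with midranks,
tie-corrected variance and 0.5 continuity correction; p clipped to
(0, 1]). The product score |phenotype/σ_NC| · (−log10 p), with σ_NC the
pseudogene phenotype standard deviation (ddof = 1), is thresholded at
the smallest observed gene score t for which

    (#pseudogenes ≥ t) / n_pseudogenes × n_genes / (#genes ≥ t) ≤ target FDR.

Hits additionally require phenotype < 0: a growth screen reads out
depletion. If no threshold qualifies, no hits are called (threshold
+inf), a valid outcome on null data. A fixed threshold can be supplied
for reproducibility studies.

## Clinical and essentiality filters

*CN/expression filter.* Per gene, samples split into copy-number gain
versus no gain (no gain = neutral ∪ loss by default; a neutral-only
grouping is available since either reading of "without gain" is
defensible). Pass requires fold change of mean TPM ≥ 2 **and** Wilcoxon
p ≤ 0.001, both boundaries inclusive. A zero no-gain mean with expressed
gain samples yields an infinite fold change that satisfies the FC
criterion (the p criterion still binds); groups with < 2 samples make
the gene untestable and it is excluded — the filter is conservative by
construction. Output is ordered by CN-gain recurrence (ties broken
alphabetically so ranks are a deterministic permutation).

*Essentiality stages*, fixed order (the ordering is part of the
procedure and deliberately not configurable): (1) binary-call panel:
remove genes essential in ≥ 90% (inclusive) of cell lines outside the
excluded lineage (default prostate); genes without data survive with a
note. (2) continuous gene-effect panel on the 0 = non-essential /
−1 = median-common-essential scale: the default percentile-rank rule
flags a gene as common essential when the 90th percentile of its
per-line fractional essentiality rank is ≤ 0.10, i.e. it is in the
most-essential 10% of genes in ≥ 90% of lines; a median-effect
threshold (≤ −0.6) and a precomputed flag list are alternatives.
(3) external-screen exclusion with union semantics by default (a hit in
*either* screen removes; intersection available, since "a significant
hit in two screens" is readable both ways). (4) metastasis expression:
keep genes with higher mean TPM in metastatic than primary samples at
Wilcoxon p ≤ 0.05 — the direction requirement is the substance, the
0.05 significance gate is this package's choice of operationalization.
Survivors are ranked by phenotype ascending, ties by Mann–Whitney p,
then symbol (a p-primary ordering is available). A per-gene trace
records each removal, and the accounting identity
|hits| = |survivors| + Σ removals is asserted on every run.

## Survival statistics

High expression = strictly above the 75th percentile computed with
linear interpolation (numpy's default, R's type 7); ties at the boundary
go to the low group, so "top quartile" never exceeds 25% plus ties.
Kaplan–Meier estimation and the log-rank test (O−E statistic with
hypergeometric variance, chi-square reference with 1 df) are delegated
to lifelines. The Cox model is fit in-package: a single binary
covariate, Newton–Raphson on the partial likelihood to |Δβ| < 1e−8
(steps damped to ±2 to stabilize early iterations), Breslow tie
handling by default with Efron as an option, Wald CI and p. Breslow is
the default because its gradient is exact and transparent in the
one-covariate case; on tie-free data it agrees with an Efron fit to
~1e−8 (cross-checked against lifelines in the tests). Complete
separation makes the partial likelihood monotone; divergence (|β| > 20
or a vanishing information) is reported as a 0/+inf hazard-ratio
sentinel with `converged=False` rather than a spurious estimate.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
with truth tables emitted separately from input files (no stage reads
truth):

* **Screen**: log-normal initial representation (σ = 0.3); negative
  binomial counts (variance μ + αμ², α = 0.01 default ≈ tight technical
  replicates; α = 0 degenerates to Poisson) at ~2000 reads/sgRNA,
  the 1000×-coverage scale of the screen design; TEND abundance
  ∝ a·2^(D·γ) renormalized; 5 sgRNAs/gene of which 20% are inert
  (γ = 0), so top-n gene scoring is exercised meaningfully; essential
  genes drawn with γ ∈ (−0.5, −0.2); 2 replicates.
* **Cohort**: log2 TPM ~ Normal(μ_g, 0.5) with μ_g ~ Normal(3.5, 1);
  additive log2 shifts for copy-number gain (δ) and metastatic status
  (m); CN gains Bernoulli per sample. Overall survival for metastatic
  samples is exponential with baseline hazard ln 2/30 per month (30-month
  median, the mCRPC scale), multiplied by exp(β) for samples in a
  prognostic gene's top expression quartile, censored Uniform(0, 80
  months) (≈20–30% censoring).
* **Essentiality**: effects Normal(−1, 0.15) for (lineage-)essential
  classes, Normal(0, 0.15) otherwise; binary calls at effect ≤ −0.5;
  100 lines, 2 prostate.

What the generators do **not** model — and hence what passing tests do
not establish about real data: PCR jackpots and sequencing error,
correlated gene–gene expression, tumor purity/ploidy, segment-level CN
geometry, non-proportional hazards, batch structure.

The narrative scenario plants four archetypes among 200 background
genes: a prostate-lineage-essential driver (γ = −0.4, gain-responsive,
metastasis-upregulated, β = ln 2), an amplified common-essential decoy
(γ = −0.45), an amplified gene with no fitness effect, and a neutral
gene. Background essentials (15 common, 8 known to external screens,
3 prostate-lineage) get γ ∈ (−0.35, −0.2): the scenario is *designed* so
the planted driver is the strongest tissue-specific dependency, which is
what "ranked first" tests; common essentials are kept to ~7% of genes so
the percentile-rank rule behaves as it does on real panels, where common
essentials are a similar minority.

## Numerical and design notes

* Exact Mann–Whitney refuses ties (falls back to the tie-corrected
  normal approximation); an all-tied sample returns p = 1 (the test has
  no discrimination).
* Spearman's p uses the t approximation with n − 2 df — appropriate at
  the ~100-sample cohort sizes targeted; constant input returns NaN.
* Result tables are written with 6 significant digits and a total sort
  order, so identical runs produce byte-identical files; the run log
  records parameters, seed and input checksums.
* CN states on disk are integers −1/0/1; an absolute-copy-number dialect
  calls gain at CN ≥ 3 (loss at ≤ 1) — a convention of this package, as
  upstream callers differ.
* Problem sizes in the test suite and acceptance script (200–250 genes,
  500 NC sgRNAs, 100–200 patients, 100 cell lines, 1000 log-rank
  replicates) are chosen so every property is measurable in seconds
  while keeping the per-gene sgRNA design, depths and effect sizes at
  the study's scale.

## Known limitations

Single-TSS libraries only; no treatment-arm (rho/tau) phenotypes; no
sgRNA-level variance shrinkage or MAGeCK-style model fitting; no
multivariable or time-dependent Cox models; the DepMap-style
percentile-rank rule depends on the gene universe in the matrix (rank
fractions are relative), so very small gene panels need the threshold
mode or a precomputed flag list.
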