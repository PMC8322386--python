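# driverseek

Pooled CRISPRi growth-screen scoring integrated with clinical genomics to
nominate tissue-specific cancer driver genes.

A genome-scale CRISPRi depletion screen finds every gene a cancer cell
line needs to proliferate — but most of those genes are needed by *all*
cells, so a raw hit list is a poor source of tumor-selective targets, and
ranking hits purely by clinical evidence (copy-number gains with
responsive expression) readily promotes amplified housekeeping genes.
`driverseek` implements the combined strategy: score the screen, call
hits against an empirical negative-control null, then intersect the hit
list with clinical copy-number/expression evidence, pan-cancer
essentiality panels, external screen exclusion lists and metastasis
expression, and finally test the survival association of the candidates.
It is written for computational biologists analyzing pooled screens in a
disease context (the defaults reflect a metastatic prostate cancer
setting), and ships a synthetic-data generator with planted ground truth
for every stage so the whole pipeline can be validated end to end.

## Method

**Screen scoring.** For sgRNA *i* with counts *c* at the start (T0) and
end (T8 ≈ 8 population doublings) of the screen, in each replicate

    γᵢ = [ log₂(rpmᵢᵀ⁸ + ψ) − log₂(rpmᵢᵀ⁰ + ψ) − median_NC(·) ] / D

where rpm is reads-per-million, ψ = 1 a pseudocount, the median over
non-targeting negative controls (NC) centers the scale, and D = 8 is the
doubling count — so γ is log₂ relative fitness per doubling (γ < 0:
depleted, gene required). Replicates are averaged; sgRNAs with < 25 T0
reads are excluded.

**Gene statistics and hit calling.** Gene phenotype = mean of the 3 most
extreme of its 5 sgRNAs (configurable); significance = two-sided
Mann–Whitney of its sgRNA γ's versus all NC γ's. Pseudogenes (random
5-NC-sgRNA groups) give the empirical null: a gene is a hit when its
product score |γ/σ_NC|·(−log₁₀ p) exceeds the smallest threshold whose
pseudogene-estimated false-discovery rate is ≤ 5%, and γ < 0.

**Filters.** (1) clinical: keep hits with ≥ 2-fold mean TPM change in
copy-number-gained vs non-gained samples at Wilcoxon p ≤ 0.001, ranked
by gain recurrence; (2) combined: remove genes essential in ≥ 90% of
non-prostate lines (binary panel), DepMap-style common essentials
(percentile-rank rule on the 0/−1 gene-effect scale), and hits of
external non-prostate CRISPRi screens; keep metastasis-upregulated genes
(Wilcoxon p ≤ 0.05); rank by phenotype, then p.

**Survival.** Samples split at the top expression quartile; Kaplan–Meier
curves, two-sided log-rank test, and a single-covariate Cox model
(Newton–Raphson, Breslow ties) reporting HR = exp(β) with a Wald 95% CI.

## Worked example

Generate the built-in four-archetype scenario (a prostate-specific
driver, an amplified common-essential decoy, an amplified-but-dispensable
gene and a neutral gene, among 200 background genes) and run the stages:

```sh
driverseek make-scenario --seed 0 --out-dir ex
driverseek score-screen --library ex/library.tsv --counts ex/counts.tsv \
    --seed 0 --out ex/gene_results.tsv
# -> 28 hits of 204 genes (product-score threshold 5.73206)
driverseek integrate --screen ex/gene_results.tsv --pickles ex/calls.tsv \
    --depmap ex/effects.tsv --xscreens ex/xscreen_1.txt --xscreens ex/xscreen_2.txt \
    --expr ex/expression.tsv --cn ex/cn.tsv --clinical ex/clinical.tsv \
    --out ex/final_ranked.tsv --trace ex/trace.tsv
# -> 1 genes -> ex/final_ranked.tsv
driverseek survival --expr ex/expression.tsv --cn ex/cn.tsv \
    --clinical ex/clinical.tsv --gene DRIVER --out ex/survival_DRIVER.tsv
# -> DRIVER: logrank chisq=12.95 p=0.0003192 HR=2.636 CI=(1.524, 4.56)
```

The final ranking contains exactly the planted driver:

```
gene    phenotype   mw_p        n_sgrnas_used  scored  product_score  hit   final_rank
DRIVER  -0.418014   0.00174342  5              True    91.8713        True  1
```

Reading it: the screen estimated the driver's fitness cost at −0.42 per
doubling (planted truth −0.4) and called 28 hits; the essentiality stages
removed the amplified common-essential decoy (which the clinical-only
ranking retains — see `ex/trace.tsv` for the per-gene removal record),
leaving the driver ranked first; its high-expression quartile more than
doubles the death hazard (HR 2.6, planted truth 2).

The same run is available as one command from a TOML config
(`driverseek run-all --config run.toml`), which also writes a `run_log.txt`
with parameters, seed and input checksums for exact reproduction. All of
the above is equally accessible from Python (`import driverseek`).

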