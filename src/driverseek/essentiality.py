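"""Pan-cancer essentiality filtering and the combined ranking.

A screen hit that is essential in nearly every cell type is a poor
tumor-selective target. This module removes such genes from the hit list
in a fixed order:

1. PICKLES-style binary calls: remove genes essential in >= 90% of
   non-prostate cell lines (boundary inclusive).
2. DepMap-style continuous gene effects: remove common-essential genes,
   computed by the percentile-rank convention (a gene whose 90th-percentile
   fractional essentiality rank across cell lines is within the most
   essential 10%) or a simple median-effect threshold; a precomputed flag
   list may be supplied instead.
3. Cross-screen exclusion: remove genes that are significant hits in
   external non-prostate CRISPRi screens (union over the supplied sets by
   default), catching false negatives of the knockout panels.
4. Metastasis-expression prioritization: keep only genes expressed higher
   in metastatic than in primary samples (two-sided Wilcoxon p <= 0.05).

Survivors are ranked by screen phenotype (most depleted first), ties by
Mann-Whitney p, then gene symbol. A per-gene trace records the stage at
which every input hit was removed, so |hits| always equals
|survivors| + total removals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import ClinicalFilterParams, clinical_filter
from .errors import CohortError, MatrixError, ValidationError
from .io import ClinicalCohort, EssentialCallMatrix, GeneEffectMatrix
from .stats import mann_whitney

logger = logging.getLogger("driverseek")

STAGES = ("pickles", "depmap", "xscreens", "met_expression")


@dataclass
class IntegrationParams:
    """Parameters of the combined filter chain."""

    pickles_frac: float = 0.90
    excluded_lineage: str = "prostate"
    depmap_method: str = "percentile_rank"  # or "threshold"
    depmap_cutoff: float = -0.6  # median-effect cutoff for "threshold" mode
    xscreen_mode: str = "union"  # or "intersection"
    met_p_threshold: float = 0.05
    rank_key: str = "phenotype_first"  # or "p_first"

    def __post_init__(self) -> None:
        if not 0 < self.pickles_frac <= 1:
            raise ValidationError("pickles_frac must lie in (0, 1]")
        if self.depmap_method not in ("percentile_rank", "threshold"):
            raise ValidationError(f"unknown depmap_method {self.depmap_method!r}")
        if self.xscreen_mode not in ("union", "intersection"):
            raise ValidationError(f"unknown xscreen_mode {self.xscreen_mode!r}")
        if self.rank_key not in ("phenotype_first", "p_first"):
            raise ValidationError(f"unknown rank_key {self.rank_key!r}")


class FilterTrace:
    """Per-gene bookkeeping across the filter chain.

    Every input hit appears exactly once; a gene has a final rank iff it
    survived all four stages. ``check()`` asserts the accounting identity
    |input| == |survivors| + sum of per-stage removals.
    """

    def __init__(self, hits) -> None:
        self.table = pd.DataFrame(
            {f"survived_{s}": pd.Series(pd.NA, index=list(hits), dtype="boolean") for s in STAGES}
        )
        self.table["final_rank"] = pd.Series(pd.NA, index=self.table.index, dtype="Int64")
        self.table["note"] = ""
        self.table.index.name = "gene"

    def record_stage(self, stage: str, survivors, notes: dict[str, str] | None = None) -> None:
        col = f"survived_{stage}"
        alive = self.table[col].isna() & self._alive_mask()
        self.table.loc[alive, col] = self.table.index[alive].isin(set(survivors))
        removed = alive & (self.table[col] == False)  # noqa: E712
        for gene in self.table.index[removed]:
            note = (notes or {}).get(gene, "")
            self.table.loc[gene, "note"] = f"removed at {stage}" + (f": {note}" if note else "")
        logger.info("stage %s: %d -> %d genes", stage, int(alive.sum()), len(survivors))

    def _alive_mask(self) -> pd.Series:
        mask = pd.Series(True, index=self.table.index)
        for s in STAGES:
            col = self.table[f"survived_{s}"]
            mask &= col.isna() | (col == True)  # noqa: E712
        return mask

    @property
    def survivors(self) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for s in STAGES:
            mask &= self.table[f"survived_{s}"] == True  # noqa: E712
        return list(self.table.index[mask])

    def removals_per_stage(self) -> dict[str, int]:
        return {
            s: int((self.table[f"survived_{s}"] == False).sum())  # noqa: E712
            for s in STAGES
        }

    def to_frame(self) -> pd.DataFrame:
        """Serialized form: nullable booleans as ''/True/False strings."""
        out = self.table.astype(object).where(self.table.notna(), "")
        return out.reset_index()

    def check(self) -> None:
        n_removed = sum(self.removals_per_stage().values())
        if len(self.table) != len(self.survivors) + n_removed:
            raise AssertionError("filter trace does not account for every input hit")


def pickles_filter(
    hits,
    calls: EssentialCallMatrix,
    frac: float = 0.90,
    excluded_lineage: str = "prostate",
) -> tuple[list[str], dict[str, str]]:
    """Remove genes essential in >= ``frac`` of non-excluded cell lines.

    Genes absent from the call matrix survive with a logged "no data"
    note. Returns the surviving genes (input order) and per-gene notes.
    """
    if not 0 < frac <= 1:
        raise ValidationError("frac must lie in (0, 1]")
    mask = calls.lineage != excluded_lineage
    if not mask.any():
        raise MatrixError("essential-call matrix has no non-excluded cell lines")
    sub = calls.calls.loc[mask]
    survivors, notes = [], {}
    for gene in hits:
        if gene not in sub.columns:
            survivors.append(gene)
            notes[gene] = "no data"
            logger.info("pickles filter: no data for %s, kept", gene)
            continue
        fraction = float(sub[gene].mean())
        if fraction >= frac:
            notes[gene] = f"essential in {fraction:.0%} of non-{excluded_lineage} lines"
        else:
            survivors.append(gene)
    return survivors, notes


def depmap_common_essential(
    effects: GeneEffectMatrix,
    method: str = "percentile_rank",
    cutoff: float = -0.6,
    precomputed=None,
) -> set[str]:
    """Identify common-essential genes from a continuous gene-effect matrix.

    percentile_rank (default, needs >= 10 cell lines): within each cell
    line genes are ranked by effect ascending (most negative first) as a
    fraction of genes; a gene is common essential when the 90th percentile
    of its fractional ranks across lines is <= 0.10 — i.e. it sits in the
    most-essential 10% of genes in at least 90% of lines.

    threshold: common essential when the median effect across lines is
    <= ``cutoff`` (default -0.6 on the 0 = non-essential / -1 = median
    common essential scale).

    ``precomputed``: an explicit gene set bypassing computation.
    """
    if precomputed is not None:
        return set(precomputed)
    if method == "threshold":
        med = effects.effects.median(axis=0)
        return set(med.index[med <= cutoff])
    if method != "percentile_rank":
        raise ValidationError(f"unknown depmap method {method!r}")
    n_lines, n_genes = effects.effects.shape
    if n_lines < 10:
        raise MatrixError("percentile_rank mode requires at least 10 cell lines")
    frac_rank = effects.effects.rank(axis=1, method="average") / n_genes
    q90 = frac_rank.quantile(0.90, axis=0)
    return set(q90.index[q90 <= 0.10])


def xscreen_filter(hits, other_hits: list[set], mode: str = "union") -> tuple[list[str], dict[str, str]]:
    """Remove genes found as hits in external CRISPRi screens.

    ``union`` (default) removes a gene present in any supplied set;
    ``intersection`` removes only genes present in every set.
    """
    sets = [set(s) for s in other_hits]
    if mode == "union":
        excluded = set().union(*sets) if sets else set()
    elif mode == "intersection":
        excluded = set.intersection(*sets) if sets else set()
    else:
        raise ValidationError(f"unknown xscreen mode {mode!r}")
    survivors = [g for g in hits if g not in excluded]
    notes = {g: "hit in external screen(s)" for g in hits if g in excluded}
    return survivors, notes


def met_expression_filter(
    hits,
    cohort: ClinicalCohort,
    p_threshold: float = 0.05,
) -> tuple[list[str], dict[str, str]]:
    """Keep genes expressed higher in metastatic than primary samples.

    A gene survives when mean TPM(metastatic) > mean TPM(primary) and the
    two-sided Wilcoxon rank-sum p is at or below ``p_threshold``.
    """
    types = cohort.clinical["cohort_type"]
    met = types == "metastatic"
    pri = types == "primary"
    if met.sum() < 2 or pri.sum() < 2:
        raise CohortError("met_expression_filter needs >= 2 metastatic and >= 2 primary samples")
    survivors, notes = [], {}
    for gene in hits:
        if gene not in cohort.expression.columns:
            notes[gene] = "no expression data"
            continue
        x_met = cohort.expression.loc[met, gene].to_numpy()
        x_pri = cohort.expression.loc[pri, gene].to_numpy()
        if x_met.mean() <= x_pri.mean():
            notes[gene] = "not higher in metastasis"
            continue
        _, p = mann_whitney(x_met, x_pri)
        if p <= p_threshold:
            survivors.append(gene)
        else:
            notes[gene] = f"met vs primary p={p:.3g} above threshold"
    return survivors, notes


def final_rank(survivors: pd.DataFrame, key: str = "phenotype_first") -> pd.DataFrame:
    """Rank the surviving genes by screen strength.

    ``phenotype_first`` (default) sorts by phenotype ascending (most
    depleted first) with Mann-Whitney p as tiebreaker; ``p_first``
    reverses the two keys. Gene symbol breaks remaining ties. Rank 1 is
    the strongest candidate driver.
    """
    out = survivors.copy()
    out = out.reset_index().rename(columns={"index": "gene"})
    if key == "phenotype_first":
        cols = ["phenotype", "mw_p", "gene"]
    elif key == "p_first":
        cols = ["mw_p", "phenotype", "gene"]
    else:
        raise ValidationError(f"unknown rank key {key!r}")
    out = out.sort_values(cols, kind="mergesort").set_index("gene")
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class PipelineResult:
    """Output bundle of the combined filter chain."""

    final_ranked: pd.DataFrame
    clinical_ranked: pd.DataFrame
    trace: FilterTrace
    removals: dict[str, int] = field(default_factory=dict)


def run_combined_pipeline(
    gene_results: pd.DataFrame,
    cohort: ClinicalCohort,
    calls: EssentialCallMatrix,
    effects: GeneEffectMatrix,
    xscreens: list[set],
    params: IntegrationParams | None = None,
    clinical_params: ClinicalFilterParams | None = None,
    clinical_cohort: ClinicalCohort | None = None,
) -> PipelineResult:
    """Run the combined functional + clinical filter chain on screen hits.

    ``gene_results`` is the full hit-called gene table (``hit`` column
    required). The clinical-only ranking (copy-number/expression filter on
    the raw hits, computed on the metastatic samples of ``cohort`` unless
    a dedicated ``clinical_cohort`` is given) is emitted alongside the
    combined ranking so the two strategies can be compared: clinical
    filtering alone admits amplified common-essential false positives that
    the essentiality stages remove.
    """
    params = params or IntegrationParams()
    if "hit" not in gene_results.columns:
        raise ValidationError("gene_results must carry a 'hit' column (run call_hits first)")
    hits = list(gene_results.index[gene_results["hit"]])
    logger.info("combined pipeline: %d screen hits enter the filter chain", len(hits))
    trace = FilterTrace(hits)

    surv, notes = pickles_filter(hits, calls, params.pickles_frac, params.excluded_lineage)
    trace.record_stage("pickles", surv, notes)

    common = depmap_common_essential(effects, params.depmap_method, params.depmap_cutoff)
    surv2 = [g for g in surv if g not in common]
    trace.record_stage("depmap", surv2, {g: "DepMap common essential" for g in surv if g in common})

    surv3, notes3 = xscreen_filter(surv2, xscreens, params.xscreen_mode)
    trace.record_stage("xscreens", surv3, notes3)

    surv4, notes4 = met_expression_filter(surv3, cohort, params.met_p_threshold)
    trace.record_stage("met_expression", surv4, notes4)
    trace.check()

    ranked = final_rank(gene_results.loc[surv4], params.rank_key)
    trace.table.loc[ranked.index, "final_rank"] = ranked["final_rank"].astype("Int64")

    cohort_for_clinical = clinical_cohort if clinical_cohort is not None else cohort.subset("metastatic")
    clinical_ranked = clinical_filter(gene_results.loc[hits], cohort_for_clinical, clinical_params)

    return PipelineResult(
        final_ranked=ranked,
        clinical_ranked=clinical_ranked,
        trace=trace,
        removals=trace.removals_per_stage(),
    )
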