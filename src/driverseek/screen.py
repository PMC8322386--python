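"""Pooled CRISPRi growth-screen scoring and hit calling.

The phenotype score gamma of an sgRNA is its log2 enrichment between the
start (T0) and end (TEND) of the screen, centered on the median of the
non-targeting negative controls and divided by the number of population
doublings — so gamma is log2 relative fitness per doubling, with negative
values marking sgRNAs whose target gene is required for growth or
survival.

Per replicate:

    rpm    = 1e6 * count / column_total          (reads per million)
    raw_i  = log2(rpm_i^TEND + ps) - log2(rpm_i^T0 + ps)
    gamma_i = (raw_i - median_NC(raw)) / doublings

The pseudocount ``ps`` is applied on the reads-per-million scale so that
rescaling any sample column (sequencing depth) leaves every gamma exactly
unchanged. Replicates are combined by unweighted mean and the combined
scores re-centered so the negative-control median is exactly zero.

Gene-level calling follows the empirical-FDR convention of the CRISPRi
screen-processing lineage: each gene's phenotype is the mean of its most
extreme sgRNAs (or of all passing sgRNAs), significance is a two-sided
Mann-Whitney test of the gene's sgRNA gammas against all negative-control
gammas, and the product score |phenotype / sigma_NC| * (-log10 p) is
thresholded at the smallest value whose estimated false-discovery rate —
from pseudogenes assembled by randomly grouping negative-control sgRNAs —
is at or below the target FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ScreenError, ValidationError
from .io import TEND, T0, CountMatrix, SgRNALibrary
from .stats import mann_whitney

logger = logging.getLogger("driverseek")

#: reference scale for the reads-per-million normalization
RPM_SCALE = 1e6


@dataclass
class ScreenParams:
    """Tunable parameters of screen scoring and hit calling.

    doublings
        population doublings between T0 and TEND (screen design: 8).
    pseudocount
        added to reads-per-million before the log-ratio (default 1).
    min_t0_reads
        sgRNAs with fewer raw T0 reads than this in any replicate are
        excluded from all gene statistics (default 25).
    gene_score_mode / n_top
        ``top_n_abs``: gene phenotype = mean of the n_top sgRNAs with the
        largest |gamma| (default 3 of 5); ``mean_all``: mean of all
        passing sgRNAs.
    pseudogene_size / n_pseudogenes
        negative-control pseudogenes are groups of ``pseudogene_size``
        NC sgRNAs (default 5, the library's sgRNAs-per-gene), drawn
        ``n_pseudogenes`` times.
    target_fdr
        empirical false-discovery rate for hit calling (default 0.05).
    """

    doublings: float = 8.0
    pseudocount: float = 1.0
    min_t0_reads: int = 25
    gene_score_mode: str = "top_n_abs"
    n_top: int = 3
    pseudogene_size: int = 5
    n_pseudogenes: int = 2000
    target_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doublings <= 0 or self.pseudocount < 0:
            raise ValidationError("doublings must be positive and pseudocount non-negative")
        if self.gene_score_mode not in ("top_n_abs", "mean_all"):
            raise ValidationError(f"unknown gene_score_mode {self.gene_score_mode!r}")
        if not 0 < self.target_fdr < 1:
            raise ValidationError("target_fdr must lie in (0, 1)")
        if self.n_top < 1 or self.pseudogene_size < 1 or self.n_pseudogenes < 1:
            raise ValidationError("n_top, pseudogene_size, n_pseudogenes must be positive")


@dataclass
class SgRNAPhenotypes:
    """Per-sgRNA phenotype scores.

    ``per_replicate``: sgRNA x replicate gamma (NC median zero within each
    replicate). ``combined``: replicate-mean gamma, re-centered so the NC
    median is exactly zero. ``pass_filter``: False excludes the sgRNA from
    every downstream gene statistic.
    """

    per_replicate: pd.DataFrame
    combined: pd.Series
    pass_filter: pd.Series
    is_control: pd.Series

    @property
    def passing_nc_gammas(self) -> np.ndarray:
        mask = self.is_control & self.pass_filter
        return self.combined[mask].to_numpy()


def compute_sgrna_phenotypes(
    counts: CountMatrix, library: SgRNALibrary, params: ScreenParams
) -> SgRNAPhenotypes:
    """Convert raw counts to per-sgRNA phenotype scores (gamma)."""
    library.require_controls()
    is_control = library.table["is_control"]
    nc_mask = is_control.to_numpy()

    per_rep = {}
    pass_filter = pd.Series(True, index=library.sgrna_ids)
    for rep in counts.replicates:
        c0 = counts.column(T0, rep).to_numpy(dtype=float)
        ct = counts.column(TEND, rep).to_numpy(dtype=float)
        if c0.sum() == 0 or ct.sum() == 0:
            raise ScreenError(f"replicate {rep} has an all-zero sample column")
        rpm0 = c0 / c0.sum() * RPM_SCALE
        rpmt = ct / ct.sum() * RPM_SCALE
        raw = np.log2(rpmt + params.pseudocount) - np.log2(rpm0 + params.pseudocount)
        raw -= np.median(raw[nc_mask])
        per_rep[rep] = raw / params.doublings
        pass_filter &= pd.Series(c0 >= params.min_t0_reads, index=library.sgrna_ids)

    per_replicate = pd.DataFrame(per_rep, index=library.sgrna_ids)
    combined = per_replicate.mean(axis=1)
    combined -= np.median(combined[nc_mask])
    n_fail = int((~pass_filter).sum())
    if n_fail:
        logger.info("read filter: %d sgRNAs below %d T0 reads excluded", n_fail, params.min_t0_reads)
    return SgRNAPhenotypes(
        per_replicate=per_replicate,
        combined=combined,
        pass_filter=pass_filter,
        is_control=is_control,
    )


def replicate_correlation(
    phenotypes: SgRNAPhenotypes,
    level: str = "sgrna",
    library: SgRNALibrary | None = None,
) -> tuple[float, int]:
    """Pearson correlation between replicate phenotype scores.

    At ``level="sgrna"`` the correlation is over passing sgRNAs; at
    ``level="gene"`` per-replicate gene scores (mean gamma over a gene's
    passing sgRNAs) are correlated instead. With more than two replicates
    the mean of all pairwise correlations is returned.
    """
    reps = list(phenotypes.per_replicate.columns)
    if len(reps) < 2:
        raise ScreenError("replicate correlation requires at least 2 replicates")
    table = phenotypes.per_replicate[phenotypes.pass_filter]
    if level == "gene":
        if library is None:
            raise ValidationError("gene-level correlation requires the library")
        targets = library.table.loc[table.index, "target"]
        table = table[~library.table.loc[table.index, "is_control"]].groupby(targets).mean()
    elif level != "sgrna":
        raise ValidationError(f"unknown correlation level {level!r}")
    rs = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            r, _ = _sps.pearsonr(table[reps[i]], table[reps[j]])
            rs.append(r)
    return float(np.mean(rs)), len(table)


def _score_group(
    gammas: np.ndarray, nc_gammas: np.ndarray, params: ScreenParams
) -> tuple[float, float]:
    """Phenotype and Mann-Whitney p for one group of sgRNA gammas."""
    if params.gene_score_mode == "top_n_abs":
        order = np.argsort(-np.abs(gammas), kind="stable")
        top = gammas[order[: params.n_top]]
        phenotype = float(np.mean(top))
    else:
        phenotype = float(np.mean(gammas))
    _, p = mann_whitney(gammas, nc_gammas)
    return phenotype, p


def gene_scores(
    phenotypes: SgRNAPhenotypes, library: SgRNALibrary, params: ScreenParams
) -> pd.DataFrame:
    """Gene-level phenotype and Mann-Whitney significance.

    Genes with fewer than 2 passing sgRNAs are reported unscored
    (``scored=False``, NaN phenotype and p).
    """
    nc = phenotypes.passing_nc_gammas
    if nc.size == 0:
        raise ScreenError("no passing negative-control sgRNAs")
    lib = library.gene_targeting
    passing = phenotypes.pass_filter
    rows = []
    for gene, sub in lib.groupby("target"):
        ids = sub.index[passing[sub.index]]
        g = phenotypes.combined[ids].to_numpy()
        if g.size < 2:
            rows.append((gene, np.nan, np.nan, g.size, False))
            continue
        phenotype, p = _score_group(g, nc, params)
        rows.append((gene, phenotype, p, g.size, True))
    out = pd.DataFrame(rows, columns=["gene", "phenotype", "mw_p", "n_sgrnas_used", "scored"])
    n_unscored = int((~out["scored"]).sum())
    if n_unscored:
        logger.info("gene scoring: %d genes with <2 passing sgRNAs left unscored", n_unscored)
    return out.set_index("gene")


def build_pseudogenes(phenotypes: SgRNAPhenotypes, params: ScreenParams) -> pd.DataFrame:
    """Score synthetic genes assembled from random negative-control sgRNAs.

    Each pseudogene is ``pseudogene_size`` distinct NC sgRNAs drawn
    without replacement (with replacement between pseudogenes), scored
    exactly like a real gene. They provide the empirical null for the
    product-score threshold.
    """
    nc = phenotypes.passing_nc_gammas
    if nc.size < params.pseudogene_size:
        raise ScreenError(
            f"need at least {params.pseudogene_size} passing NC sgRNAs, have {nc.size}"
        )
    rng = np.random.default_rng(params.seed)
    rows = []
    for k in range(params.n_pseudogenes):
        g = rng.choice(nc, size=params.pseudogene_size, replace=False)
        phenotype, p = _score_group(g, nc, params)
        rows.append((f"pseudo_{k:05d}", phenotype, p))
    return pd.DataFrame(rows, columns=["gene", "phenotype", "mw_p"]).set_index("gene")


def _product_scores(table: pd.DataFrame, sigma_nc: float) -> pd.Series:
    return (table["phenotype"].abs() / sigma_nc) * (-np.log10(table["mw_p"]))


def call_hits(
    genes: pd.DataFrame,
    pseudogenes: pd.DataFrame,
    params: ScreenParams,
    fixed_threshold: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Call depletion hits at an empirical FDR anchored to pseudogenes.

    The threshold is the smallest observed gene product score t such that

        (#pseudogenes >= t) / n_pseudogenes * n_genes / (#genes >= t)

    is at or below ``target_fdr``; a gene is a hit when its product score
    reaches the threshold *and* its phenotype is negative (growth screens
    read out depletion). A ``fixed_threshold`` bypasses calibration for
    reproducibility studies.

    Returns the gene table with ``product_score`` and ``hit`` columns
    added, plus the threshold used.
    """
    if len(pseudogenes) == 0:
        raise ScreenError("hit calling requires pseudogenes")
    sigma_nc = float(pseudogenes["phenotype"].std(ddof=1))
    if sigma_nc == 0:
        sigma_nc = np.finfo(float).tiny  # degenerate noiseless null
    out = genes.copy()
    scored = out["scored"] if "scored" in out.columns else pd.Series(True, index=out.index)
    out["product_score"] = _product_scores(out, sigma_nc)
    pseudo_scores = _product_scores(pseudogenes, sigma_nc).to_numpy()

    gene_scores_arr = out.loc[scored, "product_score"].to_numpy()
    if np.all(gene_scores_arr == 0) and np.all(pseudo_scores == 0):
        raise ScreenError("all product scores are zero; nothing to calibrate")

    if fixed_threshold is not None:
        threshold = float(fixed_threshold)
    else:
        n_genes = gene_scores_arr.size
        threshold = np.inf
        for t in np.sort(np.unique(gene_scores_arr)):
            n_above = (gene_scores_arr >= t).sum()
            pseudo_above = (pseudo_scores >= t).sum() / len(pseudo_scores) * n_genes
            if pseudo_above / n_above <= params.target_fdr:
                threshold = float(t)
                break
    out["hit"] = scored & (out["product_score"] >= threshold) & (out["phenotype"] < 0)
    logger.info(
        "hit calling: threshold %.4g, %d/%d genes called (target FDR %.3g)",
        threshold,
        int(out["hit"].sum()),
        len(out),
        params.target_fdr,
    )
    return out, threshold


def score_screen(
    counts: CountMatrix, library: SgRNALibrary, params: ScreenParams
) -> tuple[pd.DataFrame, SgRNAPhenotypes, float]:
    """Full screen scoring: counts -> gene results with hit calls.

    Convenience wrapper running phenotype computation, gene scoring,
    pseudogene construction and hit calling in sequence.
    """
    phen = compute_sgrna_phenotypes(counts, library, params)
    genes = gene_scores(phen, library, params)
    pseudo = build_pseudogenes(phen, params)
    results, threshold = call_hits(genes, pseudo, params)
    return results, phen, threshold
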