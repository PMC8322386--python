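"""Clinical-genomics filtering of screen hits.

Drivers of metastatic disease commonly show recurrent copy-number gains
whose expression responds to the gain. This module ranks screen hits by
the number of cohort samples carrying a copy-number gain of the gene and
keeps only genes where the gain produces a corresponding expression
change: fold change in mean TPM (gain vs no-gain samples) of at least 2
with a two-sided Wilcoxon rank-sum p-value of at most 0.001. Both
thresholds are boundary-inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortError, ValidationError
from .io import ClinicalCohort
from .stats import mann_whitney

logger = logging.getLogger("driverseek")

GAIN = 1


@dataclass
class ClinicalFilterParams:
    """Thresholds of the copy-number/expression filter (inclusive)."""

    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    #: "neutral_or_loss" pools neutral and loss samples as the no-gain
    #: group; "neutral_only" drops losses instead.
    no_gain_group: str = "neutral_or_loss"

    def __post_init__(self) -> None:
        if self.no_gain_group not in ("neutral_or_loss", "neutral_only"):
            raise ValidationError(f"unknown no_gain_group {self.no_gain_group!r}")


def rank_by_cn_gain(genes, cohort: ClinicalCohort) -> pd.DataFrame:
    """Rank genes by the number of cohort samples with a copy-number gain.

    Rank 1 is the most recurrently gained gene; ties are broken by gene
    symbol ascending so the ranking is a deterministic permutation.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in cohort.cn_state.columns]
    if missing:
        raise CohortError(f"gene {missing[0]!r} absent from cohort copy-number data")
    n_gain = (cohort.cn_state[genes] == GAIN).sum(axis=0)
    out = pd.DataFrame({"gene": genes, "n_gain": n_gain.to_numpy()})
    out = out.sort_values(["n_gain", "gene"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("gene")


def cn_expression_test(
    gene: str,
    cohort: ClinicalCohort,
    params: ClinicalFilterParams | None = None,
) -> dict | None:
    """Test whether a gene's expression responds to its copy-number gain.

    Returns a record with the group means, fold change, Wilcoxon p and the
    pass flag, or ``None`` when either group has fewer than 2 samples
    (the gene is untestable and the caller excludes it).

    A no-gain group mean of exactly zero with expressed gain samples
    yields an infinite fold change, which satisfies the fold-change
    criterion; the p-value criterion still applies.
    """
    params = params or ClinicalFilterParams()
    if gene not in cohort.expression.columns:
        raise CohortError(f"gene {gene!r} absent from cohort expression data")
    cn = cohort.cn_state[gene]
    tpm = cohort.expression[gene]
    gain = tpm[cn == GAIN]
    if params.no_gain_group == "neutral_or_loss":
        nogain = tpm[cn != GAIN]
    else:
        nogain = tpm[cn == 0]
    if len(gain) < 2 or len(nogain) < 2:
        logger.info("cn_expression_test: %s untestable (%d gain / %d no-gain samples)",
                    gene, len(gain), len(nogain))
        return None
    mean_gain = float(gain.mean())
    mean_nogain = float(nogain.mean())
    if mean_nogain == 0:
        fc = np.inf if mean_gain > 0 else np.nan
    else:
        fc = mean_gain / mean_nogain
    _, p = mann_whitney(gain.to_numpy(), nogain.to_numpy())
    passes = bool(fc >= params.fc_threshold) and p <= params.p_threshold
    return {
        "gene": gene,
        "mean_tpm_gain": mean_gain,
        "mean_tpm_nogain": mean_nogain,
        "fold_change": fc,
        "wilcoxon_p": p,
        "passes": passes,
    }


def clinical_filter(
    hits: pd.DataFrame,
    cohort: ClinicalCohort,
    params: ClinicalFilterParams | None = None,
) -> pd.DataFrame:
    """Apply the copy-number/expression filter to screen hits.

    ``hits`` is a gene-indexed table carrying at least ``phenotype`` and
    ``mw_p`` (screen results are passed through for reporting). The output
    keeps the hits whose expression responds to copy-number gain, ordered
    by copy-number-gain recurrence rank. An empty result is a valid
    outcome and returns an empty table with a warning.
    """
    params = params or ClinicalFilterParams()
    if len(hits) == 0:
        raise ValidationError("clinical_filter requires a non-empty hit list")
    ranks = rank_by_cn_gain(hits.index, cohort)
    rows = []
    for gene in hits.index:
        rec = cn_expression_test(gene, cohort, params)
        if rec is None or not rec["passes"]:
            continue
        rec["n_gain"] = int(ranks.loc[gene, "n_gain"])
        rec["cn_rank"] = int(ranks.loc[gene, "rank"])
        rec["phenotype"] = hits.loc[gene, "phenotype"]
        rec["mw_p"] = hits.loc[gene, "mw_p"]
        rows.append(rec)
    if not rows:
        logger.warning("clinical filter: no hits survive the CN/expression criteria")
        return pd.DataFrame(
            columns=["mean_tpm_gain", "mean_tpm_nogain", "fold_change", "wilcoxon_p",
                     "passes", "n_gain", "cn_rank", "phenotype", "mw_p"]
        )
    out = pd.DataFrame(rows).set_index("gene")
    return out.sort_values(["cn_rank"], kind="mergesort")
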