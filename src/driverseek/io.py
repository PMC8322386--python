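"""Input/output for every table the pipeline touches.

All files are plain delimited text (tab-separated by default; comma via
``sep=","``). Validation is total: every invariant documented on a domain
type is enforced at read time and raises a named error from
:mod:`driverseek.errors`.

On-disk conventions
-------------------
library
    columns ``sgrna_id``, ``target`` (gene symbol, or the literal ``NC``
    for non-targeting negative controls), optional ``tss_id``.
counts
    first column ``sgrna_id``; remaining columns are samples named
    ``<timepoint>_rep<k>`` where timepoint is ``T0`` for the start of the
    screen and anything else (``T8``, ``TEND``) for the endpoint.
cohort
    three files sharing ``sample_id``: expression (sample x gene, TPM),
    copy-number state (sample x gene, integers -1/0/1 for loss/neutral/gain,
    or absolute copy number with a gain threshold), and a clinical table
    with ``cohort_type`` (benign/primary/metastatic) and optional
    ``os_months``/``os_event``.
gene-effect / essential-call matrices
    first column ``cell_line``, second column ``lineage``, remaining
    columns one per gene (real effects, or 0/1 calls).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortError, CountsError, LibraryError, MatrixError, ValidationError

logger = logging.getLogger("driverseek")

#: literal target string marking a non-targeting negative-control sgRNA
NC_SENTINEL = "NC"

T0 = "T0"
TEND = "TEND"

COHORT_TYPES = ("benign", "primary", "metastatic")

_CN_STATE_FROM_INT = {-1: "loss", 0: "neutral", 1: "gain"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SgRNALibrary:
    """Maps sgRNA ids to target genes and flags negative controls.

    ``table`` is indexed by ``sgrna_id`` with columns ``target`` (gene
    symbol or :data:`NC_SENTINEL`) and ``is_control`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise LibraryError(f"duplicate sgrna_id {dup!r} in library")
        targets = self.table["target"]
        empty = targets.isna() | (targets.astype(str).str.strip() == "")
        if empty.any():
            bad = self.table.index[empty][0]
            raise LibraryError(f"sgRNA {bad!r} has an empty target field")
        if "is_control" not in self.table.columns:
            self.table["is_control"] = targets == NC_SENTINEL

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.table.index

    @property
    def control_ids(self) -> pd.Index:
        return self.table.index[self.table["is_control"]]

    @property
    def gene_targeting(self) -> pd.DataFrame:
        return self.table[~self.table["is_control"]]

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_targeting["target"].unique())

    @property
    def sgrnas_per_gene(self) -> pd.Series:
        """Number of sgRNAs per targeted gene (library design is 5/gene)."""
        return self.gene_targeting.groupby("target").size()

    def require_controls(self) -> None:
        if len(self.control_ids) == 0:
            raise LibraryError("library contains no negative-control sgRNAs")


@dataclass
class CountMatrix:
    """Non-negative integer sgRNA x sample read counts.

    ``samples`` is indexed by sample id with columns ``timepoint``
    (``T0``/``TEND``) and ``replicate`` (1-based int).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise CountsError("count matrix contains missing values")
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            r, c = np.argwhere((vals < 0) | (vals != np.round(vals)))[0]
            raise CountsError(
                f"negative or non-integer count at ({self.counts.index[r]}, {self.counts.columns[c]})"
            )
        self.counts = self.counts.astype(np.int64)
        for rep, grp in self.samples.groupby("replicate"):
            tps = set(grp["timepoint"])
            if not {T0, TEND} <= tps:
                raise CountsError(f"replicate {rep} lacks a {T0} or {TEND} sample")

    @property
    def replicates(self) -> list[int]:
        return sorted(self.samples["replicate"].unique())

    def column(self, timepoint: str, replicate: int) -> pd.Series:
        sel = self.samples[
            (self.samples["timepoint"] == timepoint) & (self.samples["replicate"] == replicate)
        ]
        if len(sel) != 1:
            raise CountsError(
                f"expected exactly one {timepoint} sample for replicate {replicate}, found {len(sel)}"
            )
        return self.counts[sel.index[0]]


@dataclass
class ClinicalCohort:
    """Per-sample expression (TPM), copy-number state and clinical annotation.

    ``expression`` and ``cn_state`` are sample x gene with identical
    indices; ``cn_state`` holds integers -1/0/1 (loss/neutral/gain).
    ``clinical`` is indexed by sample with ``cohort_type`` and optional
    ``os_months``/``os_event``.
    """

    expression: pd.DataFrame
    cn_state: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.cn_state.index) or not self.expression.columns.equals(
            self.cn_state.columns
        ):
            raise CohortError("expression and cn_state must share sample and gene indices")
        if not self.expression.index.equals(self.clinical.index):
            raise CohortError("clinical table must cover exactly the cohort samples")
        ev = self.expression.to_numpy(dtype=float)
        if np.isnan(ev).any():
            raise CohortError("expression matrix contains missing values")
        if (ev < 0).any():
            raise CohortError("expression (TPM) must be non-negative")
        cn = self.cn_state.to_numpy()
        if not np.isin(cn, (-1, 0, 1)).all():
            raise CohortError("cn_state entries must be -1/0/1")
        bad_type = ~self.clinical["cohort_type"].isin(COHORT_TYPES)
        if bad_type.any():
            raise CohortError(
                f"unknown cohort_type {self.clinical['cohort_type'][bad_type].iloc[0]!r}"
            )
        if "os_months" in self.clinical.columns or "os_event" in self.clinical.columns:
            months = self.clinical.get("os_months", pd.Series(np.nan, index=self.clinical.index))
            event = self.clinical.get("os_event", pd.Series(np.nan, index=self.clinical.index))
            mismatch = months.notna() != event.notna()
            if mismatch.any():
                raise CohortError(
                    f"sample {self.clinical.index[mismatch][0]!r} has os_months/os_event "
                    "present without the other"
                )
            if (months.dropna() < 0).any():
                raise CohortError("os_months must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    def subset(self, cohort_type: str) -> "ClinicalCohort":
        """Restrict to samples of one cohort type."""
        mask = self.clinical["cohort_type"] == cohort_type
        return ClinicalCohort(
            expression=self.expression.loc[mask],
            cn_state=self.cn_state.loc[mask],
            clinical=self.clinical.loc[mask],
        )

    def with_survival(self) -> "ClinicalCohort":
        """Restrict to samples with overall-survival follow-up."""
        if "os_months" not in self.clinical.columns:
            raise CohortError("cohort has no os_months column")
        mask = self.clinical["os_months"].notna()
        return ClinicalCohort(
            expression=self.expression.loc[mask],
            cn_state=self.cn_state.loc[mask],
            clinical=self.clinical.loc[mask],
        )


def _validate_lineage(matrix: pd.DataFrame, lineage: pd.Series, kind: str) -> None:
    if not matrix.index.equals(lineage.index):
        raise MatrixError(f"{kind}: lineage must be defined for every cell line")


@dataclass
class GeneEffectMatrix:
    """Continuous gene-effect scores, cell line x gene.

    Scale convention (CERES/Chronos-style): 0 corresponds to a
    non-essential gene, -1 to the median of all common essential genes.
    """

    effects: pd.DataFrame
    lineage: pd.Series

    def __post_init__(self) -> None:
        _validate_lineage(self.effects, self.lineage, "gene-effect matrix")
        if not np.isfinite(self.effects.to_numpy(dtype=float)).all():
            raise MatrixError("gene-effect matrix contains non-finite values")


@dataclass
class EssentialCallMatrix:
    """Binary essentiality calls, cell line x gene, with cell-line lineages."""

    calls: pd.DataFrame
    lineage: pd.Series

    def __post_init__(self) -> None:
        _validate_lineage(self.calls, self.lineage, "essential-call matrix")
        vals = self.calls.to_numpy()
        if vals.dtype != bool:
            if not np.isin(vals, (0, 1)).all():
                raise MatrixError("essential-call matrix must be boolean (0/1)")
            self.calls = self.calls.astype(bool)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def read_library(path, sep: str = "\t") -> SgRNALibrary:
    """Read and validate an sgRNA library table."""
    df = _read_table(path, sep)
    for col in ("sgrna_id", "target"):
        if col not in df.columns:
            raise LibraryError(f"library file missing required column {col!r}")
    df = df.set_index("sgrna_id")
    lib = SgRNALibrary(df)
    logger.info(
        "library: %d gene-targeting sgRNAs (%d genes), %d negative controls",
        len(lib.gene_targeting),
        len(lib.genes),
        len(lib.control_ids),
    )
    return lib


_SAMPLE_RE = re.compile(r"^(?P<tp>[A-Za-z0-9]+)_rep(?P<rep>\d+)$")


def parse_sample_name(name: str) -> tuple[str, int]:
    """Parse ``T0_rep1`` / ``T8_rep2`` style column names.

    ``T0`` maps to the start timepoint; any other label (``T8``, ``TEND``)
    maps to the screen endpoint.
    """
    m = _SAMPLE_RE.match(name)
    if not m:
        raise CountsError(f"cannot parse sample name {name!r} (expected '<tp>_rep<k>')")
    tp = T0 if m.group("tp").upper() == T0 else TEND
    return tp, int(m.group("rep"))


def read_counts(path, library: SgRNALibrary, sep: str = "\t") -> CountMatrix:
    """Read a count table and align it to the library's sgRNA order.

    sgRNAs present in the file but not in the library are dropped with a
    warning; sgRNAs in the library but absent from the file are an error.
    """
    df = _read_table(path, sep)
    if "sgrna_id" not in df.columns:
        raise CountsError("counts file missing required column 'sgrna_id'")
    df = df.set_index("sgrna_id")
    extra = df.index.difference(library.sgrna_ids)
    if len(extra):
        logger.warning("dropping %d sgRNAs not present in library (e.g. %s)", len(extra), extra[0])
        df = df.drop(index=extra)
    missing = library.sgrna_ids.difference(df.index)
    if len(missing):
        raise CountsError(f"counts file missing {len(missing)} library sgRNAs (e.g. {missing[0]!r})")
    df = df.loc[library.sgrna_ids]
    meta = pd.DataFrame(
        [parse_sample_name(c) for c in df.columns],
        index=df.columns,
        columns=["timepoint", "replicate"],
    )
    return CountMatrix(counts=df, samples=meta)


def read_cohort(
    expression_path,
    cn_path,
    clinical_path,
    sep: str = "\t",
    cn_dialect: str = "state",
    gain_threshold: float = 3.0,
) -> ClinicalCohort:
    """Join expression, copy-number and clinical tables on shared samples.

    ``cn_dialect="state"`` expects integer states -1/0/1; ``"absolute"``
    expects absolute copy numbers and calls gain at ``CN >= gain_threshold``
    (default 3) and loss at ``CN <= 1``.
    """
    expr = _read_table(expression_path, sep).set_index("sample_id")
    cn = _read_table(cn_path, sep).set_index("sample_id")
    clin = _read_table(clinical_path, sep).set_index("sample_id")
    if "cohort_type" not in clin.columns:
        raise CohortError("clinical file missing required column 'cohort_type'")

    shared = expr.index.intersection(cn.index).intersection(clin.index)
    if len(shared) == 0:
        raise CohortError("no samples shared between expression, cn and clinical tables")
    for name, df in (("expression", expr), ("cn", cn), ("clinical", clin)):
        dropped = df.index.difference(shared)
        if len(dropped):
            logger.info("cohort join: dropping %d %s-only samples", len(dropped), name)
    genes = expr.columns.intersection(cn.columns)
    if len(genes) == 0:
        raise CohortError("no genes shared between expression and cn tables")

    shared = shared.sort_values()
    expr = expr.loc[shared, genes]
    cn = cn.loc[shared, genes]
    clin = clin.loc[shared]
    if cn_dialect == "absolute":
        abs_cn = cn.to_numpy(dtype=float)
        state = np.zeros_like(abs_cn, dtype=np.int64)
        state[abs_cn >= gain_threshold] = 1
        state[abs_cn <= 1] = -1
        cn = pd.DataFrame(state, index=cn.index, columns=cn.columns)
    elif cn_dialect != "state":
        raise CohortError(f"unknown cn_dialect {cn_dialect!r}")
    return ClinicalCohort(expression=expr, cn_state=cn.astype(np.int64), clinical=clin)


def _read_lineage_matrix(path, sep: str) -> tuple[pd.DataFrame, pd.Series]:
    df = _read_table(path, sep)
    for col in ("cell_line", "lineage"):
        if col not in df.columns:
            raise MatrixError(f"matrix file missing required column {col!r}")
    df = df.set_index("cell_line")
    lineage = df.pop("lineage")
    return df, lineage


def read_gene_effects(path, sep: str = "\t") -> GeneEffectMatrix:
    """Read a continuous gene-effect matrix (cell_line, lineage, genes...)."""
    df, lineage = _read_lineage_matrix(path, sep)
    return GeneEffectMatrix(effects=df.astype(float), lineage=lineage)


def read_essential_calls(path, sep: str = "\t") -> EssentialCallMatrix:
    """Read a binary essential-call matrix (cell_line, lineage, genes...)."""
    df, lineage = _read_lineage_matrix(path, sep)
    return EssentialCallMatrix(calls=df, lineage=lineage)


def read_hit_list(path) -> set[str]:
    """Read an external hit list: one gene symbol per line."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def write_results(table: pd.DataFrame, path, sep: str = "\t", sort_by=None) -> None:
    """Write a result table as delimited text with a deterministic layout.

    Rows are sorted by ``sort_by`` (default: all columns left to right, a
    total order on any result table) and reals rendered with 6 significant
    digits, so writing the same table twice produces byte-identical files.
    Empty tables are an error.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    out = table.reset_index() if table.index.name else table.copy()
    keys = sort_by if sort_by is not None else list(out.columns)
    out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep=sep, index=False, float_format="%.6g")
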