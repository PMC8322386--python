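"""Synthetic pipeline inputs with planted ground truth.

Three generators emulate the data the pipeline consumes:

* ``simulate_screen`` — pooled CRISPRi growth-screen counts. Each sgRNA
  carries a per-doubling log2 fitness effect gamma (negative = depleted);
  initial library representation is log-normal, and T0/TEND read counts
  are negative-binomial around depth-scaled abundances, with TEND
  abundances proportional to ``a * 2**(doublings * gamma)`` renormalized
  (a growing population dilutes depleted sgRNAs into everyone else's
  share; negative-control centering absorbs the renormalization).
* ``simulate_cohort`` — clinical cohorts with per-gene copy-number gains,
  log-normal TPM expression shifted by copy-number gain (delta, log2
  units) and by metastatic status (m, log2 units), and exponential
  overall survival whose hazard is multiplied by exp(beta) for samples in
  the top expression quartile of designated prognostic genes.
* ``simulate_essentiality`` — cell-line x gene effect matrices on the
  0 = non-essential / -1 = median-common-essential scale, with binary
  calls at effect <= -0.5, and per-line lineage labels.

``make_narrative_scenario`` bundles all three around four archetypes —
a tissue-specific true driver, an amplified common-essential decoy, an
amplified-but-dispensable gene, and a fully neutral gene — so the
contrast between clinical-only and combined filtering can be reproduced
end to end with known truth.

Every generator is a pure function of its config (including the seed);
truth tables are returned separately from the input objects and no
pipeline stage ever reads them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ClinicalCohort,
    CountMatrix,
    EssentialCallMatrix,
    GeneEffectMatrix,
    NC_SENTINEL,
    SgRNALibrary,
)

logger = logging.getLogger("driverseek")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion * mean**2.

    dispersion = 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValidationError("nb_dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Study conditions of a simulated pooled CRISPRi screen.

    Defaults mirror the screen design this package targets: 5 sgRNAs per
    gene, 8 population doublings, two replicates, ~2000 reads/sgRNA
    (1000x-coverage scale), essential-gene fitness effects between -0.5
    and -0.2 per doubling, and a guide-activity mixture in which 20% of
    gene-targeting sgRNAs are inert (real libraries contain inactive
    guides, which is what top-n gene scoring is designed to tolerate).
    """

    n_genes: int = 200
    frac_essential: float = 0.2
    gamma_range: tuple[float, float] = (-0.5, -0.2)
    sgrnas_per_gene: int = 5
    n_nc_sgrnas: int | None = None  # default: 10 genes' worth
    active_fraction: float = 0.8
    mean_depth: float = 2000.0
    nb_dispersion: float = 0.01
    doublings: float = 8.0
    replicates: int = 2
    seed: int = 0
    #: optional explicit gene symbols (length n_genes)
    gene_names: list[str] | None = None
    #: per-gene gamma overriding the random essential assignment
    gamma_overrides: dict[str, float] = field(default_factory=dict)
    #: spread (log-space sigma) of initial library representation
    abundance_sigma: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.frac_essential <= 1:
            raise ValidationError("frac_essential must lie in [0, 1]")
        if self.gamma_range[0] > self.gamma_range[1] or self.gamma_range[1] > 0:
            raise ValidationError("gamma_range must be (lo, hi) with lo <= hi <= 0")
        if self.n_nc_sgrnas is None:
            self.n_nc_sgrnas = 10 * self.sgrnas_per_gene
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValidationError("gene_names length must equal n_genes")


def simulate_screen(config: ScreenSimConfig) -> tuple[SgRNALibrary, CountMatrix, dict]:
    """Simulate a pooled screen; returns (library, counts, truth tables)."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names or [f"GENE{i:04d}" for i in range(config.n_genes)]

    n_ess = int(round(config.frac_essential * config.n_genes))
    if config.frac_essential > 0 and n_ess < 1:
        logger.warning("frac_essential * n_genes < 1: no essential genes will be planted")
    ess_idx = rng.choice(config.n_genes, size=n_ess, replace=False)
    gene_gamma = pd.Series(0.0, index=genes)
    lo, hi = config.gamma_range
    gene_gamma.iloc[ess_idx] = rng.uniform(lo, hi, size=n_ess)
    for g, val in config.gamma_overrides.items():
        gene_gamma[g] = val

    lib_rows = []
    sg_gamma = []
    for g in genes:
        for k in range(config.sgrnas_per_gene):
            active = rng.random() < config.active_fraction
            lib_rows.append((f"{g}_sg{k + 1}", g))
            sg_gamma.append(gene_gamma[g] if active else 0.0)
    for i in range(config.n_nc_sgrnas):
        lib_rows.append((f"nc_{i:05d}", NC_SENTINEL))
        sg_gamma.append(0.0)
    lib_df = pd.DataFrame(lib_rows, columns=["sgrna_id", "target"]).set_index("sgrna_id")
    library = SgRNALibrary(lib_df)
    sg_gamma = np.asarray(sg_gamma)
    n_sg = len(sg_gamma)

    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n_sg)
    abundance /= abundance.sum()
    end_abund = abundance * 2.0 ** (config.doublings * sg_gamma)
    end_abund /= end_abund.sum()

    cols = {}
    for rep in range(1, config.replicates + 1):
        cols[f"T0_rep{rep}"] = _nb_counts(rng, abundance * config.mean_depth * n_sg, config.nb_dispersion)
        cols[f"TEND_rep{rep}"] = _nb_counts(rng, end_abund * config.mean_depth * n_sg, config.nb_dispersion)
    counts_df = pd.DataFrame(cols, index=lib_df.index)
    meta = pd.DataFrame(
        [("T0" if c.startswith("T0") else "TEND", int(c.rsplit("rep", 1)[1])) for c in counts_df],
        index=counts_df.columns,
        columns=["timepoint", "replicate"],
    )
    counts = CountMatrix(counts=counts_df, samples=meta)

    truth = {
        "genes": pd.DataFrame(
            {"gamma": gene_gamma, "essential": gene_gamma < 0}, index=pd.Index(genes, name="gene")
        ),
        "sgrnas": pd.DataFrame({"gamma": sg_gamma}, index=lib_df.index),
    }
    return library, counts, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Study conditions of a simulated clinical cohort.

    Expression is log-normal per gene (log2 TPM ~ Normal(mu_g, sigma))
    with additive log2 shifts for copy-number gain (``delta``) and
    metastatic status (``met_shift``). Overall survival is simulated for
    metastatic samples: exponential with baseline hazard ln(2)/30 per
    month (30-month median, the mCRPC scale) multiplied by exp(beta) for
    samples in a prognostic gene's top expression quartile, censored
    uniformly over a follow-up window.
    """

    n_primary: int = 60
    n_metastatic: int = 100
    n_benign: int = 0
    n_genes: int = 50
    gene_names: list[str] | None = None
    gain_prob_default: float = 0.05
    gain_prob: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)  # log2 TPM shift on CN gain
    met_shift: dict[str, float] = field(default_factory=dict)  # log2 TPM shift in mets
    beta: dict[str, float] = field(default_factory=dict)  # log hazard for high expression
    sigma: float = 0.5
    mu_mean: float = 3.5
    mu_sd: float = 1.0
    baseline_hazard: float = np.log(2) / 30.0
    censor_max: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_names is not None:
            self.n_genes = len(self.gene_names)
        if not 0 <= self.gain_prob_default <= 1:
            raise ValidationError("gain_prob_default must lie in [0, 1]")


def simulate_cohort(config: CohortSimConfig) -> tuple[ClinicalCohort, dict]:
    """Simulate a clinical cohort; returns (cohort, truth tables)."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names or [f"GENE{i:04d}" for i in range(config.n_genes)]
    samples = (
        [f"B{i:04d}" for i in range(config.n_benign)]
        + [f"P{i:04d}" for i in range(config.n_primary)]
        + [f"M{i:04d}" for i in range(config.n_metastatic)]
    )
    ctype = (
        ["benign"] * config.n_benign
        + ["primary"] * config.n_primary
        + ["metastatic"] * config.n_metastatic
    )
    n_s, n_g = len(samples), len(genes)
    is_met = np.array([c == "metastatic" for c in ctype])

    mu = rng.normal(config.mu_mean, config.mu_sd, size=n_g)
    gain_p = np.array([config.gain_prob.get(g, config.gain_prob_default) for g in genes])
    delta = np.array([config.delta.get(g, 0.0) for g in genes])
    met_shift = np.array([config.met_shift.get(g, 0.0) for g in genes])

    gain = rng.random((n_s, n_g)) < gain_p[None, :]
    log2tpm = (
        mu[None, :]
        + delta[None, :] * gain
        + met_shift[None, :] * is_met[:, None]
        + rng.normal(0.0, config.sigma, size=(n_s, n_g))
    )
    expr = pd.DataFrame(2.0 ** log2tpm, index=pd.Index(samples, name="sample_id"), columns=genes)
    cn = pd.DataFrame(gain.astype(np.int64), index=expr.index, columns=genes)

    clinical = pd.DataFrame({"cohort_type": ctype}, index=expr.index)
    clinical["os_months"] = np.nan
    clinical["os_event"] = np.nan
    if is_met.any():
        hazard = np.full(int(is_met.sum()), config.baseline_hazard)
        met_expr = expr.loc[is_met]
        for g, b in config.beta.items():
            vals = met_expr[g].to_numpy()
            high = vals > np.quantile(vals, 0.75)
            hazard = hazard * np.where(high, np.exp(b), 1.0)
        death = rng.exponential(1.0 / hazard)
        censor = rng.uniform(0.0, config.censor_max, size=hazard.size)
        clinical.loc[is_met, "os_months"] = np.minimum(death, censor)
        clinical.loc[is_met, "os_event"] = (death <= censor).astype(float)

    cohort = ClinicalCohort(expression=expr, cn_state=cn, clinical=clinical)
    truth = {
        "genes": pd.DataFrame(
            {
                "mu_log2tpm": mu,
                "gain_prob": gain_p,
                "delta": delta,
                "met_shift": met_shift,
                "beta": [config.beta.get(g, 0.0) for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# essentiality
# ---------------------------------------------------------------------------

COMMON_ESSENTIAL = "common_essential"
NON_ESSENTIAL = "non_essential"
LINEAGE_ESSENTIAL = "lineage_essential"

_DEFAULT_LINEAGES = ("lung", "breast", "colon", "ovary", "skin", "pancreas", "blood")


@dataclass
class EssentialitySimConfig:
    """Study conditions of simulated essentiality panels.

    Effects follow the anchored scale: common-essential genes draw from
    Normal(-1, 0.15) in every line, lineage-essential genes only in their
    designated lineage, non-essential genes from Normal(0, 0.15). Binary
    calls use effect <= -0.5.
    """

    n_cell_lines: int = 100
    n_prostate: int = 2
    gene_names: list[str] | None = None
    n_genes: int = 50
    #: gene -> "common_essential" | "non_essential" | ("lineage_essential", lineage)
    gene_classes: dict = field(default_factory=dict)
    effect_sd: float = 0.15
    essential_mean: float = -1.0
    call_threshold: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_names is not None:
            self.n_genes = len(self.gene_names)
        if self.n_prostate > self.n_cell_lines:
            raise ValidationError("n_prostate cannot exceed n_cell_lines")


def simulate_essentiality(
    config: EssentialitySimConfig,
) -> tuple[GeneEffectMatrix, EssentialCallMatrix, dict]:
    """Simulate gene-effect and essential-call matrices with lineages."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names or [f"GENE{i:04d}" for i in range(config.n_genes)]
    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    lineages = ["prostate"] * config.n_prostate + [
        _DEFAULT_LINEAGES[i % len(_DEFAULT_LINEAGES)]
        for i in range(config.n_cell_lines - config.n_prostate)
    ]
    lineage = pd.Series(lineages, index=pd.Index(lines, name="cell_line"), name="lineage")

    effects = np.empty((config.n_cell_lines, len(genes)))
    classes = []
    for j, g in enumerate(genes):
        cls = config.gene_classes.get(g, NON_ESSENTIAL)
        if cls == COMMON_ESSENTIAL:
            mean = np.full(config.n_cell_lines, config.essential_mean)
            label = COMMON_ESSENTIAL
        elif cls == NON_ESSENTIAL:
            mean = np.zeros(config.n_cell_lines)
            label = NON_ESSENTIAL
        elif isinstance(cls, tuple) and cls[0] == LINEAGE_ESSENTIAL:
            mean = np.where(lineage.to_numpy() == cls[1], config.essential_mean, 0.0)
            label = f"{LINEAGE_ESSENTIAL}:{cls[1]}"
        else:
            raise ValidationError(f"unknown gene class {cls!r} for gene {g}")
        effects[:, j] = rng.normal(mean, config.effect_sd)
        classes.append(label)

    eff_df = pd.DataFrame(effects, index=lineage.index, columns=genes)
    calls_df = eff_df <= config.call_threshold
    truth = {"genes": pd.DataFrame({"class": classes}, index=pd.Index(genes, name="gene"))}
    return (
        GeneEffectMatrix(effects=eff_df, lineage=lineage),
        EssentialCallMatrix(calls=calls_df, lineage=lineage),
        truth,
    )


# ---------------------------------------------------------------------------
# narrative scenario
# ---------------------------------------------------------------------------

DRIVER = "DRIVER"
COMMON_ESS_AMP = "COMMON_ESS_AMP"
AMP_ONLY = "AMP_ONLY"
NEUTRAL = "NEUTRAL"


@dataclass
class ScenarioBundle:
    """Everything a full pipeline run needs, plus the planted truth."""

    library: SgRNALibrary
    counts: CountMatrix
    cohort: ClinicalCohort
    effects: GeneEffectMatrix
    calls: EssentialCallMatrix
    xscreens: list[set]
    truth: dict
    manifest: dict


def make_narrative_scenario(seed: int = 0, n_background: int = 200) -> ScenarioBundle:
    """Bundle a four-archetype end-to-end scenario with known truth.

    Among ``n_background`` background genes, four designated genes probe
    the filter chain:

    * ``DRIVER`` — screen-essential (gamma -0.4, the strongest effect in
      the screen), essential only in prostate-lineage cell lines,
      recurrently gained with expression responding to the gain,
      metastasis-upregulated, and prognostic (hazard doubles for
      top-quartile expression). The tissue-specific true driver.
    * ``COMMON_ESS_AMP`` — screen-essential and recurrently gained with
      responsive expression, but essential in essentially every cell
      line: the amplified common-essential decoy that clinical filtering
      alone admits and the essentiality stages remove.
    * ``AMP_ONLY`` — gained with responsive expression but no fitness
      effect: never a screen hit.
    * ``NEUTRAL`` — no effects anywhere.

    Background genes include common-essential, externally-reported, and
    prostate-lineage essentials (with milder fitness effects than the
    driver) so every filter stage removes something.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4)]
    bg = [f"BG{i:04d}" for i in range(n_background)]
    genes = [DRIVER, COMMON_ESS_AMP, AMP_ONLY, NEUTRAL] + bg

    rng = np.random.default_rng(seeds[0])
    # background essential classes: common, externally-reported, prostate-lineage
    bg_common = bg[:15]
    bg_xscreen = bg[15:23]
    bg_prostate = bg[23:26]
    bg_essentials = bg_common + bg_xscreen + bg_prostate

    gamma = {g: float(rng.uniform(-0.35, -0.2)) for g in bg_essentials}
    gamma[DRIVER] = -0.4
    gamma[COMMON_ESS_AMP] = -0.45

    screen_cfg = ScreenSimConfig(
        n_genes=len(genes),
        frac_essential=0.0,
        gene_names=genes,
        gamma_overrides=gamma,
        n_nc_sgrnas=500,
        seed=seeds[1],
    )
    library, counts, screen_truth = simulate_screen(screen_cfg)

    cohort_cfg = CohortSimConfig(
        gene_names=genes,
        gain_prob={DRIVER: 0.40, COMMON_ESS_AMP: 0.35, AMP_ONLY: 0.40},
        delta={DRIVER: 1.5, COMMON_ESS_AMP: 1.5, AMP_ONLY: 1.5},
        met_shift={DRIVER: 1.0},
        beta={DRIVER: float(np.log(2))},
        seed=seeds[2],
    )
    cohort, cohort_truth = simulate_cohort(cohort_cfg)

    classes: dict = {g: COMMON_ESSENTIAL for g in bg_common}
    classes[COMMON_ESS_AMP] = COMMON_ESSENTIAL
    classes[DRIVER] = (LINEAGE_ESSENTIAL, "prostate")
    for g in bg_prostate:
        classes[g] = (LINEAGE_ESSENTIAL, "prostate")
    ess_cfg = EssentialitySimConfig(
        gene_names=genes, gene_classes=classes, seed=seeds[3]
    )
    effects, calls, ess_truth = simulate_essentiality(ess_cfg)

    xscreens = [set(bg_xscreen[:5]) | set(bg_common[:3]), set(bg_xscreen[3:]) | set(bg_common[3:6])]

    manifest = {
        "combined_rank_1": DRIVER,
        "clinical_only_contains": [COMMON_ESS_AMP],
        "removed_at_essentiality_stage": [COMMON_ESS_AMP],
        "never_hits": [AMP_ONLY, NEUTRAL],
    }
    truth = {"screen": screen_truth, "cohort": cohort_truth, "essentiality": ess_truth}
    return ScenarioBundle(
        library=library,
        counts=counts,
        cohort=cohort,
        effects=effects,
        calls=calls,
        xscreens=xscreens,
        truth=truth,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# writers: standard TSV inputs + truth/manifest as structured text
# ---------------------------------------------------------------------------


def write_screen_inputs(library: SgRNALibrary, counts: CountMatrix, out_dir) -> dict:
    """Write library.tsv and counts.tsv; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"library": out / "library.tsv", "counts": out / "counts.tsv"}
    library.table[["target"]].to_csv(paths["library"], sep="\t")
    counts.counts.to_csv(paths["counts"], sep="\t")
    return paths


def write_cohort_inputs(cohort: ClinicalCohort, out_dir) -> dict:
    """Write expression.tsv, cn.tsv and clinical.tsv; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "cn": out / "cn.tsv",
        "clinical": out / "clinical.tsv",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    cohort.cn_state.to_csv(paths["cn"], sep="\t")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", float_format="%.6g")
    return paths


def write_essentiality_inputs(
    effects: GeneEffectMatrix, calls: EssentialCallMatrix, out_dir
) -> dict:
    """Write effects.tsv and calls.tsv (cell_line, lineage, genes...)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eff = effects.effects.copy()
    eff.insert(0, "lineage", effects.lineage)
    cal = calls.calls.astype(int).copy()
    cal.insert(0, "lineage", calls.lineage)
    paths = {"effects": out / "effects.tsv", "calls": out / "calls.tsv"}
    eff.to_csv(paths["effects"], sep="\t", float_format="%.6g")
    cal.to_csv(paths["calls"], sep="\t")
    return paths


def write_scenario(bundle: ScenarioBundle, out_dir) -> dict:
    """Write a full scenario bundle as the pipeline's standard TSV inputs.

    Truth tables go to ``truth_*.tsv`` and the expected-outcome manifest
    to ``manifest.json``; pipeline stages read only the input files.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_screen_inputs(bundle.library, bundle.counts, out)
    paths |= write_cohort_inputs(bundle.cohort, out)
    paths |= write_essentiality_inputs(bundle.effects, bundle.calls, out)
    paths["xscreens"] = []
    for i, hits in enumerate(bundle.xscreens, start=1):
        p = out / f"xscreen_{i}.txt"
        p.write_text("\n".join(sorted(hits)) + "\n")
        paths["xscreens"].append(p)
    for name, tables in bundle.truth.items():
        for sub, df in tables.items():
            df.to_csv(out / f"truth_{name}_{sub}.tsv", sep="\t", float_format="%.6g")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2) + "\n")
    paths["manifest"] = out / "manifest.json"
    return paths
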