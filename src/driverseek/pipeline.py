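"""End-to-end pipeline runner with config, logging and provenance.

``run_all`` wires the stages in the fixed order screen scoring ->
clinical filter -> essentiality integration -> survival reports, writes
every output table, and records a run log with all parameters, the seed,
input checksums, and per-stage gene counts so a run can be reproduced
exactly from its log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .clinical import ClinicalFilterParams
from .errors import ConfigError, DriverseekError
from .essentiality import IntegrationParams, run_combined_pipeline
from .io import (
    read_cohort,
    read_counts,
    read_essential_calls,
    read_gene_effects,
    read_hit_list,
    read_library,
    write_results,
)
from .screen import ScreenParams, score_screen
from .survival import survival_report

logger = logging.getLogger("driverseek")

_PATH_KEYS = ("library", "counts", "expression", "cn", "clinical", "effects", "calls")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Input paths must exist at run start; unknown keys in the config file
    are rejected rather than silently ignored.
    """

    library: str
    counts: str
    expression: str
    cn: str
    clinical: str
    effects: str
    calls: str
    xscreens: list[str] = field(default_factory=list)
    out_dir: str = "driverseek_out"
    seed: int = 0
    n_survival_reports: int = 5
    screen: ScreenParams = field(default_factory=ScreenParams)
    clinical_filter: ClinicalFilterParams = field(default_factory=ClinicalFilterParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)

    def validate_paths(self) -> None:
        for key in _PATH_KEYS:
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"input path for {key!r} does not exist: {p}")
        for p in self.xscreens:
            if not Path(p).exists():
                raise ConfigError(f"external hit list does not exist: {p}")


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a run configuration from a TOML file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    sections = {
        "screen": ScreenParams,
        "clinical_filter": ClinicalFilterParams,
        "integration": IntegrationParams,
    }
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = _build_section(cls, data.pop(name, {}), name)
    top_known = {f.name for f in dataclasses.fields(RunConfig)} - set(sections)
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data, **kwargs)
    # the screen seed follows the run seed unless set explicitly
    if "seed" not in data or cfg.screen.seed == 0:
        cfg.screen = dataclasses.replace(cfg.screen, seed=cfg.seed)
    return cfg


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Returns a dict of the in-memory result tables. Any stage error aborts
    with the stage name; outputs of completed stages remain on disk.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"driverseek run (seed {config.seed})"]
    for key in _PATH_KEYS:
        p = getattr(config, key)
        log_lines.append(f"input {key}: {p} sha256:{_checksum(p)}")
    for p in config.xscreens:
        log_lines.append(f"input xscreen: {p} sha256:{_checksum(p)}")
    log_lines.append(f"params screen: {config.screen}")
    log_lines.append(f"params clinical_filter: {config.clinical_filter}")
    log_lines.append(f"params integration: {config.integration}")

    stage = "load inputs"
    try:
        library = read_library(config.library)
        counts = read_counts(config.counts, library)
        cohort = read_cohort(config.expression, config.cn, config.clinical)
        effects = read_gene_effects(config.effects)
        calls = read_essential_calls(config.calls)
        xscreens = [read_hit_list(p) for p in config.xscreens]

        stage = "score-screen"
        results, phen, threshold = score_screen(counts, library, config.screen)
        write_results(results.reset_index(), out_dir / "gene_results.tsv", sort_by=["gene"])
        log_lines.append(f"score-screen: {int(results['hit'].sum())} hits of "
                         f"{len(results)} genes at threshold {threshold:.6g}")

        stage = "integrate"
        res = run_combined_pipeline(
            results, cohort, calls, effects, xscreens,
            params=config.integration, clinical_params=config.clinical_filter,
        )
        if len(res.clinical_ranked):
            write_results(res.clinical_ranked.reset_index(),
                          out_dir / "clinical_ranked.tsv", sort_by=["cn_rank"])
        write_results(res.trace.to_frame(),
                      out_dir / "trace.tsv", sort_by=["gene"])
        if len(res.final_ranked):
            write_results(res.final_ranked.reset_index(),
                          out_dir / "final_ranked.tsv", sort_by=["final_rank"])
        for stage_name, n in res.removals.items():
            log_lines.append(f"integrate: {stage_name} removed {n}")
        log_lines.append(f"integrate: {len(res.final_ranked)} genes in final ranking")

        stage = "survival"
        reports = {}
        top = list(res.final_ranked.index[: config.n_survival_reports])
        for gene in top:
            try:
                rep = survival_report(cohort, gene)
            except DriverseekError as exc:
                log_lines.append(f"survival: {gene} skipped ({exc})")
                continue
            reports[gene] = rep
            tab = rep.km_high.to_frame("survival_high").join(
                rep.km_low.to_frame("survival_low"), how="outer"
            ).reset_index()
            write_results(tab, out_dir / f"survival_{gene}.tsv", sort_by=["time"])
            log_lines.append(
                f"survival {gene}: logrank chisq={rep.logrank_chisq:.4g} "
                f"p={rep.logrank_p:.4g} HR={rep.cox.hr:.4g} "
                f"CI=({rep.cox.ci95[0]:.4g}, {rep.cox.ci95[1]:.4g})"
            )
    except DriverseekError:
        log_lines.append(f"ABORTED at stage: {stage}")
        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("run complete: outputs in %s", out_dir)
    return {
        "gene_results": results,
        "clinical_ranked": res.clinical_ranked,
        "final_ranked": res.final_ranked,
        "trace": res.trace,
        "survival": reports,
        "threshold": threshold,
    }
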