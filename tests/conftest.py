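"""Shared fixtures: small hand-built inputs and session-scoped simulations."""

import numpy as np
import pandas as pd
import pytest

import driverseek as ds
from driverseek.screen import SgRNAPhenotypes


def make_library(gene_sgrnas: dict[str, int], n_nc: int) -> ds.SgRNALibrary:
    """Library with the given sgRNAs per gene plus n_nc negative controls."""
    rows = [(f"{g}_sg{k+1}", g) for g, n in gene_sgrnas.items() for k in range(n)]
    rows += [(f"nc_{i}", "NC") for i in range(n_nc)]
    df = pd.DataFrame(rows, columns=["sgrna_id", "target"]).set_index("sgrna_id")
    return ds.SgRNALibrary(df)


def make_counts(library: ds.SgRNALibrary, columns: dict[str, list[int]]) -> ds.CountMatrix:
    """CountMatrix from explicit per-sample count vectors in library order."""
    counts = pd.DataFrame(columns, index=library.sgrna_ids)
    meta = pd.DataFrame(
        [("T0" if c.startswith("T0") else "TEND", int(c.rsplit("rep", 1)[1])) for c in counts],
        index=counts.columns,
        columns=["timepoint", "replicate"],
    )
    return ds.CountMatrix(counts=counts, samples=meta)


def make_phenotypes(combined: dict[str, float], controls: set[str]) -> SgRNAPhenotypes:
    """SgRNAPhenotypes with given combined gammas (single pseudo-replicate)."""
    idx = pd.Index(list(combined), name="sgrna_id")
    comb = pd.Series(list(combined.values()), index=idx)
    return SgRNAPhenotypes(
        per_replicate=comb.to_frame(1),
        combined=comb,
        pass_filter=pd.Series(True, index=idx),
        is_control=pd.Series([s in controls for s in idx], index=idx),
    )


def make_cohort(
    expr: dict[str, list[float]],
    cn: dict[str, list[int]] | None = None,
    cohort_type: list[str] | None = None,
    os_months: list[float] | None = None,
    os_event: list[int] | None = None,
) -> ds.ClinicalCohort:
    """ClinicalCohort from per-gene value lists (samples S0, S1, ...)."""
    expr_df = pd.DataFrame(expr)
    n = len(expr_df)
    expr_df.index = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    cn_df = (
        pd.DataFrame(cn, index=expr_df.index)
        if cn is not None
        else pd.DataFrame(0, index=expr_df.index, columns=expr_df.columns)
    )
    clin = pd.DataFrame(
        {"cohort_type": cohort_type or ["metastatic"] * n}, index=expr_df.index
    )
    if os_months is not None:
        clin["os_months"] = os_months
        clin["os_event"] = os_event
    return ds.ClinicalCohort(expression=expr_df, cn_state=cn_df, clinical=clin)


@pytest.fixture(scope="session")
def narrative():
    """Seed-0 four-archetype scenario, scored and run through the filters."""
    bundle = ds.make_narrative_scenario(seed=0)
    results, phen, threshold = ds.score_screen(
        bundle.counts, bundle.library, ds.ScreenParams(seed=0)
    )
    res = ds.run_combined_pipeline(
        results, bundle.cohort, bundle.calls, bundle.effects, bundle.xscreens
    )
    return {"bundle": bundle, "results": results, "phen": phen, "pipeline": res}


@pytest.fixture(scope="session")
def sim_screen_scored():
    """A 200-gene, 20%-essential simulated screen scored at defaults."""
    cfg = ds.ScreenSimConfig(n_genes=200, frac_essential=0.2, n_nc_sgrnas=500, seed=11)
    library, counts, truth = ds.simulate_screen(cfg)
    results, phen, threshold = ds.score_screen(counts, library, ds.ScreenParams(seed=11))
    return {"truth": truth, "results": results, "phen": phen, "library": library}


def brute_force_mw_p(x, y) -> float:
    """Independent oracle: exact two-sided Mann-Whitney p by enumeration
    of all C(n+m, n) group assignments of the combined sample."""
    import itertools

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    comb = np.concatenate([x, y])
    n = len(x)
    us = []
    for idx in itertools.combinations(range(len(comb)), n):
        xs = comb[list(idx)]
        ys = np.delete(comb, list(idx))
        us.append(np.sum(xs[:, None] > ys[None, :]))
    us = np.asarray(us)
    u = np.sum(x[:, None] > y[None, :])
    return min(1.0, 2 * min(np.mean(us <= u), np.mean(us >= u)))
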