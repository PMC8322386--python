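"""Screen scoring: phenotype formula, gene statistics, pseudogene FDR."""

import numpy as np
import pandas as pd
import pytest

import driverseek as ds
from driverseek.errors import ScreenError
from driverseek.screen import (
    ScreenParams,
    _score_group,
    build_pseudogenes,
    call_hits,
    compute_sgrna_phenotypes,
    gene_scores,
    replicate_correlation,
)

from conftest import make_counts, make_library, make_phenotypes


class TestPhenotypeFormula:
    def test_unchanged_abundance_gives_zero(self):
        lib = make_library({"G1": 1}, 3)
        cm = make_counts(lib, {"T0_rep1": [100, 50, 50, 50], "T8_rep1": [200, 100, 100, 100]})
        phen = compute_sgrna_phenotypes(cm, lib, ScreenParams(pseudocount=1, min_t0_reads=0))
        assert phen.combined["G1_sg1"] == pytest.approx(0.0, abs=1e-12)

    def test_fourfold_depletion_over_8_doublings(self):
        # target 100 -> 25, controls constant, ps=0: gamma = log2(1/4)/8 = -0.25
        lib = make_library({"G1": 1}, 3)
        cm = make_counts(lib, {"T0_rep1": [100, 1000, 1000, 1000], "T8_rep1": [25, 1000, 1000, 1000]})
        phen = compute_sgrna_phenotypes(cm, lib, ScreenParams(pseudocount=0, min_t0_reads=0))
        assert phen.combined["G1_sg1"] == pytest.approx(-0.25, abs=1e-12)

    def test_dropout_with_pseudocount(self):
        # totals exactly 1e6 so reads-per-million equals raw counts; NC median 0
        # by construction: gamma = log2(1/101)/8
        lib = make_library({"G1": 1}, 3)
        cm = make_counts(
            lib,
            {
                "T0_rep1": [100, 400_000, 400_000, 199_900],
                "T8_rep1": [0, 400_000, 400_000, 200_000],
            },
        )
        phen = compute_sgrna_phenotypes(cm, lib, ScreenParams(pseudocount=1, min_t0_reads=0))
        assert phen.combined["G1_sg1"] == pytest.approx(np.log2(1 / 101) / 8, abs=1e-12)

    def test_nc_median_centered_exactly_zero(self, sim_screen_scored):
        phen = sim_screen_scored["phen"]
        assert np.median(phen.combined[phen.is_control]) == 0.0

    def test_depth_rescaling_is_absorbed(self):
        """Multiplying one sample column by a constant leaves every gamma
        unchanged: the pseudocount acts on the reads-per-million scale."""
        lib = make_library({"G1": 2, "G2": 2}, 5)
        rng = np.random.default_rng(7)
        base = rng.integers(50, 3000, size=9)
        end = rng.integers(50, 3000, size=9)
        p = ScreenParams(min_t0_reads=0)
        cm1 = make_counts(lib, {"T0_rep1": base, "T8_rep1": end})
        cm2 = make_counts(lib, {"T0_rep1": base, "T8_rep1": end * 7})
        g1 = compute_sgrna_phenotypes(cm1, lib, p).combined
        g2 = compute_sgrna_phenotypes(cm2, lib, p).combined
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_no_controls_is_error(self):
        lib = make_library({"G1": 2}, 0)
        cm = make_counts(lib, {"T0_rep1": [1, 2], "T8_rep1": [1, 2]})
        with pytest.raises(Exception, match="negative-control"):
            compute_sgrna_phenotypes(cm, lib, ScreenParams())

    def test_low_t0_reads_fail_filter(self):
        lib = make_library({"G1": 1}, 3)
        cm = make_counts(lib, {"T0_rep1": [10, 100, 100, 100], "T8_rep1": [10, 100, 100, 100]})
        phen = compute_sgrna_phenotypes(cm, lib, ScreenParams(min_t0_reads=25))
        assert not phen.pass_filter["G1_sg1"]
        assert phen.pass_filter["nc_0"]


class TestGeneScores:
    def test_mean_all_mode(self):
        phen = make_phenotypes(
            {f"G1_sg{i}": -1.0 for i in range(1, 6)} | {f"nc_{i}": 0.0 for i in range(5)},
            controls={f"nc_{i}" for i in range(5)},
        )
        lib = make_library({"G1": 5}, 5)
        out = gene_scores(phen, lib, ScreenParams(gene_score_mode="mean_all"))
        assert out.loc["G1", "phenotype"] == pytest.approx(-1.0)

    def test_top_n_abs_mode_picks_most_extreme(self):
        gammas = dict(zip([f"G1_sg{i}" for i in range(1, 6)], [-1.0, -0.8, -0.2, 0.0, 0.1]))
        phen = make_phenotypes(
            gammas | {f"nc_{i}": 0.0 for i in range(5)}, controls={f"nc_{i}" for i in range(5)}
        )
        lib = make_library({"G1": 5}, 5)
        out = gene_scores(phen, lib, ScreenParams(gene_score_mode="top_n_abs", n_top=3))
        assert out.loc["G1", "phenotype"] == pytest.approx((-1.0 - 0.8 - 0.2) / 3)

    def test_mw_p_exact_against_controls(self):
        phen = make_phenotypes(
            {"G1_sg1": 1.0, "G1_sg2": 2.0, "G1_sg3": 3.0, "nc_0": 4.0, "nc_1": 5.0, "nc_2": 6.0},
            controls={"nc_0", "nc_1", "nc_2"},
        )
        lib = make_library({"G1": 3}, 3)
        out = gene_scores(phen, lib, ScreenParams())
        assert out.loc["G1", "mw_p"] == pytest.approx(0.1, abs=1e-12)

    def test_under_two_sgrnas_reported_unscored(self):
        phen = make_phenotypes(
            {"G1_sg1": -1.0, "nc_0": 0.0, "nc_1": 0.1}, controls={"nc_0", "nc_1"}
        )
        lib = make_library({"G1": 1}, 2)
        out = gene_scores(phen, lib, ScreenParams())
        assert not out.loc["G1", "scored"]
        assert np.isnan(out.loc["G1", "phenotype"])


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        lib = make_library({"G1": 2, "G2": 2}, 4)
        col = list(np.arange(100, 900, 100))
        cm = make_counts(lib, {"T0_rep1": col, "T8_rep1": col[::-1],
                               "T0_rep2": col, "T8_rep2": col[::-1]})
        phen = compute_sgrna_phenotypes(cm, lib, ScreenParams(min_t0_reads=0))
        r, n = replicate_correlation(phen)
        assert r == pytest.approx(1.0)
        assert n == 8

    def test_negated_phenotypes_anticorrelate(self):
        idx = pd.Index([f"sg{i}" for i in range(10)])
        g = pd.Series(np.linspace(-1, 1, 10), index=idx)
        phen = ds.screen.SgRNAPhenotypes(
            per_replicate=pd.DataFrame({1: g, 2: -g}),
            combined=g * 0,
            pass_filter=pd.Series(True, index=idx),
            is_control=pd.Series(False, index=idx),
        )
        r, _ = replicate_correlation(phen)
        assert r == pytest.approx(-1.0)

    def test_independent_nulls_near_zero(self):
        rng = np.random.default_rng(9)
        idx = pd.Index([f"sg{i}" for i in range(10_000)])
        phen = ds.screen.SgRNAPhenotypes(
            per_replicate=pd.DataFrame(
                {1: rng.normal(size=10_000), 2: rng.normal(size=10_000)}, index=idx
            ),
            combined=pd.Series(0.0, index=idx),
            pass_filter=pd.Series(True, index=idx),
            is_control=pd.Series(False, index=idx),
        )
        r, _ = replicate_correlation(phen)
        assert abs(r) < 0.2

    def test_single_replicate_is_error(self):
        phen = make_phenotypes({"a": 0.0, "b": 1.0}, controls=set())
        with pytest.raises(ScreenError):
            replicate_correlation(phen)


class TestPseudogenes:
    def test_cardinality_and_distinct_members(self):
        rng = np.random.default_rng(7)
        gammas = {f"nc_{i}": float(g) for i, g in enumerate(rng.normal(0, 0.02, 500))}
        phen = make_phenotypes(gammas, controls=set(gammas))
        out = build_pseudogenes(phen, ScreenParams(n_pseudogenes=100, seed=7))
        assert len(out) == 100

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(8)
        gammas = {f"nc_{i}": float(g) for i, g in enumerate(rng.normal(0, 0.02, 100))}
        phen = make_phenotypes(gammas, controls=set(gammas))
        a = build_pseudogenes(phen, ScreenParams(n_pseudogenes=50, seed=3))
        b = build_pseudogenes(phen, ScreenParams(n_pseudogenes=50, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_null_pseudogene_phenotypes_center_on_zero(self, sim_screen_scored):
        phen = sim_screen_scored["phen"]
        out = build_pseudogenes(phen, ScreenParams(n_pseudogenes=2000, seed=5))
        assert abs(out["phenotype"].mean()) < 0.02

    def test_too_few_controls_is_error(self):
        phen = make_phenotypes({"nc_0": 0.0, "nc_1": 0.1}, controls={"nc_0", "nc_1"})
        with pytest.raises(ScreenError):
            build_pseudogenes(phen, ScreenParams(pseudogene_size=5))


class TestCallHits:
    def _tables(self):
        genes = pd.DataFrame(
            {"phenotype": [-0.5, 0.0], "mw_p": [1e-5, 0.9], "scored": [True, True]},
            index=pd.Index(["HIT", "NULL"], name="gene"),
        )
        rng = np.random.default_rng(0)
        pseudo = pd.DataFrame(
            {"phenotype": rng.normal(0, 0.01, 200), "mw_p": rng.uniform(0.1, 1, 200)},
            index=pd.Index([f"p{i}" for i in range(200)], name="gene"),
        )
        return genes, pseudo

    def test_clear_signal_is_called(self):
        genes, pseudo = self._tables()
        out, thr = call_hits(genes, pseudo, ScreenParams())
        assert bool(out.loc["HIT", "hit"]) is True
        assert bool(out.loc["NULL", "hit"]) is False

    def test_positive_phenotype_never_a_hit(self):
        genes, pseudo = self._tables()
        genes.loc["HIT", "phenotype"] = 0.5  # enriched, not depleted
        out, _ = call_hits(genes, pseudo, ScreenParams())
        assert not out["hit"].any()

    def test_fixed_threshold_bypasses_calibration(self):
        genes, pseudo = self._tables()
        out, thr = call_hits(genes, pseudo, ScreenParams(), fixed_threshold=1e9)
        assert thr == 1e9 and not out["hit"].any()

    @pytest.mark.parametrize("shift", [0.1, 0.5, 1.0])
    def test_more_depletion_never_lowers_product_score(self, shift):
        """For depletion-side genes, uniformly decreasing every sgRNA gamma
        is monotone in the product score."""
        rng = np.random.default_rng(42)
        nc = rng.normal(0, 0.05, 200)
        sigma = 0.05
        for _ in range(20):
            g = -np.abs(rng.normal(0, 0.1, 5))
            scores = []
            for delta in (0.0, shift):
                phenotype, p = _score_group(g - delta, nc, ScreenParams())
                scores.append(abs(phenotype / sigma) * -np.log10(p))
            assert scores[1] >= scores[0] - 1e-12


def test_planted_essentials_recovered(sim_screen_scored):
    """Gene-level estimates track the planted per-doubling fitness effects."""
    truth = sim_screen_scored["truth"]["genes"]
    results = sim_screen_scored["results"]
    ess = truth[truth["essential"]]
    mae = (results.loc[ess.index, "phenotype"] - ess["gamma"]).abs().mean()
    assert mae <= 0.05
    assert results.loc[ess.index, "hit"].mean() >= 0.9
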