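"""Composite dysregulation score: node, edge, influence components and the
permutation empirical p."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from cernet.config import PipelineConfig
from cernet.datatypes import Triplet, TripletScore
from cernet.discovery import build_gene_graph, BackgroundNetwork, largest_component, discover_triplets
from cernet.scoring import (
    LAMBDA, ScoringEngine, _dot_from_w, _dot_kernel, dot_score, edge_score,
    fisher_z, influence_component, score_triplets,
)


class TestDotScore:
    def test_zero_statistic_is_zero(self):
        # p = 1 or fc = 0 gives z = 0; the integral collapses to its
        # normalising constant, so F_Z(0) = 0 exactly
        assert dot_score(1.0, 5.0, 1.0) == pytest.approx(0.0, abs=1e-9)
        assert dot_score(0.5, 0.0, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_limit_is_one(self):
        assert dot_score(1e-300, 10.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_z(self):
        zs = np.linspace(0, 6, 40)
        vals = [1.0 - _dot_kernel(LAMBDA * z) for z in zs]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_matches_monte_carlo_product_distribution(self):
        # oracle: Z = E * |N|, E ~ Exp(rate ln10), N ~ Normal(0, 1)
        rng = np.random.default_rng(99)
        z_draws = rng.exponential(1 / LAMBDA, 10**6) * np.abs(rng.standard_normal(10**6))
        mc = (z_draws <= 3.0).mean()
        assert dot_score(10 ** -3.0, 1.0, 1.0) == pytest.approx(mc, abs=0.01)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dot_score(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            dot_score(1.5, 1.0, 1.0)

    def test_engine_interpolant_agrees_with_quadrature(self):
        w = np.geomspace(1e-6, 300, 200)
        quad = np.array([1.0 - _dot_kernel(x) for x in w])
        np.testing.assert_allclose(_dot_from_w(w), quad, atol=1e-6)


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.9) == pytest.approx(0.5 * np.log(19), rel=1e-12)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.3])
    def test_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


class TestEdgeScore:
    @pytest.mark.parametrize("r", [-0.9, -0.3, 0.0, 0.5, 0.99])
    def test_equal_correlations_give_half(self, r):
        assert edge_score(r, r, 8, 12) == pytest.approx(0.5, abs=1e-12)

    def test_reference_value_against_normal_cdf(self):
        # r_control = -0.8 -> 0 with n = 8 each: Phi(atanh(0.8) / sqrt(0.4))
        expected = ndtr(np.arctanh(0.8) / np.sqrt(0.4))
        assert edge_score(0.0, -0.8, 8, 8) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_case_correlation(self):
        vals = [edge_score(rc, -0.7, 10, 10) for rc in np.linspace(-0.95, 0.95, 30)]
        assert np.all(np.diff(vals) > 0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            edge_score(0.1, -0.5, 3, 8)


class TestInfluenceComponent:
    def test_worked_arithmetic(self):
        # universe 20, 4 neighbours (3 SDE), 5 SDE total:
        # p = [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4)
        universe = {f"g{i}" for i in range(20)}
        sde = {f"g{i}" for i in range(5)}
        neighbors = {"g0", "g1", "g2", "g10"}
        p = (comb(5, 3) * comb(15, 1) + comb(5, 4)) / comb(20, 4)
        assert influence_component(neighbors, sde, universe) == pytest.approx(1 - p, rel=1e-10)

    def test_no_sde_genes_gives_zero(self):
        universe = {f"g{i}" for i in range(10)}
        assert influence_component({"g0", "g1"}, set(), universe) == 0.0

    def test_empty_neighbourhood_gives_zero(self):
        assert influence_component(set(), {"g0"}, {"g0", "g1"}) == 0.0

    def test_perfect_enrichment_is_maximal(self):
        universe = {f"g{i}" for i in range(12)}
        sde = {f"g{i}" for i in range(4)}
        best = influence_component(sde, sde, universe)
        for other in ({"g0", "g1", "g4", "g5"}, {"g4", "g5", "g6", "g7"}):
            assert best >= influence_component(other, sde, universe)
        assert best == pytest.approx(1 - 1 / comb(12, 4), rel=1e-10)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(2, 21))
            genes = [f"g{i}" for i in range(N)]
            sde = set(rng.choice(genes, rng.integers(0, N + 1), replace=False))
            nbr = set(rng.choice(genes, rng.integers(1, N + 1), replace=False))
            k, K, n = len(nbr & sde), len(sde), len(nbr)
            p = sum(comb(K, i) * comb(N - K, n - i)
                    for i in range(k, min(K, n) + 1)) / comb(N, n)
            assert influence_component(nbr, sde, set(genes)) == pytest.approx(1 - p, rel=1e-9)


class TestCompositeScore:
    def test_triplet_score_additivity_enforced(self):
        t = Triplet("l", "m", "y")
        with pytest.raises(ValueError, match="sum of its components"):
            TripletScore(t, (0.1, 0.1, 0.1), (0.5, 0.5, 0.5), 1.0, 99.0)

    def test_score_components_sum_to_s(self, worked, worked_cfg):
        ds, inter, _ = worked
        net = largest_component(discover_triplets(ds, inter, worked_cfg))
        for ts in score_triplets(net.triplets, ds, "caseA", "control", net, worked_cfg):
            expected = sum(ts.dot_scores) + sum(ts.edge_scores) + ts.influence_score
            assert ts.S == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self, worked, worked_cfg):
        ds, inter, _ = worked
        net = largest_component(discover_triplets(ds, inter, worked_cfg))
        eng = ScoringEngine(net.triplets, ds, "caseA", "control", net, worked_cfg)
        S = eng.evaluate()["S"]
        p1 = eng.permutation_pvalues(S, 200, seed=4)
        p2 = eng.permutation_pvalues(S, 200, seed=4)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_expression_names_gene(self, worked, worked_cfg):
        ds, inter, _ = worked
        net = largest_component(discover_triplets(ds, inter, worked_cfg))
        ghost = [Triplet("lnc-1", "mir-p", "NOPE")]
        with pytest.raises(KeyError, match="NOPE"):
            ScoringEngine(ghost, ds, "caseA", "control", net, worked_cfg)


class TestPermutationP:
    def test_empirical_p_arithmetic(self):
        # Eq: emp_p = #(S_random > S) / n_perm, strict inequality
        exceed = np.array([0, 250])
        assert (exceed / 10_000)[1] == 0.025

    def test_planted_triplet_beats_all_permutations(self, worked, worked_cfg):
        ds, inter, _ = worked
        net = largest_component(discover_triplets(ds, inter, worked_cfg))
        eng = ScoringEngine(net.triplets, ds, "caseB", "control", net, worked_cfg)
        S = eng.evaluate()["S"]
        p = eng.permutation_pvalues(S, 200, seed=0)
        assert p.min() == 0.0  # fully broken triplets exceed every null draw

    def test_minimum_permutations_enforced(self, worked, worked_cfg):
        ds, inter, _ = worked
        net = largest_component(discover_triplets(ds, inter, worked_cfg))
        eng = ScoringEngine(net.triplets, ds, "caseA", "control", net, worked_cfg)
        with pytest.raises(ValueError, match="n_perm"):
            eng.permutation_pvalues(np.zeros(len(net.triplets)), 50, seed=0)

    def test_per_rna_shuffle_mode_runs(self, worked):
        ds, inter, _ = worked
        cfg = PipelineConfig(hyper_p=0.05, n_perm=100, shuffle_mode="per_rna")
        net = largest_component(discover_triplets(ds, inter, cfg))
        eng = ScoringEngine(net.triplets, ds, "caseA", "control", net, cfg)
        S = eng.evaluate()["S"]
        p = eng.permutation_pvalues(S, 100, seed=1)
        assert ((0 <= p) & (p <= 1)).all()
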