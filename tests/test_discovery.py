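"""ceRNA triplet discovery: shared-miRNA test, PCC filters, largest component."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from cernet.config import PipelineConfig
from cernet.datatypes import ExpressionDataset, InteractionSet, Triplet
from cernet.discovery import (
    discover_triplets, largest_component, pearson_with_p, shared_mirna_test,
)


def hypergeom_upper_tail(N: int, K: int, n: int, k_obs: int) -> float:
    """Independent oracle: P(X >= k_obs) by direct enumeration."""
    total = comb(N, n)
    return sum(comb(K, k) * comb(N - K, n - k)
               for k in range(k_obs, min(K, n) + 1)) / total


class TestSharedMirnaTest:
    def test_worked_arithmetic(self):
        # universe 10; sets of 5 and 4 overlapping in 4: C(5,4)*C(5,0)/C(10,4)
        universe = {f"m{i}" for i in range(10)}
        a = {f"m{i}" for i in range(5)}
        b = {f"m{i}" for i in range(4)}
        assert shared_mirna_test(a, b, universe) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = {f"m{i}" for i in range(10)}
        assert shared_mirna_test({"m0"}, {"m5"}, universe) == pytest.approx(1.0)

    def test_full_sets_degenerate(self):
        universe = {f"m{i}" for i in range(6)}
        assert shared_mirna_test(universe, universe, universe) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            shared_mirna_test({"m0"}, {"m0"}, set())

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            N = int(rng.integers(2, 16))
            universe = {f"m{i}" for i in range(N)}
            a = set(rng.choice(sorted(universe), rng.integers(1, N + 1), replace=False))
            b = set(rng.choice(sorted(universe), rng.integers(1, N + 1), replace=False))
            expected = hypergeom_upper_tail(N, len(a), len(b), len(a & b))
            assert shared_mirna_test(a, b, universe) == pytest.approx(expected, rel=1e-10)


def test_pearson_p_requires_four_points():
    with pytest.raises(ValueError):
        pearson_with_p(np.arange(3.0), np.arange(3.0))


class TestDiscovery:
    def test_worked_example_finds_exactly_planted(self, worked, worked_cfg):
        ds, inter, truth = worked
        found = {t.key for t in discover_triplets(ds, inter, worked_cfg)}
        assert found == {tuple(t) for t in truth.planted}

    def test_all_threshold_predicates_hold(self, small_sim):
        ds, inter, _ = small_sim
        cfg = PipelineConfig()
        for t in discover_triplets(ds, inter, cfg):
            assert t.shared_mirna_p < cfg.hyper_p
            assert t.pcc_lm > cfg.pcc_pos and t.pcc_ps[0] < cfg.pcc_p
            assert t.pcc_mm < cfg.pcc_neg and t.pcc_ps[1] < cfg.pcc_p
            assert t.pcc_ml < cfg.pcc_neg and t.pcc_ps[2] < cfg.pcc_p

    def test_uncurated_pair_never_emitted(self, worked, worked_cfg):
        ds, inter, truth = worked
        pruned = InteractionSet(
            {e for e in inter.mirna_mrna if e != ("mir-p", "mrna-1")},
            inter.mirna_lncrna)
        found = {t.key for t in discover_triplets(ds, pruned, worked_cfg)}
        assert ("lnc-1", "mir-p", "mrna-1") not in found

    def test_invariant_to_row_and_joint_column_order(self, worked, worked_cfg):
        ds, inter, _ = worked
        rng = np.random.default_rng(0)
        cols = list(rng.permutation(ds.samples))
        shuffled = ExpressionDataset(
            ds.mrna.sample(frac=1, random_state=1)[cols],
            ds.mirna.sample(frac=1, random_state=2)[cols],
            ds.lncrna.sample(frac=1, random_state=3)[cols],
            ds.sample_groups.loc[cols])
        a = [(t.key, round(t.pcc_lm, 12)) for t in discover_triplets(ds, inter, worked_cfg)]
        b = [(t.key, round(t.pcc_lm, 12)) for t in discover_triplets(shuffled, inter, worked_cfg)]
        assert a == b

    def test_too_few_controls_rejected(self, worked, worked_cfg):
        ds, inter, _ = worked
        sub = ds.subset_samples(ds.samples_of("control")[:3] + ds.samples_of("caseA"))
        with pytest.raises(ValueError, match="control"):
            discover_triplets(sub, inter, worked_cfg)


def _triplet_cluster(tag: str, n: int) -> list[Triplet]:
    """n triplets chained through one shared miRNA -> one component."""
    return [Triplet(f"{tag}L{i}", f"{tag}M", f"{tag}Y{i}") for i in range(n)]


class TestLargestComponent:
    def test_larger_cluster_wins(self):
        trips = _triplet_cluster("a", 5) + _triplet_cluster("b", 2)
        net = largest_component(trips)
        assert {t.lncrna[0] for t in net.triplets} == {"a"}
        assert len(net.triplets) == 5

    def test_single_triplet_identity(self):
        t = Triplet("l", "m", "y")
        net = largest_component([t])
        assert net.triplets == [t] and net.genes() == {"l", "m", "y"}

    def test_chain_through_shared_mirna_all_retained(self):
        trips = _triplet_cluster("c", 8)
        # union-find oracle over the triplets' pairwise edges
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            parent[find(a)] = find(b)

        for t in trips:
            union(t.lncrna, t.mirna)
            union(t.mirna, t.mrna)
        roots = {find(g) for t in trips for g in t.genes}
        assert len(roots) == 1
        assert len(largest_component(trips).triplets) == 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            largest_component([])
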