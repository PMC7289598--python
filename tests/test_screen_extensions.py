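import math
from math import comb

import numpy as np
import pytest

from robustgi.core_data import DataError, GeneSet
from robustgi.ppi_enrichment import build_network
from robustgi.screen_extensions import (
    ChemogeneticScreenSet,
    PathwayGeneSets,
    ViabilityMeasurement,
    chemogenetic_group_analysis,
    normalize_viability,
    passenger_candidate_pairs,
    pathway_ora,
    random_pair_null,
)
from conftest import make_alterations


def network_of(edges):
    return build_network([(a, b, 0.9) for a, b in edges])


class TestChemogenetic:
    def make_screens(self):
        universe = GeneSet("u", frozenset(f"g{i}" for i in range(12)))
        # 4 PPI partners of the target, concentrated among reproducible hits
        hits = {
            "line1": frozenset({"g1", "g2", "g3", "g4", "g5"}),
            "line2": frozenset({"g1", "g2", "g3", "g6"}),
            "line3": frozenset({"g1", "g2", "g7"}),
        }
        return ChemogeneticScreenSet("ATR", hits, universe)

    def test_group_assignment(self):
        screens = self.make_screens()
        counts = screens.hit_counts()
        assert counts["g1"] == 3  # hit in all three screens
        assert counts["g8"] == 0  # never a hit

    def test_groups_partition_universe(self):
        screens = self.make_screens()
        net = network_of([("ATR", "g1")])
        out = chemogenetic_group_analysis(screens, net)
        assert sum(out["group_sizes"].values()) == len(screens.universe)

    def test_monotone_fractions_and_oracle_p(self):
        screens = self.make_screens()
        net = network_of([("ATR", g) for g in ["g1", "g2", "g3", "g4"]])
        out = chemogenetic_group_analysis(screens, net)
        f = out["fractions"]
        assert f[0] <= f[1] <= f[2] <= f[3]
        comp = {c.groups: c for c in out["comparisons"]}
        c30 = comp[(3, 0)]
        # group 3 = {g1,g2}, both partners; group 0 = 5 genes, none partners
        assert c30.table == ((2, 0), (0, 5))
        # enumeration oracle: margins (2,5)/(2,5)
        denom = comb(7, 2)
        obs = comb(2, 2) * comb(5, 0)
        p_oracle = sum(
            comb(2, a) * comb(5, 2 - a) for a in range(3)
            if comb(2, a) * comb(5, 2 - a) <= obs
        ) / denom
        assert c30.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_target_absent_from_network_errors(self):
        screens = self.make_screens()
        with pytest.raises(DataError, match="ATR"):
            chemogenetic_group_analysis(screens, network_of([("a", "b")]))


class TestPassengerPairs:
    def alt_with_losses(self, losses):
        lines = [f"c{i}" for i in range(15)]
        return make_alterations(
            {g: [i < k for i in range(15)] for g, k in losses.items()}, lines
        )

    def test_below_min_lost_contributes_nothing(self):
        alt = self.alt_with_losses({"p1": 9})
        net = network_of([("p1", "t1")])
        assert passenger_candidate_pairs(alt, net, GeneSet("t", frozenset({"t1"}))) == []

    def test_adjacency_and_target_filter(self):
        alt = self.alt_with_losses({"p1": 12})
        net = network_of([("p1", "t1"), ("p1", "t2"), ("p1", "x")])
        pairs = passenger_candidate_pairs(
            alt, net, GeneSet("t", frozenset({"t1", "t2"})), min_lost=10
        )
        assert sorted(pairs) == [("p1", "t1"), ("p1", "t2")]

    def test_empty_network(self):
        alt = self.alt_with_losses({"p1": 12})
        assert passenger_candidate_pairs(alt, network_of([]),
                                         GeneSet("t", frozenset({"t1"}))) == []

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(9)
        passengers = [f"p{i}" for i in range(6)]
        targets = [f"t{i}" for i in range(6)]
        lines = [f"c{i}" for i in range(20)]
        alt = make_alterations(
            {p: list(rng.random(20) < 0.5) for p in passengers}, lines
        )
        edges = [(p, t) for p in passengers for t in targets if rng.random() < 0.4]
        net = network_of(edges) if edges else network_of([])
        tset = GeneSet("t", frozenset(targets[:4]))
        got = set(passenger_candidate_pairs(alt, net, tset, min_lost=8))
        expected = {
            (p, t)
            for p in passengers
            for t in targets
            if alt.calls[p].sum() >= 8 and net.has_edge(p, t) and t in tset
        }
        assert got == expected


class TestRandomPairNull:
    def test_single_rep_summary(self):
        out = random_pair_null([("a", "b"), ("c", "d")], 1, lambda pairs: 7,
                               n_reps=1, seed=0)
        assert out.median == out.mean == 7

    def test_reproducible_and_exchangeable(self):
        universe = [(f"p{i}", f"t{j}") for i in range(10) for j in range(10)]
        fn = lambda pairs: sum(a == "p1" for a, _ in pairs)
        a = random_pair_null(universe, 20, fn, n_reps=30, seed=4)
        b = random_pair_null(universe, 20, fn, n_reps=30, seed=4)
        assert a.counts == b.counts
        # no drift with replicate index: first vs second half means comparable
        first, second = np.mean(a.counts[:15]), np.mean(a.counts[15:])
        assert abs(first - second) < 2.0

    def test_oversampling_errors(self):
        with pytest.raises(ValueError):
            random_pair_null([("a", "b")], 2, lambda p: 0, n_reps=1)

    def test_global_null_counts_zero(self):
        out = random_pair_null([("a", "b")] * 0 + [("x", "y"), ("u", "v")], 1,
                               lambda pairs: 0, n_reps=5, seed=1)
        assert out.median == 0


class TestPathwayORA:
    def test_saturated_query_not_enriched(self):
        bg = GeneSet("bg", frozenset(f"g{i}" for i in range(20)))
        sets = PathwayGeneSets({"S": GeneSet("S", frozenset(list(bg)[:5]))}, bg)
        out = pathway_ora(bg, sets)
        assert out[0].p_value == pytest.approx(1.0)

    def test_hypergeometric_worked_example(self):
        bg = GeneSet("bg", frozenset(f"g{i}" for i in range(20)))
        members = frozenset({"g0", "g1", "g2", "g3", "g4"})
        query = GeneSet("q", frozenset({"g0", "g1", "g2", "g3", "g10"}))
        sets = PathwayGeneSets({"S": GeneSet("S", members)}, bg)
        (res,) = pathway_ora(query, sets)
        assert res.overlap == 4
        assert res.p_value == pytest.approx(76 / 15504, abs=1e-12)

    def test_disjoint_query(self):
        bg = GeneSet("bg", frozenset(f"g{i}" for i in range(10)))
        sets = PathwayGeneSets({"S": GeneSet("S", frozenset({"g0", "g1"}))}, bg)
        out = pathway_ora(GeneSet("q", frozenset({"g5", "g6"})), sets)
        assert out[0].overlap == 0
        assert out[0].p_value > 0.5

    def test_query_outside_background_errors(self):
        bg = GeneSet("bg", frozenset({"g1"}))
        sets = PathwayGeneSets({"S": GeneSet("S", frozenset({"g1"}))}, bg)
        with pytest.raises(DataError):
            pathway_ora(GeneSet("q", frozenset({"zz"})), sets)

    def test_matches_tail_sum_oracle_on_random_cases(self):
        rng = np.random.default_rng(17)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            bg = GeneSet("bg", frozenset(universe))
            set_members = frozenset(rng.choice(universe, size=8, replace=False))
            query = frozenset(rng.choice(universe, size=10, replace=False))
            sets = PathwayGeneSets({"S": GeneSet("S", set_members)}, bg)
            (res,) = pathway_ora(GeneSet("q", query), sets)
            M, K, N = 30, len(set_members), len(query)
            k = len(query & set_members)
            oracle = sum(
                comb(K, x) * comb(M - K, N - x) for x in range(k, min(K, N) + 1)
            ) / comb(M, N)
            assert res.p_value == pytest.approx(oracle, abs=1e-10)


class TestNormalizeViability:
    def measurements(self, extra=()):
        base = [
            ViabilityMeasurement("L1", "siCTRL", 100.0, r) for r in range(3)
        ] + [
            ViabilityMeasurement("L1", "siPLK1", 20.0, r) for r in range(3)
        ]
        return base + list(extra)

    def test_control_anchors(self):
        out = normalize_viability(self.measurements(
            [ViabilityMeasurement("L1", "GENEX", 100.0, 0),
             ViabilityMeasurement("L1", "GENEY", 20.0, 0)]
        ))
        assert out["L1"]["siCTRL"]["mean"] == pytest.approx(1.0)
        assert out["L1"]["siPLK1"]["mean"] == pytest.approx(0.0)
        assert out["L1"]["GENEX"]["mean"] == pytest.approx(1.0)
        assert out["L1"]["GENEY"]["mean"] == pytest.approx(0.0)

    def test_worked_case(self):
        out = normalize_viability(self.measurements(
            [ViabilityMeasurement("L1", "GENEX", 60.0, 0)]
        ))
        assert out["L1"]["GENEX"]["mean"] == pytest.approx(0.5)

    def test_affine_rescaling_invariance(self):
        ms = self.measurements([ViabilityMeasurement("L1", "GENEX", 55.0, 0)])
        scaled = [
            ViabilityMeasurement(m.cell_line_id, m.sirna_target,
                                 m.raw_viability * 3.7, m.replicate)
            for m in ms
        ]
        a = normalize_viability(ms)["L1"]["GENEX"]["mean"]
        b = normalize_viability(scaled)["L1"]["GENEX"]["mean"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_equal_controls_error_names_line(self):
        ms = [ViabilityMeasurement("L9", "siCTRL", 50.0, 0),
              ViabilityMeasurement("L9", "siPLK1", 50.0, 0)]
        with pytest.raises(DataError, match="L9"):
            normalize_viability(ms)
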