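"""Edge taxonomy, the four measures, conservation identity, node distances."""

import numpy as np
import pytest

from interreg import (
    EdgeValues,
    Node,
    NodeTable,
    RunConfig,
    classify_edges,
    intra_region_node_distance,
    network_summary,
    node_edge_matrix,
    r1,
    r12,
    r2,
    region_profile,
    ri,
)
from interreg.connectivity_measures import intra_edges, r2_by_subtraction
from interreg.io_model import pair_key

from conftest import constant_series_table, make_spec, random_node_table


class TestClassifyEdges:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_cardinalities_and_partition(self, n):
        spec = make_spec(n)
        for (a, b), cls in classify_edges(spec).items():
            assert len(cls.primary) == 1
            assert len(cls.primary_secondary) == 2 * (n - 2)
            assert len(cls.secondary) == (n - 2) ** 2
            # the three sets partition all (N-1)^2 inter-region node pairs
            all_edges = set(cls.all_inter())
            assert len(all_edges) == (n - 1) ** 2
            brute = {
                tuple(sorted([(a, x), (b, y)]))
                for x in spec.regions if x != a
                for y in spec.regions if y != b
            }
            assert all_edges == brute

    @pytest.mark.parametrize("n", range(3, 9))
    def test_intra_edge_count(self, n):
        spec = make_spec(n)
        for region in spec.regions:
            assert len(intra_edges(spec, region)) == (n - 1) * (n - 2) // 2

    def test_primary_edge_unlabelled_in_other_contexts(self):
        spec = make_spec(4)
        a, b, c = spec.regions[:3]
        primary_ab = classify_edges(spec)[pair_key(a, b)].primary[0]
        cls_ac = classify_edges(spec)[pair_key(a, c)]
        assert primary_ab not in set(cls_ac.all_inter())

    def test_labels_are_subject_independent(self):
        # classification is a pure function of the network spec
        spec = make_spec(5)
        assert classify_edges(spec) == classify_edges(make_spec(5))

    def test_edge_records_carry_context_labels(self, rng):
        from interreg.connectivity_measures import edge_records

        spec = make_spec(3)
        table = random_node_table(spec, rng)
        recs = edge_records(table, spec)
        assert len(recs) == 15  # C(6, 2) unordered node pairs
        a, b, c = spec.regions
        prim = next(r for r in recs if {r.node1, r.node2} == {(a, b), (b, a)})
        assert prim.labels[pair_key(a, b)] == "R1"
        assert prim.labels[pair_key(a, c)] == "none"
        intra = next(r for r in recs if {r.node1, r.node2} == {(a, b), (a, c)})
        assert intra.labels[a] == "RI"


class TestNodeEdgeMatrix:
    def test_matches_double_loop_oracle(self, rng):
        table = random_node_table(make_spec(6), rng)
        labels, M = node_edge_matrix(table)
        assert len(labels) == 30
        S = [n.series for n in table.nodes]
        for i in range(len(S)):
            for j in range(len(S)):
                expected = 1.0 if i == j else np.corrcoef(S[i], S[j])[0, 1]
                assert M[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_and_sign_flipped_series(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        table.nodes[1].series = table.nodes[0].series.copy()
        table.nodes[2].series = -table.nodes[0].series
        _, M = node_edge_matrix(table)
        assert M[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert M[0, 2] == pytest.approx(-1.0, abs=1e-12)


class TestMeasures:
    def test_r1_is_the_primary_edge_and_symmetric(self, rng):
        spec = make_spec(4)
        table = random_node_table(spec, rng, T=200)
        ev = EdgeValues(table)
        a, b = spec.regions[0], spec.regions[1]
        direct = np.corrcoef(table.node(a, b).series, table.node(b, a).series)[0, 1]
        assert r1(ev, a, b) == pytest.approx(direct, abs=1e-12)
        assert r1(ev, a, b) == r1(ev, b, a)
        assert abs(r1(ev, a, b)) < 0.5  # independent white noise at T=200

    def test_r12_n3_equals_hand_enumeration(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        a, b, c = spec.regions
        hand = (ev.value((a, b), (b, c)) + ev.value((a, c), (b, a))) / 2
        assert r12(ev, spec, a, b) == pytest.approx(hand, abs=1e-12)

    def test_r12_n6_equals_eight_edge_mean(self, rng):
        spec = make_spec(6)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        a, b = spec.regions[0], spec.regions[1]
        others = spec.regions[2:]
        edges = [ev.value((a, b), (b, i)) for i in others] + [
            ev.value((a, j), (b, a)) for j in others
        ]
        assert len(edges) == 8
        assert r12(ev, spec, a, b) == pytest.approx(np.mean(edges), abs=1e-12)

    def test_r2_n3_is_the_single_secondary_edge(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        a, b, c = spec.regions
        assert r2(ev, spec, a, b) == pytest.approx(ev.value((a, c), (b, c)), abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 6])
    def test_r2_subtraction_form_agrees(self, rng, n):
        spec = make_spec(n)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        for a, b in spec.unordered_pairs():
            assert r2(ev, spec, a, b) == pytest.approx(
                r2_by_subtraction(ev, spec, a, b), abs=1e-12
            )

    @pytest.mark.parametrize("n", range(3, 9))
    def test_conservation_identity(self, rng, n):
        """Sum of all (N-1)^2 inter-region edges = R1 + 2(N-2) R12 + (N-2)^2 R2."""
        spec = make_spec(n)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        cls = classify_edges(spec)
        for a, b in spec.unordered_pairs():
            total = ev.sum_over(cls[pair_key(a, b)].all_inter())
            recon = (
                r1(ev, a, b)
                + 2 * (n - 2) * r12(ev, spec, a, b)
                + (n - 2) ** 2 * r2(ev, spec, a, b)
            )
            assert total == pytest.approx(recon, abs=1e-10)

    def test_ri_raw_sum_is_count_times_mean(self, rng):
        spec = make_spec(6)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        a = spec.regions[0]
        assert len(intra_edges(spec, a)) == 10
        assert ri(ev, spec, a, "raw_sum") == pytest.approx(
            10 * ri(ev, spec, a, "mean"), abs=1e-10
        )

    def test_duplicate_voxel_contributes_unit_edge_to_ri(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        a, b, c = spec.regions
        dup = table.node(a, b).series.copy()
        table.node(a, c).series = dup  # same voxel selected for both targets
        ev = EdgeValues(table)
        assert ev.value((a, b), (a, c)) == pytest.approx(1.0, abs=1e-12)
        assert ri(ev, spec, a) == pytest.approx(1.0, abs=1e-12)  # only intra pair

    def test_degenerate_maximum_all_measures_one(self):
        spec = make_spec(4)
        table = constant_series_table(spec)
        ms = network_summary(table, spec)
        for d in (ms.r1, ms.r12, ms.r2, ms.ri):
            for v in d.values():
                assert v == pytest.approx(1.0, abs=1e-12)
        assert all(v == pytest.approx(1.0) for v in ms.network_means().values())

    def test_measures_bounded_and_symmetric(self, rng):
        spec = make_spec(5)
        ms = network_summary(random_node_table(spec, rng), spec)
        for d in (ms.r1, ms.r12, ms.r2, ms.ri):
            for v in d.values():
                assert -1.0 <= v <= 1.0
        # keys are canonical unordered pairs: symmetry by construction
        assert set(ms.r1) == {pair_key(a, b) for a, b in spec.unordered_pairs()}


class TestRegionProfileAndSummary:
    def test_summary_matches_hand_calculation_n3(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        ev = EdgeValues(table)
        ms = network_summary(table, spec)
        a, b, _ = spec.regions
        assert ms.r1[pair_key(a, b)] == pytest.approx(r1(ev, a, b), abs=1e-12)
        assert ms.r1_network == pytest.approx(
            np.mean([r1(ev, x, y) for x, y in spec.unordered_pairs()]), abs=1e-12
        )

    def test_profile_is_mean_of_containing_pairs(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        ms = network_summary(table, spec)
        a, b, c = spec.regions
        prof = region_profile(a, ms, spec)
        assert prof["R1"] == pytest.approx(
            (ms.r1[pair_key(a, b)] + ms.r1[pair_key(a, c)]) / 2, abs=1e-12
        )
        assert prof["RI"] == ms.ri[a]

    def test_profile_all_ones_for_degenerate_table(self):
        spec = make_spec(4)
        ms = network_summary(constant_series_table(spec), spec)
        for region in spec.regions:
            assert all(
                v == pytest.approx(1.0, abs=1e-12)
                for v in region_profile(region, ms, spec).values()
            )

    def test_incomplete_table_rejected(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        table.nodes.pop()
        with pytest.raises(ValueError, match="incomplete"):
            network_summary(table, spec)


class TestNodeDistance:
    def test_coincident_nodes_distance_zero(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        for n in table.nodes:
            if n.source_region == "r0":
                n.voxel = (4, 4, 4)
        assert intra_region_node_distance("r0", table) == 0.0

    def test_three_four_five_triangle(self, rng):
        spec = make_spec(3)
        table = random_node_table(spec, rng)
        nodes_r0 = [n for n in table.nodes if n.source_region == "r0"]
        nodes_r0[0].voxel = (0, 0, 0)
        nodes_r0[1].voxel = (3, 4, 0)
        assert intra_region_node_distance("r0", table) == pytest.approx(5.0)

    def test_matches_pairwise_oracle(self, rng):
        spec = make_spec(6)
        table = random_node_table(spec, rng)
        coords = [n.voxel for n in table.nodes if n.source_region == "r0"]
        dists = [
            np.sqrt(sum((p - q) ** 2 for p, q in zip(c1, c2)))
            for i, c1 in enumerate(coords)
            for c2 in coords[i + 1:]
        ]
        assert len(dists) == 10
        assert intra_region_node_distance("r0", table) == pytest.approx(np.mean(dists))
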