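"""Network construction, density, polyploid rescaling, comparison and rates."""

import numpy as np
import pytest

from pinevol.assay import InteractionCall
from pinevol.network import (
    PIN,
    OrthologMap,
    build_network,
    compare_networks,
    degree_and_hub_profile,
    density,
    edge_key,
    gain_loss_rates,
    rescale_by_polyploidy,
    subfunctionalization_check,
    swap_protein,
)


def call(a, b, status="positive", mode="dimeric", delta=5.0):
    return InteractionCall(
        pair=edge_key(a, b), mode=mode, mediator=None,
        mean_signal=6.0, delta=delta, status=status,
        p_value=None if status == "autoactive_excluded" else 0.01,
    )


def pin_of(nodes, edges, label="net", t=0.0):
    return PIN.from_edges(label, t, nodes, edges)


class TestBuildNetwork:
    def test_all_negative_gives_edgeless_network(self):
        calls = [call("A", "B", "negative"), call("B", "C", "negative")]
        pin, excluded = build_network(calls, "e", 0.0)
        assert pin.nodes == {"A", "B", "C"}
        assert pin.edges == frozenset()
        assert excluded == []

    def test_positive_self_pair_is_loop(self):
        pin, _ = build_network([call("A", "A")], "e", 0.0)
        assert pin.edges == {("A", "A")}

    def test_mode_filter_selects_mediated_only(self):
        calls = [
            call("A", "B", mode="dimeric"),
            call("B", "C", mode="mediated"),
            call("C", "D", mode="mediated"),
            call("A", "D", "negative", mode="mediated"),
        ]
        pin, _ = build_network(calls, "e", 0.0, mode_filter="mediated")
        assert pin.edges == {("B", "C"), ("C", "D")}

    def test_autoactive_pairs_excluded_and_reported(self):
        calls = [call("A", "B", "autoactive_excluded"), call("B", "C")]
        pin, excluded = build_network(calls, "e", 0.0)
        assert pin.edges == {("B", "C")}
        assert len(excluded) == 1 and excluded[0].pair == ("A", "B")


class TestDensity:
    def test_complete_with_loops_is_one(self):
        nodes = ["a", "b", "c"]
        edges = [(x, y) for i, x in enumerate(nodes) for y in nodes[i:]]
        assert density(pin_of(nodes, edges)) == 1.0

    def test_edgeless_is_zero(self):
        assert density(pin_of(["a", "b"], [])) == 0.0

    def test_direct_count(self):
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("d", "d")]
        assert density(pin_of("abcd", edges)) == pytest.approx(5 / 10)

    def test_conventions_disagree_on_loops(self):
        p = pin_of("ab", [("a", "a"), ("a", "b")])
        assert density(p, "pairs") == pytest.approx(2 / 3)
        assert density(p, "pairs_noself") == pytest.approx(1 / 1)
        assert density(p, "matrix") == pytest.approx(3 / 4)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            density(pin_of([], []))


class TestRescaleByPolyploidy:
    def test_node_count_multiplies(self):
        p = pin_of("abcde", [("a", "b")])
        r, _ = rescale_by_polyploidy(p, 3)
        assert r.n == 15

    def test_single_kept_copy_pair_inherits_one_edge(self):
        p = pin_of("ab", [("a", "b")])
        r, _ = rescale_by_polyploidy(p, 3, keep=["a~1", "b~2"])
        assert r.edges == {edge_key("a~1", "b~2")}

    def test_loop_expansion_among_kept_copies(self):
        # Ancestral homodimer triplicated, two copies kept:
        # 2 loops + 1 cross-copy pair.
        p = pin_of("a", [("a", "a")])
        r, _ = rescale_by_polyploidy(p, 3, keep=["a~1", "a~2"])
        assert r.edges == {("a~1", "a~1"), ("a~2", "a~2"), ("a~1", "a~2")}

    def test_density_preserved_exactly_in_matrix_convention(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            nodes = [f"n{i}" for i in range(n)]
            pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i:]]
            edges = [p for p in pairs if rng.random() < 0.4]
            if not edges:
                continue
            p = pin_of(nodes, edges)
            r, _ = rescale_by_polyploidy(p, 3)
            assert density(r, "matrix") == pytest.approx(
                density(p, "matrix"), abs=1e-15
            )
            # The unordered-pairs convention is preserved only up to a O(1/n)
            # loop-weighting correction.
            assert density(r, "pairs") == pytest.approx(density(p, "pairs"), abs=0.1)

    def test_target_size_deterministic(self):
        p = pin_of("abc", [("a", "b")])
        r1, _ = rescale_by_polyploidy(p, 3, target_size=5)
        r2, _ = rescale_by_polyploidy(p, 3, target_size=5)
        assert r1.nodes == r2.nodes and r1.n == 5

    def test_bad_keep_rejected(self):
        p = pin_of("ab", [])
        with pytest.raises(ValueError, match="keep"):
            rescale_by_polyploidy(p, 2, keep=["zz~1"])


class TestCompareNetworks:
    def test_identity_map_identical_networks(self):
        a = pin_of("abc", [("a", "b"), ("c", "c")], t=120.0)
        b = pin_of("abc", [("a", "b"), ("c", "c")], t=109.0)
        cmp = compare_networks(a, b, OrthologMap.identity(a.nodes))
        assert cmp.conserved == b.edges
        assert not cmp.gained and not cmp.lost

    def test_one_added_edge_is_gained(self):
        a = pin_of("abc", [("a", "b")], t=120.0)
        b = pin_of("abc", [("a", "b"), ("b", "c")], t=109.0)
        cmp = compare_networks(a, b, OrthologMap.identity(a.nodes))
        assert cmp.gained == {("b", "c")}
        assert not cmp.lost

    def test_planted_rewiring_counts_recovered(self):
        rng = np.random.default_rng(9)
        nodes = [f"p{i}" for i in range(6)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i:]]
        edges = [p for p in pairs if rng.random() < 0.5]
        a = pin_of(nodes, edges, t=120.0)
        r, omap = rescale_by_polyploidy(a, 3)
        # Plant: remove every image of two ancestral edges (losses), add
        # three brand-new descendant edges (gains).
        lost_anc = sorted(a.edges)[:2]
        removed = {
            e for e in r.edges
            if (omap.ancestor_of(e[0]), omap.ancestor_of(e[1])) in
            {tuple(sorted(x)) for x in lost_anc}
        }
        non_edges = sorted(
            {edge_key(u, v) for u in r.nodes for v in r.nodes} - r.edges
        )
        added = set(non_edges[:3])
        b = PIN("b", 109.0, r.nodes, frozenset((r.edges - removed) | added))
        cmp = compare_networks(a, b, omap)
        assert cmp.gained == added
        assert cmp.lost == set(lost_anc)
        assert cmp.conserved == r.edges - removed

    def test_partition_invariant_and_inverse_check(self):
        # Random network pairs: conserved+gained partitions b's edges and
        # lost edges are exactly the ancestral edges without surviving image.
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(3, 10))
            nodes = [f"x{i}" for i in range(n)]
            pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i:]]
            e_a = frozenset(p for p in pairs if rng.random() < 0.4)
            e_b = frozenset(p for p in pairs if rng.random() < 0.4)
            a = PIN("a", 120.0, frozenset(nodes), e_a)
            b = PIN("b", 109.0, frozenset(nodes), e_b)
            cmp = compare_networks(a, b, OrthologMap.identity(nodes))
            assert cmp.conserved | cmp.gained == b.edges
            assert not (cmp.conserved & cmp.gained)
            # Inverse: rebuilding b from a's surviving edges plus gains.
            rebuilt = (a.edges - cmp.lost) | cmp.gained
            assert rebuilt == b.edges

    def test_unmapped_descendant_edge_counts_gained(self):
        a = pin_of("a", [], t=120.0)
        b = pin_of(["a", "new"], [("a", "new")], t=109.0)
        cmp = compare_networks(a, b, OrthologMap.identity(["a"]))
        assert cmp.gained == {("a", "new")}

    def test_nonpositive_divergence_rejected(self):
        a = pin_of("ab", [], t=100.0)
        b = pin_of("ab", [], t=100.0)
        with pytest.raises(ValueError):
            compare_networks(a, b, OrthologMap.identity(["a", "b"]))


class TestGainLossRates:
    def test_zero_gained(self):
        a = pin_of("abc", [("a", "b")], t=120.0)
        b = pin_of("abc", [("a", "b")], t=109.0)
        cmp = compare_networks(a, b, OrthologMap.identity(a.nodes))
        gain, loss = gain_loss_rates(cmp)
        assert gain == 0.0 and loss == 0.0

    def test_direct_arithmetic(self):
        # 2 gained over 10 potential pairs and 11 mya.
        a = pin_of("abcd", [], t=120.0)
        b = pin_of("abcd", [("a", "b"), ("c", "d")], t=109.0)
        cmp = compare_networks(a, b, OrthologMap.identity(a.nodes))
        gain, _ = gain_loss_rates(cmp)
        assert gain == pytest.approx(2 / (10 * 11))


class TestHubProfileAndSwap:
    def test_full_promiscuity(self):
        nodes = list("abcd")
        edges = [("a", x) for x in nodes]  # a binds everything incl. itself
        rep = degree_and_hub_profile(pin_of(nodes, edges), hub_min=3, island_max=1)
        assert rep["a"]["promiscuity"] == 1.0
        assert rep["a"]["class"] == "hub"

    def test_isolated_node_is_island(self):
        rep = degree_and_hub_profile(pin_of("ab", [("a", "a")]), hub_min=2, island_max=0)
        assert rep["b"]["degree"] == 0
        assert rep["b"]["class"] == "island"

    def test_star_center_degree(self):
        leaves = [f"l{i}" for i in range(6)]
        edges = [("hub", l) for l in leaves]
        rep = degree_and_hub_profile(
            pin_of(leaves + ["hub"], edges), hub_min=6, island_max=1
        )
        assert rep["hub"]["degree"] == 6
        assert rep["hub"]["class"] == "hub"

    def test_swap_full_promiscuity(self, small_pin):
        calls = [call("ancE", n) for n in sorted(small_pin.nodes)]
        rep = swap_protein(small_pin, "ancE", calls)
        assert rep["promiscuity"] == 1.0
        assert rep["degree"] == small_pin.n

    def test_swap_no_positives(self, small_pin):
        calls = [call("anc", n, "negative") for n in sorted(small_pin.nodes)]
        rep = swap_protein(small_pin, "anc", calls)
        assert rep["degree"] == 0

    def test_swap_agrees_with_native_degree(self, small_pin):
        node = sorted(small_pin.nodes)[0]
        rep = swap_protein(
            small_pin, "foreign", [], native_counterpart=node
        )
        assert rep["native_degree"] == small_pin.degree(node)
        profile = degree_and_hub_profile(small_pin, hub_min=5, island_max=1)
        assert rep["native_degree"] == profile[node]["degree"]

    def test_swap_id_collision_rejected(self, small_pin):
        node = sorted(small_pin.nodes)[0]
        with pytest.raises(ValueError, match="collides"):
            swap_protein(small_pin, node, [])


class TestSubfunctionalization:
    @pytest.mark.parametrize(
        "ancestor, descendants, combined, deficit",
        [
            (9, [6, 3], 9, 0),       # exact additive partitioning
            (17, [8, 4, 2, 0], 14, 3),  # net loss of 3 vs additive
            (5, [], 0, 5),
        ],
    )
    def test_worked_examples(self, ancestor, descendants, combined, deficit):
        assert subfunctionalization_check(ancestor, descendants) == (combined, deficit)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            subfunctionalization_check(-1, [2])
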