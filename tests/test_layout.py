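import numpy as np
import pytest

from phenotier import (
    LayoutConfig,
    PhenotypeMatrix,
    build_class_graph,
    build_tiered_graph,
    compute_resource_classes,
    compute_strain_classes,
    hamming_distance_matrix,
    pca_on_similarity,
    place_outer_tiers,
    place_resource_classes,
    place_strain_classes,
    similarity_matrix,
)
from phenotier.layout import _respace

from .conftest import random_matrix


class TestRespace:
    def test_no_overlap_untouched(self):
        out = _respace(np.array([-0.5, 0.5]), 0.01)
        assert out.tolist() == [-0.5, 0.5]

    def test_hand_computed_run(self):
        # the two-member run centers on 0.10 and spreads at epsilon
        out = _respace(np.array([0.10, 0.10, 0.50]), 0.02)
        assert out == pytest.approx([0.09, 0.11, 0.50])

    def test_single_value(self):
        assert _respace(np.array([0.3]), 0.05).tolist() == [0.3]

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError, match="epsilon"):
            _respace(np.array([0.0, 1.0]), 0.0)

    def test_min_gap_and_run_mean_preserved(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 15))
            coords = rng.random(n)
            eps = float(rng.uniform(0.01, 0.3))
            out = _respace(coords, eps)
            gaps = np.diff(np.sort(out))
            assert np.all(gaps >= eps - 1e-9)
            # order preserved
            assert np.array_equal(np.argsort(coords, kind="stable"), np.argsort(out, kind="stable"))
            # global mean of each merged run equals mean of its raw coordinates:
            # runs are maximal blocks at exactly-epsilon spacing in sorted order
            s = np.sort(out)
            raw_sorted = coords[np.argsort(coords, kind="stable")]
            start = 0
            for i in range(1, n + 1):
                if i == n or s[i] - s[i - 1] > eps + 1e-9:
                    assert np.mean(s[start:i]) == pytest.approx(
                        np.mean(raw_sorted[start:i]), abs=1e-9
                    )
                    start = i

    def test_untouched_outside_runs(self, rng):
        coords = np.array([0.0, 0.5, 1.0, 1.004, 2.0])
        out = _respace(coords, 0.01)
        assert out[0] == 0.0 and out[1] == 0.5 and out[4] == 2.0
        assert out[3] - out[2] == pytest.approx(0.01)

    def test_all_identical_spread_at_epsilon(self):
        out = _respace(np.zeros(5), 0.1)
        assert np.allclose(np.sort(out), [-0.2, -0.1, 0.0, 0.1, 0.2])
        assert out.mean() == pytest.approx(0.0)

    def test_displacement_bound(self, rng):
        # each point moves at most (run size - 1)/2 * epsilon from its raw spot
        for _ in range(20):
            coords = rng.random(12)
            eps = 0.05
            out = _respace(coords, eps)
            assert np.all(np.abs(out - coords) <= (len(coords) - 1) / 2 * eps + 1e-9)


def small_pipeline(m):
    sp = compute_strain_classes(m)
    rp = compute_resource_classes(m)
    cg = build_class_graph(sp, rp, m)
    ordination = pca_on_similarity(similarity_matrix(hamming_distance_matrix(m)))
    return sp, rp, cg, ordination


class TestPlaceStrainClasses:
    def test_distinct_coords_unchanged(self, rng):
        m = random_matrix(rng, 6, 8)
        sp, _, _, ordination = small_pipeline(m)
        y = place_strain_classes(ordination, sp, epsilon=1e-9)
        coord = ordination.component(1)
        idx = {n: i for i, n in enumerate(ordination.names)}
        for c in sp.classes:
            assert y[c.name] == pytest.approx(coord[idx[c.members[0]]], abs=1e-6)

    def test_epsilon_validation(self, rng):
        m = random_matrix(rng, 4, 5)
        sp, _, _, ordination = small_pipeline(m)
        with pytest.raises(ValueError):
            place_strain_classes(ordination, sp, epsilon=-1.0)

    def test_pc1_order_preserved(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 10, 6)
            sp, _, _, ordination = small_pipeline(m)
            y = place_strain_classes(ordination, sp, epsilon=0.05)
            coord = ordination.component(1)
            idx = {n: i for i, n in enumerate(ordination.names)}
            raw = [coord[idx[c.members[0]]] for c in sp.classes]
            placed = [y[c.name] for c in sp.classes]
            order_raw = np.argsort(raw, kind="stable")
            order_placed = np.argsort(placed, kind="stable")
            assert np.array_equal(order_raw, order_placed)


class TestPlaceResourceClasses:
    def test_single_predecessor(self):
        m = PhenotypeMatrix(("a", "b"), ("r1", "r2"), np.array([[1, 0], [0, 1]]))
        sp, rp, cg, _ = small_pipeline(m)
        strain_y = {sp.classes[0].name: 0.3, sp.classes[1].name: 0.9}
        y, flagged = place_resource_classes(cg, strain_y)
        # r1 is linked only from a's class
        target = rp.class_of()["r1"]
        assert y[target] == pytest.approx(0.3)
        assert not flagged

    def test_barycenter_is_mean(self):
        m = PhenotypeMatrix(("a", "b"), ("r1",), np.array([[1], [1]]))
        # two strain classes would collapse here; craft distinct rows instead
        m = PhenotypeMatrix(("a", "b"), ("r1", "r2"), np.array([[1, 1], [1, 0]]))
        sp, rp, cg, _ = small_pipeline(m)
        strain_y = {sp.classes[0].name: 0.0, sp.classes[1].name: 2.0}
        y, _ = place_resource_classes(cg, strain_y)
        shared = rp.class_of()["r1"]  # consumed by both classes
        assert y[shared] == pytest.approx(1.0)

    def test_in_degree_zero_fallback_and_flag(self):
        m = PhenotypeMatrix(
            ("a", "b"), ("used", "unused"), np.array([[1, 0], [0, 0]])
        )
        sp, rp, cg, _ = small_pipeline(m)
        strain_y = {sp.classes[0].name: -1.0, sp.classes[1].name: 3.0}
        y, flagged = place_resource_classes(cg, strain_y)
        target = rp.class_of()["unused"]
        assert target in flagged
        assert y[target] == pytest.approx(1.0)  # midpoint of [-1, 3]


class TestPlaceOuterTiers:
    def test_singleton_class_member_at_class_y(self):
        m = PhenotypeMatrix(("a", "b"), ("r1", "r2"), np.eye(2, dtype=int))
        sp = compute_strain_classes(m)
        y = place_outer_tiers(sp, {"B1": 0.2, "B2": 5.0}, epsilon=0.02)
        assert y["a"] == pytest.approx(0.2)

    def test_three_member_centered_stack(self):
        m = PhenotypeMatrix(
            ("a", "b", "c", "d"), ("r1", "r2"),
            np.array([[1, 0], [1, 0], [1, 0], [0, 1]]),
        )
        sp = compute_strain_classes(m)
        y = place_outer_tiers(sp, {"B1": 0.0, "B2": 9.0}, epsilon=0.02)
        assert sorted([y["a"], y["b"], y["c"]]) == pytest.approx([-0.02, 0.0, 0.02])

    def test_overlapping_stacks_respaced(self):
        m = PhenotypeMatrix(
            ("a", "b", "c", "d"), ("r1", "r2"),
            np.array([[1, 0], [1, 0], [0, 1], [0, 1]]),
        )
        sp = compute_strain_classes(m)
        y = place_outer_tiers(sp, {"B1": 0.0, "B2": 0.01}, epsilon=0.02)
        vals = np.sort(list(y.values()))
        assert np.all(np.diff(vals) >= 0.02 - 1e-12)


class TestBuildTieredGraph:
    def test_identity_three_by_three_counts(self):
        m = PhenotypeMatrix(("a", "b", "c"), ("r1", "r2", "r3"), np.eye(3, dtype=int))
        g, _ = build_tiered_graph(m)
        assert len(g.nodes) == 3 + 3 + 3 + 3
        assert len(g.edges) == 3 + 3 + 3

    def test_all_ones_four_by_five_counts(self):
        m = PhenotypeMatrix(
            tuple("abcd"), tuple(f"r{j}" for j in range(5)), np.ones((4, 5), dtype=int)
        )
        with pytest.warns(UserWarning, match="zero total variance"):
            g, _ = build_tiered_graph(m)
        assert len(g.nodes) == 4 + 1 + 1 + 5
        assert len(g.edges) == 4 + 1 + 5

    def test_association_matrix_matches_edges(self, rng):
        m = random_matrix(rng, 10, 8)
        g, am = build_tiered_graph(m)
        pos = {nid: i for i, nid in enumerate(am.node_ids)}
        expected = np.zeros_like(am.adjacency)
        for src, dst in g.edges:
            expected[pos[src], pos[dst]] = True
        assert np.array_equal(am.adjacency, expected)

    def test_association_matrix_block_structure(self, rng):
        m = random_matrix(rng, 8, 7)
        g, am = build_tiered_graph(m)
        tier_of = {n.id: n.tier for n in g.nodes}
        tiers = np.array([tier_of[nid] for nid in am.node_ids])
        assert np.all(np.diff(tiers) >= 0)  # tier-ordered nodes
        for i, j in np.argwhere(am.adjacency):
            assert tiers[j] == tiers[i] + 1

    def test_min_gap_invariant_tier2(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 12, 5)
            g, _ = build_tiered_graph(m)
            ys = np.sort([n.y for n in g.tier_nodes(2)])
            if len(ys) > 1:
                assert np.all(np.diff(ys) >= g.epsilon - 1e-9)

    def test_barycenter_identity(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 9, 6)
            g, _ = build_tiered_graph(m)
            node = {n.id: n for n in g.nodes}
            preds = {}
            for src, dst in g.edges:
                if node[src].tier == 2 and node[dst].tier == 3:
                    preds.setdefault(dst, []).append(node[src].y)
            for t3 in g.tier_nodes(3):
                if t3.id in preds:
                    assert t3.y == pytest.approx(np.mean(preds[t3.id]), abs=1e-12)

    def test_tier1_degree_and_conservation(self, rng):
        m = random_matrix(rng, 7, 5)
        g, _ = build_tiered_graph(m)
        t1 = g.tier_nodes(1)
        assert len(t1) == m.n_strains
        node = {n.id: n for n in g.nodes}
        for n in t1:
            out = [e for e in g.edges if e[0] == n.id]
            assert len(out) == 1
            assert node[out[0][1]].tier == 2

    def test_degree_annotations_match_class_graph(self, rng):
        m = random_matrix(rng, 8, 6)
        sp = compute_strain_classes(m)
        rp = compute_resource_classes(m)
        cg = build_class_graph(sp, rp, m)
        g, _ = build_tiered_graph(m)
        node = {n.id: n for n in g.nodes}
        for c, deg in zip(sp.classes, cg.out_degree):
            assert node[c.name].degree == deg
        for c, deg in zip(rp.classes, cg.in_degree):
            assert node[c.name].degree == deg

    def test_size_annotations(self, rng):
        m = random_matrix(rng, 8, 6)
        sp = compute_strain_classes(m)
        g, _ = build_tiered_graph(m)
        node = {n.id: n for n in g.nodes}
        for c in sp.classes:
            assert node[c.name].size == c.size

    def test_explicit_epsilon_and_tier_x(self, rng):
        m = random_matrix(rng, 6, 5)
        g, _ = build_tiered_graph(m, LayoutConfig(epsilon=0.5, tier_x=(0.0, 2.0, 4.0, 6.0)))
        assert g.epsilon == 0.5
        xs = {n.tier: n.x for n in g.nodes}
        assert xs == {1: 0.0, 2: 2.0, 3: 4.0, 4: 6.0}

    def test_pcoa_mode_runs(self, rng):
        m = random_matrix(rng, 6, 5)
        g, _ = build_tiered_graph(m, LayoutConfig(method="pcoa"))
        g.validate()

    def test_bad_method_rejected(self, rng):
        m = random_matrix(rng, 4, 4)
        with pytest.raises(ValueError, match="unknown ordination method"):
            build_tiered_graph(m, LayoutConfig(method="nmds"))
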