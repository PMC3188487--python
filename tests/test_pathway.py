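"""Pathway construction: dominant response directions, overlap graph, and the
exact max-product path search (checked against brute-force enumeration)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prscan.enm import ElasticNetworkModel, build_hessian, compute_compliance
from prscan.fixtures import FixtureSpec, make_fixture
from prscan.pathway import (OverlapGraph, build_overlap_graph, candidate_set,
                            dominant_direction, max_weight_pathway,
                            overlap_coefficient)
from prscan.structures import BindingPocket


def pocket_of(indices):
    return BindingPocket(residue_selectors=[i + 1 for i in indices],
                         resolved_indices=list(indices))


def brute_force_best_path(nodes, edges):
    """Enumerate every maximal (source-to-sink) monotone path; return the
    winner under (product weight, length, smaller start)."""
    has_in = {b for (_, b) in edges}
    has_out = {a for (a, _) in edges}
    sources = [v for v in nodes if v in has_out and v not in has_in]
    best = None

    def extend(path, weight):
        nonlocal best
        last = path[-1]
        nxt = [(b, w) for (a, b), w in edges.items() if a == last]
        if not nxt:
            if len(path) > 1:
                key = (weight, len(path), -path[0])
                if best is None or key > best[0]:
                    best = (key, list(path))
            return
        for b, w in nxt:
            extend(path + [b], weight * w)

    for s in sources:
        extend([s], 1.0)
    return best


class TestOverlapCoefficient:
    def test_identical_vectors(self):
        v = np.array([0.0, 0.0, 1.0])
        assert overlap_coefficient(v, v) == 1.0

    def test_orthogonal_vectors(self):
        assert overlap_coefficient(np.array([1.0, 0, 0]),
                                   np.array([0, 1.0, 0])) == 0.0

    def test_antiparallel_counts_as_aligned(self):
        v = np.array([1.0, 0, 0]) / 1.0
        assert overlap_coefficient(v, -v) == 1.0

    def test_symmetry(self, rng):
        a = rng.normal(size=3); a /= np.linalg.norm(a)
        b = rng.normal(size=3); b /= np.linalg.norm(b)
        assert overlap_coefficient(a, b) == overlap_coefficient(b, a)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(np.array([2.0, 0, 0]), np.array([1.0, 0, 0]))


class TestDominantDirection:
    def test_two_mass_dominant_direction_is_bond_axis(self):
        m = make_fixture(FixtureSpec(kind="two_mass", n_residues=2, spacing=3.8))
        c = compute_compliance(build_hessian(m), expected_null_modes=5)
        dr = dominant_direction(c, 1, pocket_of([0]))
        v = dr.vector(1, 0)
        assert abs(abs(v[0]) - 1.0) <= 1e-9
        assert np.abs(v[1:]).max() <= 1e-9

    def test_matches_independent_svd_of_blocks(self, cloud30_enm):
        c = cloud30_enm.compliance_
        pocket = pocket_of([0, 1])
        for k in (5, 12, 29):
            dr = dominant_direction(c, k, pocket)
            for s in pocket.resolved_indices:
                block = c.matrix[3 * k : 3 * k + 3, 3 * s : 3 * s + 3]
                w, vecs = np.linalg.eigh(block.T @ block)
                ref = vecs[:, np.argmax(w)]
                ref_left = block @ ref
                ref_left /= np.linalg.norm(ref_left)
                got = dr.vector(k, s)
                assert abs(abs(np.dot(got, ref_left)) - 1.0) <= 1e-8

    def test_spectrum_descending_nonnegative(self, cloud30_enm):
        dr = dominant_direction(cloud30_enm.compliance_, 7, pocket_of([0, 3, 4]))
        for entry in dr.entries.values():
            s = entry.spectrum
            assert np.all(np.diff(s) <= 1e-15)
            assert np.all(s >= -1e-15)
            assert 1 / 3 - 1e-12 <= entry.collectivity <= 1 + 1e-12

    def test_self_block_eigenvalues_nonnegative(self, cloud30_enm):
        dr = dominant_direction(cloud30_enm.compliance_, 4, pocket_of([4]))
        assert np.all(dr.entries[(4, 4)].spectrum >= 0)

    def test_canonical_sign_fixed(self, cloud30_enm):
        dr = dominant_direction(cloud30_enm.compliance_, 9, pocket_of([1]))
        v = dr.vector(9, 1)
        first_nonzero = v[np.nonzero(np.abs(v) > 1e-12)[0][0]]
        assert first_nonzero > 0


class TestCandidateSet:
    def test_window_three_adds_both_neighbors(self, cloud30):
        # hot residue 320-analogue: index 9 (author number 10)
        cand = candidate_set([9], cloud30, window=3)
        assert cand == [8, 9, 10]

    def test_terminus_keeps_existing_neighbors_only(self, cloud30):
        assert candidate_set([0], cloud30, window=3) == [0, 1]
        last = cloud30.n_residues - 1
        assert candidate_set([last], cloud30, window=3) == [last - 1, last]

    def test_window_one_is_identity(self, cloud30):
        assert candidate_set([3, 7], cloud30, window=1) == [3, 7]

    def test_accepts_hot_tuples_in_author_numbering(self, cloud30):
        cand = candidate_set([("A", 10, "", 2.0)], cloud30, window=3)
        assert cand == [8, 9, 10]

    def test_even_window_rejected(self, cloud30):
        with pytest.raises(ValueError):
            candidate_set([3], cloud30, window=2)


class TestOverlapGraph:
    def test_zero_cutoff_gives_complete_dag(self, cloud30_enm):
        pocket = pocket_of([0, 1])
        cand = [3, 5, 8, 11]
        dr = dominant_direction(cloud30_enm.compliance_, cand[0], pocket)
        for k in cand[1:]:
            dr.entries.update(
                dominant_direction(cloud30_enm.compliance_, k, pocket).entries)
        g = build_overlap_graph(cand, dr, cutoff=0.0)
        assert len(g.edges) == len(cand) * (len(cand) - 1) // 2
        assert all(a < b for a, b in g.edges)

    def test_impossible_cutoff_gives_empty_edges(self, cloud30_enm):
        pocket = pocket_of([0])
        cand = [3, 5, 8]
        dr = dominant_direction(cloud30_enm.compliance_, cand[0], pocket)
        for k in cand[1:]:
            dr.entries.update(
                dominant_direction(cloud30_enm.compliance_, k, pocket).entries)
        g = build_overlap_graph(cand, dr, cutoff=1.5)
        assert g.edges == {}

    def test_edge_weights_within_cutoff_and_one(self, cloud30_enm):
        pocket = pocket_of([0, 1, 2])
        cand = list(range(10, 20))
        dr = dominant_direction(cloud30_enm.compliance_, cand[0], pocket)
        for k in cand[1:]:
            dr.entries.update(
                dominant_direction(cloud30_enm.compliance_, k, pocket).entries)
        g = build_overlap_graph(cand, dr, cutoff=0.5)
        assert all(0.5 <= w <= 1.0 for w in g.edges.values())


class TestMaxWeightPathway:
    def test_printed_two_edge_chain_and_product(self):
        g = OverlapGraph(nodes=[314, 327, 338],
                         edges={(314, 327): 0.99, (327, 338): 0.98}, cutoff=0.98)
        pw = max_weight_pathway(g)
        assert [r[1] for r in pw.residues] == [315, 328, 339]  # indices+1 labels
        assert pw.indices == [314, 327, 338]
        assert pw.total_weight == pytest.approx(0.99 * 0.98, abs=1e-12)
        assert pw.total_weight == pytest.approx(0.9702, abs=1e-12)

    def test_prefers_heavier_maximal_path(self):
        # chain A: 1→2→3 with 0.99·0.99, chain B: 5→6→7 with 0.98·0.98
        g = OverlapGraph(nodes=[1, 2, 3, 5, 6, 7],
                         edges={(1, 2): 0.99, (2, 3): 0.99,
                                (5, 6): 0.98, (6, 7): 0.98}, cutoff=0.9)
        pw = max_weight_pathway(g)
        assert pw.indices == [1, 2, 3]
        assert pw.total_weight == pytest.approx(0.99**2)

    def test_single_edge_graph(self):
        g = OverlapGraph(nodes=[2, 9], edges={(2, 9): 0.991}, cutoff=0.98)
        pw = max_weight_pathway(g)
        assert pw.indices == [2, 9]
        assert pw.edge_overlaps == [0.991]

    def test_no_edges_yields_single_node_with_warning(self):
        g = OverlapGraph(nodes=[4, 7], edges={}, cutoff=0.98)
        pw = max_weight_pathway(g)
        assert pw.indices == [4]
        assert pw.total_weight == 1.0
        assert "no edges" in pw.warning

    def test_total_weight_is_product_of_edges(self):
        g = OverlapGraph(nodes=list(range(6)),
                         edges={(0, 1): 0.99, (1, 3): 0.985, (3, 5): 0.992},
                         cutoff=0.98)
        pw = max_weight_pathway(g)
        assert pw.total_weight == pytest.approx(np.prod(pw.edge_overlaps), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_dp_equals_brute_force_on_random_dags(self, data):
        n = data.draw(st.integers(min_value=2, max_value=10))
        nodes = list(range(n))
        edges = {}
        for a in range(n):
            for b in range(a + 1, n):
                if data.draw(st.booleans(), label=f"edge{a}-{b}"):
                    edges[(a, b)] = round(data.draw(
                        st.floats(min_value=0.5, max_value=1.0,
                                  allow_nan=False), label=f"w{a}-{b}"), 3)
        g = OverlapGraph(nodes=nodes, edges=edges, cutoff=0.0)
        pw = max_weight_pathway(g)
        ref = brute_force_best_path(nodes, edges)
        if ref is None:
            assert pw.edge_overlaps == []
        else:
            (w, length, neg_start), path = ref
            assert pw.indices == path
            assert pw.total_weight == pytest.approx(w, abs=1e-12)

    def test_removing_nodes_never_increases_weight_over_all_paths(self, rng):
        """Over the set of ALL monotone paths (not just maximal ones) the best
        product weight is monotone under node removal: deleting a node only
        removes candidates. (Among maximal paths alone this can fail, because
        removal may cut short a forced low-weight extension.)"""

        def best_over_all_paths(nodes, edges):
            best = [0.0]

            def extend(last, weight):
                best[0] = max(best[0], weight)
                for (a, b), w in edges.items():
                    if a == last:
                        extend(b, weight * w)

            for (a, b), w in edges.items():
                extend(b, w)
            return best[0]

        for _ in range(30):
            n = 8
            edges = {}
            for a in range(n):
                for b in range(a + 1, n):
                    if rng.random() < 0.5:
                        edges[(a, b)] = float(rng.uniform(0.5, 1.0))
            if not edges:
                continue
            drop = int(rng.integers(n))
            sub_edges = {e: w for e, w in edges.items() if drop not in e}
            assert best_over_all_paths([v for v in range(n) if v != drop],
                                       sub_edges) <= \
                best_over_all_paths(list(range(n)), edges) + 1e-12


def test_full_and_truncated_networks_can_disagree(cloud30):
    """Removing terminal residues before network construction changes the
    compliance and can change the pathway (the structural analogue of a
    distal-helix truncation)."""
    enm_full = ElasticNetworkModel().fit(cloud30)
    truncated = cloud30.drop_residues([27, 28, 29, 30])
    enm_trunc = ElasticNetworkModel().fit(truncated)
    pocket = pocket_of(range(5))
    cand = list(range(6, 24))
    def pathway_for(enm):
        dr = dominant_direction(enm.compliance_, cand[0], pocket)
        for k in cand[1:]:
            dr.entries.update(dominant_direction(enm.compliance_, k, pocket).entries)
        g = build_overlap_graph(cand, dr, cutoff=0.9)
        return max_weight_pathway(g)
    pw_full = pathway_for(enm_full)
    pw_trunc = pathway_for(enm_trunc)
    # the compliance genuinely differs on the shared residues
    nshared = truncated.n_residues
    assert not np.allclose(enm_full.compliance_.matrix[: 3 * nshared, : 3 * nshared],
                           enm_trunc.compliance_.matrix)
    assert pw_full.indices and pw_trunc.indices
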