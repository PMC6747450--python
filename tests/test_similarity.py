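"""Similarity-matrix tests, each backed by a brute-force oracle where the
value is not hand-derivable."""

import numpy as np
import pytest

from cnndlp.netio import DiseaseOntology
from cnndlp.similarity import (
    best_match_average,
    bma_matrix,
    compute_bundle,
    first_kind_similarities,
    functional_similarity,
    fuse,
    mirna_kernel,
    second_kind_similarities,
    semantic_similarity,
    term_contributions,
)


def brute_bma(neigh_a, neigh_b, kernel):
    """Independent double-loop best-match-average oracle."""
    a, b = sorted(set(neigh_a)), sorted(set(neigh_b))
    if not a or not b:
        return 0.0
    fwd = sum(max(kernel[x, y] for y in b) for x in a)
    bwd = sum(max(kernel[x, y] for x in a) for y in b)
    return (fwd + bwd) / (len(a) + len(b))


def recursive_contribution(edges, term, delta):
    """Independent recursive Wang-contribution oracle over (child, parent) edges."""
    children = {}
    for c, p in edges:
        children.setdefault(p, []).append(c)

    contrib = {term: 1.0}

    def visit(t):
        if t in contrib:
            return contrib[t]
        vals = [visit(c) for c in children.get(t, []) if reachable(c)]
        contrib[t] = delta * max(vals)
        return contrib[t]

    def reachable(t):
        # t is on a path from term up to an ancestor
        if t == term:
            return True
        return any(reachable(c) for c, p in edges if p == t)

    parents = {c: [] for c, _ in edges}
    ancestors = set()
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for c, p in edges:
            if c == t and p not in ancestors:
                ancestors.add(p)
                frontier.append(p)
    for t in ancestors:
        visit(t)
    return contrib


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self, two_branch_ontology):
        D = semantic_similarity(two_branch_ontology, ["d1", "d2"])
        assert D[0, 0] == D[1, 1] == 1.0

    def test_disjoint_dags_give_zero(self):
        onto = DiseaseOntology(
            terms={"a", "b"}, parent_edges=set(), disease_to_term={"d1": "a", "d2": "b"}
        )
        D = semantic_similarity(onto, ["d1", "d2"])
        assert D[0, 1] == 0.0

    def test_shared_root_toy_value(self, two_branch_ontology):
        # ancestors {t1, root} and {t2, root}: shared root contributes 0.5 each;
        # (0.5 + 0.5) / (1.5 + 1.5) = 1/3
        D = semantic_similarity(two_branch_ontology, ["d1", "d2"], delta=0.5)
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_contributions_match_recursive_oracle(self):
        edges = {("t3", "t2"), ("t2", "t1"), ("t3", "t4"), ("t4", "t1"), ("t2", "t0")}
        onto = DiseaseOntology(
            terms={"t0", "t1", "t2", "t3", "t4"},
            parent_edges=edges,
            disease_to_term={"d": "t3"},
        )
        got = term_contributions(onto, "t3", delta=0.5)
        expect = recursive_contribution(edges, "t3", 0.5)
        assert got == pytest.approx(expect)

    def test_unmapped_disease_rejected(self, two_branch_ontology):
        with pytest.raises(ValueError, match="no ontology term"):
            semantic_similarity(two_branch_ontology, ["d1", "dX"])

    def test_symmetric_unit_interval(self, small_dataset):
        net, onto, _ = small_dataset
        D = semantic_similarity(onto, net.disease_ids)
        assert np.allclose(D, D.T, atol=1e-12)
        assert D.min() >= 0 and D.max() <= 1


class TestBestMatchAverage:
    def test_identical_sets_identity_kernel(self):
        assert best_match_average({0, 1}, {0, 1}, np.eye(3)) == 1.0

    def test_empty_set_rule(self):
        assert best_match_average(set(), {0}, np.eye(2)) == 0.0

    def test_worked_example_two_thirds(self):
        # disease sets {d1,d2,d4} vs {d2,d4,d5} under the identity kernel
        assert best_match_average({0, 1, 3}, {1, 3, 4}, np.eye(5)) == pytest.approx(2 / 3)

    def test_out_of_kernel_neighbor_rejected(self):
        with pytest.raises(ValueError, match="outside kernel"):
            best_match_average({5}, {0}, np.eye(2))

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            k = rng.random((n, n))
            k = (k + k.T) / 2
            np.fill_diagonal(k, 1.0)
            a = set(map(int, rng.choice(n, rng.integers(1, n + 1), replace=False)))
            b = set(map(int, rng.choice(n, rng.integers(1, n + 1), replace=False)))
            assert best_match_average(a, b, k) == pytest.approx(brute_bma(a, b, k))


class TestFunctionalSimilarity:
    def test_identical_disease_sets(self):
        A = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
        L = functional_similarity(A, np.eye(3))
        assert L[0, 1] == 1.0

    def test_zero_degree_rule(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        L = functional_similarity(A, np.eye(2))
        assert L[0, 1] == 0.0 and L[1, 1] == 1.0

    def test_identity_kernel_matches_oracle(self, rng):
        A = (rng.random((3, 5)) < 0.5).astype(float)
        L = functional_similarity(A, np.eye(5))
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                ni = set(np.flatnonzero(A[i]))
                nj = set(np.flatnonzero(A[j]))
                assert L[i, j] == pytest.approx(brute_bma(ni, nj, np.eye(5)))


class TestFirstAndSecondKind:
    def test_common_disease_toy(self):
        # N(l1)={d2}, N(l3)={d1,d2}: (1 + (0+1)) / (1+2) = 2/3
        A = np.zeros((3, 2))
        A[0, 1] = 1
        A[2, 0] = A[2, 1] = 1
        L1, _ = first_kind_similarities(A, np.eye(3), np.eye(2))
        assert L1[0, 2] == pytest.approx(2 / 3)

    def test_disjoint_neighbors_identity_kernel(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        L1, _ = first_kind_similarities(A, np.eye(2), np.eye(2))
        assert L1[0, 1] == 0.0

    def test_similar_neighbor_case(self):
        # neighbor sets {d1} and {d2} with kernel(d1,d2)=0.8
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        D = np.array([[1.0, 0.8], [0.8, 1.0]])
        L1, _ = first_kind_similarities(A, np.eye(2), D)
        assert L1[0, 1] == pytest.approx(0.8)

    def test_mirna_kernel_examples(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        D = np.array([[1.0, 0.4], [0.4, 1.0]])
        M = mirna_kernel(C, D)
        assert M[0, 2] == 1.0  # identical disease sets
        assert M[0, 1] == pytest.approx(0.4)  # single-pair best match

    def test_mirna_zero_degree(self):
        C = np.array([[1.0], [0.0]])
        M = mirna_kernel(C, np.eye(1))
        assert M[0, 1] == 0.0 and M[1, 1] == 1.0

    def test_second_kind_toy(self):
        # N(l1)={m1,m3}, N(l2)={m3}, identity kernel: (0+1 + 1)/(2+1) = 2/3
        B = np.array([[1.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        C = np.zeros((3, 2))
        L2, _ = second_kind_similarities(B, C, np.eye(3))
        assert L2[0, 1] == pytest.approx(2 / 3)

    def test_shared_all_partners(self):
        B = np.array([[1.0, 1.0], [1.0, 1.0]])
        L2, _ = second_kind_similarities(B, np.zeros((2, 2)), np.eye(2))
        assert L2[0, 1] == 1.0

    def test_exhaustive_small_graphs_match_oracle(self, rng):
        # all 512 bipartite graphs on 3x3 plus random graphs up to 6x6
        def check(adj, kernel):
            got = bma_matrix(adj, kernel)
            n = adj.shape[0]
            for i in range(n):
                for j in range(n):
                    ni = set(np.flatnonzero(adj[i]))
                    nj = set(np.flatnonzero(adj[j]))
                    expect = 1.0 if i == j else brute_bma(ni, nj, kernel)
                    assert got[i, j] == pytest.approx(expect), (adj, i, j)

        for bits in range(512):
            adj = np.array([(bits >> k) & 1 for k in range(9)], float).reshape(3, 3)
            check(adj, np.eye(3))
        for _ in range(60):
            nr, nc = rng.integers(2, 7, size=2)
            adj = (rng.random((nr, nc)) < 0.4).astype(float)
            k = rng.random((nc, nc))
            k = (k + k.T) / 2
            np.fill_diagonal(k, 1.0)
            check(adj, k)


class TestFuse:
    def test_endpoints(self, rng):
        a, b = rng.random((3, 3)), rng.random((3, 3))
        assert np.array_equal(fuse(a, b, 1.0), a)
        assert np.array_equal(fuse(a, b, 0.0), b)

    def test_direct_arithmetic(self):
        assert fuse(np.array([[0.5]]), np.array([[0.3]]), 0.9)[0, 0] == pytest.approx(0.48)

    def test_weight_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fuse(np.eye(2), np.eye(2), 1.5)

    def test_monotone_in_first_argument(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        bumped = a.copy()
        bumped[2, 1] += 0.1
        assert (fuse(bumped, b, 0.7) >= fuse(a, b, 0.7) - 1e-15).all()


class TestBundle:
    def test_all_matrices_symmetric_unit_interval(self, small_dataset):
        net, onto, _ = small_dataset
        bundle = compute_bundle(net, onto)
        for name in ("L", "D", "L1", "D1", "L2", "D2", "M", "Lc", "Dc"):
            m = getattr(bundle, name)
            assert np.allclose(m, m.T, atol=1e-12), name
            assert m.min() >= 0 and m.max() <= 1 + 1e-12, name
            assert np.allclose(np.diag(m), 1.0), name

    def test_a_override_changes_only_a_derived(self, small_dataset):
        net, onto, _ = small_dataset
        full = compute_bundle(net, onto)
        masked = compute_bundle(net, onto, A_override=np.zeros_like(net.A))
        assert np.array_equal(full.D, masked.D)
        assert np.array_equal(full.M, masked.M)
        assert np.array_equal(full.L2, masked.L2)
        assert not np.array_equal(full.L1, masked.L1)
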