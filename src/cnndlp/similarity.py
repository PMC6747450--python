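"""Similarity matrices over the heterogeneous network.

Two families of similarity feed the pair-embedding layers:

* Ontology-driven: disease semantic similarity ``D`` computed Wang-style on
  each disease's term DAG (depth-decayed ancestor contributions), and the
  lncRNA functional similarity ``L`` induced from ``D`` through associated
  disease sets.
* Topology-driven: "first-kind" similarities ``L1``/``D1`` from the
  lncRNA-disease bipartite graph and "second-kind" similarities ``L2``/``D2``
  from the lncRNA-miRNA and miRNA-disease graphs, with an miRNA kernel ``M``
  bridging the latter.

All four topology-driven matrices are instantiations of one operator,
best-match average over neighbor sets with an inner kernel: with kernel
``K`` and neighbor sets ``N(a)``, ``N(b)``,

    sim(a, b) = ( sum_{x in N(a)} max_{y in N(b)} K(x, y)
                + sum_{y in N(b)} max_{x in N(a)} K(x, y) ) / (|N(a)| + |N(b)|)

which is high when the sets share common members (K(x, x) = 1) and nonzero
when they merely contain similar members. Nodes with no neighbors get
off-diagonal similarity 0 and diagonal 1 (no evidence is not self-
dissimilarity).

The fused matrices are convex combinations: Lc = alpha*L1 + (1-alpha)*L2 and
Dc = beta*D1 + (1-beta)*D2.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .netio import DiseaseOntology, HeterogeneousNetwork

__all__ = [
    "SimilarityBundle",
    "semantic_similarity",
    "term_contributions",
    "best_match_average",
    "bma_matrix",
    "functional_similarity",
    "first_kind_similarities",
    "mirna_kernel",
    "second_kind_similarities",
    "fuse",
    "compute_bundle",
]

#: Canonical decay factor of the Wang semantic-contribution scheme.
DEFAULT_DELTA = 0.5


@dataclasses.dataclass
class SimilarityBundle:
    """All similarity matrices plus the fusion weights used to combine them."""

    L: np.ndarray  # lncRNA functional, Nl x Nl
    D: np.ndarray  # disease semantic, Nd x Nd
    L1: np.ndarray
    D1: np.ndarray
    L2: np.ndarray
    D2: np.ndarray
    M: np.ndarray  # miRNA kernel, Nm x Nm
    Lc: np.ndarray
    Dc: np.ndarray
    alpha: float
    beta: float


def term_contributions(
    ontology: DiseaseOntology, term: str, delta: float = DEFAULT_DELTA
) -> dict[str, float]:
    """Semantic contribution of every ancestor of ``term`` (term included).

    The term itself contributes 1; an ancestor t contributes
    ``delta * max(contribution of its children on paths to the term)``,
    i.e. ``delta ** depth`` along the best (shortest in decay) path.
    """
    g = ontology.graph()  # child -> parent
    if term not in g:
        raise ValueError(f"term {term!r} not in ontology")
    contrib = {term: 1.0}
    # Process ancestors in topological order of the child->parent graph so
    # every child's contribution is final before its parents are visited.
    ancestors = nx.descendants(g, term) | {term}
    sub = g.subgraph(ancestors)
    for t in nx.topological_sort(sub):
        if t == term:
            continue
        contrib[t] = delta * max(contrib[c] for c in sub.predecessors(t))
    return contrib


def semantic_similarity(
    ontology: DiseaseOntology,
    disease_ids: list[str] | None = None,
    delta: float = DEFAULT_DELTA,
) -> np.ndarray:
    """Wang-style disease semantic similarity matrix.

    For diseases i, j with ancestor contribution maps S_i, S_j:

        D(i, j) = sum_{t in both} (S_i(t) + S_j(t)) / (sum S_i + sum S_j)

    Symmetric with unit diagonal; 0 when the term DAGs share no ancestors.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    if disease_ids is None:
        disease_ids = sorted(ontology.disease_to_term)
    for d in disease_ids:
        if d not in ontology.disease_to_term:
            raise ValueError(f"disease {d!r} has no ontology term mapping")
    contribs = {}
    for d in disease_ids:
        t = ontology.disease_to_term[d]
        if t not in contribs:
            contribs[t] = term_contributions(ontology, t, delta)
    totals = {t: sum(c.values()) for t, c in contribs.items()}
    n = len(disease_ids)
    sim = np.eye(n)
    for i in range(n):
        ti = ontology.disease_to_term[disease_ids[i]]
        ci = contribs[ti]
        for j in range(i + 1, n):
            tj = ontology.disease_to_term[disease_ids[j]]
            cj = contribs[tj]
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                sim[i, j] = sim[j, i] = num / (totals[ti] + totals[tj])
    return sim


def best_match_average(
    neighbors_a: set[int] | list[int],
    neighbors_b: set[int] | list[int],
    kernel: np.ndarray,
) -> float:
    """Best-match-average similarity of two neighbor sets under ``kernel``.

    Returns 0 if either set is empty (the 0-degree rule).
    """
    a = sorted(set(neighbors_a))
    b = sorted(set(neighbors_b))
    if not a or not b:
        return 0.0
    n = kernel.shape[0]
    for x in (*a, *b):
        if not 0 <= x < n:
            raise ValueError(f"neighbor index {x} outside kernel of size {n}")
    sub = kernel[np.ix_(a, b)]
    return float(sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (len(a) + len(b))


def bma_matrix(adjacency: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Pairwise best-match average between the rows of a bipartite adjacency.

    ``adjacency`` is n x m binary (row node -> column-node neighbor sets) and
    ``kernel`` an m x m similarity over the column universe. Vectorized:
    P[i, d] = max_{a in N(i)} kernel[a, d] gives, for each row node i, the
    best kernel match of every column node against i's neighbor set; then
    the cross terms are inner products of P with neighbor indicators.
    """
    adj = np.asarray(adjacency, dtype=float)
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    P = np.zeros((n, adj.shape[1]))
    for i in range(n):
        members = np.flatnonzero(adj[i])
        if members.size:
            P[i] = kernel[members].max(axis=0)
    cross = P @ adj.T  # cross[i, j] = sum_{b in N(j)} max_{a in N(i)} K(a, b)
    denom = deg[:, None] + deg[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (cross + cross.T) / denom
    sim[denom == 0] = 0.0
    sim[(deg[:, None] == 0) | (deg[None, :] == 0)] = 0.0
    np.fill_diagonal(sim, 1.0)
    return sim


def functional_similarity(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """lncRNA functional similarity from associated-disease sets under D."""
    _check_kernel(D, A.shape[1])
    return bma_matrix(A, D)


def first_kind_similarities(
    A: np.ndarray, L_base: np.ndarray, D_base: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-kind similarities from the lncRNA-disease bipartite graph.

    L1 compares lncRNAs through their associated disease sets (kernel
    ``D_base``); D1 compares diseases through their associated lncRNA sets
    (kernel ``L_base``). Because the kernels have unit diagonal, common
    neighbors and merely similar neighbors both contribute.
    """
    _check_kernel(D_base, A.shape[1])
    _check_kernel(L_base, A.shape[0])
    return bma_matrix(A, D_base), bma_matrix(A.T, L_base)


def mirna_kernel(C: np.ndarray, D_base: np.ndarray) -> np.ndarray:
    """miRNA-miRNA kernel from miRNA-disease association profiles under D."""
    _check_kernel(D_base, C.shape[1])
    return bma_matrix(C, D_base)


def second_kind_similarities(
    B: np.ndarray, C: np.ndarray, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Second-kind similarities through the miRNA layer.

    L2 compares lncRNAs through their interacting miRNA sets and D2 compares
    diseases through their associated miRNA sets, both under the miRNA
    kernel ``M``.
    """
    _check_kernel(M, B.shape[1])
    _check_kernel(M, C.shape[0])
    return bma_matrix(B, M), bma_matrix(C.T, M)


def fuse(S_first: np.ndarray, S_second: np.ndarray, weight: float) -> np.ndarray:
    """Convex combination ``weight * S_first + (1 - weight) * S_second``."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"fusion weight must be in [0, 1], got {weight}")
    a, b = np.asarray(S_first, float), np.asarray(S_second, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return weight * a + (1.0 - weight) * b


def compute_bundle(
    network: HeterogeneousNetwork,
    ontology: DiseaseOntology,
    alpha: float = 0.9,
    beta: float = 0.8,
    delta: float = DEFAULT_DELTA,
    A_override: np.ndarray | None = None,
) -> SimilarityBundle:
    """Compute every similarity matrix for one network.

    ``A_override`` substitutes for the association matrix in every A-derived
    similarity (L, L1, D1 and hence Lc, Dc); the cross-validation protocol
    uses it to recompute similarities with held-out test associations masked
    out. B/C-derived matrices (M, L2, D2) and the ontology-derived D do not
    depend on A.
    """
    A = network.A if A_override is None else np.asarray(A_override, float)
    D = semantic_similarity(ontology, network.disease_ids, delta)
    L = functional_similarity(A, D)
    L1, D1 = first_kind_similarities(A, L, D)
    M = mirna_kernel(network.C, D)
    L2, D2 = second_kind_similarities(network.B, network.C, M)
    return SimilarityBundle(
        L=L,
        D=D,
        L1=L1,
        D1=D1,
        L2=L2,
        D2=D2,
        M=M,
        Lc=fuse(L1, L2, alpha),
        Dc=fuse(D1, D2, beta),
        alpha=alpha,
        beta=beta,
    )


def _check_kernel(kernel: np.ndarray, size: int) -> None:
    k = np.asarray(kernel)
    if k.shape != (size, size):
        raise ValueError(f"kernel shape {k.shape} does not match universe size {size}")
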