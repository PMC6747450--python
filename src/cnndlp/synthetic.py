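"""Synthetic heterogeneous networks with planted group structure.

The generator emulates the statistical skeleton of the real tri-layer data
(lncRNA-disease, lncRNA-miRNA, miRNA-disease) without any external download:
every node is assigned one of ``g`` latent groups, and each bipartite edge is
drawn independently with probability ``p_in`` when its endpoints share a
group and ``p_out`` otherwise. Because all three graphs are coupled through
the same group assignment, the miRNA layer genuinely carries association
signal, mirroring the premise that miRNA interactions help lncRNA-disease
prediction.

The companion ontology generator builds a rooted tree of terms and maps
diseases to leaves in group order, so diseases in the same latent group sit
under nearby ancestors and their Wang-style semantic similarity correlates
with the planted groups.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .netio import DiseaseOntology, HeterogeneousNetwork

__all__ = ["SyntheticSpec", "generate_network", "generate_ontology", "write_dataset"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the planted-group generator.

    Defaults are the package's standard study conditions: 60 lncRNAs, 40
    diseases, 50 miRNAs in 4 groups, within-group edge probability 0.4
    against a 0.02 background — dense enough that held-out associations are
    recoverable, sparse enough that the positive:negative imbalance is
    severe, as in the real data.
    """

    n_lncrna: int = 60
    n_disease: int = 40
    n_mirna: int = 50
    n_groups: int = 4
    p_in: float = 0.4
    p_out: float = 0.02
    ontology_depth: int = 4
    ontology_branching: int = 3
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < 1.0 or not 0.0 < self.p_in <= 1.0:
            raise ValueError("probabilities must satisfy 0 <= p_out < p_in <= 1")
        if self.p_out >= self.p_in:
            raise ValueError("p_out must be strictly below p_in")
        if min(self.n_lncrna, self.n_disease, self.n_mirna) < self.n_groups:
            raise ValueError("each node class needs at least n_groups members")
        if self.ontology_depth < 1 or self.ontology_branching < 1:
            raise ValueError("ontology depth and branching must be >= 1")


@dataclasses.dataclass
class GroupTruth:
    """Planted group assignment per node class."""

    lncrna: np.ndarray
    disease: np.ndarray
    mirna: np.ndarray


def _group_assign(rng: np.random.Generator, n: int, g: int) -> np.ndarray:
    # Every group is guaranteed at least one member before uniform fill.
    base = np.arange(g)
    rest = rng.integers(0, g, size=n - g)
    groups = np.concatenate([base, rest])
    rng.shuffle(groups)
    return groups


def _block_graph(
    rng: np.random.Generator,
    rows: np.ndarray,
    cols: np.ndarray,
    p_in: float,
    p_out: float,
) -> np.ndarray:
    same = rows[:, None] == cols[None, :]
    p = np.where(same, p_in, p_out)
    return (rng.random(p.shape) < p).astype(float)


def generate_network(spec: SyntheticSpec) -> tuple[HeterogeneousNetwork, GroupTruth]:
    """Draw a coupled three-graph network; reproducible for a given seed."""
    rng = np.random.default_rng(spec.seed)
    gl = _group_assign(rng, spec.n_lncrna, spec.n_groups)
    gd = _group_assign(rng, spec.n_disease, spec.n_groups)
    gm = _group_assign(rng, spec.n_mirna, spec.n_groups)
    A = _block_graph(rng, gl, gd, spec.p_in, spec.p_out)
    B = _block_graph(rng, gl, gm, spec.p_in, spec.p_out)
    C = _block_graph(rng, gm, gd, spec.p_in, spec.p_out)
    net = HeterogeneousNetwork(
        lncrna_ids=[f"l{i + 1}" for i in range(spec.n_lncrna)],
        disease_ids=[f"d{j + 1}" for j in range(spec.n_disease)],
        mirna_ids=[f"m{k + 1}" for k in range(spec.n_mirna)],
        A=A,
        B=B,
        C=C,
    )
    return net, GroupTruth(lncrna=gl, disease=gd, mirna=gm)


def generate_ontology(
    n_disease: int,
    depth: int,
    branching: int,
    seed: int,
    groups: np.ndarray | None = None,
) -> DiseaseOntology:
    """Random rooted term tree with diseases mapped to leaves.

    The tree has the given depth and branching factor (leaves = branching **
    depth); an error is raised if there are fewer leaves than diseases. When
    ``groups`` is given, diseases are ordered by group before being assigned
    to consecutive leaves in tree order, so same-group diseases share deeper
    ancestors than cross-group ones.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n_leaves = branching**depth
    if n_leaves < n_disease:
        raise ValueError(
            f"tree with depth {depth} and branching {branching} has {n_leaves} "
            f"leaves, fewer than {n_disease} diseases"
        )
    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()
    level = ["root"]
    for d in range(1, depth + 1):
        nxt = []
        for parent in level:
            for b in range(branching):
                child = f"{parent}.{b}"
                edges.add((child, parent))
                nxt.append(child)
        level = nxt
    leaves = level  # depth-first order: adjacent leaves share deep ancestors

    disease_ids = [f"d{j + 1}" for j in range(n_disease)]
    if groups is None:
        order = rng.permutation(n_disease)
    else:
        # Stable sort by group with a seeded shuffle inside each group.
        jitter = rng.random(n_disease)
        order = np.lexsort((jitter, np.asarray(groups)))
    # Spread leaf picks evenly so grouped diseases occupy contiguous subtrees.
    leaf_slots = np.linspace(0, n_leaves - 1, n_disease).round().astype(int)
    mapping = {
        disease_ids[node]: leaves[leaf_slots[pos]] for pos, node in enumerate(order)
    }
    terms = {"root"} | {c for c, _ in edges} | {p for _, p in edges}
    return DiseaseOntology(terms=terms, parent_edges=edges, disease_to_term=mapping)


def write_dataset(spec: SyntheticSpec, outdir: str | Path) -> GroupTruth:
    """Generate a network + ontology and write the standard file layout.

    Produces the node lists, edge lists, ontology TSV and disease->term
    mapping consumed by :func:`cnndlp.netio.load_network`. Returns the
    planted group truth (also written as ``groups.tsv`` for reference).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, truth = generate_network(spec)
    onto = generate_ontology(
        spec.n_disease,
        spec.ontology_depth,
        spec.ontology_branching,
        spec.seed + 1,
        groups=truth.disease,
    )
    for name, ids in (
        ("lncrnas.txt", net.lncrna_ids),
        ("diseases.txt", net.disease_ids),
        ("mirnas.txt", net.mirna_ids),
    ):
        (outdir / name).write_text("\n".join(ids) + "\n")
    _write_edges(outdir / "lncrna_disease.tsv", net.A, net.lncrna_ids, net.disease_ids)
    _write_edges(outdir / "lncrna_mirna.tsv", net.B, net.lncrna_ids, net.mirna_ids)
    _write_edges(outdir / "mirna_disease.tsv", net.C, net.mirna_ids, net.disease_ids)
    with (outdir / "ontology.tsv").open("w") as fh:
        for child, parent in sorted(onto.parent_edges):
            fh.write(f"{child}\t{parent}\n")
    with (outdir / "disease_terms.tsv").open("w") as fh:
        for d in net.disease_ids:
            fh.write(f"{d}\t{onto.disease_to_term[d]}\n")
    with (outdir / "groups.tsv").open("w") as fh:
        for ids, assign in (
            (net.lncrna_ids, truth.lncrna),
            (net.disease_ids, truth.disease),
            (net.mirna_ids, truth.mirna),
        ):
            for node, grp in zip(ids, assign):
                fh.write(f"{node}\t{grp}\n")
    return truth


def _write_edges(path: Path, m: np.ndarray, row_ids: list[str], col_ids: list[str]) -> None:
    with path.open("w") as fh:
        for i, j in zip(*np.nonzero(m)):
            fh.write(f"{row_ids[i]}\t{col_ids[j]}\n")
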