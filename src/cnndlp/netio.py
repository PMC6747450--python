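"""Data model and file I/O for the heterogeneous lncRNA-disease-miRNA network.

The method operates on three coupled bipartite graphs held as dense binary
matrices:

* ``A`` (Nl x Nd) -- lncRNA-disease associations,
* ``B`` (Nl x Nm) -- lncRNA-miRNA interactions,
* ``C`` (Nm x Nd) -- miRNA-disease associations,

together with a disease ontology DAG used for semantic similarity. Node
universes are supplied as explicit id lists so that isolated nodes (degree 0)
are representable; edge lists are two-column TSV files of ids.

Matrix files are TSV with the column ids in the first row and the row id as
the first field of every data row. All matrices are dense: at the scale this
method targets (a few hundred nodes per class) sparsity buys nothing and
dense arrays feed directly into the convolutional model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HeterogeneousNetwork",
    "DiseaseOntology",
    "RankedPredictions",
    "load_node_list",
    "load_edge_list",
    "load_ontology",
    "load_network",
    "save_matrix",
    "load_matrix",
]


@dataclasses.dataclass
class HeterogeneousNetwork:
    """The three bipartite adjacency matrices plus node-id indices.

    Invariants: all matrix entries are 0/1, shapes agree with the id lists,
    and id lists contain no duplicates (checked in ``__post_init__``).
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    mirna_ids: list[str]
    A: np.ndarray  # Nl x Nd
    B: np.ndarray  # Nl x Nm
    C: np.ndarray  # Nm x Nd

    def __post_init__(self) -> None:
        for name, ids in (
            ("lncrna_ids", self.lncrna_ids),
            ("disease_ids", self.disease_ids),
            ("mirna_ids", self.mirna_ids),
        ):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate ids in {name}")
        nl, nd, nm = len(self.lncrna_ids), len(self.disease_ids), len(self.mirna_ids)
        expected = {"A": (nl, nd), "B": (nl, nm), "C": (nm, nd)}
        for name, shape in expected.items():
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != shape:
                raise ValueError(f"matrix {name} has shape {m.shape}, expected {shape}")
            if not np.isin(m, (0.0, 1.0)).all():
                raise ValueError(f"matrix {name} has non-binary entries")
            setattr(self, name, m)

    @property
    def n_lncrna(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)


@dataclasses.dataclass
class DiseaseOntology:
    """A disease-term DAG plus the disease -> term mapping.

    ``parent_edges`` is a set of ``(child, parent)`` pairs; the relation must
    be acyclic. Several diseases may map to the same term.
    """

    terms: set[str]
    parent_edges: set[tuple[str, str]]
    disease_to_term: dict[str, str]

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        for disease, term in self.disease_to_term.items():
            if term not in self.terms:
                raise ValueError(f"disease {disease!r} maps to unknown term {term!r}")

    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph over all terms (isolated terms included)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.parent_edges)
        return g

    def roots(self) -> set[str]:
        children = {c for c, _ in self.parent_edges}
        return self.terms - children


@dataclasses.dataclass
class RankedPredictions:
    """Per-disease ranked candidate lists.

    ``rows`` holds (disease id, lncRNA id, score, rank, known) tuples; within
    each disease ranks are 1..n with non-increasing scores.
    """

    rows: list[tuple[str, str, float, int, bool]]

    def __post_init__(self) -> None:
        by_disease: dict[str, list[tuple[int, float]]] = {}
        for d, _, score, rank, _ in self.rows:
            by_disease.setdefault(d, []).append((rank, score))
        for d, entries in by_disease.items():
            entries.sort()
            ranks = [r for r, _ in entries]
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(f"ranks for disease {d!r} are not 1..n")
            scores = [s for _, s in entries]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValueError(f"scores for disease {d!r} increase with rank")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["disease", "lncrna", "score", "rank", "known"]
        )

    def save(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("disease\tlncrna\tscore\trank\tknown\n")
            for d, l, score, rank, known in self.rows:
                fh.write(f"{d}\t{l}\t{score:.10f}\t{rank}\t{int(known)}\n")


def load_node_list(path: str | Path) -> list[str]:
    """Read one id per line; blank lines ignored."""
    ids = [line.strip() for line in Path(path).read_text().splitlines()]
    ids = [i for i in ids if i]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate ids in node list {path}")
    return ids


def load_edge_list(
    path: str | Path, row_ids: Sequence[str], col_ids: Sequence[str]
) -> np.ndarray:
    """Build a binary incidence matrix from a two-column TSV edge list.

    Entry (i, j) is 1 iff the pair appears at least once; duplicates are
    idempotent and line order is irrelevant. Unknown ids and malformed lines
    raise with the offending id / line number.
    """
    row_index = {r: i for i, r in enumerate(row_ids)}
    col_index = {c: j for j, c in enumerate(col_ids)}
    m = np.zeros((len(row_ids), len(col_ids)))
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two fields, got {len(fields)}")
        r, c = fields
        if r not in row_index:
            raise ValueError(f"{path}:{lineno}: unknown row id {r!r}")
        if c not in col_index:
            raise ValueError(f"{path}:{lineno}: unknown column id {c!r}")
        m[row_index[r], col_index[c]] = 1.0
    return m


def load_ontology(
    path: str | Path, disease_to_term: Mapping[str, str] | None = None
) -> DiseaseOntology:
    """Read a child TAB parent TSV into a :class:`DiseaseOntology`.

    Roots are terms that never appear as a child. If ``disease_to_term`` is
    omitted, every term doubles as a disease id mapping to itself.
    """
    edges: set[tuple[str, str]] = set()
    terms: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two fields, got {len(fields)}")
        child, parent = fields
        edges.add((child, parent))
        terms.update((child, parent))
    if disease_to_term is None:
        disease_to_term = {t: t for t in terms}
    return DiseaseOntology(
        terms=terms, parent_edges=edges, disease_to_term=dict(disease_to_term)
    )


def load_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV of disease id -> ontology term id."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two fields, got {len(fields)}")
        mapping[fields[0]] = fields[1]
    return mapping


def load_network(datadir: str | Path) -> HeterogeneousNetwork:
    """Load the standard dataset layout written by ``cnndlp simulate``.

    Expects ``lncrnas.txt``, ``diseases.txt``, ``mirnas.txt`` node lists and
    ``lncrna_disease.tsv``, ``lncrna_mirna.tsv``, ``mirna_disease.tsv`` edge
    lists under ``datadir``.
    """
    datadir = Path(datadir)
    lnc = load_node_list(datadir / "lncrnas.txt")
    dis = load_node_list(datadir / "diseases.txt")
    mir = load_node_list(datadir / "mirnas.txt")
    return HeterogeneousNetwork(
        lncrna_ids=lnc,
        disease_ids=dis,
        mirna_ids=mir,
        A=load_edge_list(datadir / "lncrna_disease.tsv", lnc, dis),
        B=load_edge_list(datadir / "lncrna_mirna.tsv", lnc, mir),
        C=load_edge_list(datadir / "mirna_disease.tsv", mir, dis),
    )


def save_matrix(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a labelled matrix as TSV (column ids in the header row)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {m.shape} inconsistent with {len(row_ids)} row ids "
            f"and {len(col_ids)} column ids"
        )
    with Path(path).open("w") as fh:
        fh.write("\t".join(["id", *col_ids]) + "\n")
        for rid, row in zip(row_ids, m):
            fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix written by :func:`save_matrix`.

    Returns ``(matrix, row_ids, col_ids)``; values round-trip to at least 12
    significant digits. Ragged rows or a header inconsistent with the data
    rows raise.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(col_ids) + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {len(col_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        row_ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    return np.array(rows, dtype=float).reshape(len(row_ids), len(col_ids)), row_ids, col_ids
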