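"""Molecular similarity networks (and generic similarity-matrix networks).

Nodes are molecules (or arbitrary identifiers), edges are pairwise
similarities at or above a cutoff. Molecular similarity is Tanimoto over
circular (Morgan) fingerprints; the same topology construction accepts
any precomputed symmetric similarity matrix, e.g. from sequence
alignments. Isolated nodes are kept so below-cutoff members stay visible.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .chem_core import MoleculeRecord, fingerprint, tanimoto

__all__ = [
    "build_similarity_network",
    "build_from_matrix",
    "export_graph",
    "read_graphml",
]


def build_similarity_network(mols: list[MoleculeRecord], cutoff: float) -> nx.Graph:
    """All-pairs Tanimoto network over circular fingerprints.

    Edge kept iff similarity >= cutoff; self-pairs are excluded by
    construction. Node identifiers must be unique.
    """
    if len(mols) < 2:
        raise ValueError("similarity network requires >= 2 molecules")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    ids = [m.identifier or m.key for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node identifiers")
    g = nx.Graph(cutoff=cutoff)
    fps = [fingerprint(m, "circular") for m in mols]
    for i, m in enumerate(mols):
        g.add_node(ids[i], structure=m.structure)
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            w = tanimoto(fps[i], fps[j])
            if w >= cutoff:
                g.add_edge(ids[i], ids[j], weight=w)
    return g


def build_from_matrix(ids: list[str], matrix, cutoff: float) -> nx.Graph:
    """Network from a precomputed square symmetric similarity matrix.

    The diagonal is ignored (expected to be the unit self-similarity);
    asymmetry beyond 1e-9 is an error.
    """
    mat = np.asarray(matrix, dtype=float)
    n = len(ids)
    if mat.shape != (n, n):
        raise ValueError(f"matrix shape {mat.shape} does not match {n} ids")
    if len(set(ids)) != n:
        raise ValueError("duplicate node identifiers")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("similarity matrix is asymmetric beyond tolerance")
    g = nx.Graph(cutoff=cutoff)
    g.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= cutoff:
                g.add_edge(ids[i], ids[j], weight=float(mat[i, j]))
    return g


def export_graph(g: nx.Graph, path: str, format: str = "graphml") -> None:
    """Write GraphML (lossless round trip) or SIF plus an edge-weight TSV."""
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(g.edges()):
                fh.write(f"{u}\tsim\t{v}\n")
            for node in sorted(g.nodes()):
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
        with open(str(path) + ".weights.tsv", "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6f}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graphml(path: str) -> nx.Graph:
    return nx.read_graphml(path)
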