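"""Clonal lineage as a minimum spanning tree over subclone genotypes.

Once subclone genotypes are inferred, their evolutionary relationship is
approximated by the MST of the complete graph over the genotypes (plus an
all-zero root representing the unmutated normal state), with Hamming
distance as the edge weight.  Under infinite-sites-like evolution the MST of
the true clone genotypes recovers the ancestry chain, and on real data it is
a cheap, assumption-light lineage sketch.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class LineageTree:
    """MST over subclone genotypes.

    ``genotypes`` stacks the node genotypes (row 0 is the zero-genotype root
    when present); ``edges`` are (u, v, weight) with u < v; ``root`` is the
    display root index.
    """

    genotypes: np.ndarray
    edges: list[tuple[int, int, int]]
    root: int
    has_root_node: bool


def build_mst(C, include_root: bool = True) -> LineageTree:
    """Minimum spanning tree of the subclone genotypes.

    Edges of the complete graph are weighted by Hamming distance and
    inserted in lexicographic order so Kruskal's tie-breaking is
    deterministic.  Duplicate genotypes are allowed (zero-weight edges).
    """
    C = np.atleast_2d(np.asarray(C, dtype=np.int8))
    if C.shape[0] < 1:
        raise ValueError("need at least one subclone genotype")
    nodes = (np.vstack([np.zeros((1, C.shape[1]), dtype=np.int8), C])
             if include_root else C)
    n = nodes.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(u + 1, n):
            g.add_edge(u, v, weight=int(np.sum(nodes[u] != nodes[v])))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted((min(u, v), max(u, v), d["weight"])
                   for u, v, d in mst.edges(data=True))
    return LineageTree(genotypes=nodes, edges=edges, root=0,
                       has_root_node=include_root)


def total_weight(tree: LineageTree) -> int:
    return sum(w for _, _, w in tree.edges)


def to_newick(tree: LineageTree, sizes=None) -> str:
    """Newick string rooted at the tree's root, branch lengths = weights.

    ``sizes`` (cells per subclone, ordered like the non-root nodes) are
    embedded as bracketed comments after each subclone label.
    """
    adj: dict[int, list[tuple[int, int]]] = {
        i: [] for i in range(tree.genotypes.shape[0])}
    for u, v, w in tree.edges:
        adj[u].append((v, w))
        adj[v].append((u, w))

    def label(v: int) -> str:
        if tree.has_root_node and v == 0:
            return "root"
        k = v - 1 if tree.has_root_node else v
        name = f"clone_{k}"
        if sizes is not None:
            name += f"[{int(sizes[k])}]"
        return name

    def fmt(v: int, parent: int) -> str:
        kids = [(c, w) for c, w in adj[v] if c != parent]
        if not kids:
            return label(v)
        inner = ",".join(f"{fmt(c, v)}:{w}" for c, w in kids)
        return f"({inner}){label(v)}"

    return fmt(tree.root, -1) + ";"


def edges_to_tsv(tree: LineageTree, path) -> None:
    """Write the edge list as TSV (parent, child, weight) rooted at root."""
    with open(path, "wt") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, w in tree.edges:
            fh.write(f"{u}\t{v}\t{w}\n")
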