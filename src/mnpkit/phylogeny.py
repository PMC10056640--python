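"""Neighbor-joining trees from MNP-derived distances, plus Newick export.

The agglomeration is the classical Saitou–Nei algorithm: at each step join
the pair minimizing Q[i][j] = (n−2)·d[i][j] − Σ_k d[i][k] − Σ_k d[j][k],
with branch lengths from the standard two-point formulas, negative lengths
clamped to zero, and reduced distances d[u][k] = (d[i][k]+d[j][k]−d[i][j])/2.
Ties on Q break deterministically to the lexicographically smallest (i, j)
in the current node ordering. The result is an unrooted tree, represented
with a trifurcating root node.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
from skbio import TreeNode

from .genotyping import MISSING, CoreSet, GenotypeTable
from .similarity import GsMatrix


class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over named samples."""

    def __init__(self, samples: Sequence[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        n = len(samples)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.samples = list(samples)
        self.d = d

    def __len__(self) -> int:
        return len(self.samples)


def distance_from_gs(gsm: GsMatrix) -> DistanceMatrix:
    """d = 1 − GS."""
    return DistanceMatrix(gsm.samples, 1.0 - gsm.gs)


def distance_pdist(table: GenotypeTable, core: CoreSet | None = None) -> DistanceMatrix:
    """Per-site mismatch fraction over concatenated core-marker haplotypes."""
    markers = core.marker_ids if core is not None else table.markers
    concat = table.data[markers].agg("".join, axis=1)
    if concat.str.contains(rf"\{MISSING}", regex=True).any():
        raise ValueError("pdist distance requires a complete (core) genotype table")
    samples = list(concat.index)
    seqs = [np.frombuffer(s.encode(), dtype="S1") for s in concat]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("concatenated haplotypes differ in length")
    total = lengths.pop()
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = np.count_nonzero(seqs[i] != seqs[j]) / total
            d[i, j] = d[j, i] = mism
    return DistanceMatrix(samples, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Build the unrooted neighbor-joining tree for a distance matrix.

    Requires at least 3 samples; 2 samples yield the trivial two-leaf tree
    with the distance split evenly across the root.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("nj_tree requires at least 2 samples")
    nodes = [TreeNode(name=s) for s in dm.samples]
    if n == 2:
        nodes[0].length = nodes[1].length = dm.d[0, 1] / 2.0
        return TreeNode(children=nodes)

    d = dm.d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = np.full((m, m), np.inf)
        flat[iu] = q[iu]
        i, j = np.unravel_index(np.argmin(flat), flat.shape)  # row-major → lexicographic

        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new_node = TreeNode(children=[nodes[i], nodes[j]])

        dik = d[i, :]
        djk = d[j, :]
        dnew = (dik + djk - dij) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new_node]

    # final trifurcation: closed-form branch lengths for three nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(length, 0.0)
    return TreeNode(children=nodes)


def path_length_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path lengths of a tree, as a DistanceMatrix."""
    skdm = tree.tip_tip_distances()
    return DistanceMatrix(list(skdm.ids), skdm.data)


def to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths in 6-decimal fixed format."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            label = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            label += f":{node.length:.6f}"
        return label

    return fmt(tree) + ";"


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def tree_cut_partition(tree: TreeNode, k: int) -> dict[str, str]:
    """Cut the tree into ``k`` leaf clusters by removing its longest branches.

    Internal branches (not incident to a leaf) are considered first, longest
    first; pendant branches follow, so that any ``k`` up to the number of
    leaves is reachable. A cut that would strand a leafless fragment is
    skipped. Cluster labels C1, C2, ... are assigned by descending cluster
    size then lexicographically smallest member.
    """
    tips = [t.name for t in tree.tips()]
    if not (1 <= k <= len(tips)):
        raise ValueError(f"k={k} outside [1, {len(tips)}]")

    graph = nx.Graph()
    edges = []  # (internal_rank, -length, tiebreak, parent_id, child_id)
    ids: dict[int, TreeNode] = {}
    for node in tree.traverse(include_self=True):
        ids[id(node)] = node
        if node.parent is None:
            graph.add_node(id(node))
            continue
        graph.add_edge(id(node.parent), id(node))
        is_internal = not node.is_tip()
        tiebreak = min(t.name for t in node.tips()) if is_internal else node.name
        edges.append((0 if is_internal else 1, -(node.length or 0.0), tiebreak,
                      id(node.parent), id(node)))
    edges.sort()

    def leaf_clusters() -> list[list[str]]:
        out = []
        for comp in nx.connected_components(graph):
            names = sorted(ids[nid].name for nid in comp if ids[nid].is_tip())
            if names:
                out.append(names)
        return out

    for _, _, _, u, v in edges:
        if len(leaf_clusters()) >= k:
            break
        graph.remove_edge(u, v)
        if any(not any(ids[nid].is_tip() for nid in comp)
               for comp in nx.connected_components(graph)):
            graph.add_edge(u, v)  # would strand a leafless fragment

    clusters = leaf_clusters()
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return {name: f"C{rank}" for rank, comp in enumerate(clusters, 1) for name in comp}


def annotate_leaves(
    tree: TreeNode,
    metadata: Mapping[str, "SampleRecord"],
    partition: Mapping[str, str],
    path: str | Path | None = None,
) -> list[dict[str, str]]:
    """Per-leaf annotation rows (pedigree, cap color, source) for display tools.

    ``metadata`` maps sample id → record with ``cap_color`` and ``source``
    attributes; every leaf must be covered. Written as TSV when ``path``
    is given, in a form consumable by iTOL-style annotation pipelines.
    """
    rows = []
    for tip in tree.tips():
        name = tip.name
        if name not in metadata:
            raise KeyError(f"leaf {name!r} has no metadata record")
        rec = metadata[name]
        rows.append({
            "leaf": name,
            "pedigree": partition.get(name, ""),
            "cap_color": rec.cap_color,
            "source": rec.source,
        })
    if path is not None:
        with open(path, "w") as fh:
            fh.write("leaf\tpedigree\tcap_color\tsource\n")
            for row in rows:
                fh.write(f"{row['leaf']}\t{row['pedigree']}\t{row['cap_color']}\t{row['source']}\n")
    return rows
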