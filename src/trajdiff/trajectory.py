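"""Cluster-based minimum-spanning-tree pseudotime construction.

Cells in the harmonized embedding are grouped by k-means; a Euclidean minimum
spanning tree over the cluster centers gives the trajectory backbone.  After
the user designates an origin cluster (directly, or via marker genes that
should peak at the start), every root-to-leaf cluster sequence is a branch;
branches passing through the same early clusters share those cells.  Each
cell's pseudotime is the arc length from the origin end of its branch to its
orthogonal projection on the nearest backbone segment flanking its own
cluster, rescaled per branch to [0, 1] before model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger("trajdiff")

ELBOW_KMIN = 2
ELBOW_KMAX = 25
ELBOW_REL_DROP = 0.10


@dataclass
class Branch:
    """One root-to-leaf path of the trajectory tree."""

    clusters: tuple           # ordered cluster sequence from origin
    member_cells: np.ndarray  # cell ids on the sequence's clusters
    pseudotime: dict          # cell id -> arc-length pseudotime (raw units)
    scaled_pseudotime: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return "->".join(str(c) for c in self.clusters)

    def __post_init__(self):
        if not self.scaled_pseudotime and self.pseudotime:
            vals = np.array(list(self.pseudotime.values()))
            lo, hi = vals.min(), vals.max()
            span = hi - lo if hi > lo else 1.0
            self.scaled_pseudotime = {
                c: (v - lo) / span for c, v in self.pseudotime.items()
            }


@dataclass
class TrajectoryTree:
    n_clusters: int
    cluster_of_cell: np.ndarray     # cluster id per cell
    centers: np.ndarray             # n_clusters x D
    mst_edges: list                 # (i, j, weight) tuples
    origin_cluster: int = None
    branches: list = field(default_factory=list)
    cell_ids: np.ndarray = None

    def validate(self):
        if len(self.mst_edges) != self.n_clusters - 1:
            raise ValueError("MST must have n_clusters - 1 edges")
        g = nx.Graph()
        g.add_nodes_from(range(self.n_clusters))
        g.add_edges_from((i, j) for i, j, _ in self.mst_edges)
        if not nx.is_connected(g):
            raise ValueError("MST does not span all clusters")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _wss_curve(embedding, ks, seed):
    wss = []
    for k in ks:
        if k == 1:
            wss.append(float(((embedding - embedding.mean(0)) ** 2).sum()))
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(embedding)
        wss.append(km.inertia_)
    return np.array(wss)


def choose_k_elbow(embedding, seed: int = 1,
                   kmin: int = ELBOW_KMIN, kmax: int = ELBOW_KMAX) -> int:
    """Elbow rule: smallest k whose next cluster explains < 10% more of the
    total variance (within-cluster SS drop relative to the k=1 baseline)."""
    kmax = min(kmax, embedding.shape[0] - 1)
    ks = list(range(kmin, kmax + 2))
    wss = _wss_curve(embedding, ks, seed)
    total = _wss_curve(embedding, [1], seed)[0]
    if total <= 0:
        return kmin
    for i in range(len(ks) - 1):
        if (wss[i] - wss[i + 1]) / total < ELBOW_REL_DROP:
            return ks[i]
    return kmax


def cluster_cells(embedding, k: int | None = None, seed: int = 1):
    """K-means clustering of cells in the embedding.

    When ``k`` is absent it is chosen by the elbow rule.  Ten restarts; the
    best-inertia solution is kept.  Cells are presented to k-means in a
    canonical (lexicographic coordinate) order so that, at a fixed seed, the
    assignment is invariant to permutations of the input rows.
    """
    embedding = np.asarray(embedding, dtype=float)
    if k is None:
        k = choose_k_elbow(embedding, seed=seed)
    if k < 2:
        raise ValueError("k must be >= 2")
    if embedding.shape[0] < k:
        raise ValueError("fewer cells than clusters")
    order = np.lexsort(embedding.T[::-1])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(embedding[order])
    labels = np.empty(embedding.shape[0], dtype=int)
    labels[order] = km.labels_
    return labels, km.cluster_centers_


# ---------------------------------------------------------------------------
# Spanning tree and branches
# ---------------------------------------------------------------------------

def build_mst(centers) -> list:
    """Euclidean minimum spanning tree over cluster centers.

    Ties are broken deterministically by lower cluster index (edges are
    inserted in lexicographic order and Kruskal's sort is stable).
    """
    centers = np.asarray(centers, dtype=float)
    n = centers.shape[0]
    if n < 2:
        raise ValueError("need at least 2 centers")
    if not np.all(np.isfinite(centers)):
        raise ValueError("non-finite center coordinates")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    dup = False
    for i in range(n):
        for j in range(i + 1, n):
            w = float(np.linalg.norm(centers[i] - centers[j]))
            if w == 0:
                dup = True
            g.add_edge(i, j, weight=w)
    if dup:
        logger.warning("duplicate centers; MST tie broken by lower index")
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return sorted((min(i, j), max(i, j), d["weight"])
                  for i, j, d in mst.edges(data=True))


def origin_from_markers(dataset, marker_genes, cluster_of_cell) -> int:
    """Origin = cluster with the highest mean marker expression."""
    missing = [g for g in marker_genes if g not in set(dataset.gene_ids)]
    if missing:
        raise KeyError(f"marker genes absent from dataset: {missing}")
    expr = np.vstack([dataset.gene_values(g) for g in marker_genes]).mean(axis=0)
    clusters = np.unique(cluster_of_cell)
    means = [expr[cluster_of_cell == c].mean() for c in clusters]
    return int(clusters[int(np.argmax(means))])


def root_and_enumerate(mst_edges, origin: int, n_clusters: int) -> list:
    """Enumerate branches: one ordered cluster sequence per root-to-leaf path.

    Nodes with degree > 2 are branching points; paths through them share the
    upstream clusters, so early cells belong to every downstream branch.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_clusters))
    g.add_edges_from((i, j) for i, j, _ in mst_edges)
    if origin not in g:
        raise ValueError(f"origin cluster {origin} not in tree")
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1 and n != origin)
    if not leaves:  # single-node tree
        return [(origin,)]
    return [tuple(nx.shortest_path(g, origin, leaf)) for leaf in leaves]


def _project_to_segment(points, a, b, lo=0.0, hi=1.0):
    """Orthogonal projection of points onto segment a-b.

    The projection parameter is clipped to [lo, hi]; terminal segments pass
    infinite bounds so cells beyond the first/last center keep their order
    instead of collapsing onto the endpoint.  Returns (offset along the
    segment in arc-length units, squared distance to the projection)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        off = np.zeros(points.shape[0])
    else:
        off = np.clip((points - a) @ ab / denom, lo, hi)
    proj = a + off[:, None] * ab
    d2 = ((points - proj) ** 2).sum(axis=1)
    return off * np.sqrt(denom), d2


def assign_pseudotime(cluster_sequence, embedding, cluster_of_cell,
                      cell_ids=None):
    """Arc-length pseudotime for cells on a branch's cluster sequence.

    Each cell is projected onto the nearest of the backbone segments flanking
    its own cluster; pseudotime is the arc length from the origin end to the
    projection.  Ties (equidistant segments) resolve to the earlier segment.
    """
    seq = list(cluster_sequence)
    if len(seq) == 0:
        raise ValueError("empty branch")
    embedding = np.asarray(embedding, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(embedding.shape[0])
    member = np.isin(cluster_of_cell, seq)
    cells = np.flatnonzero(member)
    pt = {}
    if len(seq) == 1:
        for c in cells:
            pt[cell_ids[c]] = 0.0
        return pt
    # cumulative arc length at each center
    cum = np.zeros(len(seq))
    for i in range(1, len(seq)):
        cum[i] = cum[i - 1] + np.linalg.norm(
            embedding_center(seq[i], embedding, cluster_of_cell)
            - embedding_center(seq[i - 1], embedding, cluster_of_cell)
        )
    centers = {c: embedding_center(c, embedding, cluster_of_cell) for c in seq}
    pos_in_seq = {c: i for i, c in enumerate(seq)}
    n_seg = len(seq) - 1
    for c in cells:
        i = pos_in_seq[cluster_of_cell[c]]
        candidates = []
        for j in ([i - 1, i] if 0 < i < len(seq) - 1 else
                  [i] if i == 0 else [i - 1]):
            a, b = centers[seq[j]], centers[seq[j + 1]]
            lo = -np.inf if j == 0 else 0.0
            hi = np.inf if j == n_seg - 1 else 1.0
            off, d2 = _project_to_segment(embedding[c][None, :], a, b,
                                          lo=lo, hi=hi)
            candidates.append((float(d2[0]), j, float(off[0])))
        d2best, jbest, off = min(candidates, key=lambda z: (z[0], z[1]))
        pt[cell_ids[c]] = cum[jbest] + off
    # shift so the branch's origin end sits at pseudotime zero
    lo = min(pt.values())
    return {k: v - lo for k, v in pt.items()}


def embedding_center(cluster, embedding, cluster_of_cell):
    return embedding[cluster_of_cell == cluster].mean(axis=0)


# ---------------------------------------------------------------------------
# End-to-end construction
# ---------------------------------------------------------------------------

def build_trajectory(
    embedding,
    cell_ids=None,
    k: int | None = None,
    origin: int | None = None,
    marker_dataset=None,
    marker_genes=None,
    seed: int = 1,
) -> TrajectoryTree:
    """Cluster, span, root and enumerate: the full backbone construction.

    The origin is either a cluster id or derived from marker genes
    (``marker_dataset`` + ``marker_genes``).
    """
    embedding = np.asarray(embedding, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(embedding.shape[0])
    cell_ids = np.asarray(cell_ids, dtype=object)
    labels, centers = cluster_cells(embedding, k=k, seed=seed)
    # recompute centers as assignment means so projections match clusters
    centers = np.vstack([embedding[labels == c].mean(axis=0)
                         for c in range(centers.shape[0])])
    edges = build_mst(centers)
    if origin is None:
        if marker_genes is None or marker_dataset is None:
            raise ValueError("provide origin cluster or marker genes")
        origin = origin_from_markers(marker_dataset, marker_genes, labels)
    sequences = root_and_enumerate(edges, origin, centers.shape[0])
    branches = []
    for seq in sequences:
        pt = assign_pseudotime(seq, embedding, labels, cell_ids=cell_ids)
        member = np.array([cid for cid in cell_ids if cid in pt], dtype=object)
        branches.append(Branch(clusters=seq, member_cells=member, pseudotime=pt))
    tree = TrajectoryTree(
        n_clusters=centers.shape[0], cluster_of_cell=labels, centers=centers,
        mst_edges=edges, origin_cluster=int(origin), branches=branches,
        cell_ids=cell_ids,
    )
    tree.validate()
    return tree


def cell_pseudotime(tree: TrajectoryTree) -> pd.Series:
    """Raw arc-length pseudotime per cell (shared clusters agree across
    branches since all branches start at the same origin)."""
    pt = {}
    for br in tree.branches:
        pt.update(br.pseudotime)
    return pd.Series(pt, dtype=float)


def branch_table(tree: TrajectoryTree) -> pd.DataFrame:
    rows = []
    for br in tree.branches:
        for cid in br.member_cells:
            rows.append((cid, br.name, br.pseudotime[cid],
                         br.scaled_pseudotime[cid]))
    return pd.DataFrame(
        rows, columns=["cell_id", "branch_id", "pseudotime_raw",
                       "pseudotime_scaled"])
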