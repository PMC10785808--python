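"""Shortest path map (SPM) construction.

A protein is turned into a residue graph: nodes are residues, and an edge
joins residues *i, j* whenever their Cα atoms stay on average closer than a
cutoff (6 Å by default).  Each edge carries the dimensionless length

    l_ij = −ln |C_ij|,

where C_ij is the dynamic cross-correlation of the two residues' Cα
displacements from a common reference (the medoid of the most populated
conformational cluster),

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩).

Strongly (anti)correlated neighbours get short ("heavy") edges.  One
shortest path is then computed for every unordered residue pair; edges are
scored by how many of those paths traverse them, normalized so the busiest
edge scores 1, and the map keeps edges whose normalized weight exceeds a
threshold (0.3 by default).  A residue's *prominence* is the number of
pair-paths in which it appears strictly between the endpoints — the raw
per-residue SPM score used for cross-method comparison.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import ConsistencyError, CorrelationRangeError, InsufficientDataError
from .trajectory import (
    ResidueIndexMap,
    ScoreVector,
    TrajectoryEnsemble,
    kabsch_superpose,
)

logger = logging.getLogger(__name__)

#: Contact criterion: mean Cα–Cα distance strictly below this (Å).
DEFAULT_CONTACT_CUTOFF = 6.0
#: Keep edges whose normalized usage strictly exceeds this.
DEFAULT_WEIGHT_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# Cluster reference


@dataclass
class ClusterReference:
    """Representative (medoid) Cα frame of the most populated cluster."""

    frame: np.ndarray
    frame_index: int
    labels: np.ndarray
    cluster_sizes: dict[int, int]


def _pairwise_ca_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs Cα RMSD after optimal superposition of each pair."""
    f = coords.shape[0]
    rmsd = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            _, r = kabsch_superpose(coords[j], coords[i])
            rmsd[i, j] = rmsd[j, i] = r
    return rmsd


def reference_from_clustering(
    ensemble: TrajectoryEnsemble,
    method: str = "average",
    cutoff: float | None = 1.0,
    k: int | None = None,
    max_frames: int | None = None,
) -> ClusterReference:
    """Pick the reference frame by hierarchical clustering on Cα RMSD.

    Frames are clustered (scipy hierarchical clustering, ``method`` linkage)
    on the matrix of pairwise Cα RMSDs after pairwise superposition; the
    returned frame is the medoid of the most populated cluster.  Pass either
    a distance ``cutoff`` (Å) or a cluster count ``k``.  ``max_frames``
    limits clustering to an evenly spaced frame subset (the medoid is still
    a genuine ensemble frame).
    """
    ca = ensemble.calpha()
    if ca.n_frames == 1:
        return ClusterReference(ca.frame(0).copy(), 0, np.array([1]), {1: 1})
    if max_frames is not None and ca.n_frames > max_frames:
        subset = np.linspace(0, ca.n_frames - 1, max_frames).round().astype(int)
        subset = np.unique(subset)
    else:
        subset = np.arange(ca.n_frames)
    rmsd = _pairwise_ca_rmsd(ca.coordinates[subset])
    z = linkage(squareform(rmsd, checks=False), method=method)
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        labels = fcluster(z, t=cutoff, criterion="distance")
    counts = np.bincount(labels)
    top = int(np.argmax(counts))  # ties: lowest label wins (deterministic)
    members = np.flatnonzero(labels == top)
    medoid_local = members[int(np.argmin(rmsd[np.ix_(members, members)].sum(axis=1)))]
    sizes = {int(lbl): int(c) for lbl, c in enumerate(counts) if lbl > 0 and c > 0}
    logger.info("cluster sizes %s; representative frame %d", sizes, subset[medoid_local])
    return ClusterReference(
        frame=ca.frame(int(subset[medoid_local])).copy(),
        frame_index=int(subset[medoid_local]),
        labels=labels,
        cluster_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Correlation matrix


@dataclass
class CorrelationMatrix:
    """Dynamic cross-correlation C_ij of Cα displacements, in [−1, 1]."""

    values: np.ndarray
    residue_map: ResidueIndexMap
    reference: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        residues = list(self.residue_map.author_numbers)
        pd.DataFrame(self.values, index=residues, columns=residues).to_csv(
            path, sep="\t", index_label="residue"
        )


def correlation_matrix(
    ensemble: TrajectoryEnsemble,
    reference: np.ndarray | ClusterReference,
    fit: bool = True,
) -> CorrelationMatrix:
    """Cα displacement cross-correlation relative to a reference frame.

    Each frame is Kabsch-superposed onto the reference on all Cα atoms
    before displacements are measured (``fit=False`` skips this, appropriate
    for fixtures generated without global rigid motion).  Residues with zero
    displacement variance get a zeroed row/column (diagonal included) and a
    logged degeneracy warning.
    """
    if isinstance(reference, ClusterReference):
        reference = reference.frame
    ca = ensemble.calpha()
    if ca.n_frames < 2:
        raise InsufficientDataError("correlation needs at least 2 frames")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ca.n_atoms, 3):
        raise ConsistencyError("reference frame does not match the Calpha selection")
    disp = np.empty_like(ca.coordinates)
    for f in range(ca.n_frames):
        frame = ca.coordinates[f]
        if fit:
            frame, _ = kabsch_superpose(frame, reference)
        disp[f] = frame - reference
    inner = np.einsum("fik,fjk->ij", disp, disp)
    var = np.diag(inner).copy()
    degenerate = var <= 0
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, inner / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    if degenerate.any():
        bad = [ca.residue_map().to_author(i) for i in np.flatnonzero(degenerate)]
        logger.warning("zero displacement variance for residues %s", bad)
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    return CorrelationMatrix(corr, ca.residue_map(), reference)


# ---------------------------------------------------------------------------
# Contact graph


def contact_graph(
    ensemble: TrajectoryEnsemble, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> nx.Graph:
    """Undirected residue graph: edge iff mean Cα distance < cutoff (strict).

    Nodes are author residue numbers; edges carry ``mean_distance`` (Å).
    """
    ca = ensemble.calpha()
    mean_d = np.zeros(ca.n_atoms * (ca.n_atoms - 1) // 2)
    for f in range(ca.n_frames):
        mean_d += pdist(ca.coordinates[f])
    mean_d = squareform(mean_d / ca.n_frames)
    residues = ca.residue_map().author_numbers
    graph = nx.Graph(residue_numbers=tuple(residues))
    graph.add_nodes_from(residues)
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if mean_d[i, j] < cutoff:
                graph.add_edge(residues[i], residues[j], mean_distance=float(mean_d[i, j]))
    return graph


# ---------------------------------------------------------------------------
# Shortest path map


@dataclass
class SPMResult:
    """Edge table, thresholded map and per-residue prominence of one SPM."""

    edges: pd.DataFrame
    prominence: ScoreVector
    residue_map: ResidueIndexMap
    n_paths: int
    unreachable_pairs: int
    dropped_zero_correlation_edges: int
    threshold: float

    @property
    def thresholded_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["kept"]]

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for row in self.edges.itertuples():
            g.add_edge(
                int(row.residue_i),
                int(row.residue_j),
                length=float(row.length),
                usage=int(row.usage),
                normalized_weight=float(row.normalized_weight),
                kept=bool(row.kept),
            )
        nx.write_graphml(g, str(path))


def _deterministic_dijkstra(
    adjacency: list[list[tuple[int, float]]], n: int, source: int
) -> tuple[np.ndarray, np.ndarray]:
    """Dijkstra tree with lexicographic (min internal index) tie-breaking.

    Among equal-length routes into a node, the predecessor with the smallest
    internal index (restricted to nodes settled earlier, which keeps the
    predecessor graph acyclic even with zero-length edges) is chosen, so the
    returned tree — hence every per-pair path — is deterministic.
    """
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=int)
    settled = np.zeros(n, dtype=bool)
    dist[source] = 0.0
    heap: list[tuple[float, int]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if settled[u]:
            continue
        settled[u] = True
        for v, w in adjacency[u]:
            if settled[v]:
                continue
            nd = d + w
            eps = 1e-12 * max(1.0, abs(nd))
            if nd < dist[v] - eps:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif nd <= dist[v] + eps and (pred[v] == -1 or u < pred[v]):
                pred[v] = u
    return dist, pred


def spm_build(
    graph: nx.Graph,
    correlation: CorrelationMatrix,
    threshold: float = DEFAULT_WEIGHT_THRESHOLD,
) -> SPMResult:
    """Accumulate one shortest path per residue pair into the SPM.

    Edge lengths are ``−ln|C_ij|``; contact edges whose correlation is
    exactly zero are infinitely long and dropped.  Usage counts are
    normalized so the busiest edge weighs 1; the thresholded map keeps edges
    with weight strictly above ``threshold``.
    """
    residues = tuple(graph.graph.get("residue_numbers", sorted(graph.nodes)))
    rmap = ResidueIndexMap(residues)
    if set(residues) != set(graph.nodes) or len(residues) != correlation.n_residues:
        raise ConsistencyError("graph and correlation matrix disagree on residues")
    n = len(residues)

    adjacency: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    edge_lengths: dict[tuple[int, int], float] = {}
    dropped = 0
    for a, b in graph.edges:
        i, j = rmap.to_internal(a), rmap.to_internal(b)
        c = abs(float(correlation.values[i, j]))
        if c > 1.0 + 1e-9:
            raise CorrelationRangeError(f"|C| = {c} for edge ({a}, {b}) exceeds 1")
        if c > 1.0:
            logger.warning("clamping |C| = %.15f to 1 for edge (%d, %d)", c, a, b)
            c = 1.0
        if c == 0.0:
            dropped += 1
            continue
        length = -np.log(c)
        key = (min(i, j), max(i, j))
        edge_lengths[key] = length
        adjacency[i].append((j, length))
        adjacency[j].append((i, length))
    for neigh in adjacency:
        neigh.sort()

    usage = {key: 0 for key in edge_lengths}
    visits = np.zeros(n, dtype=int)
    n_paths = 0
    unreachable = 0
    for s in range(n):
        dist, pred = _deterministic_dijkstra(adjacency, n, s)
        for t in range(s + 1, n):
            if not np.isfinite(dist[t]):
                unreachable += 1
                continue
            n_paths += 1
            node = t
            while node != s:
                p = pred[node]
                key = (min(p, node), max(p, node))
                usage[key] += 1
                if node != t:
                    visits[node] += 1
                node = p

    max_usage = max(usage.values(), default=0)
    rows = []
    for (i, j), length in sorted(edge_lengths.items()):
        u = usage[(i, j)]
        w = u / max_usage if max_usage > 0 else 0.0
        rows.append(
            {
                "residue_i": rmap.to_author(i),
                "residue_j": rmap.to_author(j),
                "length": length,
                "usage": u,
                "normalized_weight": w,
                "kept": w > threshold,
            }
        )
    edges = pd.DataFrame(
        rows,
        columns=["residue_i", "residue_j", "length", "usage", "normalized_weight", "kept"],
    )
    prominence = ScoreVector(
        method_tag="SPM",
        residues=np.array(residues),
        values=visits.astype(float),
        polarity="high_means_rigid",
        units="count",
    )
    return SPMResult(
        edges=edges,
        prominence=prominence,
        residue_map=rmap,
        n_paths=n_paths,
        unreachable_pairs=unreachable,
        dropped_zero_correlation_edges=dropped,
        threshold=threshold,
    )


def run_spm(
    ensemble: TrajectoryEnsemble,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    threshold: float = DEFAULT_WEIGHT_THRESHOLD,
    fit: bool = True,
    max_cluster_frames: int | None = 200,
) -> SPMResult:
    """End-to-end SPM: cluster reference → correlation → contacts → map."""
    reference = reference_from_clustering(ensemble, max_frames=max_cluster_frames)
    corr = correlation_matrix(ensemble, reference, fit=fit)
    graph = contact_graph(ensemble, cutoff=contact_cutoff)
    return spm_build(graph, corr, threshold=threshold)
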