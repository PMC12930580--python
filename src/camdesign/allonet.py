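"""Dynamic network analysis of residue trajectories.

Builds an occupancy-filtered residue interaction graph from a trajectory
(edges: residue pairs whose heavy atoms come within a distance cutoff in
more than a given fraction of frames), weights edges by the dynamic
cross-correlation of residue marker displacements (w = -log|C|, the
convention of the VMD NetworkView lineage of tools), and derives allosteric
observables: optimal source-to-sink paths via Floyd-Warshall, weighted edge
betweenness, and Girvan-Newman communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .statecontacts import CONTACT_CUTOFF, residue_sort_key

logger = logging.getLogger(__name__)

#: Occupancy threshold: edges must be present in strictly more than this
#: fraction of frames.
DEFAULT_OCCUPANCY_MIN = 0.75


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

@dataclass
class ResidueTrajectory:
    """Residue-resolved trajectory.

    coords : (n_frames, n_atoms, 3) float array
    atom_resids : (n_atoms,) residue id per atom
    marker_atoms : residue id -> atom index of the marker atom (Cα-like);
        defaults to the first atom of each residue.
    """

    coords: np.ndarray
    atom_resids: np.ndarray
    marker_atoms: dict | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        self.atom_resids = np.asarray(self.atom_resids)
        if self.atom_resids.shape[0] != self.coords.shape[1]:
            raise ValueError("atom_resids length must match n_atoms")
        self.resids = sorted(set(self.atom_resids.tolist()), key=residue_sort_key)
        if self.marker_atoms is None:
            self.marker_atoms = {}
            for r in self.resids:
                self.marker_atoms[r] = int(
                    np.nonzero(self.atom_resids == r)[0][0]
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def residue_atoms(self, resid) -> np.ndarray:
        return np.nonzero(self.atom_resids == resid)[0]

    def marker_positions(self) -> np.ndarray:
        """(n_frames, n_residues, 3) marker coordinates, residue-sorted."""
        idx = [self.marker_atoms[r] for r in self.resids]
        return self.coords[:, idx, :]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DynamicNetwork:
    """Occupancy-filtered residue graph; edges carry occupancy / correlation /
    weight attributes."""

    graph: nx.Graph
    cutoff: float = CONTACT_CUTOFF
    occupancy_min: float = DEFAULT_OCCUPANCY_MIN
    exclude_adjacent: bool = True

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes, key=residue_sort_key)


@dataclass
class PathSet:
    """Optimal paths from one source to several sinks."""

    source: object
    paths: dict  # sink -> (node sequence, total length)


@dataclass
class CommunityPartition:
    assignment: dict  # node -> community id
    modularity: float

    def communities(self) -> list:
        groups: dict = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _is_adjacent(a, b) -> bool:
    try:
        return abs(int(a) - int(b)) <= 1
    except (TypeError, ValueError):
        return False


def build_network(trajectory: ResidueTrajectory,
                  cutoff: float = CONTACT_CUTOFF,
                  occupancy_min: float = DEFAULT_OCCUPANCY_MIN,
                  exclude_adjacent: bool = True) -> DynamicNetwork:
    """Residue graph with edges filtered on strict contact occupancy.

    A pair is in contact in a frame iff its minimum heavy-atom distance is
    below ``cutoff``; the edge is kept iff the fraction of frames in contact
    is strictly greater than ``occupancy_min``. Sequence-adjacent pairs
    (|Δindex| <= 1) are excluded by default.
    """
    if trajectory.n_frames < 2:
        raise ValueError(
            f"need at least 2 frames to estimate occupancy, "
            f"got {trajectory.n_frames}"
        )
    resids = trajectory.resids
    if len(resids) < 2:
        raise ValueError("need at least 2 residues")
    atom_idx = {r: trajectory.residue_atoms(r) for r in resids}
    n_frames = trajectory.n_frames
    graph = nx.Graph()
    graph.add_nodes_from(resids)
    coords = trajectory.coords
    for i, a in enumerate(resids):
        xa = coords[:, atom_idx[a], :]          # (F, na, 3)
        for b in resids[i + 1:]:
            if exclude_adjacent and _is_adjacent(a, b):
                continue
            xb = coords[:, atom_idx[b], :]      # (F, nb, 3)
            d = np.linalg.norm(xa[:, :, None, :] - xb[:, None, :, :], axis=-1)
            mind = d.reshape(n_frames, -1).min(axis=1)
            occupancy = float(np.mean(mind < cutoff))
            if occupancy > occupancy_min:
                graph.add_edge(a, b, occupancy=occupancy)
    return DynamicNetwork(graph=graph, cutoff=cutoff,
                          occupancy_min=occupancy_min,
                          exclude_adjacent=exclude_adjacent)


def displacement_correlation(trajectory: ResidueTrajectory) -> np.ndarray:
    """Normalized displacement cross-correlation matrix of residue markers.

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>) over marker
    displacements about the mean position; symmetric with unit diagonal.
    """
    if trajectory.n_frames < 10:
        raise ValueError(
            f"need at least 10 frames for correlations, "
            f"got {trajectory.n_frames}"
        )
    x = trajectory.marker_positions()
    dx = x - x.mean(axis=0, keepdims=True)      # (F, R, 3)
    inner = np.einsum("fia,fja->ij", dx, dx)
    var = np.diag(inner)
    zero = np.nonzero(var <= 0.0)[0]
    if zero.size:
        bad = [trajectory.resids[i] for i in zero]
        raise ValueError(f"zero-variance residue marker(s): {bad}")
    c = inner / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    return c


def weight_edges(network: DynamicNetwork, correlation: np.ndarray,
                 epsilon: float = 1e-6) -> DynamicNetwork:
    """Attach w_ij = -log|C_ij| weights (|C| clipped into [epsilon, 1]).

    ``correlation`` is indexed in residue-sorted order, matching
    :func:`displacement_correlation`. Returns a new network; the absolute
    correlation is also stored per edge (used as the modularity weight).
    """
    resids = network.nodes
    index = {r: i for i, r in enumerate(resids)}
    graph = network.graph.copy()
    for a, b, attrs in graph.edges(data=True):
        c = abs(float(correlation[index[a], index[b]]))
        c = min(max(c, epsilon), 1.0)
        attrs["correlation"] = float(correlation[index[a], index[b]])
        attrs["abs_correlation"] = c
        attrs["weight"] = -np.log(c)
    return DynamicNetwork(graph=graph, cutoff=network.cutoff,
                          occupancy_min=network.occupancy_min,
                          exclude_adjacent=network.exclude_adjacent)


# ---------------------------------------------------------------------------
# Paths, betweenness, communities
# ---------------------------------------------------------------------------

def floyd_warshall(network: DynamicNetwork):
    """All-pairs shortest distances and successor matrix.

    Deterministic: nodes are processed in sorted order and a relaxation is
    applied only on strict improvement, so among co-optimal paths the one
    routed through the smallest intermediate node index is kept.
    """
    nodes = network.nodes
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nxt = -np.ones((n, n), dtype=int)
    np.fill_diagonal(nxt, np.arange(n))
    for a, b, attrs in network.graph.edges(data=True):
        w = float(attrs.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({a!r}, {b!r})")
        i, j = index[a], index[b]
        if w < dist[i, j]:
            dist[i, j] = dist[j, i] = w
            nxt[i, j] = j
            nxt[j, i] = i
    for k in range(n):
        for i in range(n):
            dik = dist[i, k]
            if not np.isfinite(dik):
                continue
            for j in range(n):
                alt = dik + dist[k, j]
                if alt < dist[i, j]:
                    dist[i, j] = alt
                    nxt[i, j] = nxt[i, k]
    return nodes, dist, nxt


def optimal_paths(network: DynamicNetwork, source, sinks) -> PathSet:
    """Floyd-Warshall optimal paths from ``source`` to each sink."""
    nodes, dist, nxt = floyd_warshall(network)
    index = {v: i for i, v in enumerate(nodes)}
    if source not in index:
        raise ValueError(f"source {source!r} is not a network node")
    paths = {}
    for sink in sinks:
        if sink not in index:
            raise ValueError(f"sink {sink!r} is not a network node")
        i, j = index[source], index[sink]
        if not np.isfinite(dist[i, j]):
            raise ValueError(f"sink {sink!r} is unreachable from {source!r}")
        path = [source]
        k = i
        while k != j:
            k = int(nxt[k, j])
            path.append(nodes[k])
        paths[sink] = (path, float(dist[i, j]))
    return PathSet(source=source, paths=paths)


def edge_betweenness(network: DynamicNetwork) -> dict:
    """Weighted shortest-path edge betweenness (unnormalized, undirected).

    Co-optimal paths split the count equally (Brandes accumulation).
    """
    raw = nx.edge_betweenness_centrality(network.graph, weight="weight",
                                         normalized=False)
    return {tuple(sorted(e, key=residue_sort_key)): v for e, v in raw.items()}


def detect_communities(network: DynamicNetwork) -> CommunityPartition:
    """Girvan-Newman communities at the modularity maximum.

    Iteratively removes the edge of maximal weighted betweenness (weight =
    -log|C|) and scores every partition encountered — including the initial
    one — by weighted modularity with |C| edge weights; the best-scoring
    partition is returned. Community ids are assigned in order of each
    community's smallest node.
    """
    graph = network.graph
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes for community detection")
    if not all("abs_correlation" in d for _, _, d in graph.edges(data=True)):
        raise ValueError("network edges carry no correlations; "
                         "call weight_edges first")

    def score(partition):
        return nx.community.modularity(graph, partition,
                                       weight="abs_correlation")

    work = graph.copy()
    best_partition = [set(c) for c in nx.connected_components(work)]
    best_mod = score(best_partition)
    n_comms = len(best_partition)
    while work.number_of_edges():
        eb = nx.edge_betweenness_centrality(work, weight="weight",
                                            normalized=False)
        edge = max(sorted(eb, key=lambda e: tuple(map(residue_sort_key, e))), key=lambda e: eb[e])
        work.remove_edge(*edge)
        parts = [set(c) for c in nx.connected_components(work)]
        if len(parts) > n_comms:
            n_comms = len(parts)
            mod = score(parts)
            if mod > best_mod:
                best_mod = mod
                best_partition = parts
    assignment = {}
    ordered = sorted(best_partition,
                     key=lambda c: residue_sort_key(min(c, key=residue_sort_key)))
    for cid, comm in enumerate(ordered):
        for node in comm:
            assignment[node] = cid
    return CommunityPartition(assignment=assignment, modularity=float(best_mod))
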