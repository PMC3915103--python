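"""Directed cost graph over atlases + subject, shortest-path clustering and
exemplar selection.

The selection scheme works on a directed graph whose vertices are the
atlas images plus the subject.  Each directed edge i -> j carries the cost
``e_ij = w1*Mhat_ij + w2*Hhat_ij`` computed by the similarity module from
the i -> j registration.  Subject outgoing edges are never needed (every
path terminates at the subject), so they are left absent (infinite cost),
halving the number of subject registrations.

Selection proceeds in three steps, recomputed per subject:

1. All-pairs shortest paths by Floyd–Warshall; a next-hop table makes
   every path reconstructible.  The default path cost is the bottleneck
   (minimax) aggregation — the cost of a path is its worst edge — under
   which an atlas reaches the subject through similar atlases whenever its
   own direct edge is worse than theirs.  Additive aggregation is also
   available, but for approximately metric edge costs (as produced by
   accurate registrations) every additive shortest path is the direct
   edge, the clustering degenerates to singletons and selection becomes
   vacuous; see the methods note.
2. Clustering: each atlas's shortest path to the subject is reconstructed;
   atlases whose paths share at least one atlas vertex (the subject
   excluded) are merged into one cluster, closed transitively.  Since an
   atlas lies on its own path, an atlas routed through a neighbour always
   joins that neighbour's cluster; atlases with direct-edge paths that no
   other path crosses form singleton clusters.
3. One exemplar per cluster: the member with the smallest shortest-path
   cost to the subject (ties -> smallest node index).  Its voting weight
   is one minus its DIRECT edge cost to the subject, clamped to [0, 1].

Intuition: clusters capture anatomical modes of the atlas population, and
taking a single exemplar per mode both keeps fusion close to the subject
and prevents an over-represented mode from out-voting the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ValidationError
from .registration import RegistrationResult
from .similarity import CostWeights, edge_cost, harmonic_energy, intensity_msd, normalize_terms
from .volumes import LabelVolume, VolumeImage, warp

__all__ = [
    "AtlasGraph",
    "PathTable",
    "SelectionResult",
    "build_graph",
    "floyd_warshall",
    "reconstruct_path",
    "cluster_atlases",
    "select_exemplars",
]

logger = logging.getLogger(__name__)


@dataclass
class AtlasGraph:
    """Cost graph over ``node_ids``; the subject is the last node.

    ``cost[i, j]`` is the directed edge cost i -> j in [0, 1]; absent edges
    (subject outgoing) are ``inf``; the diagonal is 0.  Raw and normalized
    term matrices are kept for audit.
    """

    node_ids: list[str]
    cost: np.ndarray
    M: np.ndarray
    H: np.ndarray
    Mhat: np.ndarray
    Hhat: np.ndarray
    weights: CostWeights

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def subject_index(self) -> int:
        return self.n_nodes - 1

    @property
    def atlas_indices(self) -> list[int]:
        return list(range(self.n_nodes - 1))


@dataclass
class PathTable:
    """All-pairs shortest-path costs plus a next-hop matrix for reconstruction."""

    dist: np.ndarray
    next_hop: np.ndarray


@dataclass
class SelectionResult:
    """Clusters (partition of atlas ids), one exemplar per cluster, voting weights."""

    clusters: list[list[str]]
    exemplars: list[str]
    weights: list[float]
    paths: dict[str, list[str]] = dc_field(default_factory=dict)


def build_graph(
    subject: VolumeImage,
    atlases: list[VolumeImage],
    registrations: dict[tuple[str, str], RegistrationResult],
    w: CostWeights | None = None,
    mask: LabelVolume | np.ndarray | None = None,
    atlas_ids: list[str] | None = None,
    subject_id: str = "subject",
) -> AtlasGraph:
    """Assemble the directed cost graph from pairwise registrations.

    ``registrations`` maps ``(moving_id, fixed_id)`` to the corresponding
    result; every atlas->atlas and atlas->subject pair must be present.
    For each edge the moving image is warped through its field, the
    intensity MSD and harmonic energy computed, both term matrices jointly
    min–max normalized, and the weighted cost formed.
    """
    w = w or CostWeights()
    ids = atlas_ids or [f"atlas{i:02d}" for i in range(len(atlases))]
    if len(ids) != len(atlases):
        raise ValidationError("atlas_ids length must match atlases")
    if len(atlases) < 1:
        raise ValidationError("at least one atlas is required")
    if subject_id in ids:
        raise ValidationError(f"subject id {subject_id!r} collides with an atlas id")
    node_ids = ids + [subject_id]
    n = len(node_ids)
    images = {aid: img for aid, img in zip(ids, atlases)}
    images[subject_id] = subject

    required = [(a, b) for a in ids for b in node_ids if a != b]
    missing = [p for p in required if p not in registrations]
    if missing:
        raise ValidationError(f"missing registrations for pairs: {missing}")

    M = np.full((n, n), np.nan)
    H = np.full((n, n), np.nan)
    for a, b in required:
        i, j = node_ids.index(a), node_ids.index(b)
        reg = registrations[(a, b)]
        warped = warp(images[a], reg.field, "linear")
        M[i, j] = intensity_msd(images[b], warped, mask)
        H[i, j] = harmonic_energy(reg.field)
    Mhat, Hhat = normalize_terms(M, H)
    cost = np.full((n, n), np.inf)
    present = np.isfinite(Mhat) & np.isfinite(Hhat)
    cost[present] = edge_cost(Mhat[present], Hhat[present], w)
    np.fill_diagonal(cost, 0.0)
    return AtlasGraph(node_ids, cost, M, H, Mhat, Hhat, w)


def floyd_warshall(g: AtlasGraph | np.ndarray, path_cost: str = "bottleneck") -> PathTable:
    """Exact all-pairs shortest paths.

    ``path_cost`` selects the aggregation: ``"bottleneck"`` (default)
    scores a path by its maximum edge cost, ``"additive"`` by the sum of
    edge costs.  Strict-improvement updates keep, among equal-cost paths,
    the one found first (fewer intermediate vertices, smaller indices) —
    deterministic tie-breaking.
    """
    if path_cost not in ("bottleneck", "additive"):
        raise ValidationError(f"unknown path_cost {path_cost!r}")
    cost = g.cost if isinstance(g, AtlasGraph) else np.asarray(g, dtype=np.float64)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValidationError(f"cost must be square, got {cost.shape}")
    if np.any(cost[np.isfinite(cost)] < 0):
        raise ValidationError("negative edge costs are not allowed")
    n = cost.shape[0]
    dist = cost.copy()
    np.fill_diagonal(dist, 0.0)
    next_hop = np.full((n, n), -1, dtype=np.int64)
    finite = np.isfinite(dist)
    src, dst = np.nonzero(finite)
    next_hop[src, dst] = dst
    np.fill_diagonal(next_hop, np.arange(n))
    for k in range(n):
        if path_cost == "additive":
            alt = dist[:, k, None] + dist[None, k, :]
        else:
            alt = np.maximum(dist[:, k, None], dist[None, k, :])
        better = alt < dist - 1e-15
        if better.any():
            dist = np.where(better, alt, dist)
            hop_via_k = np.broadcast_to(next_hop[:, k, None], (n, n))
            next_hop = np.where(better, hop_via_k, next_hop)
    return PathTable(dist, next_hop)


def reconstruct_path(pt: PathTable, i: int, j: int) -> list[int]:
    """Vertex sequence of the stored shortest path i -> j (inclusive)."""
    if pt.next_hop[i, j] < 0:
        raise ValidationError(f"no path from node {i} to node {j}")
    path = [i]
    guard = pt.dist.shape[0] + 1
    while i != j:
        i = int(pt.next_hop[i, j])
        path.append(i)
        if len(path) > guard:
            raise ValidationError("cycle detected during path reconstruction")
    return path


def cluster_atlases(pt: PathTable, g: AtlasGraph) -> list[list[str]]:
    """Partition atlases by shared vertices on their shortest paths to the subject.

    Returned clusters and their members are sorted by node index.
    """
    t = g.subject_index
    parent = list(range(g.n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a in g.atlas_indices:
        if not np.isfinite(pt.dist[a, t]):
            raise ValidationError(f"atlas {g.node_ids[a]!r} cannot reach the subject")
        for v in reconstruct_path(pt, a, t):
            if v != t:
                union(a, v)
    groups: dict[int, list[int]] = {}
    for a in g.atlas_indices:
        groups.setdefault(find(a), []).append(a)
    clusters = [sorted(members) for _, members in sorted(groups.items())]
    return [[g.node_ids[i] for i in members] for members in clusters]


def select_exemplars(
    clusters: list[list[str]], pt: PathTable, g: AtlasGraph
) -> SelectionResult:
    """Pick per cluster the member closest to the subject (shortest-path cost).

    The voting weight of an exemplar is one minus its direct edge cost to
    the subject, clamped to [0, 1]; a zero weight is legal but logged.
    """
    t = g.subject_index
    index = {nid: i for i, nid in enumerate(g.node_ids)}
    exemplars: list[str] = []
    weights: list[float] = []
    paths: dict[str, list[str]] = {}
    for cluster in clusters:
        if not cluster:
            raise RuntimeError("internal error: empty cluster")
        members = sorted(index[c] for c in cluster)
        # bottleneck path costs tie across a chained cluster; the direct
        # edge cost then identifies the member genuinely closest to the subject
        best = min(members, key=lambda m: (pt.dist[m, t], g.cost[m, t], m))
        direct = g.cost[best, t]
        weight = float(np.clip(1.0 - direct, 0.0, 1.0))
        if weight == 0.0:
            logger.warning(
                "exemplar %s has direct edge cost %.3f -> zero voting weight",
                g.node_ids[best],
                direct,
            )
        exemplars.append(g.node_ids[best])
        weights.append(weight)
    for a in g.atlas_indices:
        paths[g.node_ids[a]] = [g.node_ids[v] for v in reconstruct_path(pt, a, t)]
    return SelectionResult(clusters, exemplars, weights, paths)
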