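"""Graph metrics on streamline-weighted structural connectomes.

Streamline weights are converted to edge lengths by elementwise
reciprocal (stronger connections are topologically closer), after which
the module computes weighted shortest path lengths (Dijkstra) and
unnormalized edge betweenness centrality (Brandes' algorithm with
fractional credit over tied shortest paths, counted over unordered node
pairs).  Per-MEG-edge structural profiles average direct weight, shortest
path length, and that edge's betweenness across subjects.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .datatypes import StructConnectome
from .selection import ParcelEdge

logger = logging.getLogger(__name__)


@dataclass
class LengthGraph:
    """Edge-length graph derived from a streamline-weight matrix."""

    node_ids: np.ndarray
    lengths: np.ndarray  # (p, p), np.inf where no edge, 0 diagonal

    def index_of(self, parcel_id: int) -> int:
        idx = np.flatnonzero(self.node_ids == parcel_id)
        if not len(idx):
            raise KeyError(f"parcel {parcel_id} absent from the graph")
        return int(idx[0])


@dataclass
class StructuralProfile:
    """Subject-averaged structural metrics for one MEG-derived edge."""

    edge: ParcelEdge
    mean_streamlines: float
    mean_spl: float  # inf if any subject is disconnected for this pair
    mean_ebc: float
    n_finite_spl: int


def weight_to_length(connectome: StructConnectome, mapping: str = "reciprocal") -> LengthGraph:
    """Map streamline weights to edge lengths.

    'reciprocal' (default): length = 1/weight; 'neg_log': length =
    −log(w / max(w)) + tiny, an alternative monotone mapping.  Zero-weight
    pairs have no edge (infinite length).
    """
    w = connectome.weights
    lengths = np.full_like(w, np.inf, dtype=float)
    pos = w > 0
    if mapping == "reciprocal":
        lengths[pos] = 1.0 / w[pos]
    elif mapping == "neg_log":
        wmax = w[pos].max() if pos.any() else 1.0
        lengths[pos] = -np.log(w[pos] / wmax) + 1e-12
    else:
        raise ValueError("mapping must be 'reciprocal' or 'neg_log'")
    np.fill_diagonal(lengths, 0.0)
    return LengthGraph(node_ids=connectome.node_ids.copy(), lengths=lengths)


def _length_csr(graph: LengthGraph) -> sp.csr_matrix:
    finite = np.isfinite(graph.lengths) & (graph.lengths > 0)
    rows, cols = np.nonzero(finite)
    return sp.csr_matrix(
        (graph.lengths[rows, cols], (rows, cols)), shape=graph.lengths.shape
    )


def shortest_path_matrix(graph: LengthGraph) -> np.ndarray:
    """All-pairs weighted shortest path lengths (Dijkstra); inf if disconnected."""
    return _csgraph_dijkstra(_length_csr(graph), directed=False)


def shortest_path_length(graph: LengthGraph, a: int, b: int) -> float:
    """Shortest path length between parcels ``a`` and ``b`` (0 if a == b)."""
    ia, ib = graph.index_of(a), graph.index_of(b)
    if ia == ib:
        return 0.0
    d = _csgraph_dijkstra(_length_csr(graph), directed=False, indices=ia)
    return float(d[ib])


def edge_betweenness(graph: LengthGraph, normalized: bool = False, tol: float = 1e-12) -> dict:
    """Unnormalized weighted edge betweenness centrality (Brandes).

    For each edge, the number of weighted shortest paths between all
    unordered node pairs that traverse it, with fractional credit when
    several shortest paths tie (within ``tol``).  Keys are unordered node
    index pairs ``(i, j)`` with i < j.  With ``normalized=True`` the counts
    are scaled by 2/(n(n−1)).
    """
    L = graph.lengths
    n = L.shape[0]
    nbrs = [np.flatnonzero(np.isfinite(L[i]) & (np.arange(n) != i)) for i in range(n)]
    cb: dict[tuple[int, int], float] = {
        (i, int(j)): 0.0 for i in range(n) for j in nbrs[i] if i < j
    }
    for s in range(n):
        # Dijkstra with predecessor lists and path counts
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            d_v, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for w in nbrs[v]:
                alt = d_v + L[v, w]
                if alt < dist[w] - tol:
                    dist[w] = alt
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (alt, int(w)))
                elif abs(alt - dist[w]) <= tol and not done[w]:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                c = (sigma[v] / sigma[w]) * (1.0 + delta[w])
                key = (v, w) if v < w else (w, v)
                cb[key] += c
                delta[v] += c
    # each unordered pair (s, t) was counted from both endpoints
    for key in cb:
        cb[key] /= 2.0
    if normalized:
        scale = 2.0 / (n * (n - 1)) if n > 1 else 1.0
        for key in cb:
            cb[key] *= scale
    return cb


def structural_profile(edge: ParcelEdge, connectomes: list[StructConnectome],
                       mapping: str = "reciprocal") -> StructuralProfile:
    """Subject-averaged direct weight, shortest path length, and betweenness.

    A subject in whom the two parcels are disconnected contributes an
    infinite shortest path length; the mean is then reported as inf with
    the count of finite subjects retained.  An absent direct edge
    contributes betweenness 0.
    """
    profiles = structural_profiles([edge], connectomes, mapping)
    return profiles[0]


def structural_profiles(edges: list[ParcelEdge], connectomes: list[StructConnectome],
                        mapping: str = "reciprocal") -> list[StructuralProfile]:
    """Batch version of :func:`structural_profile`.

    Shortest-path distances and the full edge-betweenness dictionary are
    computed once per subject and shared across edges.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    n_subj = len(connectomes)
    streams = np.zeros((len(edges), n_subj))
    spls = np.zeros((len(edges), n_subj))
    ebcs = np.zeros((len(edges), n_subj))
    for s, conn in enumerate(connectomes):
        graph = weight_to_length(conn, mapping)
        dmat = shortest_path_matrix(graph)
        ebc = edge_betweenness(graph)
        for e_i, edge in enumerate(edges):
            ia = conn.index_of(edge.parcel_a)
            ib = conn.index_of(edge.parcel_b)
            streams[e_i, s] = conn.weights[ia, ib]
            spls[e_i, s] = dmat[ia, ib]
            key = (min(ia, ib), max(ia, ib))
            ebcs[e_i, s] = ebc.get(key, 0.0)
    out = []
    for e_i, edge in enumerate(edges):
        finite = np.isfinite(spls[e_i])
        mean_spl = float(spls[e_i].mean()) if finite.all() else np.inf
        if not finite.all():
            logger.info(
                "edge %s disconnected in %d/%d subjects; mean shortest path length is inf",
                edge, int((~finite).sum()), n_subj,
            )
        out.append(
            StructuralProfile(
                edge=edge,
                mean_streamlines=float(streams[e_i].mean()),
                mean_spl=mean_spl,
                mean_ebc=float(ebcs[e_i].mean()),
                n_finite_spl=int(finite.sum()),
            )
        )
    return out
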