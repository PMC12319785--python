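"""Data-driven selection of task-modulated connections.

The selection stage works entirely on the first measurement session to
avoid circularity with the session-spanning reliability analysis:

1. mass-univariate paired t-tests of the naming − visual coherence
   contrast over subjects, per grid-pair connection;
2. thresholding at an uncorrected alpha (selection A: 1e-3, selection B:
   1e-4) combined with a minimum 4 cm endpoint-distance filter against
   spatial-leakage artifacts;
3. single-linkage spatial clustering of the surviving connections into
   bundles (link threshold 1.3 cm, minimum 20 members);
4. mapping bundles to parcel-level edges and aggregating the contrast by
   summing over *all* grid pairs between the two parcels;
5. labeling each parcel edge's modulation direction from the session-1
   group mean.

A separate screen flags parcels whose task power difference exceeds 20%
for more than four subjects (power confounds coherence contrasts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .datatypes import ConnTensor, GridGeometry, Parcellation

logger = logging.getLogger(__name__)

SELECTION_ALPHAS = {"A": 1e-3, "B": 1e-4}
MIN_ENDPOINT_DISTANCE_MM = 40.0
BUNDLE_MAX_LINK_MM = 13.0
BUNDLE_MIN_SIZE = 20
POWER_THRESHOLD = 0.20
POWER_MIN_SUBJECTS = 5  # "more than four subjects"


@dataclass
class ConnectionStats:
    """Per-connection paired-t results over subjects (session 1)."""

    t: np.ndarray  # (m,) t statistic, nan where degenerate
    p: np.ndarray  # (m,) two-sided p, nan where degenerate
    mean_contrast: np.ndarray  # (m,)
    degenerate: np.ndarray  # (m,) bool: zero-variance differences
    n_subjects: int


@dataclass
class Bundle:
    """A spatial cluster of supra-threshold grid-pair connections."""

    members: np.ndarray  # indices into the tensor's connection axis

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ParcelEdge:
    """An unordered pair of included parcels in one band × window."""

    parcel_a: int
    parcel_b: int
    band: str
    window: str
    direction: str | None = None

    def __post_init__(self):
        if self.parcel_a == self.parcel_b:
            raise ValueError("parcel edge must join two distinct parcels")
        if self.parcel_a > self.parcel_b:
            a, b = self.parcel_b, self.parcel_a
            object.__setattr__(self, "parcel_a", a)
            object.__setattr__(self, "parcel_b", b)

    def key(self) -> tuple:
        return (self.parcel_a, self.parcel_b, self.band, self.window)


def paired_t_contrast(tensor: ConnTensor, band: str, window: str, session: int = 1) -> ConnectionStats:
    """Paired t-test of naming − visual coherence per connection.

    Connections with zero-variance differences across subjects are flagged
    degenerate (t and p set to NaN) and excluded from selection.
    """
    diffs = tensor.contrast(band, window, session)  # (n_subjects, m)
    n = diffs.shape[0]
    if n < 3:
        raise ValueError("paired t-test requires at least 3 subjects")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("%d degenerate (zero-variance) connections flagged", degenerate.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return ConnectionStats(t=t, p=p, mean_contrast=mean, degenerate=degenerate, n_subjects=n)


def threshold_connections(
    statsres: ConnectionStats,
    tensor: ConnTensor,
    geometry: GridGeometry,
    alpha: float,
    min_endpoint_distance: float = MIN_ENDPOINT_DISTANCE_MM,
) -> np.ndarray:
    """Indices of connections with p < alpha and endpoint distance >= limit.

    The distance limit is inclusive (a connection exactly at the limit is
    retained); degenerate connections are never selected.
    """
    dist = geometry.pair_distances(tensor.pairs)
    with np.errstate(invalid="ignore"):
        keep = (~statsres.degenerate) & (statsres.p < alpha) & (dist >= min_endpoint_distance)
    return np.flatnonzero(keep)


def connection_distance_matrix(
    ends_a1: np.ndarray,
    ends_b1: np.ndarray,
    ends_a2: np.ndarray | None = None,
    ends_b2: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise distance between undirected connections.

    For connections c1=(a1,b1), c2=(a2,b2) the distance is the smaller,
    over the two possible endpoint pairings, of the *larger*
    endpoint-to-endpoint distance: two connections are close only if both
    endpoints can be matched within the distance.  With two arguments,
    computes the within-set matrix; with four, set 1 against set 2.
    """
    if ends_a2 is None:
        ends_a2, ends_b2 = ends_a1, ends_b1

    def _cross(x, y):
        return np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)

    straight = np.maximum(_cross(ends_a1, ends_a2), _cross(ends_b1, ends_b2))
    crossed = np.maximum(_cross(ends_a1, ends_b2), _cross(ends_b1, ends_a2))
    return np.minimum(straight, crossed)


def cluster_bundles(
    selected: np.ndarray,
    tensor: ConnTensor,
    geometry: GridGeometry,
    max_link: float = BUNDLE_MAX_LINK_MM,
    min_size: int = BUNDLE_MIN_SIZE,
) -> list[Bundle]:
    """Single-linkage bundles of selected connections.

    Bundles are connected components of the graph that links two
    connections when their distance (see
    :func:`connection_distance_matrix`) is <= ``max_link``; components
    smaller than ``min_size`` are discarded.
    """
    selected = np.asarray(selected, dtype=int)
    if len(selected) == 0:
        return []
    pairs = tensor.pairs[selected]
    ca = geometry.coords[pairs[:, 0]]
    cb = geometry.coords[pairs[:, 1]]
    # chunked to bound the m^2 distance matrix memory
    mtot = len(selected)
    adj_rows, adj_cols = [], []
    chunk = 2000
    for start in range(0, mtot, chunk):
        stop = min(start + chunk, mtot)
        d = connection_distance_matrix(ca[start:stop], cb[start:stop], ca, cb)
        r, c = np.nonzero(d <= max_link)
        adj_rows.append(r + start)
        adj_cols.append(c)
        del d
    rows = np.concatenate(adj_rows)
    cols = np.concatenate(adj_cols)
    graph = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(mtot, mtot))
    n_comp, labels = connected_components(graph, directed=False)
    bundles = []
    for comp in range(n_comp):
        members = selected[labels == comp]
        if len(members) >= min_size:
            bundles.append(Bundle(members=np.sort(members)))
    logger.info(
        "bundle clustering: %d selected connections -> %d components, %d retained bundles",
        mtot, n_comp, len(bundles),
    )
    return bundles


def bundles_to_parcel_edges(
    bundles: list[Bundle],
    tensor: ConnTensor,
    geometry: GridGeometry,
    parcellation: Parcellation,
    band: str,
    window: str,
) -> list[ParcelEdge]:
    """Map bundle member connections to unique included-parcel pairs.

    A member contributes the unordered pair of its endpoint parcels; pairs
    touching excluded (anterior) parcels and within-parcel pairs are
    dropped; duplicates are merged.
    """
    included = set(int(p) for p in parcellation.included_ids())
    seen: set[tuple[int, int]] = set()
    for bundle in bundles:
        pr = tensor.pairs[bundle.members]
        pa = geometry.parcel_id[pr[:, 0]]
        pb = geometry.parcel_id[pr[:, 1]]
        for a, b in zip(pa, pb):
            a, b = int(a), int(b)
            if a == b or a not in included or b not in included:
                continue
            seen.add((min(a, b), max(a, b)))
    return [ParcelEdge(a, b, band, window) for a, b in sorted(seen)]


def parcel_aggregate(
    tensor: ConnTensor,
    geometry: GridGeometry,
    edge: ParcelEdge,
) -> np.ndarray:
    """Summed task contrast for one parcel edge: shape (n_subjects, 2).

    The sum runs over *all* grid pairs in the tensor's connection index
    with one endpoint in each parcel — not only the t-test-selected
    connections.
    """
    pa = geometry.parcel_id[tensor.pairs[:, 0]]
    pb = geometry.parcel_id[tensor.pairs[:, 1]]
    a, b = edge.parcel_a, edge.parcel_b
    mask = ((pa == a) & (pb == b)) | ((pa == b) & (pb == a))
    if not mask.any():
        raise ValueError(
            f"no grid pairs between parcels {a} and {b} in the connection index"
        )
    out = np.empty((tensor.n_subjects, 2))
    for session in (1, 2):
        out[:, session - 1] = tensor.contrast(edge.band, edge.window, session)[:, mask].sum(axis=1)
    return out


def modulation_direction(series: np.ndarray) -> str:
    """'increase' or 'decrease' from the session-1 group-mean summed contrast."""
    m = float(np.mean(series[:, 0]))
    if m == 0.0:
        logger.warning("exact zero group-mean contrast; direction tie-broken to 'increase'")
        return "increase"
    return "increase" if m > 0 else "decrease"


def power_screen(
    power: np.ndarray,
    threshold: float = POWER_THRESHOLD,
    min_subjects: int = POWER_MIN_SUBJECTS,
) -> np.ndarray:
    """Flag parcels with large task power differences in many subjects.

    ``power`` has shape (n_subjects, n_parcels, ..., 2) with the last axis
    (naming, visual).  The relative difference is normalized by the
    condition mean, ``r = |Pn − Pv| / ((Pn + Pv)/2)`` (0 where both are
    zero); an entry along the trailing parcel axes is flagged when ``r >
    threshold`` for at least ``min_subjects`` subjects.  Returns a boolean
    array over the non-subject axes (parcel, ...).
    """
    power = np.asarray(power, dtype=float)
    if (power < 0).any():
        raise ValueError("power values must be nonnegative")
    pn = power[..., 0]
    pv = power[..., 1]
    denom = (pn + pv) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(pn - pv) / denom
    r = np.where(denom == 0, 0.0, r)
    exceed = (r > threshold).sum(axis=0)
    return exceed >= min_subjects


@dataclass
class SelectedEdge:
    """A parcel edge with its aggregated series and modulation direction."""

    edge: ParcelEdge
    series: np.ndarray  # (n_subjects, 2)
    n_selected_connections: int


def select_parcel_edges(
    tensor: ConnTensor,
    geometry: GridGeometry,
    parcellation: Parcellation,
    alpha: float,
    min_endpoint_distance: float = MIN_ENDPOINT_DISTANCE_MM,
    max_link: float = BUNDLE_MAX_LINK_MM,
    min_size: int = BUNDLE_MIN_SIZE,
) -> list[SelectedEdge]:
    """Run the full selection chain over every band × window."""
    out: list[SelectedEdge] = []
    for band in tensor.bands:
        for window in tensor.windows:
            st = paired_t_contrast(tensor, band, window, session=1)
            sel = threshold_connections(st, tensor, geometry, alpha, min_endpoint_distance)
            bundles = cluster_bundles(sel, tensor, geometry, max_link, min_size)
            edges = bundles_to_parcel_edges(bundles, tensor, geometry, parcellation, band, window)
            logger.info(
                "band %s window %s: %d connections pass threshold, %d bundles, %d parcel edges",
                band, window, len(sel), len(bundles), len(edges),
            )
            for edge in edges:
                series = parcel_aggregate(tensor, geometry, edge)
                direction = modulation_direction(series)
                edge = ParcelEdge(edge.parcel_a, edge.parcel_b, band, window, direction)
                out.append(SelectedEdge(edge=edge, series=series, n_selected_connections=len(sel)))
    return out
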