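"""Core data containers for the connectivity reliability pipeline.

The pipeline operates on four kinds of input: a dense coherence tensor
defined over pairs of source-space grid points (:class:`ConnTensor`), the
grid geometry and its parcellation (:class:`GridGeometry`,
:class:`Parcellation`), a per-subject behavior table, and per-subject
structural connectomes (:class:`StructConnectome`).  All containers are
plain ``numpy``/``pandas``-backed dataclasses with explicit validation so
that file round-trips can be checked for identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("naming", "visual")
#: canonical frequency bands of interest, Hz
DEFAULT_BANDS = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "low_beta": (14.0, 20.0),
    "high_beta": (21.0, 30.0),
    "low_gamma": (31.0, 45.0),
    "high_gamma": (60.0, 90.0),
}
#: canonical post-stimulus analysis windows, ms
DEFAULT_WINDOWS = {
    "0-400": (0.0, 400.0),
    "400-800": (400.0, 800.0),
    "800-1200": (800.0, 1200.0),
}

BEHAVIOR_COLUMNS = ("fluency_s", "fluency_animal", "ran_ras_mean")


class SchemaError(ValueError):
    """An input file or container violates its documented schema."""


@dataclass(frozen=True)
class PlantedEdge:
    """Ground-truth specification of one planted parcel-level effect.

    ``mu`` is the mean task contrast (naming − visual coherence) per grid-pair
    connection; ``sigma_b`` the between-subject SD of the per-connection
    latent contrast; ``direction`` follows the sign of ``mu``.
    """

    parcel_a: int
    parcel_b: int
    band: str
    window: str
    mu: float
    sigma_b: float
    direction: str = "increase"

    def key(self) -> tuple:
        a, b = sorted((self.parcel_a, self.parcel_b))
        return (a, b, self.band, self.window)


@dataclass
class SynthDesign:
    """Full description of a synthetic test-retest connectivity study.

    Defaults mirror the study design the pipeline targets: 19 subjects
    measured in two sessions, six frequency bands and three post-stimulus
    time windows, with a desk-scale source grid.
    """

    n_subjects: int = 19
    n_sessions: int = 2
    n_grid_points: int = 400
    n_parcels_per_hemi: int = 10
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    planted_edges: list = field(default_factory=list)
    session_noise_sd: float = 0.01
    behavior_coupling: list = field(default_factory=list)  # (PlantedEdge, beta)
    structural_boost: float = 1.0
    anterior_exclude_frac: float = 0.1
    shell_radius_mm: float = 70.0
    baseline_range: tuple = (0.2, 0.5)
    session_offset_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sessions != 2:
            raise ValueError("design requires exactly 2 sessions (k=2 ICC)")
        if self.n_grid_points < 2 * self.n_parcels_per_hemi:
            raise ValueError(
                "invalid design: n_grid_points must be >= 2 * n_parcels_per_hemi"
            )
        if self.session_noise_sd < 0:
            raise ValueError("session_noise_sd must be >= 0")
        if self.structural_boost < 1:
            raise ValueError("structural_boost must be >= 1")
        for e in self.planted_edges:
            if e.sigma_b < 0:
                raise ValueError("sigma_b must be >= 0")
            if e.band not in self.bands or e.window not in self.windows:
                raise ValueError(f"planted edge references unknown band/window: {e}")
        planted_keys = {e.key() for e in self.planted_edges}
        for e, _beta in self.behavior_coupling:
            if e.key() not in planted_keys:
                raise ValueError(f"behavior coupling references non-planted edge {e}")

    def theoretical_icc(self, edge: PlantedEdge) -> float:
        """Population ICC implied by the variance components of one edge."""
        denom = edge.sigma_b**2 + self.session_noise_sd**2
        if denom == 0:
            return 0.0
        return edge.sigma_b**2 / denom


@dataclass
class GridGeometry:
    """Source-space grid points: 3D coordinates (mm), hemisphere, parcel."""

    coords: np.ndarray  # (n, 3) float, mm
    hemisphere: np.ndarray  # (n,) str array, 'left'/'right'
    parcel_id: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        self.parcel_id = np.asarray(self.parcel_id, dtype=int)
        if not np.isfinite(self.coords).all():
            raise SchemaError("grid coordinates must be finite")
        n = len(self.coords)
        if len(self.hemisphere) != n or len(self.parcel_id) != n:
            raise SchemaError("geometry arrays must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def pair_distances(self, pairs: np.ndarray) -> np.ndarray:
        """Euclidean endpoint distance (mm) for an (m, 2) array of point pairs."""
        pairs = np.asarray(pairs)
        d = self.coords[pairs[:, 0]] - self.coords[pairs[:, 1]]
        return np.linalg.norm(d, axis=1)


@dataclass
class Parcellation:
    """Parcel table: id, name, hemisphere, inclusion flag, centroid.

    ``included`` is False for the most anterior parcels, which are excluded
    from connection selection (eye-movement artifacts and poor sensor
    coverage make their connectivity estimates unspecific).
    """

    table: pd.DataFrame  # columns: parcel_id, name, hemisphere, included
    centroids: np.ndarray | None = None  # (n_parcels, 3) mm, aligned to table rows

    def __post_init__(self) -> None:
        required = {"parcel_id", "name", "hemisphere", "included"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"parcellation missing columns: {sorted(missing)}")
        if self.table["parcel_id"].duplicated().any():
            raise SchemaError("parcel ids must be unique")
        for hemi in ("left", "right"):
            sub = self.table[self.table["hemisphere"] == hemi]
            if len(sub) and not sub["included"].any():
                raise SchemaError(f"no included parcel in hemisphere {hemi}")

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table["parcel_id"].to_numpy()

    def hemisphere_of(self, parcel_id: int) -> str:
        row = self.table.loc[self.table["parcel_id"] == parcel_id]
        if row.empty:
            raise KeyError(f"unknown parcel {parcel_id}")
        return str(row["hemisphere"].iloc[0])

    def is_included(self, parcel_id: int) -> bool:
        row = self.table.loc[self.table["parcel_id"] == parcel_id]
        if row.empty:
            raise KeyError(f"unknown parcel {parcel_id}")
        return bool(row["included"].iloc[0])

    def included_ids(self) -> np.ndarray:
        return self.table.loc[self.table["included"], "parcel_id"].to_numpy()


@dataclass
class ConnTensor:
    """Dense coherence values over grid-pair connections.

    ``values`` has shape (n_subjects, 2 sessions, 2 tasks, n_bands,
    n_windows, n_connections) with tasks ordered (naming, visual); entries
    are coherence, dimensionless in [0, 1].  ``pairs`` holds the shared
    connection index as (i, j) grid-point ids with i < j.
    """

    values: np.ndarray
    pairs: np.ndarray  # (m, 2) int, i < j
    subjects: np.ndarray
    bands: list
    windows: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.values.ndim != 6:
            raise SchemaError("values must be 6-dimensional")
        ns, nd, nt, nb, nw, m = self.values.shape
        if nd != 2 or nt != 2:
            raise SchemaError("expected 2 sessions and 2 tasks")
        if nb != len(self.bands) or nw != len(self.windows):
            raise SchemaError("band/window axis mismatch")
        if self.pairs.shape != (m, 2):
            raise SchemaError("pairs must align with the connection axis")
        if (self.pairs[:, 0] >= self.pairs[:, 1]).any():
            raise SchemaError("connection index must satisfy i < j (no self-pairs)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise SchemaError("coherence values must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_connections(self) -> int:
        return self.values.shape[5]

    def band_index(self, band: str) -> int:
        return list(self.bands).index(band)

    def window_index(self, window: str) -> int:
        return list(self.windows).index(window)

    def contrast(self, band: str, window: str, session: int) -> np.ndarray:
        """Naming − visual coherence, shape (n_subjects, n_connections).

        ``session`` is 1-based (1 or 2), matching the study protocol.
        """
        if session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        b, w = self.band_index(band), self.window_index(window)
        v = self.values[:, session - 1, :, b, w, :]
        return v[:, 0, :] - v[:, 1, :]


@dataclass
class StructConnectome:
    """Symmetric nonnegative parcel×parcel streamline-weight matrix."""

    subject: int
    node_ids: np.ndarray  # parcel ids, aligned to matrix rows
    weights: np.ndarray  # (p, p) float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        p = len(self.node_ids)
        if self.weights.shape != (p, p):
            raise SchemaError("weight matrix must be square over the node set")
        if not np.allclose(self.weights, self.weights.T):
            raise SchemaError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise SchemaError("weight matrix must have zero diagonal")
        if (self.weights < 0).any():
            raise SchemaError("streamline weights must be nonnegative")

    def index_of(self, parcel_id: int) -> int:
        idx = np.flatnonzero(self.node_ids == parcel_id)
        if not len(idx):
            raise KeyError(f"parcel {parcel_id} absent from connectome node set")
        return int(idx[0])


def validate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Check the behavior table schema: one row per subject, three scores."""
    for col in ("subject",) + BEHAVIOR_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"behavior table missing column {col!r}")
    if table["subject"].duplicated().any():
        raise SchemaError("behavior table must have one row per subject")
    scores = table[list(BEHAVIOR_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise SchemaError("behavior scores must be finite")
    return table


def design_to_dict(design: SynthDesign) -> dict:
    """JSON/YAML-serializable representation of a design (for manifests)."""
    d = dataclasses.asdict(design)
    d["planted_edges"] = [dataclasses.asdict(e) for e in design.planted_edges]
    d["behavior_coupling"] = [
        {"edge": dataclasses.asdict(e), "beta": beta}
        for e, beta in design.behavior_coupling
    ]
    d["baseline_range"] = list(design.baseline_range)
    return d


def design_from_dict(d: dict) -> SynthDesign:
    d = dict(d)
    d["planted_edges"] = [PlantedEdge(**e) for e in d.get("planted_edges", [])]
    d["behavior_coupling"] = [
        (PlantedEdge(**c["edge"]), float(c["beta"]))
        for c in d.get("behavior_coupling", [])
    ]
    if "baseline_range" in d:
        d["baseline_range"] = tuple(d["baseline_range"])
    if "bands" in d:
        d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
    if "windows" in d:
        d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
    return SynthDesign(**d)
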