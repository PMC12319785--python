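"""File formats: HDF5 connectivity container, CSV/TSV tables, JSON parcellation.

The dense coherence tensor travels as HDF5 (layout below); everything
else is plain text so intermediate results can be inspected and partially
re-run.

HDF5 layout::

    /geometry/coords      (n, 3) float64, mm
    /geometry/hemisphere  (n,)   bytes, b'left' / b'right'
    /geometry/parcel      (n,)   int
    /parcels/parcel_id, /parcels/name, /parcels/hemisphere,
    /parcels/included, /parcels/centroids
    /conn/values          (n_subj, 2, 2, n_bands, n_windows, m) float64
    /conn/pairs           (m, 2) int
    attrs: subjects, band_names, band_edges_hz, window_names,
           window_edges_ms, seed
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    BEHAVIOR_COLUMNS,
    ConnTensor,
    GridGeometry,
    Parcellation,
    SchemaError,
    StructConnectome,
    validate_behavior,
)

FLOAT_FORMAT = "%.10g"


def write_connectivity_h5(
    path,
    tensor: ConnTensor,
    geometry: GridGeometry,
    parcellation: Parcellation,
    band_edges: dict | None = None,
    window_edges: dict | None = None,
    seed: int | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("geometry")
        g.create_dataset("coords", data=geometry.coords)
        g.create_dataset("hemisphere", data=np.char.encode(geometry.hemisphere.astype(str)))
        g.create_dataset("parcel", data=geometry.parcel_id)
        p = f.create_group("parcels")
        t = parcellation.table
        p.create_dataset("parcel_id", data=t["parcel_id"].to_numpy(dtype=int))
        p.create_dataset("name", data=np.char.encode(t["name"].to_numpy(dtype=str)))
        p.create_dataset("hemisphere", data=np.char.encode(t["hemisphere"].to_numpy(dtype=str)))
        p.create_dataset("included", data=t["included"].to_numpy(dtype=bool))
        if parcellation.centroids is not None:
            p.create_dataset("centroids", data=parcellation.centroids)
        c = f.create_group("conn")
        c.create_dataset("values", data=tensor.values)
        c.create_dataset("pairs", data=tensor.pairs)
        f.attrs["subjects"] = np.asarray(tensor.subjects, dtype=int)
        f.attrs["band_names"] = [str(b) for b in tensor.bands]
        f.attrs["window_names"] = [str(w) for w in tensor.windows]
        if band_edges:
            f.attrs["band_edges_hz"] = np.array([band_edges[b] for b in tensor.bands], dtype=float)
        if window_edges:
            f.attrs["window_edges_ms"] = np.array([window_edges[w] for w in tensor.windows], dtype=float)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def read_connectivity_h5(path) -> tuple[ConnTensor, GridGeometry, Parcellation]:
    with h5py.File(path, "r") as f:
        try:
            geometry = GridGeometry(
                coords=f["geometry/coords"][()],
                hemisphere=np.char.decode(f["geometry/hemisphere"][()]),
                parcel_id=f["geometry/parcel"][()],
            )
            table = pd.DataFrame(
                {
                    "parcel_id": f["parcels/parcel_id"][()],
                    "name": np.char.decode(f["parcels/name"][()]),
                    "hemisphere": np.char.decode(f["parcels/hemisphere"][()]),
                    "included": f["parcels/included"][()].astype(bool),
                }
            )
            centroids = f["parcels/centroids"][()] if "parcels/centroids" in f else None
            parcellation = Parcellation(table=table, centroids=centroids)
            tensor = ConnTensor(
                values=f["conn/values"][()],
                pairs=f["conn/pairs"][()],
                subjects=np.asarray(f.attrs["subjects"], dtype=int),
                bands=[str(b) for b in f.attrs["band_names"]],
                windows=[str(w) for w in f.attrs["window_names"]],
            )
        except KeyError as exc:
            raise SchemaError(f"connectivity container missing dataset: {exc}") from exc
    return tensor, geometry, parcellation


def write_behavior_csv(path, behavior: pd.DataFrame) -> None:
    validate_behavior(behavior)
    behavior.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_behavior_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_behavior(table)


def write_parcellation_json(path, parcellation: Parcellation) -> None:
    payload = {
        "parcels": parcellation.table.to_dict(orient="records"),
        "centroids": None
        if parcellation.centroids is None
        else np.asarray(parcellation.centroids).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=bool) + "\n")


def read_parcellation_json(path) -> Parcellation:
    payload = json.loads(Path(path).read_text())
    table = pd.DataFrame(payload["parcels"])
    centroids = payload.get("centroids")
    return Parcellation(
        table=table,
        centroids=None if centroids is None else np.asarray(centroids, dtype=float),
    )


def write_structural_tsv(path, connectomes: list[StructConnectome]) -> None:
    rows = []
    for conn in connectomes:
        iu = np.triu_indices(len(conn.node_ids), k=1)
        for i, j in zip(*iu):
            w = conn.weights[i, j]
            if w > 0:
                rows.append(
                    (conn.subject, int(conn.node_ids[i]), int(conn.node_ids[j]), w)
                )
    df = pd.DataFrame(rows, columns=["subject", "parcel_a", "parcel_b", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_structural_tsv(path, node_ids=None) -> list[StructConnectome]:
    """Read per-subject connectomes from an edge-list TSV.

    Entries are undirected; a pair listed in both orientations must carry
    the same weight or a :class:`SchemaError` is raised with the offending
    record.  ``node_ids`` fixes the node set (default: all parcels in the
    file).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "parcel_a", "parcel_b", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"structural TSV missing columns: {sorted(missing)}")
    if node_ids is None:
        node_ids = np.unique(
            np.concatenate([df["parcel_a"].to_numpy(), df["parcel_b"].to_numpy()])
        ).astype(int)
    node_ids = np.asarray(node_ids, dtype=int)
    pos = {int(p): i for i, p in enumerate(node_ids)}
    out = []
    for subject, sub in df.groupby("subject", sort=True):
        w = np.zeros((len(node_ids), len(node_ids)))
        seen = {}
        for rec_no, row in enumerate(sub.itertuples(index=False)):
            a, b = int(row.parcel_a), int(row.parcel_b)
            if a not in pos or b not in pos:
                raise SchemaError(
                    f"structural TSV subject {subject} record {rec_no}: parcel outside node set"
                )
            if a == b:
                raise SchemaError(
                    f"structural TSV subject {subject} record {rec_no}: self-loop {a}"
                )
            key = (min(a, b), max(a, b))
            if key in seen and not np.isclose(seen[key], row.weight):
                raise SchemaError(
                    f"structural TSV subject {subject} record {rec_no}: asymmetric duplicate "
                    f"for pair {key}: {seen[key]} vs {row.weight}"
                )
            seen[key] = float(row.weight)
            w[pos[a], pos[b]] = w[pos[b], pos[a]] = float(row.weight)
        out.append(StructConnectome(subject=int(subject), node_ids=node_ids, weights=w))
    return out


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
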