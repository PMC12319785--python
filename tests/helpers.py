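"""Shared constructors for small hand-built containers."""

import numpy as np
import pandas as pd

from retestconn.datatypes import ConnTensor, GridGeometry, Parcellation


def make_tensor(diffs, baseline=0.3, pairs=None, bands=("b",), windows=("w",)):
    """Build a minimal one-band/one-window tensor from session-wise contrasts.

    ``diffs`` has shape (n_subjects, n_sessions, n_connections): the
    naming − visual contrast realized on top of a constant baseline.
    """
    diffs = np.asarray(diffs, dtype=float)
    ns, nd, m = diffs.shape
    if pairs is None:
        pairs = np.column_stack([np.arange(m), np.arange(m) + m])
    values = np.full((ns, nd, 2, 1, 1, m), baseline)
    values[:, :, 0, 0, 0, :] += diffs
    return ConnTensor(values=values, pairs=np.asarray(pairs), subjects=np.arange(ns),
                      bands=list(bands), windows=list(windows))


def make_geometry(coords, parcel_id=None):
    coords = np.asarray(coords, dtype=float)
    hemis = np.where(coords[:, 0] < 0, "left", "right")
    if parcel_id is None:
        parcel_id = np.zeros(len(coords), dtype=int)
    return GridGeometry(coords=coords, hemisphere=hemis, parcel_id=np.asarray(parcel_id))


def make_parcellation(hemis, included=None, centroids=None):
    """Parcellation with ids 0..n-1 and the given hemisphere labels."""
    n = len(hemis)
    included = [True] * n if included is None else included
    table = pd.DataFrame(
        {
            "parcel_id": np.arange(n),
            "name": [f"P{i}" for i in range(n)],
            "hemisphere": hemis,
            "included": included,
        }
    )
    return Parcellation(table=table, centroids=centroids)
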