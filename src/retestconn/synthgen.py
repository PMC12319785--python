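"""Synthetic test-retest connectivity studies with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at the level the pipeline consumes (grid-pair coherence values,
behavior scores, parcel-wise structural connectomes):

* per-subject latent task contrasts ``delta ~ N(mu, sigma_b^2)`` on grid-pair
  connections between planted parcel pairs, observed in each session with
  independent noise ``eps ~ N(0, sigma_e^2)`` — giving a population ICC of
  ``sigma_b^2 / (sigma_b^2 + sigma_e^2)`` for the parcel-summed contrast;
* behavior scores optionally coupled to the subject latents of planted
  edges, so the per-edge regression screen has planted true positives;
* structural streamline weights with distance-decaying, heavy-tailed
  baselines and a multiplicative boost on planted-reliable parcel pairs.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    BEHAVIOR_COLUMNS,
    ConnTensor,
    GridGeometry,
    Parcellation,
    PlantedEdge,
    StructConnectome,
    SynthDesign,
    validate_behavior,
)

logger = logging.getLogger(__name__)

# rng stream labels, combined with the design seed so each stage has an
# independent but reproducible stream
_STREAM_GEOMETRY = 11
_STREAM_BEHAVIOR = 13
_STREAM_CONNECTIVITY = 17
_STREAM_STRUCTURAL = 19


def _rng(design: SynthDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(stream,)))


def gen_geometry(design: SynthDesign) -> tuple[GridGeometry, Parcellation]:
    """Generate grid points on two hemispheric shells and a parcellation.

    Points lie on a sphere of radius ``shell_radius_mm`` (with small radial
    jitter); hemisphere is encoded by the sign of x (x < 0 left).  Each
    hemisphere is partitioned into ``n_parcels_per_hemi`` parcels by
    nearest-seed-centroid assignment, seeds drawn from the points
    themselves.  The most anterior parcels (largest centroid y) are flagged
    ``included=False``.
    """
    design.validate()
    rng = _rng(design, _STREAM_GEOMETRY)
    n = design.n_grid_points
    n_left = n // 2
    sides = np.array(["left"] * n_left + ["right"] * (n - n_left))

    # uniform directions on the sphere, mirrored into the correct hemisphere
    vec = rng.standard_normal((n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    sign = np.where(sides == "left", -1.0, 1.0)
    vec[:, 0] = sign * np.abs(vec[:, 0])
    radius = design.shell_radius_mm + rng.normal(0.0, 2.0, size=n)
    coords = vec * radius[:, None]

    parcel_id = np.full(n, -1, dtype=int)
    rows = []
    centroids = []
    next_id = 0
    for hemi in ("left", "right"):
        idx = np.flatnonzero(sides == hemi)
        seeds = rng.choice(idx, size=design.n_parcels_per_hemi, replace=False)
        seed_coords = coords[seeds]
        d = np.linalg.norm(coords[idx][:, None, :] - seed_coords[None, :, :], axis=2)
        assign = d.argmin(axis=1)
        ids = next_id + np.arange(design.n_parcels_per_hemi)
        parcel_id[idx] = ids[assign]
        # anterior exclusion: +y is anterior by convention
        n_excl = int(np.ceil(design.anterior_exclude_frac * design.n_parcels_per_hemi))
        n_excl = min(n_excl, design.n_parcels_per_hemi - 1)
        order = np.argsort(seed_coords[:, 1])  # ascending y; last = most anterior
        excluded_local = set(order[len(order) - n_excl:]) if n_excl else set()
        for local, pid in enumerate(ids):
            rows.append(
                {
                    "parcel_id": int(pid),
                    "name": f"{hemi[0].upper()}{local:02d}",
                    "hemisphere": hemi,
                    "included": local not in excluded_local,
                }
            )
            centroids.append(seed_coords[local])
        next_id += design.n_parcels_per_hemi

    geometry = GridGeometry(coords=coords, hemisphere=sides, parcel_id=parcel_id)
    parcellation = Parcellation(table=pd.DataFrame(rows), centroids=np.asarray(centroids))
    return geometry, parcellation


def gen_behavior(design: SynthDesign) -> pd.DataFrame:
    """Draw the three language-performance scores, i.i.d. across subjects.

    Scores emulate letter fluency, category (animal) fluency, and the mean
    of the two rapid-naming tests; the three columns are generated
    independently, hence approximately uncorrelated in-sample.
    """
    rng = _rng(design, _STREAM_BEHAVIOR)
    loc_scale = {"fluency_s": (15.0, 4.0), "fluency_animal": (22.0, 5.0), "ran_ras_mean": (30.0, 6.0)}
    data = {"subject": np.arange(design.n_subjects)}
    for col in BEHAVIOR_COLUMNS:
        loc, scale = loc_scale[col]
        data[col] = rng.normal(loc, scale, size=design.n_subjects)
    return validate_behavior(pd.DataFrame(data))


def _edge_pair_mask(edge: PlantedEdge, geometry: GridGeometry, pairs: np.ndarray) -> np.ndarray:
    pa = geometry.parcel_id[pairs[:, 0]]
    pb = geometry.parcel_id[pairs[:, 1]]
    a, b = edge.parcel_a, edge.parcel_b
    return ((pa == a) & (pb == b)) | ((pa == b) & (pb == a))


def _behavior_combination(behavior: pd.DataFrame) -> np.ndarray:
    """Unit-variance equal-weight combination of the standardized scores."""
    z = behavior[list(BEHAVIOR_COLUMNS)].to_numpy(dtype=float)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    return z.sum(axis=1) / np.sqrt(z.shape[1])


def gen_connectivity(
    design: SynthDesign,
    geometry: GridGeometry,
    behavior: pd.DataFrame | None = None,
) -> tuple[ConnTensor, pd.DataFrame]:
    """Generate the coherence tensor and the ground-truth table.

    Coherence is realized as a per-connection baseline ``b_c ~ U(baseline
    range)`` for the visual task and ``b_c + contrast`` for naming, clipped
    to [0, 1]; the pipeline consumes only the difference.  Returns the
    tensor and a table with one row per planted edge (mu, sigma_b, sigma_e,
    theoretical ICC, coupled/boosted flags, number of grid pairs).
    """
    design.validate()
    coupled_keys = {e.key(): beta for e, beta in design.behavior_coupling}
    if coupled_keys and behavior is None:
        raise ValueError("behavior table required when behavior_coupling is set")

    rng = _rng(design, _STREAM_CONNECTIVITY)
    n_pts = geometry.n_points
    iu = np.triu_indices(n_pts, k=1)
    pairs = np.column_stack(iu).astype(int)
    m = len(pairs)
    ns = design.n_subjects
    bands = list(design.bands)
    windows = list(design.windows)
    sigma_e = design.session_noise_sd

    baseline = rng.uniform(*design.baseline_range, size=m)
    score_comb = _behavior_combination(behavior) if behavior is not None else None

    values = np.empty((ns, 2, 2, len(bands), len(windows), m))
    planted_by_bw: dict[tuple[str, str], list[PlantedEdge]] = {}
    for e in design.planted_edges:
        planted_by_bw.setdefault((e.band, e.window), []).append(e)

    truth_rows = []
    n_clipped = 0
    n_total = 0
    for bi, band in enumerate(bands):
        for wi, window in enumerate(windows):
            delta = np.zeros((ns, m))
            for e in planted_by_bw.get((band, window), []):
                mask = _edge_pair_mask(e, geometry, pairs)
                n_pairs = int(mask.sum())
                if n_pairs == 0:
                    raise ValueError(
                        f"planted edge {e} has no grid pairs between its parcels"
                    )
                latent = rng.normal(e.mu, e.sigma_b, size=(ns, n_pairs))
                beta = coupled_keys.get(e.key())
                if beta is not None:
                    # per-pair share beta/n_pairs so the parcel-summed
                    # contrast gains exactly beta * score combination
                    latent += (beta / n_pairs) * score_comb[:, None]
                delta[:, mask] = latent
                truth_rows.append(
                    {
                        "parcel_a": min(e.parcel_a, e.parcel_b),
                        "parcel_b": max(e.parcel_a, e.parcel_b),
                        "band": band,
                        "window": window,
                        "mu": e.mu,
                        "sigma_b": e.sigma_b,
                        "sigma_e": sigma_e,
                        "theoretical_icc": design.theoretical_icc(e),
                        "coupled": beta is not None,
                        "boosted": design.structural_boost > 1
                        and design.theoretical_icc(e) > 0.4,
                        "direction": "increase" if e.mu >= 0 else "decrease",
                        "n_grid_pairs": n_pairs,
                    }
                )
            for d in range(2):
                eps = rng.normal(0.0, sigma_e, size=(ns, m)) if sigma_e > 0 else 0.0
                offset = (
                    rng.normal(0.0, design.session_offset_sd)
                    if design.session_offset_sd > 0
                    else 0.0
                )
                naming = baseline[None, :] + delta + eps + offset
                n_clipped += int(np.count_nonzero((naming < 0) | (naming > 1)))
                n_total += naming.size
                values[:, d, 0, bi, wi, :] = np.clip(naming, 0.0, 1.0)
                values[:, d, 1, bi, wi, :] = baseline[None, :]

    if n_total and n_clipped / n_total > 0.01:
        msg = (
            f"clipping affected {100 * n_clipped / n_total:.2f}% of naming values; "
            "the design is ill-scaled for the [0, 1] coherence range"
        )
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    tensor = ConnTensor(
        values=values,
        pairs=pairs,
        subjects=np.arange(ns),
        bands=bands,
        windows=windows,
    )
    truth_cols = [
        "parcel_a", "parcel_b", "band", "window", "mu", "sigma_b", "sigma_e",
        "theoretical_icc", "coupled", "boosted", "direction", "n_grid_pairs",
    ]
    ground_truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return tensor, ground_truth


def gen_structural(
    design: SynthDesign,
    parcellation: Parcellation,
    ground_truth: pd.DataFrame | None = None,
    decay_mm: float = 40.0,
    base_weight: float = 300.0,
    lognormal_sigma: float = 1.0,
) -> list[StructConnectome]:
    """Generate per-subject structural connectomes over included parcels.

    Baseline weights are heavy-tailed (log-normal) with an expectation that
    decays with inter-centroid distance, emulating the strong distance
    dependence of streamline counts.  Parcel pairs planted as reliable
    (ground-truth theoretical ICC > 0.4) are multiplied by
    ``design.structural_boost``.
    """
    design.validate()
    rng = _rng(design, _STREAM_STRUCTURAL)
    included = parcellation.table["included"].to_numpy(dtype=bool)
    node_ids = parcellation.parcel_ids[included]
    cents = parcellation.centroids[included]
    p = len(node_ids)
    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    expectation = base_weight * np.exp(-d / decay_mm)

    boost = np.ones((p, p))
    if ground_truth is not None and len(ground_truth):
        boosted = ground_truth.loc[ground_truth["boosted"], ["parcel_a", "parcel_b"]]
        pos = {int(pid): i for i, pid in enumerate(node_ids)}
        for _, row in boosted.iterrows():
            a, b = int(row["parcel_a"]), int(row["parcel_b"])
            if a in pos and b in pos:
                boost[pos[a], pos[b]] = boost[pos[b], pos[a]] = design.structural_boost

    out = []
    iu = np.triu_indices(p, k=1)
    for s in range(design.n_subjects):
        noise = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(iu[0]))
        w = np.zeros((p, p))
        w[iu] = expectation[iu] * noise * boost[iu]
        w = w + w.T
        out.append(StructConnectome(subject=s, node_ids=node_ids, weights=w))
    return out


@dataclass
class SynthDataset:
    """Everything one simulated study produces."""

    design: SynthDesign
    geometry: GridGeometry
    parcellation: Parcellation
    tensor: ConnTensor
    ground_truth: pd.DataFrame
    behavior: pd.DataFrame
    connectomes: list


def simulate_dataset(design: SynthDesign) -> SynthDataset:
    """Run all generators in order (geometry, behavior, connectivity, structural)."""
    geometry, parcellation = gen_geometry(design)
    behavior = gen_behavior(design)
    tensor, ground_truth = gen_connectivity(design, geometry, behavior=behavior)
    connectomes = gen_structural(design, parcellation, ground_truth)
    return SynthDataset(design, geometry, parcellation, tensor, ground_truth, behavior, connectomes)


def gen_edge_matrices(
    n_edges: int,
    n_subjects: int,
    mu: float,
    sigma_b: float,
    sigma_e: float,
    rng: np.random.Generator,
    k: int = 2,
) -> np.ndarray:
    """Subject × session contrast matrices under the generative noise model.

    Returns shape (n_edges, n_subjects, k): ``delta_s + eps_{s,d}`` with
    ``delta ~ N(mu, sigma_b^2)`` and ``eps ~ N(0, sigma_e^2)``.  This is the
    same model the tensor generator uses per grid-pair connection, exposed
    directly for ICC calibration studies.
    """
    delta = rng.normal(mu, sigma_b, size=(n_edges, n_subjects, 1))
    eps = rng.normal(0.0, sigma_e, size=(n_edges, n_subjects, k))
    return delta + eps


def null_design(
    seed: int = 0,
    n_grid_points: int = 142,
    n_subjects: int = 19,
    session_noise_sd: float = 0.01,
) -> SynthDesign:
    """A design with no planted effects: one band, one window.

    The default grid size yields 10011 grid-pair connections, a convenient
    scale for checking the false-positive calibration of the selection
    stage.
    """
    return SynthDesign(
        n_subjects=n_subjects,
        n_grid_points=n_grid_points,
        n_parcels_per_hemi=5,
        bands={"theta": (4.0, 7.0)},
        windows={"0-400": (0.0, 400.0)},
        session_noise_sd=session_noise_sd,
        seed=seed,
    )


def strong_effect_design(seed: int = 0) -> SynthDesign:
    """The documented strong-effect preset for end-to-end recovery studies.

    Plants twelve parcel edges in two tiers sharing the session noise
    sd 0.01: six reliable edges (sigma_b = 0.03, population ICC 0.9,
    contrast 0.06 per grid pair, behaviorally coupled, structurally
    boosted) and six unreliable edges (sigma_b = 0.003, population ICC
    about 0.08, contrast 0.04, uncoupled, unboosted).  Edge locations are
    chosen among included parcels with inter-centroid distance >= 60 mm so
    the 4 cm endpoint filter cannot remove whole bundles, and with at
    least 12 grid points per parcel so a planted pair supports well over
    the 20-connection bundle minimum; directions alternate so both
    modulation signs occur.
    """
    base = SynthDesign(
        n_subjects=19,
        n_grid_points=400,
        n_parcels_per_hemi=8,
        bands={"high_beta": (21.0, 30.0), "low_gamma": (31.0, 45.0)},
        windows={"0-400": (0.0, 400.0), "400-800": (400.0, 800.0), "800-1200": (800.0, 1200.0)},
        session_noise_sd=0.01,
        structural_boost=5.0,
        seed=seed,
    )
    geometry, parcellation = gen_geometry(base)
    point_counts = {
        int(pid): int((geometry.parcel_id == pid).sum())
        for pid in parcellation.parcel_ids
    }
    big_enough = parcellation.table["parcel_id"].map(lambda p: point_counts[int(p)] >= 12)
    usable = parcellation.table["included"] & big_enough
    ids = parcellation.table.loc[usable, "parcel_id"].to_numpy()
    cents = parcellation.centroids[usable.to_numpy(dtype=bool)]
    # deterministic choice of well-separated parcel pairs
    far_pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.linalg.norm(cents[i] - cents[j]) >= 60.0:
                far_pairs.append((int(ids[i]), int(ids[j])))
    if len(far_pairs) < 12:
        raise ValueError("geometry offers too few well-separated parcel pairs")
    pick = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
    chosen = [far_pairs[i] for i in pick.choice(len(far_pairs), size=12, replace=False)]
    # the parcel-summed contrast scales with the grid-pair count of the pair;
    # alternate tiers through the count-sorted pairs so the planted per-pair
    # strength difference, not parcel size, separates the tiers
    chosen.sort(key=lambda ab: point_counts[ab[0]] * point_counts[ab[1]], reverse=True)
    tiers = ["reliable", "unreliable"] * 6

    bw = [(b, w) for b in base.bands for w in base.windows]
    planted, coupling = [], []
    for t, ((a, b), tier) in enumerate(zip(chosen, tiers)):
        band, window = bw[t % len(bw)]
        sign = 1.0 if t % 2 == 0 else -1.0
        direction = "increase" if sign > 0 else "decrease"
        if tier == "reliable":
            e = PlantedEdge(a, b, band, window, mu=sign * 0.06, sigma_b=0.03,
                            direction=direction)
            planted.append(e)
            coupling.append((e, 1.0))
        else:
            e = PlantedEdge(a, b, band, window, mu=sign * 0.04, sigma_b=0.003,
                            direction=direction)
            planted.append(e)
    base.planted_edges = planted
    base.behavior_coupling = coupling
    return base
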