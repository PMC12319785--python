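"""End-to-end orchestration: select → reliability → properties (+ structural).

``run_pipeline`` ties the stages together in analysis order, writes
per-stage TSVs plus a JSON run manifest, and returns the in-memory
results.  All numeric defaults in :class:`PipelineConfig` are the
analysis constants of the published procedure and every one is
overridable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .datatypes import ConnTensor, GridGeometry, Parcellation, StructConnectome
from .properties import (
    behavior_association,
    laterality,
    property_report,
    strength_summary,
    PropertyReport,
)
from .reliability import icc_report
from .selection import SELECTION_ALPHAS, power_screen, select_parcel_edges
from .structnet import structural_profiles

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    selection: str = "B"  # 'A' (1e-3) or 'B' (1e-4)
    icc_threshold: float = 0.4
    bundle_min_size: int = 20
    bundle_max_link_mm: float = 13.0
    min_endpoint_distance_mm: float = 40.0
    power_threshold: float = 0.20
    power_min_subjects: int = 5
    chi2_correction: str = "auto"  # 'auto' | 'on' | 'off'
    conf: float = 0.95
    seed: int = 0

    def alpha(self) -> float:
        try:
            return SELECTION_ALPHAS[self.selection]
        except KeyError:
            raise ValueError("selection preset must be 'A' or 'B'") from None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    edge_table: pd.DataFrame
    series: dict  # edge key -> (n_subjects, 2) summed contrast
    report: PropertyReport | None
    manifest: dict


def _check_subjects(tensor: ConnTensor, behavior: pd.DataFrame,
                    connectomes: list[StructConnectome] | None) -> None:
    subj_t = set(int(s) for s in tensor.subjects)
    subj_b = set(int(s) for s in behavior["subject"])
    problems = []
    if subj_t != subj_b:
        problems.append(f"connectivity vs behavior: {sorted(subj_t ^ subj_b)}")
    if connectomes is not None:
        subj_s = set(c.subject for c in connectomes)
        if subj_t != subj_s:
            problems.append(f"connectivity vs structural: {sorted(subj_t ^ subj_s)}")
    if problems:
        raise ValueError("subject mismatch across inputs: " + "; ".join(problems))


def run_pipeline(
    tensor: ConnTensor,
    geometry: GridGeometry,
    parcellation: Parcellation,
    behavior: pd.DataFrame,
    connectomes: list[StructConnectome] | None = None,
    config: PipelineConfig | None = None,
    outdir=None,
    input_checksums: dict | None = None,
    power: np.ndarray | None = None,
) -> PipelineResult:
    """Execute selection, ICC, and property stages; optionally write results.

    Stage outputs (written when ``outdir`` is given): ``series.tsv``
    (per-edge summed contrasts), ``icc.tsv`` (one row per edge with ICC,
    95% CI, label, direction, laterality, strength, behavioral fit, and
    structural profile), ``report.tsv`` + ``report.txt`` (the pooled
    consistent-vs-inconsistent comparisons), and ``manifest.json`` (config
    hash, input checksums, per-stage edge counts and timings).
    """
    config = config or PipelineConfig()
    _check_subjects(tensor, behavior, connectomes)
    timings = {}
    counts = {}

    if power is not None:
        flags = power_screen(power, config.power_threshold, config.power_min_subjects)
        counts["power_flagged"] = int(np.count_nonzero(flags))
        if counts["power_flagged"]:
            logger.warning(
                "power screen: %d parcel/band/window entries exceed the %d%% "
                "task power difference in >= %d subjects (reported, not excluded)",
                counts["power_flagged"], int(100 * config.power_threshold),
                config.power_min_subjects,
            )

    t0 = time.perf_counter()
    selected = select_parcel_edges(
        tensor, geometry, parcellation,
        alpha=config.alpha(),
        min_endpoint_distance=config.min_endpoint_distance_mm,
        max_link=config.bundle_max_link_mm,
        min_size=config.bundle_min_size,
    )
    timings["select_s"] = round(time.perf_counter() - t0, 3)
    counts["parcel_edges"] = len(selected)
    logger.info("selection %s: %d parcel edges", config.selection, len(selected))

    t0 = time.perf_counter()
    rows = []
    series_map = {}
    for se in selected:
        edge = se.edge
        res = icc_report(se.series, threshold=config.icc_threshold, conf=config.conf)
        beh = behavior_association(se.series.mean(axis=1), behavior, edge)
        row = {
            "parcel_a": edge.parcel_a,
            "parcel_b": edge.parcel_b,
            "band": edge.band,
            "window": edge.window,
            "direction": edge.direction,
            "laterality": laterality(edge, parcellation),
            "icc": res.icc,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "label": res.label,
            "strength": strength_summary(se.series),
            "F": beh.F,
            "p_behavior": beh.p,
            "fitted": beh.fitted,
        }
        rows.append(row)
        series_map[edge.key()] = se.series
    edge_table = pd.DataFrame(
        rows,
        columns=[
            "parcel_a", "parcel_b", "band", "window", "direction", "laterality",
            "icc", "ci_low", "ci_high", "label", "strength", "F", "p_behavior", "fitted",
        ],
    )
    timings["reliability_s"] = round(time.perf_counter() - t0, 3)
    counts["consistent"] = int((edge_table["label"] == "consistent").sum()) if len(edge_table) else 0

    if connectomes is not None and len(selected):
        t0 = time.perf_counter()
        profiles = structural_profiles([se.edge for se in selected], connectomes)
        edge_table["mean_streamlines"] = [p.mean_streamlines for p in profiles]
        edge_table["mean_spl"] = [p.mean_spl for p in profiles]
        edge_table["mean_ebc"] = [p.mean_ebc for p in profiles]
        timings["structural_s"] = round(time.perf_counter() - t0, 3)

    report = None
    if len(edge_table):
        t0 = time.perf_counter()
        report = property_report(edge_table, continuity=config.chi2_correction)
        timings["properties_s"] = round(time.perf_counter() - t0, 3)
    else:
        logger.info("no parcel edges selected; downstream reports are empty")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "input_checksums": input_checksums or {},
        "edge_counts": counts,
        "stage_timings": timings,
        "n_subjects": int(tensor.n_subjects),
        "n_connections": int(tensor.n_connections),
    }

    result = PipelineResult(
        config=config, edge_table=edge_table, series=series_map, report=report, manifest=manifest
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_tsv(outdir / "icc.tsv", result.edge_table)

    series_rows = []
    for (a, b, band, window), series in sorted(result.series.items()):
        for s in range(series.shape[0]):
            for d in (1, 2):
                series_rows.append((a, b, band, window, s, d, series[s, d - 1]))
    rio.write_tsv(
        outdir / "series.tsv",
        pd.DataFrame(
            series_rows,
            columns=["parcel_a", "parcel_b", "band", "window", "subject", "session", "value"],
        ),
    )

    report_rows = []
    rep = result.report
    if rep is not None:
        if rep.consistency_fit_chi2:
            c = rep.consistency_fit_chi2
            report_rows.append(("consistency_x_fit_chi2", c.statistic, c.p, c.df,
                                json.dumps(c.group_summaries)))
        if rep.laterality_direction_chi2:
            c = rep.laterality_direction_chi2
            report_rows.append(("laterality_x_direction_chi2", c.statistic, c.p, c.df,
                                json.dumps(c.group_summaries)))
        for metric, c in rep.comparisons.items():
            if c is not None:
                report_rows.append((f"mwu_{metric}", c.statistic, c.p, None,
                                    json.dumps(c.group_summaries)))
    rio.write_tsv(
        outdir / "report.tsv",
        pd.DataFrame(report_rows, columns=["test", "statistic", "p", "df", "details"]),
    )
    (outdir / "report.txt").write_text(format_report(result))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True) + "\n")


def format_report(result: PipelineResult) -> str:
    lines = []
    rep = result.report
    n_edges = len(result.edge_table)
    lines.append(f"Selected parcel edges (pooled over bands and windows): {n_edges}")
    if rep is None:
        lines.append("No edges selected; nothing to compare.")
        return "\n".join(lines) + "\n"
    pct = 100.0 * rep.n_consistent / n_edges if n_edges else 0.0
    lines.append(
        f"Consistent (ICC > {result.config.icc_threshold}): {rep.n_consistent} "
        f"({pct:.1f}%); inconsistent: {rep.n_inconsistent}"
    )
    if rep.consistency_fit_chi2:
        c = rep.consistency_fit_chi2
        lines.append(
            f"Consistency x behavioral fit: chi2({c.df}, N={c.group_summaries['N']}) = "
            f"{c.statistic:.2f}, p = {c.p:.3g}"
            + (" (Yates)" if c.continuity_correction else "")
        )
    if rep.laterality_direction_chi2:
        c = rep.laterality_direction_chi2
        lines.append(
            f"Laterality x direction (consistent edges): chi2({c.df}, "
            f"N={c.group_summaries['N']}) = {c.statistic:.2f}, p = {c.p:.3g}"
        )
    for metric, c in rep.comparisons.items():
        if c is None:
            continue
        g = c.group_summaries
        lines.append(
            f"{metric}: median consistent {g['median_a']:.4g} vs inconsistent "
            f"{g['median_b']:.4g}; U = {c.statistic:.6g}, p = {c.p:.3g}"
        )
    for notice in rep.notices:
        lines.append(f"note: {notice}")
    return "\n".join(lines) + "\n"


def file_checksums(paths: dict) -> dict:
    out = {}
    for name, path in paths.items():
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        out[name] = h.hexdigest()[:16]
    return out
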