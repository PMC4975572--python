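"""Readers, writers, run configuration and the one-shot pipeline.

Coordinate files are comma-separated with a header row and columns
``fibre_id, group, x_um, y_um, z_um`` — one row per nucleus, multiple fibres
per file, everything in micrometres.  Result tables are tab-separated; numbers
in them are printed with 4 significant figures, with full precision retained
in a JSON sidecar that the ``compare`` stage consumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FibreOrderError, ParseError, PipelineError
from .score import (
    AnovaReport,
    GroupSummary,
    OrdernessResult,
    compare_groups,
    score_fibre,
    summarize_groups,
)
from .synthetic import FibreRecord

log = logging.getLogger(__name__)

COORD_COLUMNS = ["fibre_id", "group", "x_um", "y_um", "z_um"]

RESULT_COLUMNS = [
    "fibre_id", "group", "n_nuclei", "radius_um", "length_um",
    "ME_um", "MR_um", "MR_se_um", "MO_um", "g", "g_percent", "flags",
]

MIN_NUCLEI = 4


@dataclass(frozen=True)
class RunConfig:
    """Run parameters for the scoring pipeline.

    metric
        ``geodesic`` (unrolled-cylinder distance, default) or ``chord``
        (3D straight-line distance between projected surface points).
    mr_reps
        Monte-Carlo repetitions for the random reference MR.
    mo_restarts, mo_iterations
        Restarts and per-restart iterations of the maximin optimizer for MO.
    master_seed
        Single seed from which all per-fibre sub-seeds are derived.
    min_separation
        Optional surface distance (µm) below which near-duplicate nuclei are
        collapsed before scoring; None disables the filter.
    clip_g
        Clip g into [0, 1] instead of flagging out-of-range values.
    """

    metric: str = "geodesic"
    mr_reps: int = 1000
    mo_restarts: int = 8
    mo_iterations: int = 2000
    master_seed: int = 0
    min_separation: float | None = None
    clip_g: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.metric not in ("geodesic", "chord"):
            raise ValueError(f"unknown metric {self.metric!r}")
        for name in ("mr_reps", "mo_restarts", "mo_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def digest(self) -> str:
        """Stable 12-hex-digit digest of the configuration."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def read_fibres(path: str | Path) -> list[FibreRecord]:
    """Read a coordinate file into fibre records, preserving input order.

    Raises :class:`ParseError` (with line numbers, header = line 1) on missing
    columns, non-numeric coordinates, or a fibre whose rows disagree on the
    group label.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"fibre_id": str, "group": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        log.warning("%s: empty coordinate file", path)
        return []
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} in header (line 1)")
    if df.empty:
        log.warning("%s: no coordinate rows", path)
        return []
    for col in ("x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ParseError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = coerced
    records = []
    for fid in df["fibre_id"].unique():
        sub = df[df["fibre_id"] == fid]
        groups = sub["group"].unique()
        if len(groups) > 1:
            lines = ", ".join(str(i + 2) for i in sub.index[:5])
            raise ParseError(
                f"{path}: fibre {fid!r} has conflicting group labels {list(groups)} "
                f"(lines {lines}, ...)"
            )
        records.append(
            FibreRecord(fibre_id=str(fid), group=str(groups[0]),
                        nuclei=sub[["x_um", "y_um", "z_um"]].to_numpy())
        )
    return records


def write_fibres(records: list[FibreRecord], path: str | Path) -> None:
    """Write fibre records in the standard coordinate format (full precision)."""
    frames = []
    for r in records:
        frames.append(pd.DataFrame({
            "fibre_id": r.fibre_id,
            "group": r.group,
            "x_um": r.nuclei[:, 0],
            "y_um": r.nuclei[:, 1],
            "z_um": r.nuclei[:, 2],
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COORD_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def write_fit_table(records: list[FibreRecord], path: str | Path) -> None:
    """Standalone geometry summary: fit each fibre's cylinder and write a
    tab-separated table ``fibre_id, n_nuclei, radius_um, length_um``.
    Fibres that cannot be fitted are skipped with a warning."""
    from .geometry import fit_cylinder

    with open(path, "w") as fh:
        fh.write("fibre_id\tn_nuclei\tradius_um\tlength_um\n")
        for r in records:
            try:
                cyl = fit_cylinder(r.nuclei)
            except FibreOrderError as exc:
                log.warning("fit table: fibre %s skipped (%s)", r.fibre_id, exc)
                continue
            fh.write(f"{r.fibre_id}\t{r.nuclei.shape[0]}\t{_fmt(cyl.radius)}\t{_fmt(cyl.length)}\n")


def _fmt(x: float) -> str:
    """4-significant-figure presentation format."""
    return f"{x:.4g}"


def _result_row(r: OrdernessResult) -> dict:
    return {
        "fibre_id": r.fibre_id,
        "group": r.group,
        "n_nuclei": r.n_nuclei,
        "radius_um": r.radius_um,
        "length_um": r.length_um,
        "ME_um": r.me,
        "MR_um": r.mr,
        "MR_se_um": r.mr_se,
        "MO_um": r.mo,
        "g": r.g,
        "g_percent": r.g_percent,
        "flags": ";".join(r.flags),
    }


def write_results(results: list[OrdernessResult], out_dir: str | Path) -> tuple[Path, Path]:
    """Write the per-fibre table (``scores.tsv``, 4 s.f.) and its full-precision
    JSON sidecar (``scores.json``).  Returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [_result_row(r) for r in results]
    tsv = out / "scores.tsv"
    with open(tsv, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(
                _fmt(row[c]) if isinstance(row[c], float) else str(row[c])
                for c in RESULT_COLUMNS
            ) + "\n")
    sidecar = out / "scores.json"
    payload = [dataclasses.asdict(r) | {"flags": list(r.flags)} for r in results]
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return tsv, sidecar


def read_results(path: str | Path) -> list[OrdernessResult]:
    """Read the full-precision sidecar back into result objects."""
    with open(path) as fh:
        payload = json.load(fh)
    return [OrdernessResult(**(d | {"flags": tuple(d["flags"])})) for d in payload]


def write_group_outputs(
    summaries: list[GroupSummary],
    report: AnovaReport | None,
    out_dir: str | Path,
) -> None:
    """Write the group table, the plain-text ANOVA block and its key-value twin."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "groups.tsv", "w") as fh:
        fh.write("group\tn_fibres\tmean_g_percent\tse_g_percent\n")
        for s in summaries:
            fh.write(f"{s.group}\t{s.n_fibres}\t{_fmt(s.mean_g_percent)}\t{_fmt(s.se_g_percent)}\n")
    lines = []
    kv = {}
    if report is None:
        lines.append("ANOVA: not performed (fewer than 2 groups)")
    else:
        lines.append("One-way ANOVA on per-fibre orderness (g, percent)")
        lines.append(
            f"F({report.df_between}, {report.df_within}) = {_fmt(report.F)}, p = {_fmt(report.p)}"
        )
        lines.append("Bonferroni-adjusted pairwise comparisons:")
        kv.update({
            "F": report.F, "df_between": report.df_between,
            "df_within": report.df_within, "p": report.p,
        })
        for (a, b), p in sorted(report.pairwise_bonferroni_p.items()):
            lines.append(f"  {a} vs {b}: p = {_fmt(p)}")
            kv[f"p_{a}_vs_{b}"] = p
    with open(out / "anova.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(out / "anova.yaml", "w") as fh:
        yaml.safe_dump(kv, fh, sort_keys=True)


@dataclass(frozen=True)
class PipelineResult:
    results: list[OrdernessResult]
    failures: dict[str, str]
    summaries: list[GroupSummary]
    anova: AnovaReport | None


def run_pipeline(
    input_path: str | Path, config: RunConfig, out_dir: str | Path
) -> PipelineResult:
    """Score every fibre in a coordinate file and write all output artefacts.

    Fibres that fail a stage (too few nuclei, degenerate geometry, ...) are
    recorded in ``failures.tsv`` and excluded from group statistics; the run
    itself fails (:class:`PipelineError`) only if *every* fibre fails.
    Identical input + config + seed reproduce all output files byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fibres = read_fibres(input_path)
    results: list[OrdernessResult] = []
    failures: dict[str, str] = {}
    for fibre in fibres:
        if fibre.nuclei.shape[0] < MIN_NUCLEI:
            failures[fibre.fibre_id] = f"only {fibre.nuclei.shape[0]} nuclei (need >= {MIN_NUCLEI})"
            log.warning("fibre %s excluded: %s", fibre.fibre_id, failures[fibre.fibre_id])
            continue
        try:
            results.append(score_fibre(fibre, config))
        except FibreOrderError as exc:
            failures[fibre.fibre_id] = f"{type(exc).__name__}: {exc}"
            log.warning("fibre %s failed: %s", fibre.fibre_id, failures[fibre.fibre_id])
    if fibres and not results:
        raise PipelineError("all fibres failed; see failures")
    write_results(results, out)
    with open(out / "failures.tsv", "w") as fh:
        fh.write("fibre_id\treason\n")
        for fid, reason in failures.items():
            fh.write(f"{fid}\t{reason}\n")
    try:
        summaries, anova = compare_groups(results)
    except FibreOrderError as exc:
        log.warning("group comparison skipped: %s", exc)
        summaries, anova = (summarize_groups(results) if results else []), None
    write_group_outputs(summaries, anova, out)
    meta = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "master_seed": config.master_seed,
        "fibreorder_version": __version__,
        "n_fibres_scored": len(results),
        "n_fibres_failed": len(failures),
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return PipelineResult(results=results, failures=failures, summaries=summaries, anova=anova)
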