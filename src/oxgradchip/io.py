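"""File formats and run configuration.

Delimited text for tracks, profiles and summaries; TIFF for intensity and
concentration fields; YAML for the run configuration.  Track files carry a
header (track_id, frame, t_min, x_um, y_um[, label]) with one row per
(track, frame); an import dialect maps MTrackJ-style point exports onto
this schema.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .chip_model import ChipGeometry, ConcentrationField, MaterialProps
from .errors import ValidationError
from .synthetic import WalkParams
from .track_stats import AngularHistogram, TrackSet

REQUIRED_TRACK_COLUMNS = ("track_id", "frame", "t_min", "x_um", "y_um")


@dataclass(frozen=True)
class TrackFileDialect:
    """How a delimited track file maps onto the canonical schema.

    ``columns`` maps file column names to canonical names; canonical names
    absent from the map are looked up verbatim.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(default_factory=dict)
    label_column: str | None = "label"


#: MTrackJ "Points" table export (one row per tracked point)
MTRACKJ_DIALECT = TrackFileDialect(
    delimiter=",",
    columns={
        "TID": "track_id",
        "PID": "frame",
        "t [min]": "t_min",
        "x [um]": "x_um",
        "y [um]": "y_um",
    },
    label_column=None,
)


def parse_tracks(
    path: str | Path, dialect: TrackFileDialect = TrackFileDialect()
) -> TrackSet:
    """Read a delimited track file into a validated TrackSet.

    Rows are sorted by (track_id, t); missing columns, duplicated
    (track, frame) rows, non-numeric coordinates and non-monotone times
    are rejected with the offending row/field named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    df = df.rename(columns=dict(dialect.columns))
    for col in REQUIRED_TRACK_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    for col in ("t_min", "x_um", "y_um"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValidationError(
                f"{path.name}: non-numeric value in column {col!r} at line {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 2
            raise ValidationError(
                f"{path.name}: missing value in column {col!r} at line {row}"
            )
        df[col] = converted
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = df.loc[dup, ["track_id", "frame"]].iloc[0]
        raise ValidationError(
            f"{path.name}: duplicated (track, frame) = "
            f"({row['track_id']}, {row['frame']})"
        )
    if dialect.label_column and dialect.label_column in df.columns:
        df = df.rename(columns={dialect.label_column: "label"})
    df = df.sort_values(["track_id", "t_min"], kind="mergesort")
    try:
        return TrackSet.from_frame(df, name=path.stem)
    except ValidationError as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc


def write_tracks(
    tracks: TrackSet, path: str | Path, dialect: TrackFileDialect = TrackFileDialect()
) -> Path:
    """Write a TrackSet in the canonical delimited schema."""
    path = Path(path)
    df = tracks.to_frame()
    df.to_csv(path, sep=dialect.delimiter, index=False)
    return path


def write_field_tiff(
    fields: ConcentrationField | Sequence[ConcentrationField], path: str | Path
) -> Path:
    """Export concentration fields as a 32-bit float TIFF, one page per
    time point (row 0 of each page = chip bottom)."""
    if isinstance(fields, ConcentrationField):
        fields = [fields]
    if not fields:
        raise ValidationError("no fields to write")
    stack = np.stack([f.values for f in fields]).astype(np.float32)
    if stack.shape[0] == 1:
        stack = stack[0]  # single time point: plain 2D image
    path = Path(path)
    tifffile.imwrite(path, stack)
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF intensity image (or stack) as float."""
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_image(img: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    return path


@dataclass
class OximetrySettings:
    strip_width: int = 10
    c_ambient: float = 21.0
    gradient_axis: int = 1


@dataclass
class AnalysisSettings:
    gradient_axis: str = "x"
    gradient_sign: int = 1
    n_bins: int = 8
    aggregation: str = "per_cell"


@dataclass
class RunConfig:
    """Validated run configuration binding all pipeline stages."""

    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    materials: MaterialProps = field(default_factory=MaterialProps)
    oximetry: OximetrySettings = field(default_factory=OximetrySettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    synth: WalkParams = field(default_factory=WalkParams)
    seed: int = 0
    out_dir: str = "results"


def _build_section(cls, data: Mapping, where: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        warnings.warn(
            f"config section {where!r}: ignoring unknown keys {unknown}",
            stacklevel=3,
        )
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"config section {where!r}: {exc}") from exc


def read_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are not fatal: they are reported in a warning listing
    them, so typos surface without blocking a run.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path.name}: top level must be a mapping")
    sections = {
        "geometry": ChipGeometry,
        "materials": MaterialProps,
        "oximetry": OximetrySettings,
        "analysis": AnalysisSettings,
        "synth": WalkParams,
    }
    unknown = sorted(set(raw) - set(sections) - {"seed", "out_dir"})
    if unknown:
        warnings.warn(f"config {path.name}: ignoring unknown keys {unknown}", stacklevel=2)
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ValidationError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, raw[name], name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kwargs["out_dir"] = str(raw["out_dir"])
    return RunConfig(**kwargs)


def write_report(
    out_dir: str | Path,
    summaries: Mapping[str, pd.DataFrame],
    aggregate: pd.DataFrame | None = None,
    histograms: Mapping[str, AngularHistogram] | None = None,
    comparisons: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write analysis outputs plus run metadata to ``out_dir``.

    Emits one per-cell summary table per condition, the per-condition
    aggregate, histogram tables, an optional comparisons table, and
    ``run_metadata.json`` recording config, seed and library versions.
    File contents are deterministic given identical inputs (timestamps are
    deliberately omitted).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []

    for cond, df in summaries.items():
        p = out_dir / f"summary_{cond}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if aggregate is not None:
        p = out_dir / "aggregate.csv"
        aggregate.to_csv(p, index=False)
        written.append(p)
    for cond, hist in (histograms or {}).items():
        p = out_dir / f"histogram_{cond}.csv"
        hist.to_frame().to_csv(p, index=False)
        written.append(p)
    comparisons_written = comparisons is not None and len(comparisons) > 0
    if comparisons_written:
        p = out_dir / "comparisons.csv"
        comparisons.to_csv(p, index=False)
        written.append(p)

    meta = {
        "package": {"name": "oxgradchip", "version": __version__},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "conditions": sorted(summaries),
        "comparisons_written": bool(comparisons_written),
        "config": _config_dict(config) if config is not None else None,
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written


def _config_dict(config: RunConfig) -> dict:
    def section(obj):
        return {f.name: getattr(obj, f.name) for f in dc_fields(obj)}

    return {
        "geometry": section(config.geometry),
        "materials": section(config.materials),
        "oximetry": section(config.oximetry),
        "analysis": section(config.analysis),
        "synth": section(config.synth),
        "seed": config.seed,
        "out_dir": config.out_dir,
    }
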