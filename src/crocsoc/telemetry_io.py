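"""Reading, validation and writing of the study's tabular data.

All tables are plain CSV with a header row and ISO-8601 timestamps.
Timestamps are stored internally as timezone-aware UTC; calendar-month
assignment elsewhere in the package applies a configurable study-timezone
offset (the field site sits at UTC+10), because month boundaries depend
on it.

Schemas
-------
detections : tag_id, receiver_id, timestamp
receivers  : receiver_id, chainage_km [, x, y, active_from, active_to]
river      : vertex_index, x, y   (planar metres)  — or a GeoJSON LineString
individuals: individual_id, sex, total_length_m
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, shape

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["tag_id", "receiver_id", "timestamp"]
RECEIVER_COLUMNS = ["receiver_id", "chainage_km"]
INDIVIDUAL_COLUMNS = ["individual_id", "sex", "total_length_m"]
VALID_SEXES = {"male", "female", "unknown"}


class SchemaError(ValueError):
    """A required column is missing or a cell violates an invariant."""


@dataclass(frozen=True)
class RiverAxis:
    """A single-channel river centreline.

    Parameters
    ----------
    line : shapely.LineString
        Channel centreline in planar metres.

    The cumulative distance along the line, in km from the first vertex
    (the downstream origin), is the *chainage*. Chainage is strictly
    increasing along the vertex order by construction.
    """

    line: LineString

    def __post_init__(self) -> None:
        if self.line.is_empty or len(self.line.coords) < 2:
            raise SchemaError("river axis must have at least two vertices")
        if self.line.length <= 0:
            raise SchemaError("river axis must have positive length")

    @property
    def length_km(self) -> float:
        return self.line.length / 1000.0

    @property
    def vertex_chainage_km(self) -> np.ndarray:
        xy = np.asarray(self.line.coords)
        seg = np.hypot(*np.diff(xy, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(seg)]) / 1000.0

    @classmethod
    def straight(cls, length_km: float) -> "RiverAxis":
        """A straight west-east channel, handy for simulations."""
        return cls(LineString([(0.0, 0.0), (length_km * 1000.0, 0.0)]))

    def project(self, x: float, y: float) -> float:
        """Chainage (km) of the nearest centreline point to (x, y) metres.

        Distance is measured along the line; for a point equidistant from
        two parts of the channel the lower chainage wins (shapely's
        ``project`` returns the first — i.e. most downstream — nearest
        point along the line).
        """
        return self.line.project(Point(x, y)) / 1000.0


class StudyData(NamedTuple):
    detections: pd.DataFrame
    receivers: pd.DataFrame
    river_axis: RiverAxis
    individuals: pd.DataFrame


@dataclass
class ValidationReport:
    """Flags from cross-checking the loaded tables. Nothing is dropped."""

    orphan_receiver_rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    unknown_tag_rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    out_of_deployment_rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    detections_per_individual: pd.Series = field(default_factory=pd.Series)

    @property
    def clean(self) -> bool:
        return (
            self.orphan_receiver_rows.empty
            and self.unknown_tag_rows.empty
            and self.out_of_deployment_rows.empty
        )


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column '{col}'")


def _parse_timestamps(series: pd.Series, table: str) -> pd.Series:
    parsed = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise SchemaError(
            f"{table} table: unparseable timestamp {series[bad].iloc[0]!r} "
            f"at line {line}"
        )
    return parsed


def load_detections(path: str | Path) -> pd.DataFrame:
    """Load and de-duplicate a detection table.

    Exact duplicates (same tag, receiver and timestamp) are removed with a
    logged count; near-duplicates are kept. The result is sorted by
    (tag_id, timestamp).
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "receiver_id": str})
    _require_columns(df, DETECTION_COLUMNS, "detections")
    if (df["tag_id"].astype(str).str.len() == 0).any():
        raise SchemaError("detections table: empty tag_id")
    if (df["receiver_id"].astype(str).str.len() == 0).any():
        raise SchemaError("detections table: empty receiver_id")
    df["timestamp"] = _parse_timestamps(df["timestamp"], "detections")
    n0 = len(df)
    df = df.drop_duplicates(subset=DETECTION_COLUMNS)
    removed = n0 - len(df)
    if removed:
        logger.info("removed %d exact duplicate detection rows", removed)
    return (
        df.sort_values(["tag_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)[DETECTION_COLUMNS]
    )


def load_receivers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"receiver_id": str})
    _require_columns(df, RECEIVER_COLUMNS, "receivers")
    if (df["chainage_km"] < 0).any():
        bad = df.loc[df["chainage_km"] < 0, "receiver_id"].iloc[0]
        raise SchemaError(f"receivers table: negative chainage for receiver {bad!r}")
    if df["receiver_id"].duplicated().any():
        raise SchemaError("receivers table: duplicate receiver_id")
    for col in ("active_from", "active_to"):
        if col in df.columns:
            df[col] = _parse_timestamps(df[col], "receivers")
    if {"active_from", "active_to"} <= set(df.columns):
        both = df["active_from"].notna() & df["active_to"].notna()
        if (df.loc[both, "active_from"] >= df.loc[both, "active_to"]).any():
            raise SchemaError("receivers table: active_from must precede active_to")
    return df.reset_index(drop=True)


def load_individuals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    _require_columns(df, INDIVIDUAL_COLUMNS, "individuals")
    if (df["total_length_m"] <= 0).any():
        raise SchemaError("individuals table: total_length_m must be positive")
    unknown_sex = set(df["sex"]) - VALID_SEXES
    if unknown_sex:
        raise SchemaError(f"individuals table: invalid sex value(s) {unknown_sex}")
    return df.reset_index(drop=True)


def load_river_axis(path: str | Path) -> RiverAxis:
    """Load a river centreline from vertex CSV or a GeoJSON LineString."""
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        with open(path) as fh:
            gj = json.load(fh)
        geom = gj.get("geometry", gj) if gj.get("type") == "Feature" else gj
        line = shape(geom)
        if not isinstance(line, LineString):
            raise SchemaError("river GeoJSON must contain a LineString")
        return RiverAxis(line)
    df = pd.read_csv(path)
    _require_columns(df, ["x", "y"], "river")
    if "vertex_index" in df.columns:
        df = df.sort_values("vertex_index")
    return RiverAxis(LineString(df[["x", "y"]].to_numpy()))


def load_study(paths: Mapping[str, str | Path]) -> StudyData:
    """Load all four input tables.

    ``paths`` maps ``detections``, ``receivers``, ``river``, ``individuals``
    to file locations.
    """
    return StudyData(
        detections=load_detections(paths["detections"]),
        receivers=load_receivers(paths["receivers"]),
        river_axis=load_river_axis(paths["river"]),
        individuals=load_individuals(paths["individuals"]),
    )


def validate_study(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    individuals: pd.DataFrame,
) -> ValidationReport:
    """Cross-check the loaded tables; flags only, nothing is dropped."""
    known_receivers = set(receivers["receiver_id"])
    known_tags = set(individuals["individual_id"])

    orphan = detections[~detections["receiver_id"].isin(known_receivers)]
    unknown = detections[~detections["tag_id"].isin(known_tags)]

    out_rows = []
    if {"active_from", "active_to"} <= set(receivers.columns):
        merged = detections.merge(
            receivers[["receiver_id", "active_from", "active_to"]],
            on="receiver_id",
            how="inner",
        )
        before = merged["active_from"].notna() & (
            merged["timestamp"] < merged["active_from"]
        )
        after = merged["active_to"].notna() & (merged["timestamp"] > merged["active_to"])
        out_rows = merged.loc[before | after, DETECTION_COLUMNS]
    out_of_deployment = (
        pd.DataFrame(out_rows) if len(out_rows) else pd.DataFrame(columns=DETECTION_COLUMNS)
    )

    counts = detections.groupby("tag_id").size()
    return ValidationReport(
        orphan_receiver_rows=orphan.reset_index(drop=True),
        unknown_tag_rows=unknown.reset_index(drop=True),
        out_of_deployment_rows=out_of_deployment.reset_index(drop=True),
        detections_per_individual=counts,
    )


def _config_hash(config: object) -> str:
    text = json.dumps(config, default=str, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: object = None,
) -> dict:
    """Write each table as CSV and return (and save) a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "files": {}}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False)
        manifest["files"][fname] = {"rows": int(len(table))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
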