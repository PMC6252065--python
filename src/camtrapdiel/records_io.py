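"""Reading, validation and event-level filtering of detection tables.

Detections are held in a :class:`pandas.DataFrame` with one row per
detection event (a multi-animal image is a single event with a
``group_size``).  The canonical columns are listed in :data:`COLUMNS`;
:func:`read_detections` maps arbitrary input headers onto them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical detection-table columns.
COLUMNS = [
    "species",
    "site_id",
    "camera_id",
    "timestamp",
    "latitude",
    "longitude",
    "group_size",
]

SITE_COLUMNS = ["site_id", "latitude", "longitude", "utc_offset"]

#: Default separation below which two same-species captures at one camera
#: are treated as re-triggers of a single activity event.
DEFAULT_INDEPENDENCE_INTERVAL = timedelta(hours=1)


class SchemaError(ValueError):
    """A required column is missing or the header cannot be mapped."""


class RowError(ValueError):
    """One or more data rows failed validation; message lists row numbers."""


@dataclass(frozen=True)
class DetectionRecord:
    """One independent detection event of a species at a camera.

    A group of conspecifics captured in a single image is one record with
    ``group_size`` > 1, not several records.
    """

    species: str
    site_id: str
    camera_id: str
    timestamp: datetime
    latitude: float
    longitude: float
    group_size: int = 1

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.group_size < 1:
            raise ValueError(f"group_size {self.group_size} must be >= 1")


@dataclass
class EventStream:
    """Independence-filtered detections plus the interval that defined them."""

    records: pd.DataFrame
    independence_interval: timedelta = DEFAULT_INDEPENDENCE_INTERVAL
    n_removed: int = 0
    removed_per_species: Mapping[str, int] = field(default_factory=dict)


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Parse ISO-8601 timestamps, falling back to the DD/MM/YYYY HH:MM dialect."""
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        fallback = pd.to_datetime(raw[bad], errors="coerce", dayfirst=True)
        parsed = parsed.copy()
        parsed[bad] = fallback
    return parsed


def read_detections(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a detection CSV into the canonical detection table.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``{canonical_name: input_column_name}`` for files
        whose headers differ from :data:`COLUMNS`.  Unmapped canonical
        names are looked up verbatim.

    Returns
    -------
    pandas.DataFrame
        Sorted by (species, camera_id, timestamp), with ``timestamp`` as
        datetime64 and ``group_size`` defaulting to 1 where absent.

    Raises
    ------
    SchemaError
        If a required column is missing.
    RowError
        If any row has an unparseable timestamp or out-of-range
        coordinates; the message names the offending rows (1-based data
        row numbers, header excluded).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {}
    for canonical in COLUMNS:
        source = schema.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical != "group_size":
            raise SchemaError(f"{path}: missing required column {source!r}")
    df = raw.rename(columns=rename)
    if "group_size" not in df.columns:
        df["group_size"] = 1
    df = df[COLUMNS].copy()

    errors: list[str] = []
    ts = _parse_timestamps(df["timestamp"])
    for idx in df.index[ts.isna()]:
        errors.append(f"row {idx + 1}: unparseable timestamp {df.loc[idx, 'timestamp']!r}")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    for idx in df.index[lat.isna() | (lat < -90) | (lat > 90)]:
        errors.append(f"row {idx + 1}: latitude {df.loc[idx, 'latitude']!r} outside [-90, 90]")
    for idx in df.index[lon.isna() | (lon < -180) | (lon > 180)]:
        errors.append(f"row {idx + 1}: longitude {df.loc[idx, 'longitude']!r} outside [-180, 180]")
    gs = pd.to_numeric(df["group_size"], errors="coerce")
    for idx in df.index[gs.isna() | (gs < 1)]:
        errors.append(f"row {idx + 1}: group_size {df.loc[idx, 'group_size']!r} must be >= 1")
    if errors:
        raise RowError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))

    df["timestamp"] = ts.dt.floor("min")
    df["latitude"] = lat
    df["longitude"] = lon
    df["group_size"] = gs.astype(int)
    df["species"] = df["species"].astype(str)
    df["site_id"] = df["site_id"].astype(str)
    df["camera_id"] = df["camera_id"].astype(str)
    return df.sort_values(["species", "camera_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    """Write a detection table as CSV in the dialect read_detections consumes."""
    out = df[COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read the site table: site_id, latitude, longitude, utc_offset (hours)."""
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing site column(s) {missing}")
    df = df[SITE_COLUMNS].copy()
    df["site_id"] = df["site_id"].astype(str)
    return df


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    """Build a canonical detection table from DetectionRecord objects."""
    rows = [
        (r.species, r.site_id, r.camera_id, r.timestamp, r.latitude, r.longitude, r.group_size)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values(["species", "camera_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )


def filter_independent(
    records: pd.DataFrame,
    interval: timedelta = DEFAULT_INDEPENDENCE_INTERVAL,
) -> EventStream:
    """Keep only detections separated by at least ``interval`` per species-camera.

    A greedy forward scan per (species, camera_id): the first capture is
    retained, and each subsequent capture is retained iff it falls at
    least ``interval`` after the most recently *retained* capture of that
    species at that camera.  Captures in the same minute (burst triggers)
    collapse to one record first.  Consecutive retained events are then
    guaranteed to be >= ``interval`` apart.

    Raises
    ------
    ValueError
        If ``interval`` is negative.
    """
    if interval < timedelta(0):
        raise ValueError("independence interval must be non-negative")
    df = records.sort_values(["species", "camera_id", "timestamp"], kind="stable")
    df = df.drop_duplicates(subset=["species", "camera_id", "timestamp"], keep="first")

    keep_idx: list[int] = []
    for _, group in df.groupby(["species", "camera_id"], sort=False):
        last_kept: pd.Timestamp | None = None
        for idx, ts in zip(group.index, group["timestamp"]):
            if last_kept is None or ts - last_kept >= interval:
                keep_idx.append(idx)
                last_kept = ts
    kept = df.loc[keep_idx].sort_values(
        ["species", "camera_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)

    raw_counts = records.groupby("species").size()
    kept_counts = kept.groupby("species").size()
    removed = (raw_counts - kept_counts.reindex(raw_counts.index, fill_value=0)).astype(int)
    for sp, n_rm in removed.items():
        logger.info(
            "independence filter: %s %d raw -> %d independent (%d removed)",
            sp, raw_counts[sp], raw_counts[sp] - n_rm, n_rm,
        )
    return EventStream(
        records=kept,
        independence_interval=interval,
        n_removed=int(removed.sum()),
        removed_per_species=removed.to_dict(),
    )


def restrict_to_cooccurrence(
    records: pd.DataFrame,
    species_a: str,
    species_b: str,
    location_key: str = "site_id",
) -> tuple[pd.DataFrame, set[str]]:
    """Restrict a species pair to locations where both were detected.

    Returns the subset of ``records`` for the two species at shared
    locations, plus the retained location set.  ``location_key`` selects
    the notion of location (broad study area ``site_id`` by default, or
    individual ``camera_id``).
    """
    if location_key not in ("site_id", "camera_id"):
        raise ValueError(f"location_key must be site_id or camera_id, got {location_key!r}")
    present = set(records["species"])
    for sp in (species_a, species_b):
        if sp not in present:
            raise ValueError(f"species {sp!r} absent from detection table")
    locs_a = set(records.loc[records["species"] == species_a, location_key])
    locs_b = set(records.loc[records["species"] == species_b, location_key])
    shared = locs_a & locs_b
    if not shared:
        logger.warning("no shared %s for %s and %s", location_key, species_a, species_b)
    mask = records["species"].isin([species_a, species_b]) & records[location_key].isin(shared)
    return records.loc[mask].reset_index(drop=True), shared


def camera_days(records: pd.DataFrame) -> int:
    """Count active camera-days: distinct (camera, date) pairs with detections."""
    return int(
        records.assign(date=records["timestamp"].dt.date)
        .groupby(["camera_id", "date"])
        .ngroups
    )
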