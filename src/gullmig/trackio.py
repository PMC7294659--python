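"""Telemetry table I/O and preprocessing.

Input tracks are Movebank-dialect CSV (``timestamp``, ``location-long``,
``location-lat``, ``argos:lc``, ``individual-local-identifier``) plus a
populations manifest (``individual``, ``population``, ``colony_lon``,
``colony_lat``).  Preprocessing mirrors standard Argos practice before
state-space modelling: duplicate-timestamp removal (keep first) and an
iterative 200 km/h speed filter against the last retained fix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import haversine_km

log = logging.getLogger(__name__)

#: Argos Doppler quality grades plus F for GPS-quality (zero-error) fixes.
LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "F")

FIX_COLUMNS = ["timestamp", "location-long", "location-lat", "argos:lc",
               "individual-local-identifier"]
MANIFEST_COLUMNS = ["individual", "population", "colony_lon", "colony_lat"]


@dataclass(frozen=True)
class Track:
    """One individual's time-ordered fixes with population metadata.

    ``fixes`` columns: ``time`` (tz-aware UTC), ``lon``, ``lat``, ``lc``.
    """

    individual: str
    population: str
    colony: tuple[float, float]  # (lon, lat) degrees
    fixes: pd.DataFrame

    def __len__(self) -> int:
        return len(self.fixes)

    def with_fixes(self, fixes: pd.DataFrame) -> "Track":
        return replace(self, fixes=fixes.reset_index(drop=True))


def _validate_fixes(df: pd.DataFrame) -> None:
    bad_lat = ~df["location-lat"].between(-90.0, 90.0)
    bad_lon = ~df["location-long"].between(-180.0, 180.0)
    if bad_lat.any() or bad_lon.any():
        rows = df.index[bad_lat | bad_lon].tolist()[:5]
        raise ValueError(f"coordinates out of range at rows {rows}")
    lc = df["argos:lc"].astype(str)
    unknown = ~lc.isin(LOCATION_CLASSES)
    if unknown.any():
        row = int(df.index[unknown][0])
        raise ValueError(
            f"unknown location-class token {lc.iloc[row]!r} at row {row}; "
            f"expected one of {LOCATION_CLASSES}")


def read_tracks(fixes_path, manifest_path) -> list[Track]:
    """Read fixes + manifest CSVs into per-individual :class:`Track`\\ s.

    Fixes are grouped by individual and time-sorted (stable, so equal
    timestamps keep file order for the keep-first duplicate rule).  GPS
    rows with a missing ``argos:lc`` are assigned class F.  An individual
    present in the fixes but absent from the manifest is an error.
    """
    fixes_path, manifest_path = Path(fixes_path), Path(manifest_path)
    df = pd.read_csv(fixes_path, dtype={"argos:lc": str,
                                        "individual-local-identifier": str})
    missing = [c for c in FIX_COLUMNS if c not in df.columns and c != "argos:lc"]
    if missing:
        raise ValueError(f"{fixes_path}: missing columns {missing}")
    if "argos:lc" not in df.columns:
        df["argos:lc"] = "F"
    df["argos:lc"] = df["argos:lc"].fillna("F").astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    _validate_fixes(df)

    manifest = pd.read_csv(manifest_path, dtype={"individual": str})
    miss = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if miss:
        raise ValueError(f"{manifest_path}: missing columns {miss}")
    manifest = manifest.set_index("individual")

    tracks = []
    absent = sorted(set(df["individual-local-identifier"]) - set(manifest.index))
    if absent:
        raise ValueError(f"individuals missing from manifest: {absent}")
    for ind, grp in df.groupby("individual-local-identifier", sort=True):
        row = manifest.loc[ind]
        fixes = pd.DataFrame({
            "time": grp["timestamp"],
            "lon": grp["location-long"].astype(float),
            "lat": grp["location-lat"].astype(float),
            "lc": grp["argos:lc"],
        }).sort_values("time", kind="stable").reset_index(drop=True)
        tracks.append(Track(
            individual=str(ind),
            population=str(row["population"]),
            colony=(float(row["colony_lon"]), float(row["colony_lat"])),
            fixes=fixes,
        ))
    return tracks


def write_tracks(tracks: list[Track], fixes_path, manifest_path) -> None:
    """Write tracks back to the Movebank-dialect CSV pair."""
    frames, rows = [], []
    for t in tracks:
        frames.append(pd.DataFrame({
            "timestamp": t.fixes["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "location-long": t.fixes["lon"],
            "location-lat": t.fixes["lat"],
            "argos:lc": t.fixes["lc"],
            "individual-local-identifier": t.individual,
        }))
        rows.append({"individual": t.individual, "population": t.population,
                     "colony_lon": t.colony[0], "colony_lat": t.colony[1]})
    pd.concat(frames, ignore_index=True).to_csv(fixes_path, index=False)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)


def deduplicate(track: Track) -> Track:
    """Drop repeated timestamps, keeping the first occurrence.

    A duplicate is an identical (individual, timestamp) pair; when the
    coordinates differ the first-in-file row wins (documented rule).
    """
    fixes = track.fixes.drop_duplicates(subset="time", keep="first")
    return track.with_fixes(fixes)


def speed_filter(track: Track, vmax: float = 200.0) -> Track:
    """Remove fixes implying speed > ``vmax`` km/h from the last retained fix.

    Forward single pass: the first fix is retained; each subsequent fix
    is kept only if the great-circle speed from the previously *retained*
    fix is within ``vmax`` (McConnell-style re-linking).  Output is a
    subsequence of the input and the pass is idempotent.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    f = track.fixes
    if len(f) <= 1:
        return track.with_fixes(f)
    t = f["time"].astype("int64").to_numpy() / 1e9  # epoch seconds
    lon, lat = f["lon"].to_numpy(), f["lat"].to_numpy()
    keep = [0]
    for i in range(1, len(f)):
        j = keep[-1]
        dt_h = (t[i] - t[j]) / 3600.0
        if dt_h <= 0:
            keep.append(i)  # simultaneous after dedup should not occur
            continue
        d = haversine_km(lon[j], lat[j], lon[i], lat[i])
        if d / dt_h <= vmax:
            keep.append(i)
    removed = len(f) - len(keep)
    if removed:
        log.info("speed_filter: removed %d of %d fixes for %s",
                 removed, len(f), track.individual)
    return track.with_fixes(f.iloc[keep])


def preprocess(track: Track, vmax: float = 200.0) -> Track:
    """Deduplicate then speed-filter one track."""
    return speed_filter(deduplicate(track), vmax=vmax)
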