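"""Travel/stopover day classification and migration-window detection.

A regularized day is a *travel* day if either

1. within a 3-transition sliding window, the day-to-day latitude change
   exceeds a threshold (default 0.3 deg) in a consistent direction on at
   least 2 of the 3 transitions and the day's own change is one of them
   (sustained directed travel); or
2. the displacement from the previous day exceeds a jump threshold
   (default 75 km).

Otherwise it is a *stopover* day.  The two thresholds correspond to the
90th percentile of day-to-day latitude change and distance in the data
that motivated them; :func:`derive_thresholds` reproduces that
derivation for any input set.

Autumn migration starts on the first day of the travel period that
takes the bird beyond a 200 km radius of its breeding colony (the final
departure, so pre-migratory movements that loop back are excluded), and
ends with the travel period that arrives at the latitude where the bird
then remains for the winter.  "Remains" is operationalized as staying
within a +/-1 deg latitude band for at least 21 subsequent tracked days
— a stand-in rule whose parameters are exposed in the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import geodesic_km
from .ssm.model import DailyPath

log = logging.getLogger(__name__)

TRAVEL_LABEL = "travel"
STOPOVER_LABEL = "stopover"
NO_LABEL = ""   # gap-flagged days carry no label


@dataclass(frozen=True)
class ClassifierConfig:
    lat_step_deg: float = 0.3
    window: int = 3              # transitions per sliding window (fixed)
    require: int = 2             # qualifying transitions per window
    jump_km: float = 75.0
    colony_radius_km: float = 200.0
    percentile_mode: bool = False
    percentile: float = 90.0
    winter_band_deg: float = 1.0
    winter_dwell_days: int = 21
    bridge_single_gaps: bool = False

    def __post_init__(self) -> None:
        if self.lat_step_deg <= 0 or self.jump_km <= 0 or self.colony_radius_km <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")


@dataclass(frozen=True)
class MigrationWindow:
    detected: bool
    start: pd.Timestamp | None = None
    end: pd.Timestamp | None = None
    start_idx: int | None = None
    end_idx: int | None = None
    residency_confirmed: bool = True
    candidate_start_idx: tuple = ()
    reason: str = ""


@dataclass(frozen=True)
class StopoverSite:
    centroid: tuple          # (lon, lat)
    length_days: int
    start_idx: int
    end_idx: int


@dataclass
class DayLabelSeries:
    """Per-day labels plus the detected migration window for one track."""

    individual: str
    days: pd.DatetimeIndex
    labels: np.ndarray              # TRAVEL_LABEL/STOPOVER_LABEL/NO_LABEL
    migration_window: MigrationWindow
    stopover_sites: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        w = self.migration_window
        in_win = np.zeros(len(self.days), dtype=bool)
        if w.detected:
            in_win[w.start_idx:w.end_idx + 1] = True
        return pd.DataFrame({
            "individual": self.individual,
            "date": self.days.strftime("%Y-%m-%d"),
            "label": self.labels,
            "in_window": in_win,
        })


def _transitions(daily: DailyPath, cfg: ClassifierConfig):
    """Day-to-day latitude change and displacement, NaN where undefined.

    Transition t describes the movement into day t (from day t-1); it is
    defined only when both endpoints are unflagged (optionally bridging
    a single flagged day when ``bridge_single_gaps``).
    """
    n = len(daily)
    dlat = np.full(n, np.nan)
    disp = np.full(n, np.nan)
    ok = ~daily.gap_flag
    for t in range(1, n):
        src = t - 1
        if not ok[t]:
            continue
        if not ok[src]:
            if cfg.bridge_single_gaps and t >= 2 and ok[t - 2]:
                src = t - 2
            else:
                continue
        dlat[t] = daily.lat[t] - daily.lat[src]
        disp[t] = geodesic_km((daily.lon[src], daily.lat[src]),
                              (daily.lon[t], daily.lat[t]))
    return dlat, disp


def classify_days(daily: DailyPath, cfg: ClassifierConfig | None = None) -> np.ndarray:
    """Label every unflagged day travel/stopover by the two criteria."""
    cfg = cfg or ClassifierConfig()
    n = len(daily)
    if int((~daily.gap_flag).sum()) == 0:
        raise ValueError("all days are gap-flagged; nothing to classify")
    if int((~daily.gap_flag).sum()) < 3:
        raise ValueError("need at least 3 unflagged days to classify")
    dlat, disp = _transitions(daily, cfg)

    travel = np.zeros(n, dtype=bool)
    # criterion 2: single-day jump
    travel |= np.nan_to_num(disp, nan=-np.inf) > cfg.jump_km
    # criterion 1: sustained latitude trend in a sliding window
    qual_pos = dlat > cfg.lat_step_deg
    qual_neg = dlat < -cfg.lat_step_deg
    W = cfg.window
    for w0 in range(1, n - W + 1):
        idx = np.arange(w0, w0 + W)
        if np.any(np.isnan(dlat[idx])):
            continue  # windows must consist of consecutive defined transitions
        for qual in (qual_pos, qual_neg):
            if qual[idx].sum() >= cfg.require:
                travel[idx[qual[idx]]] = True

    labels = np.where(travel, TRAVEL_LABEL, STOPOVER_LABEL).astype(object)
    labels[daily.gap_flag] = NO_LABEL
    return labels


def derive_thresholds(daily_paths: list, percentile: float = 90.0,
                      cfg: ClassifierConfig | None = None):
    """Percentile of pooled |dlat| and daily displacement over all tracks.

    Linear-interpolation quantile (numpy default).  Returns
    ``(lat_step_deg, jump_km)``.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    cfg = cfg or ClassifierConfig()
    dlats, disps = [], []
    for daily in daily_paths:
        dlat, disp = _transitions(daily, cfg)
        dlats.append(np.abs(dlat[~np.isnan(dlat)]))
        disps.append(disp[~np.isnan(disp)])
    dlats = np.concatenate(dlats) if dlats else np.array([])
    disps = np.concatenate(disps) if disps else np.array([])
    if len(dlats) == 0:
        raise ValueError("no defined day-to-day transitions in the input")
    return (float(np.percentile(dlats, percentile)),
            float(np.percentile(disps, percentile)))


def _travel_runs(labels: np.ndarray):
    """Maximal runs of consecutive travel days as (start, end) inclusive."""
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if lab == TRAVEL_LABEL:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
                start = None
    if start is not None:
        runs.append((start, len(labels) - 1))
    return runs


def find_migration_window(labels: np.ndarray, daily: DailyPath,
                          colony: tuple,
                          cfg: ClassifierConfig | None = None) -> MigrationWindow:
    """Detect the autumn migration window from labels and positions."""
    cfg = cfg or ClassifierConfig()
    n = len(daily)
    ok = ~daily.gap_flag
    dist = np.full(n, np.nan)
    for i in range(n):
        if ok[i]:
            dist[i] = geodesic_km(colony, (daily.lon[i], daily.lat[i]))

    runs = _travel_runs(labels)
    # candidate departure runs: travel runs containing a beyond-radius day
    beyond = np.nan_to_num(dist, nan=-np.inf) > cfg.colony_radius_km
    candidates = [r for r in runs if beyond[r[0]:r[1] + 1].any()]
    if not candidates:
        return MigrationWindow(detected=False,
                               reason="no travel run exits the colony radius")

    inside_days = np.flatnonzero(np.nan_to_num(dist, nan=np.inf)
                                 <= cfg.colony_radius_km)
    last_inside = int(inside_days.max()) if len(inside_days) else -1
    # departure run: the run achieving the *final* exit from the radius,
    # i.e. the first candidate containing a beyond-radius day after the
    # last day spent inside it (re-departures supersede aborted exits)
    final = [r for r in candidates
             if np.any(beyond[r[0]:r[1] + 1]
                       & (np.arange(r[0], r[1] + 1) > last_inside))]
    start_run = final[0] if final else candidates[-1]
    if len(candidates) > 1:
        log.info("%s: %d candidate departure runs %s; using %s",
                 daily.individual, len(candidates),
                 [c[0] for c in candidates], start_run)

    start_idx = start_run[0]

    # arrival run: the last travel run followed by winter residency
    end_run = None
    residency_ok = True
    for r in [r for r in runs if r[0] >= start_idx]:
        tail = np.flatnonzero(ok & (np.arange(n) > r[1]))
        if len(tail) < cfg.winter_dwell_days:
            continue
        lat_end = daily.lat[r[1]]
        if np.all(np.abs(daily.lat[tail] - lat_end) <= cfg.winter_band_deg):
            end_run = r
    if end_run is None:
        later = [r for r in runs if r[0] >= start_idx]
        end_run = later[-1] if later else start_run
        residency_ok = False
        log.warning("%s: winter residency not confirmed after any travel run; "
                    "using last travel run as migration end", daily.individual)

    end_idx = max(end_run[1], start_idx)
    return MigrationWindow(
        detected=True,
        start=daily.days[start_idx], end=daily.days[end_idx],
        start_idx=start_idx, end_idx=end_idx,
        residency_confirmed=residency_ok,
        candidate_start_idx=tuple(c[0] for c in candidates))


def group_stopovers(labels: np.ndarray, daily: DailyPath,
                    window: MigrationWindow) -> list:
    """Maximal runs of stopover days inside the window become sites.

    Sites are temporal runs, not spatial clusters: two runs separated by
    a single travel day stay distinct even at the same location.
    """
    if not window.detected:
        raise ValueError("no migration window detected")
    sites = []
    i = window.start_idx
    while i <= window.end_idx:
        if labels[i] == STOPOVER_LABEL:
            j = i
            while j + 1 <= window.end_idx and labels[j + 1] == STOPOVER_LABEL:
                j += 1
            sites.append(StopoverSite(
                centroid=(float(np.mean(daily.lon[i:j + 1])),
                          float(np.mean(daily.lat[i:j + 1]))),
                length_days=j - i + 1, start_idx=i, end_idx=j))
            i = j + 1
        else:
            i += 1
    return sites


def segment_track(daily: DailyPath, colony: tuple,
                  cfg: ClassifierConfig | None = None) -> DayLabelSeries:
    """Classify days, detect the window, and group stopovers for one track."""
    cfg = cfg or ClassifierConfig()
    labels = classify_days(daily, cfg)
    window = find_migration_window(labels, daily, colony, cfg)
    sites = group_stopovers(labels, daily, window) if window.detected else []
    return DayLabelSeries(individual=daily.individual, days=daily.days,
                          labels=labels, migration_window=window,
                          stopover_sites=sites)
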