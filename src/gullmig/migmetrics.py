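"""The ten per-track migration characteristics.

All distances are orthodromic (shortest-surface) on the WGS-84
ellipsoid via Vincenty's inverse method.  Conventions, fixed globally
so population contrasts are unaffected:

* *migration distance* — sum of day-over-day geodesic steps whose
  destination day is a travel day inside the migration window (the
  departure step into the window's first day counts; movement on
  stopover days does not).
* *duration* — (end − start) in days, plus 1 (both endpoint days count).
* *start/end date* — ordinal day of year; the year is kept separately.
* *directness* — migration distance over the geodesic between the
  departure origin (the day before the first travel day, whose step is
  part of the distance) and the last day of the window; a perfectly
  straight transit scores exactly 1.  The reciprocal is also reported
  since either orientation appears in the literature.
* *migration speed* — distance / duration;  *travel speed* — distance /
  number of travel days.
* *total stopover days*, *travel:stopover ratio* (distance per stopover
  day; undefined when there are none), and per-site *stopover lengths*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geo import GeodesicSpec, geodesic_km
from .segment import (DayLabelSeries, STOPOVER_LABEL, TRAVEL_LABEL)
from .ssm.model import DailyPath

log = logging.getLogger(__name__)

#: the ten characteristics, in reporting order
CHARACTERISTICS = (
    "migration_distance_km", "duration_days", "start_doy", "end_doy",
    "directness", "migration_speed_km_day", "travel_speed_km_day",
    "total_stopover_days", "travel_stopover_ratio_km_day", "stopover_lengths",
)


@dataclass(frozen=True)
class MigrationSummary:
    individual: str
    migration_distance_km: float
    duration_days: int
    start_doy: int
    end_doy: int
    directness: float
    migration_speed_km_day: float
    travel_speed_km_day: float
    total_stopover_days: int
    travel_stopover_ratio_km_day: float   # NaN when no stopover days
    stopover_lengths: tuple
    # bookkeeping beyond the ten characteristics
    n_travel_days: int = 0
    start_year: int = 0
    end_year: int = 0
    directness_reciprocal: float = np.nan

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in CHARACTERISTICS}
        d["individual"] = self.individual
        d["n_travel_days"] = self.n_travel_days
        d["start_year"] = self.start_year
        d["end_year"] = self.end_year
        d["directness_reciprocal"] = self.directness_reciprocal
        d["stopover_lengths"] = ";".join(str(x) for x in self.stopover_lengths)
        return d


def summarize(daily: DailyPath, labels: DayLabelSeries,
              spec: GeodesicSpec | None = None) -> MigrationSummary:
    """Compute the ten characteristics for one track.

    Requires a detected migration window with at least one travel day;
    refuses (raises ``ValueError``) otherwise.
    """
    spec = spec or GeodesicSpec()
    win = labels.migration_window
    if not win.detected:
        raise ValueError(f"{daily.individual}: no migration window detected")
    s, e = win.start_idx, win.end_idx
    lab = labels.labels

    travel_days = [t for t in range(s, e + 1) if lab[t] == TRAVEL_LABEL]
    stop_days = [t for t in range(s, e + 1) if lab[t] == STOPOVER_LABEL]
    if not travel_days:
        raise ValueError(f"{daily.individual}: no travel day inside the window")

    dist = 0.0
    for t in travel_days:
        if t == 0 or daily.gap_flag[t] or daily.gap_flag[t - 1]:
            continue
        dist += geodesic_km((daily.lon[t - 1], daily.lat[t - 1]),
                            (daily.lon[t], daily.lat[t]), spec)

    duration = e - s + 1
    # chord from the departure origin (the day before the first travel
    # day, whose step is counted in the distance) to the arrival day
    s0 = s - 1 if s > 0 and not daily.gap_flag[s - 1] else s
    chord = geodesic_km((daily.lon[s0], daily.lat[s0]),
                        (daily.lon[e], daily.lat[e]), spec)
    directness = dist / chord if chord > 0 else np.nan

    n_stop = len(stop_days)
    if n_stop == 0:
        ratio = np.nan
        log.info("%s: zero stopover days; travel:stopover ratio undefined",
                 daily.individual)
    else:
        ratio = dist / n_stop

    lengths = tuple(site.length_days for site in labels.stopover_sites)
    start_day = daily.days[s]
    end_day = daily.days[e]
    return MigrationSummary(
        individual=daily.individual,
        migration_distance_km=dist,
        duration_days=int(duration),
        start_doy=int(start_day.dayofyear),
        end_doy=int(end_day.dayofyear),
        directness=float(directness),
        migration_speed_km_day=dist / duration,
        travel_speed_km_day=dist / len(travel_days),
        total_stopover_days=int(n_stop),
        travel_stopover_ratio_km_day=float(ratio),
        stopover_lengths=lengths,
        n_travel_days=len(travel_days),
        start_year=int(start_day.year),
        end_year=int(end_day.year),
        directness_reciprocal=float(1.0 / directness) if directness else np.nan,
    )
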