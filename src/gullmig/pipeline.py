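"""Glue joining the pipeline stages on tabular inputs/outputs.

These helpers are what the analysis drivers, the CLI and the acceptance
computations share: each stage stays in its own module; this one only
moves containers between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import trackio
from .migmetrics import summarize
from .segment import ClassifierConfig, derive_thresholds, segment_track
from .ssm import MCMCConfig, DailyPath, ErrorModel, fit_ssm, prune_gaps


def daily_paths_from_csv(path) -> list:
    """Read a daily-paths CSV (individual, date, lon, lat, p_travel,
    gap_flag) back into :class:`DailyPath` objects."""
    df = pd.read_csv(path, dtype={"individual": str})
    out = []
    for ind, grp in df.groupby("individual", sort=True):
        grp = grp.sort_values("date")
        out.append(DailyPath(
            individual=str(ind),
            days=pd.DatetimeIndex(pd.to_datetime(grp["date"], utc=True)),
            lon=grp["lon"].to_numpy(), lat=grp["lat"].to_numpy(),
            p_travel=grp["p_travel"].to_numpy(),
            gap_flag=grp["gap_flag"].to_numpy(dtype=bool)))
    return out


def segment_all(dailies: list, manifest: pd.DataFrame,
                cfg: ClassifierConfig | None = None):
    """Segment every track; returns (labels table, windows table).

    In percentile mode the two thresholds are first derived from the
    pooled day-to-day steps of all tracks.
    """
    cfg = cfg or ClassifierConfig()
    if cfg.percentile_mode:
        lat_step, jump = derive_thresholds(dailies, cfg.percentile, cfg)
        cfg = ClassifierConfig(
            lat_step_deg=lat_step, jump_km=jump,
            colony_radius_km=cfg.colony_radius_km,
            winter_band_deg=cfg.winter_band_deg,
            winter_dwell_days=cfg.winter_dwell_days)
    lab_frames, win_rows = [], []
    for daily in dailies:
        colony = (float(manifest.loc[daily.individual, "colony_lon"]),
                  float(manifest.loc[daily.individual, "colony_lat"]))
        series = segment_track(daily, colony, cfg)
        lab_frames.append(series.to_frame())
        w = series.migration_window
        win_rows.append({
            "individual": daily.individual,
            "detected": w.detected,
            "start": str(w.start.date()) if w.detected else "",
            "end": str(w.end.date()) if w.detected else "",
            "residency_confirmed": w.residency_confirmed,
        })
    return (pd.concat(lab_frames, ignore_index=True),
            pd.DataFrame(win_rows))


def summaries_table(dailies: list, manifest: pd.DataFrame,
                    cfg: ClassifierConfig | None = None,
                    birds: dict | None = None) -> pd.DataFrame:
    """Ten characteristics per track, one row each, with population label.

    ``birds`` optionally maps track id -> animal id (several annual
    tracks may belong to one individual); defaults to the track id.
    """
    cfg = cfg or ClassifierConfig()
    rows = []
    for daily in dailies:
        colony = (float(manifest.loc[daily.individual, "colony_lon"]),
                  float(manifest.loc[daily.individual, "colony_lat"]))
        series = segment_track(daily, colony, cfg)
        if not series.migration_window.detected:
            continue
        summ = summarize(daily, series)
        d = summ.to_dict()
        d["population"] = str(manifest.loc[daily.individual, "population"])
        d["bird"] = (birds or {}).get(daily.individual, daily.individual)
        rows.append(d)
    return pd.DataFrame(rows)


def response_table(summaries: pd.DataFrame, response: str) -> pd.DataFrame:
    """Reshape the summaries table for one GLMM response.

    ``stopover_length`` expands to one row per stopover site per track;
    every other response is one row per track.  The individual column
    used for the random intercept is the animal (``bird``) when present.
    """
    ind_col = "bird" if "bird" in summaries.columns else "individual"
    rows = []
    for _, r in summaries.iterrows():
        if response == "stopover_length":
            lengths = r.get("stopover_lengths", "")
            if isinstance(lengths, str):
                vals = [int(v) for v in lengths.split(";") if v != ""]
            elif np.isscalar(lengths) and pd.isna(lengths):
                vals = []    # empty CSV cell: track without stopovers
            else:
                vals = list(lengths)
            for v in vals:
                rows.append({"population": r["population"],
                             "individual": r[ind_col], response: v})
        else:
            val = r[response]
            if np.isfinite(val):
                rows.append({"population": r["population"],
                             "individual": r[ind_col], response: val})
    return pd.DataFrame(rows)


def run_pipeline(tracks: list, mcmc: MCMCConfig | None = None,
                 error_model: ErrorModel | None = None,
                 cfg: ClassifierConfig | None = None,
                 birds: dict | None = None):
    """Raw tracks -> preprocessing -> SSM (per population) -> pruning ->
    segmentation -> characteristics table.

    Returns ``(summaries table, daily paths, fits by population)``.
    """
    cfg = cfg or ClassifierConfig()
    clean = [trackio.preprocess(t) for t in tracks]
    manifest = pd.DataFrame(
        [{"individual": t.individual, "population": t.population,
          "colony_lon": t.colony[0], "colony_lat": t.colony[1]}
         for t in clean]).set_index("individual")
    dailies, fits = [], {}
    for pop in sorted({t.population for t in clean}):
        grp = [t for t in clean if t.population == pop]
        fit = fit_ssm(grp, mcmc, error_model=error_model)
        fits[pop] = fit
        times = {t.individual: t.fixes["time"] for t in grp}
        for daily in fit.daily_paths:
            dailies.append(prune_gaps(daily, times[daily.individual]))
    table = summaries_table(dailies, manifest, cfg, birds=birds)
    return table, dailies, fits
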