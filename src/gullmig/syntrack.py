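"""Synthetic gull-migration tracks with known ground truth.

Two generators share the tangent-plane DCRW machinery:

* :func:`simulate_dcrw` — the *pure* two-state switching
  first-difference correlated random walk, exactly the process model
  the SSM fits.  Used for parameter-recovery studies.
* :func:`simulate_migration` — a schedule-driven autumn migration:
  residency at the breeding colony, travel bouts steered toward a
  wintering target (optionally via a lateral detour waypoint, which
  controls route directness) interleaved with multi-day stopovers,
  then winter residency.  Ground truth (daily positions, behavioural
  states, migration window and the ten characteristics) is stored with
  each track; the truth summary is computed by the same metric code the
  pipeline uses, so truth and pipeline output are directly comparable.

Observation is separate (:func:`observe_track`): daily truth positions
are linearly interpolated in the plane, thinned through a transmitter
duty cycle, assigned an Argos location class, and perturbed with
class-specific Student-t error (class F: none).

Seeding: one master seed per population config; the per-individual /
per-track streams are ``default_rng([seed, individual_index, repeat,
purpose])`` where purpose 0 = movement, 1 = observation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import TangentPlane
from .migmetrics import MigrationSummary, summarize
from .segment import (DayLabelSeries, MigrationWindow, STOPOVER_LABEL,
                      TRAVEL_LABEL, group_stopovers)
from .ssm.model import DailyPath, ErrorModel, FORAGE, SSMParams, TRAVEL
from .trackio import Track

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DutyCycle:
    """Transmitter schedule: ``on_hours`` on / ``off_hours`` off, repeating
    from local midnight of the first tracked day, with ``fixes_per_day``
    fixes on average (placed uniformly over the on-time)."""

    on_hours: float = 10.0
    off_hours: float = 24.0
    fixes_per_day: float = 6.0

    def __post_init__(self) -> None:
        if self.on_hours <= 0:
            raise ValueError("duty cycle has no on-hours")
        if self.off_hours < 0:
            raise ValueError("off_hours must be >= 0")
        if self.fixes_per_day <= 0:
            raise ValueError("mean fixes per day must be positive")


@dataclass(frozen=True)
class SimConfig:
    """One population's simulation settings (the study conditions)."""

    population_label: str = "pop"
    n_individuals: int = 5
    tracks_per_individual: tuple = ()   # empty = one track each
    colony: tuple = (-66.75, 44.57)
    winter_target: tuple = (-70.0, 42.0)
    n_days: int = 100
    start_date: str = "2015-08-05"
    state_params: SSMParams = field(default_factory=SSMParams)
    duty_cycle: DutyCycle = field(default_factory=DutyCycle)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0
    # migration schedule (see module docstring); km and days
    pre_days: float = 12.0
    pre_days_sd: float = 4.0
    travel_step_km: float = 300.0
    step_sd_between: float = 35.0
    step_sd_within: float = 25.0
    travel_noise_km: float = 12.0
    travel_bout_days: float = 4.0
    stopover_bout_days: float = 6.0
    p_stopover: float = 0.7
    waypoints: tuple = ()            # optional (lon, lat) route via-points
    waypoint_jitter_km: float = 40.0  # per-individual route variation
    route_spread_sd: float = 0.25    # per-individual lateral route stretch
    detour_frac: float = 0.30        # used only when no waypoints are given
    detour_sd: float = 0.05
    forage_sd_km: float = 2.0
    departure_step_min_km: float = 250.0  # departure day clears the colony area
    winter_min_days: int = 30

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.n_days < 2:
            raise ValueError("need at least two days")
        if self.tracks_per_individual and \
                len(self.tracks_per_individual) != self.n_individuals:
            raise ValueError("tracks_per_individual must match n_individuals")

    def repeats(self) -> tuple:
        return self.tracks_per_individual or tuple([1] * self.n_individuals)


@dataclass
class TrueTrack:
    """Ground truth for one simulated track."""

    individual: str                 # track identifier (bird + migration)
    bird: str                       # animal identifier (for random effects)
    population: str
    colony: tuple
    plane: TangentPlane
    daily: DailyPath                # noiseless daily positions, p_travel = state
    states: np.ndarray              # int per day: TRAVEL/FORAGE
    migration_window: MigrationWindow | None = None
    summary: MigrationSummary | None = None

    def __post_init__(self) -> None:
        if len(self.states) != len(self.daily):
            raise ValueError("states and daily positions must align")
        w = self.migration_window
        if w is not None and w.detected and not w.start_idx <= w.end_idx:
            raise ValueError("migration window start must precede its end")

    def true_labels(self) -> DayLabelSeries:
        """Day labels implied by the true states and scheduled window."""
        labels = np.where(self.states == TRAVEL, TRAVEL_LABEL,
                          STOPOVER_LABEL).astype(object)
        series = DayLabelSeries(
            individual=self.individual, days=self.daily.days,
            labels=labels, migration_window=self.migration_window)
        if self.migration_window is not None and self.migration_window.detected:
            series.stopover_sites = group_stopovers(
                labels, self.daily, self.migration_window)
        return series


def _daily_path(individual, plane, x, states, start_date) -> DailyPath:
    lon, lat = plane.to_lonlat(x[:, 0], x[:, 1])
    days = pd.date_range(pd.Timestamp(start_date, tz="UTC"),
                         periods=len(x), freq="D")
    return DailyPath(individual=individual, days=days, lon=lon, lat=lat,
                     p_travel=(states == TRAVEL).astype(float),
                     gap_flag=np.zeros(len(x), dtype=bool))


def simulate_dcrw(params: SSMParams, n_days: int, start: tuple,
                  seed, init_state: int | None = None,
                  individual: str = "sim", start_date: str = "2015-08-05",
                  plane: TangentPlane | None = None) -> TrueTrack:
    """Simulate the pure switching DCRW (the SSM's process model).

    ``start`` is (lon, lat); displacements follow
    d_t = gamma_b R(theta_b) d_{t-1} + N(0, Sigma) with the state chain
    from ``params.trans`` (initially the stationary distribution unless
    ``init_state`` is given).  Deterministic given ``seed``.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(seed)
    plane = plane or TangentPlane(*start)
    x0 = np.array(plane.to_plane(*start), dtype=float)

    P = np.asarray(params.trans, dtype=float)
    Ms = [params.rotation(0), params.rotation(1)]
    L = np.linalg.cholesky(np.asarray(params.process_cov, dtype=float))

    states = np.empty(n_days, dtype=np.int64)
    if init_state is None:
        pi = params.stationary_distribution()
        states[0] = rng.choice(2, p=pi)
    else:
        states[0] = int(init_state)
    for t in range(1, n_days):
        states[t] = rng.choice(2, p=P[states[t - 1]])

    x = np.empty((n_days, 2))
    x[0] = x0
    d_prev = np.zeros(2)
    for t in range(1, n_days):
        d = Ms[states[t]] @ d_prev + L @ rng.standard_normal(2)
        x[t] = x[t - 1] + d
        d_prev = d
    daily = _daily_path(individual, plane, x, states, start_date)
    return TrueTrack(individual=individual, bird=individual,
                     population="dcrw", colony=start, plane=plane,
                     daily=daily, states=states)


def _forage_step(x_prev, anchor, sd, rng):
    # anchored wander: small pull back keeps residency tight
    return 0.3 * (anchor - x_prev) + rng.normal(0.0, sd, 2)


def _route_plane(cfg: SimConfig) -> TangentPlane:
    """Plane for migration simulation, anchored at the route midpoint.

    Anchoring at the colony would stretch east-west steps ever more as
    the bird moves equatorward (the plane's degree-per-km ratio is fixed
    at the reference latitude); the midpoint keeps the metric distortion
    roughly balanced over the whole route.
    """
    return TangentPlane((cfg.colony[0] + cfg.winter_target[0]) / 2.0,
                        (cfg.colony[1] + cfg.winter_target[1]) / 2.0)


def _individual_route(cfg: SimConfig, plane: TangentPlane,
                      rng: np.random.Generator) -> list:
    """Per-individual via-points (tangent-plane km), jittered; ends at the
    wintering target.  Each via-point's lateral deviation from the
    straight colony-target line is stretched by a per-individual factor,
    which is what generates between-individual variation in route length
    (hence distance and directness).  Without configured waypoints, a
    single lateral detour waypoint at ``detour_frac`` of the direct
    distance is used."""
    target = np.array(plane.to_plane(*cfg.winter_target), dtype=float)
    if cfg.waypoints:
        colony = np.array(plane.to_plane(*cfg.colony), dtype=float)
        u = (target - colony) / np.linalg.norm(target - colony)
        stretch = max(rng.normal(1.0, cfg.route_spread_sd), 0.3)
        pts = []
        for wp in cfg.waypoints:
            p = np.array(plane.to_plane(*wp), dtype=float)
            along = colony + u * float((p - colony) @ u)
            p = along + stretch * (p - along) \
                + rng.normal(0.0, cfg.waypoint_jitter_km, 2)
            pts.append(p)
    else:
        detour = rng.normal(cfg.detour_frac, cfg.detour_sd)
        D = float(np.linalg.norm(target))
        u = target / D
        perp = np.array([-u[1], u[0]])
        pts = [target / 2.0 + perp * detour * D] if detour != 0.0 else []
    return pts + [target]


def simulate_migration(cfg: SimConfig, individual: str, bird: str,
                       rng: np.random.Generator,
                       ind_step_km: float, route: list,
                       start_date: str) -> TrueTrack:
    """One schedule-driven migration track with full ground truth."""
    plane = _route_plane(cfg)
    n = cfg.n_days
    x = np.zeros((n, 2))
    colony_xy = np.array(plane.to_plane(*cfg.colony), dtype=float)
    x[0] = colony_xy
    states = np.full(n, FORAGE, dtype=np.int64)
    pre = int(max(2, round(rng.normal(cfg.pre_days, cfg.pre_days_sd))))
    deadline = n - cfg.winter_min_days

    t = 1
    while t < min(pre + 1, n):
        x[t] = x[t - 1] + _forage_step(x[t - 1], colony_xy, cfg.forage_sd_km, rng)
        t += 1

    arrived = False
    leg = 0                        # index into the route's via-points
    start_idx = end_idx = None
    while t < n and not arrived:
        bout = 1 + rng.poisson(max(cfg.travel_bout_days - 1, 0.0))
        for _ in range(bout):
            if t >= n or arrived:
                break
            rem_vec = route[leg] - x[t - 1]
            rem = float(np.linalg.norm(rem_vec))
            # via-points hand over at a tighter radius than the final
            # target so the route actually follows the configured arc
            while leg < len(route) - 1 and rem < 0.7 * ind_step_km:
                leg += 1
                rem_vec = route[leg] - x[t - 1]
                rem = float(np.linalg.norm(rem_vec))
            if leg == len(route) - 1 and rem <= 1.5 * ind_step_km:
                d = rem_vec        # final approach: land on the target
                arrived = True
            else:
                step = max(rng.normal(ind_step_km, cfg.step_sd_within),
                           0.5 * ind_step_km)
                if start_idx is None:
                    # the scheduled departure day leaves the colony area,
                    # so schedule and radius-based detection agree
                    step = max(step, cfg.departure_step_min_km)
                d = step * rem_vec / rem + rng.normal(0.0, cfg.travel_noise_km, 2)
            x[t] = x[t - 1] + d
            states[t] = TRAVEL
            if start_idx is None:
                start_idx = t
            end_idx = t
            t += 1
        if arrived or t >= n:
            break
        if t < deadline and rng.random() < cfg.p_stopover:
            stop = 1 + rng.poisson(max(cfg.stopover_bout_days - 1, 0.0))
            anchor = x[t - 1].copy()
            for _ in range(stop):
                if t >= n:
                    break
                x[t] = x[t - 1] + _forage_step(x[t - 1], anchor,
                                               cfg.forage_sd_km, rng)
                t += 1

    if not arrived:
        log.warning("%s: track ended before reaching the wintering target",
                    individual)
    anchor = x[t - 1].copy()
    while t < n:
        x[t] = x[t - 1] + _forage_step(x[t - 1], anchor, cfg.forage_sd_km, rng)
        t += 1

    daily = _daily_path(individual, plane, x, states, start_date)
    window = MigrationWindow(
        detected=start_idx is not None,
        start=daily.days[start_idx] if start_idx is not None else None,
        end=daily.days[end_idx] if end_idx is not None else None,
        start_idx=start_idx, end_idx=end_idx,
        residency_confirmed=arrived)
    truth = TrueTrack(individual=individual, bird=bird,
                      population=cfg.population_label, colony=cfg.colony,
                      plane=plane, daily=daily, states=states,
                      migration_window=window)
    if window.detected:
        truth.summary = summarize(daily, truth.true_labels())
    return truth


def observe_track(truth: TrueTrack, duty_cycle: DutyCycle,
                  error_model: ErrorModel, seed) -> Track:
    """Thin the continuous true path through the duty cycle and add
    class-structured Student-t error; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    n = len(truth.daily)
    if n < 2:
        raise ValueError("truth track too short to observe")
    span = float(n - 1)  # fractional days over which interpolation is defined

    # on-time intervals of the repeating duty cycle, in fractional days
    period = (duty_cycle.on_hours + duty_cycle.off_hours) / 24.0
    on_len = duty_cycle.on_hours / 24.0
    starts = np.arange(0.0, span, period) if period > 0 else np.array([0.0])
    lo = starts
    hi = np.minimum(starts + on_len, span)
    keep = hi > lo
    lo, hi = lo[keep], hi[keep]
    lengths = hi - lo
    total_on = float(lengths.sum())
    if total_on <= 0:
        raise ValueError("duty cycle leaves no on-time inside the track")

    k = rng.poisson(duty_cycle.fixes_per_day * span)
    pos_in_on = np.sort(rng.uniform(0.0, total_on, size=k))
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    iv = np.searchsorted(cum, pos_in_on, side="right") - 1
    iv = np.clip(iv, 0, len(lo) - 1)
    tau = lo[iv] + (pos_in_on - cum[iv])

    xk, yk = truth.plane.to_plane(truth.daily.lon, truth.daily.lat)
    days = np.arange(n, dtype=float)
    px = np.interp(tau, days, xk)
    py = np.interp(tau, days, yk)

    classes, freqs = error_model.normalized_freqs()
    lc = rng.choice(len(classes), size=k, p=freqs)
    lc_names = np.array(classes, dtype=object)[lc]
    scale = np.array([error_model.scales_km[c] for c in classes])[lc]
    df = np.array([error_model.df[c] for c in classes])[lc]
    err = np.zeros((k, 2))
    noisy = scale > 0
    if noisy.any():
        err[noisy, 0] = scale[noisy] * rng.standard_t(df[noisy])
        err[noisy, 1] = scale[noisy] * rng.standard_t(df[noisy])

    lon, lat = truth.plane.to_lonlat(px + err[:, 0], py + err[:, 1])
    t0 = truth.daily.days[0]
    times = t0 + pd.to_timedelta(np.round(tau * 86400.0).astype(np.int64), unit="s")
    fixes = pd.DataFrame({"time": times, "lon": lon, "lat": lat,
                          "lc": lc_names}).sort_values(
        "time", kind="stable").reset_index(drop=True)
    return Track(individual=truth.individual, population=truth.population,
                 colony=truth.colony, fixes=fixes)


def simulate_population(configs: list) -> tuple:
    """Simulate every configured population; returns (tracks, truths)."""
    if not configs:
        raise ValueError("need at least one population config")
    tracks, truths, seen = [], [], set()
    for cfg in configs:
        reps = cfg.repeats()
        plane = _route_plane(cfg)
        for i in range(cfg.n_individuals):
            bird = f"{cfg.population_label}_{i:02d}"
            ind_rng = np.random.default_rng([cfg.seed, i, 0, 0])
            ind_step = max(120.0, ind_rng.normal(cfg.travel_step_km,
                                                 cfg.step_sd_between))
            route = _individual_route(cfg, plane, ind_rng)
            for r in range(reps[i]):
                tid = bird if reps[i] == 1 else f"{bird}y{r}"
                if tid in seen:
                    raise ValueError(f"duplicate individual ID {tid}")
                seen.add(tid)
                start = (pd.Timestamp(cfg.start_date)
                         + pd.Timedelta(days=365 * r)).strftime("%Y-%m-%d")
                rng = np.random.default_rng([cfg.seed, i, r, 1])
                truth = simulate_migration(cfg, tid, bird, rng,
                                           ind_step, route, start)
                obs = observe_track(truth, cfg.duty_cycle, cfg.error_model,
                                    seed=[cfg.seed, i, r, 2])
                truths.append(truth)
                tracks.append(obs)
    return tracks, truths


def write_truth(truths: list, out_dir) -> None:
    """Truth sidecar: per-day CSV and per-track JSON summaries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in truths:
        df = tr.daily.to_frame()
        df["state"] = np.where(tr.states == TRAVEL, "travel", "forage")
        rows.append(df[["individual", "date", "lon", "lat", "state"]])
    pd.concat(rows, ignore_index=True).to_csv(out_dir / "truth_daily.csv",
                                              index=False)
    summaries = {}
    for tr in truths:
        if tr.summary is None:
            continue
        d = tr.summary.to_dict()
        d["population"] = tr.population
        d["bird"] = tr.bird
        w = tr.migration_window
        d["window_start"] = str(w.start.date()) if w and w.detected else None
        d["window_end"] = str(w.end.date()) if w and w.detected else None
        summaries[tr.individual] = d
    with open(out_dir / "truth_summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=1, default=float)
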