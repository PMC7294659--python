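"""Bayesian hierarchical switching-DCRW fitting by Gibbs sampling.

The process model is the two-state first-difference correlated random
walk of :mod:`gullmig.ssm.model` on a local tangent plane; the
observation model links every irregular fix to the time-weighted linear
interpolation of the two bracketing daily positions, perturbed by
location-class-specific Student-t error.  Movement parameters are
shared across all individuals in the call (one fit per breeding
population); each individual keeps its own latent daily path and state
sequence.

The sampler alternates exact conditional draws:

1. daily positions per individual — Kalman forward filter / backward
   sampler with the t errors expanded as a scale mixture of normals
   (one latent Gamma precision per fix per coordinate);
2. behavioural states per individual — discrete forward-backward;
3. per-fix error precisions — conjugate Gamma;
4. transition matrix rows — conjugate Dirichlet;
5. per-state persistence/turning (a, b) = gamma (cos theta, sin theta)
   — conjugate bivariate normal on the unit disk (gamma <= 1 enforced
   by rejection);
6. process covariance — conjugate inverse-Wishart.

Draws are relabelled so state 0 is always the higher-persistence
(travel) state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from ..geo import TangentPlane
from ..trackio import Track
from ._kernels import kalman_ffbs, state_ffbs
from .diagnostics import Diagnostics, diagnose
from .model import DailyPath, ErrorModel, MCMCConfig

log = logging.getLogger(__name__)

_J = np.array([[0.0, -1.0], [1.0, 0.0]])

#: near-zero observation scale standing in for "error radius of 0 m" (class F)
F_CLASS_SCALE_KM = 1e-3

SCALAR_PARAMS = ("gamma_travel", "gamma_forage", "theta_travel", "theta_forage",
                 "sigma_xx", "sigma_yy", "sigma_xy",
                 "trans_travel_travel", "trans_forage_forage")


@dataclass
class _TrackData:
    """Per-individual arrays prepared for the kernels."""
    individual: str
    T: int
    t0: pd.Timestamp
    obs_start: np.ndarray   # (T+1,) pointers into the fix arrays
    obs_w: np.ndarray
    obs_y: np.ndarray       # (n, 2) planar km
    scale: np.ndarray       # (n,) per-fix t scale, km
    nu: np.ndarray          # (n,)
    is_f: np.ndarray        # (n,) bool: GPS-quality, no precision update
    times: pd.DatetimeIndex
    m0: np.ndarray
    C0: np.ndarray


@dataclass
class SSMFit:
    """Posterior sample, daily paths and diagnostics from one fit."""

    samples: dict                      # name -> (n_chains, n_draws)
    daily_paths: list
    diagnostics: Diagnostics
    config: MCMCConfig
    plane: TangentPlane
    skipped: list = field(default_factory=list)

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.samples[name]))

    def credible_interval(self, name: str, level: float = 0.95):
        a = np.asarray(self.samples[name]).ravel()
        q = (1.0 - level) / 2.0
        return float(np.quantile(a, q)), float(np.quantile(a, 1.0 - q))


def _prepare_track(track: Track, plane: TangentPlane,
                   error_model: ErrorModel) -> _TrackData | None:
    fixes = track.fixes
    if len(fixes) == 0:
        log.warning("skipping %s: no usable fixes", track.individual)
        return None
    times = pd.DatetimeIndex(fixes["time"])
    t0 = times.min().floor("D")
    t_last = times.max().floor("D")
    T = int((t_last - t0).days) + 2
    if T < 3:
        raise ValueError(
            f"track {track.individual} spans fewer than 3 days")
    tau = (times - t0).total_seconds().to_numpy() / 86400.0
    k = np.floor(tau).astype(np.int64)
    w = tau - k
    x, y = plane.to_plane(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    obs_y = np.column_stack([x, y])
    if not np.all(np.isfinite(obs_y)):
        bad = int(np.flatnonzero(~np.isfinite(obs_y).all(axis=1))[0])
        raise ValueError(
            f"non-finite observation for {track.individual} at fix {bad} "
            f"({times[bad]})")
    lc = fixes["lc"].astype(str).to_numpy()
    scale = np.array([error_model.scales_km.get(c, np.nan) for c in lc])
    if np.any(np.isnan(scale)):
        missing = sorted(set(lc) - set(error_model.scales_km))
        raise ValueError(f"no error scale configured for classes {missing}")
    nu = np.array([error_model.df.get(c, 4.0) for c in lc], dtype=float)
    is_f = scale <= 0
    scale = np.where(is_f, F_CLASS_SCALE_KM, scale)

    step = k + 1  # Kalman step owning the fix (state holds x_{k+1}, x_k)
    order = np.argsort(step, kind="stable")
    counts = np.bincount(step[order], minlength=T)
    obs_start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    m0 = np.concatenate([obs_y[0], obs_y[0]])
    C0 = np.diag([1e4, 1e4, 1e4, 1e4])
    return _TrackData(
        individual=track.individual, T=T, t0=t0,
        obs_start=obs_start, obs_w=w[order].astype(float),
        obs_y=obs_y[order], scale=scale[order], nu=nu[order],
        is_f=is_f[order], times=times[order], m0=m0, C0=C0)


def _interp_positions(td: _TrackData) -> np.ndarray:
    # fractional day of each fix, reconstructed from its step and weight
    steps = np.repeat(np.arange(td.T), np.diff(td.obs_start))
    t_frac = steps - 1 + td.obs_w
    order = np.argsort(t_frac)
    days = np.arange(td.T, dtype=float)
    xi = np.interp(days, t_frac[order], td.obs_y[order, 0])
    yi = np.interp(days, t_frac[order], td.obs_y[order, 1])
    return np.column_stack([xi, yi])


def _ab_matrices(ab: np.ndarray) -> np.ndarray:
    """(2,2) array of per-state (a, b) -> stacked gamma*R matrices."""
    Ms = np.empty((2, 2, 2))
    for s in range(2):
        a, b = ab[s]
        Ms[s] = a * np.eye(2) + b * _J
    return Ms


def fit_ssm(tracks: list, mcmc: MCMCConfig | None = None,
            error_model: ErrorModel | None = None,
            plane: TangentPlane | None = None) -> SSMFit:
    """Fit the hierarchical switching DCRW to one population's tracks.

    Returns posterior scalar samples per chain, per-individual daily
    paths (posterior-mean positions and P(travel), un-pruned), and
    convergence diagnostics.  Deterministic given ``mcmc.seed``.
    """
    if not tracks:
        raise ValueError("need at least one track")
    mcmc = mcmc or MCMCConfig()
    error_model = error_model or ErrorModel()
    if plane is None:
        plane = TangentPlane(*tracks[0].colony)

    data, skipped = [], []
    for tr in tracks:
        td = _prepare_track(tr, plane, error_model)
        if td is None:
            skipped.append(tr.individual)
        else:
            data.append(td)
    if not data:
        raise ValueError("no track has usable fixes")

    n_keep = mcmc.retained_per_chain
    samples = {name: np.zeros((mcmc.n_chains, n_keep)) for name in SCALAR_PARAMS}
    x_sum = [np.zeros((td.T, 2)) for td in data]
    trav_sum = [np.zeros(td.T) for td in data]
    total_kept = 0

    prior_iw_df, prior_iw_scale = 4.0, np.diag([100.0, 100.0])
    prior_ab_prec = 1e-4

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([int(mcmc.seed) % (2**31), chain])

        # over-dispersed initialization
        ab = np.array([
            [rng.uniform(0.5, 0.95), 0.0],
            [rng.uniform(0.02, 0.45), 0.0]])
        trans = np.array([[0.8, 0.2], [0.3, 0.7]])
        b_cur, obs_var, disp_pool = [], [], []
        for td in data:
            xi = _interp_positions(td)
            d = np.linalg.norm(np.diff(xi, axis=0), axis=1)
            thr = np.quantile(d, rng.uniform(0.4, 0.75)) if len(d) else 0.0
            b = np.ones(td.T, dtype=np.int64)
            b[1:][d > max(thr, 1e-9)] = 0
            b_cur.append(b)
            obs_var.append((td.scale[:, None] ** 2) * np.ones((1, 2)))
            disp_pool.append(np.diff(xi, axis=0))
        dp = np.concatenate(disp_pool, axis=0)
        Sigma = np.cov(dp.T) + 25.0 * np.eye(2) if len(dp) > 2 else 400.0 * np.eye(2)

        kept = 0
        for it in range(mcmc.n_samples):
            Ms = _ab_matrices(ab)
            Sinv = np.linalg.inv(Sigma)
            logdetS = float(np.log(np.linalg.det(Sigma)))
            logP = np.log(np.clip(trans, 1e-12, 1.0))

            xs, ds = [], []
            for j, td in enumerate(data):
                randn = rng.standard_normal((td.T, 4))
                x = kalman_ffbs(td.T, td.m0, td.C0, Ms, Sigma, b_cur[j],
                                td.obs_start, td.obs_w, td.obs_y,
                                obs_var[j], randn)
                d = np.zeros((td.T, 2))
                d[1:] = np.diff(x, axis=0)
                unif = rng.random(td.T)
                b_cur[j] = state_ffbs(d, Ms, Sinv, logdetS, logP, unif)
                xs.append(x)
                ds.append(d)
                # conjugate per-fix precision update (scale mixture of normals)
                steps = np.repeat(np.arange(td.T), np.diff(td.obs_start))
                pred = (td.obs_w[:, None] * x[np.minimum(steps, td.T - 1)]
                        + (1.0 - td.obs_w)[:, None] * x[np.maximum(steps - 1, 0)])
                r2 = ((td.obs_y - pred) / td.scale[:, None]) ** 2
                lam = rng.gamma((td.nu[:, None] + 1.0) / 2.0,
                                2.0 / (td.nu[:, None] + r2))
                lam[td.is_f] = 1.0
                obs_var[j] = (td.scale[:, None] ** 2) / np.maximum(lam, 1e-12)

            # transition matrix
            counts = np.zeros((2, 2))
            for b in b_cur:
                for s in range(2):
                    for s2 in range(2):
                        counts[s, s2] += np.sum((b[2:-1] == s) & (b[3:] == s2))
            trans = np.vstack([rng.dirichlet(1.0 + counts[s]) for s in range(2)])

            # per-state (a, b) regression: d_t = (a I + b J) d_{t-1} + eta
            prev = np.concatenate([d[1:-1] for d in ds], axis=0)
            cur = np.concatenate([d[2:] for d in ds], axis=0)
            st = np.concatenate([b[2:] for b in b_cur], axis=0)
            for s in range(2):
                sel = st == s
                if not np.any(sel):
                    g = rng.uniform(0.0, 1.0)
                    th = rng.uniform(-np.pi, np.pi)
                    ab[s] = [g * np.cos(th), g * np.sin(th)]
                    continue
                u1 = prev[sel]                       # (n,2)
                u2 = u1 @ _J.T                       # J d_{t-1}
                y = cur[sel]
                S11 = np.einsum("ni,ij,nj->", u1, Sinv, u1)
                S12 = np.einsum("ni,ij,nj->", u1, Sinv, u2)
                S22 = np.einsum("ni,ij,nj->", u2, Sinv, u2)
                r1 = np.einsum("ni,ij,nj->", u1, Sinv, y)
                r2_ = np.einsum("ni,ij,nj->", u2, Sinv, y)
                prec = np.array([[S11 + prior_ab_prec, S12],
                                 [S12, S22 + prior_ab_prec]])
                cov = np.linalg.inv(prec)
                mean = cov @ np.array([r1, r2_])
                L = np.linalg.cholesky(cov)
                for _ in range(50):
                    cand = mean + L @ rng.standard_normal(2)
                    if cand @ cand <= 1.0:
                        break
                else:
                    cand = cand / np.sqrt(cand @ cand) * 0.999
                ab[s] = cand

            # process covariance
            Ms_new = _ab_matrices(ab)
            resid = cur - np.where((st == 0)[:, None],
                                   prev @ Ms_new[0].T, prev @ Ms_new[1].T)
            S_post = prior_iw_scale + resid.T @ resid
            Sigma = invwishart.rvs(df=prior_iw_df + len(resid),
                                   scale=S_post, random_state=rng)

            # identification: state 0 = travel = higher persistence
            g0 = float(np.hypot(*ab[0]))
            g1 = float(np.hypot(*ab[1]))
            if g0 < g1:
                ab = ab[::-1].copy()
                trans = trans[::-1, ::-1].copy()
                b_cur = [1 - b for b in b_cur]
                g0, g1 = g1, g0

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 \
                    and kept < n_keep:
                row = {
                    "gamma_travel": g0, "gamma_forage": g1,
                    "theta_travel": np.arctan2(ab[0, 1], ab[0, 0]),
                    "theta_forage": np.arctan2(ab[1, 1], ab[1, 0]),
                    "sigma_xx": Sigma[0, 0], "sigma_yy": Sigma[1, 1],
                    "sigma_xy": Sigma[0, 1],
                    "trans_travel_travel": trans[0, 0],
                    "trans_forage_forage": trans[1, 1],
                }
                for name, v in row.items():
                    samples[name][chain, kept] = v
                for j in range(len(data)):
                    x_sum[j] += xs[j]
                    trav_sum[j] += (b_cur[j] == 0)
                kept += 1
                total_kept += 1

    daily_paths = []
    for j, td in enumerate(data):
        xm = x_sum[j] / total_kept
        lon, lat = plane.to_lonlat(xm[:, 0], xm[:, 1])
        days = pd.date_range(td.t0, periods=td.T, freq="D", tz="UTC")
        daily_paths.append(DailyPath(
            individual=td.individual, days=days,
            lon=lon, lat=lat,
            p_travel=trav_sum[j] / total_kept,
            gap_flag=np.zeros(td.T, dtype=bool)))

    diag = diagnose(samples)
    return SSMFit(samples=samples, daily_paths=daily_paths,
                  diagnostics=diag, config=mcmc, plane=plane,
                  skipped=skipped)
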