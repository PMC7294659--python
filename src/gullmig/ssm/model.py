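"""Parameter containers for the switching first-difference correlated
random walk (DCRW) and its MCMC configuration.

State convention throughout the package: index 0 = travelling,
index 1 = foraging.  Identification is by move persistence:
γ_travel ≥ γ_forage (the sampler relabels draws to satisfy this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAVEL, FORAGE = 0, 1
STATE_NAMES = ("travel", "forage")


@dataclass(frozen=True)
class ErrorModel:
    """Class-structured positional error for satellite fixes.

    Each Argos location class gets an independent Student-t error per
    planar coordinate with scale ``scales_km[c]`` (km) and ``df[c]``
    degrees of freedom; class F (GPS) is error-free.  ``class_freqs``
    are the simulation frequencies of the classes; fitting only uses
    the scales/df.  The default scales are round-number stand-ins for
    published empirical Argos error distributions (which are outside
    this package's scope), exposed for configuration.
    """

    scales_km: dict = field(default_factory=lambda: {
        "3": 0.5, "2": 1.0, "1": 2.5, "0": 10.0, "F": 0.0})
    df: dict = field(default_factory=lambda: {
        "3": 4.0, "2": 4.0, "1": 4.0, "0": 4.0, "F": np.inf})
    class_freqs: dict = field(default_factory=lambda: {
        "3": 0.1, "2": 0.2, "1": 0.3, "0": 0.3, "F": 0.1})

    def __post_init__(self) -> None:
        for c, s in self.scales_km.items():
            if not np.isfinite(s) or s < 0:
                raise ValueError(f"error scale for class {c!r} must be >= 0")
        for c, v in self.df.items():
            if not v > 2:
                raise ValueError(f"t degrees of freedom for class {c!r} must exceed 2")
        f = np.array(list(self.class_freqs.values()), dtype=float)
        if (f < 0).any() or f.sum() <= 0:
            raise ValueError("class frequencies must be non-negative and sum > 0")

    def normalized_freqs(self) -> tuple[list, np.ndarray]:
        classes = list(self.class_freqs)
        f = np.array([self.class_freqs[c] for c in classes], dtype=float)
        return classes, f / f.sum()


@dataclass(frozen=True)
class SSMParams:
    """Two-state switching DCRW parameters.

    Daily displacement (km, tangent plane): d_t = γ_b R(θ_b) d_{t−1} + η,
    η ~ N(0, Σ) with Σ shared across states; the behavioural state b_t
    follows a first-order Markov chain with transition matrix ``trans``.
    """

    gamma: tuple = (0.85, 0.15)            # move persistence, [travel, forage]
    theta: tuple = (0.0, 0.0)              # mean turning angle, radians
    process_cov: np.ndarray = field(
        default_factory=lambda: np.diag([400.0, 400.0]))  # km^2
    trans: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, 0.1], [0.2, 0.8]]))
    error_model: ErrorModel = field(default_factory=ErrorModel)

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        if g.shape != (2,) or th.shape != (2,):
            raise ValueError("gamma and theta must have one entry per state")
        if not np.all(np.isfinite(g)) or not np.all(np.isfinite(th)):
            raise ValueError("non-finite movement parameters")
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("gamma must lie in [0, 1]")
        S = np.asarray(self.process_cov, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("process_cov must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("process_cov must be positive-definite")
        P = np.asarray(self.trans, dtype=float)
        if P.shape != (2, 2) or np.any(P < 0) or np.any(P > 1) \
                or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("trans rows must be probabilities summing to 1")

    def rotation(self, state: int) -> np.ndarray:
        """γ_s R(θ_s) as a 2x2 matrix."""
        g, th = self.gamma[state], self.theta[state]
        c, s = np.cos(th), np.sin(th)
        return g * np.array([[c, -s], [s, c]])

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the 2-state chain (eigendecomposition)."""
        P = np.asarray(self.trans, dtype=float)
        w, v = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler run lengths.

    The desk-scale default (2 chains x 4,000 samples, 1,000 burn-in,
    thin 5) is sized for routine runs and testing; production-scale runs
    (e.g. 2 x 400,000 with 50,000 burn-in and thin 50, retaining 7,000
    draws per chain) are configured through the same fields.
    """

    n_chains: int = 2
    n_samples: int = 4000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.burn_in < self.n_samples):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_samples")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        """Post-burn-in draws kept per chain after thinning."""
        return (self.n_samples - self.burn_in) // self.thin


@dataclass
class DailyPath:
    """Posterior daily (24 h) position estimates for one individual."""

    individual: str
    days: pd.DatetimeIndex          # one calendar day per entry (UTC)
    lon: np.ndarray
    lat: np.ndarray
    p_travel: np.ndarray            # posterior P(travel) per day
    gap_flag: np.ndarray            # True where the estimate is withheld

    def __post_init__(self) -> None:
        n = len(self.days)
        for name in ("lon", "lat", "p_travel", "gap_flag"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n days {n}")
            setattr(self, name, arr)
        self.gap_flag = self.gap_flag.astype(bool)
        ok = ~self.gap_flag
        if not (np.all(np.isfinite(self.lon[ok])) and np.all(np.isfinite(self.lat[ok]))):
            raise ValueError("non-finite position on an unflagged day")

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual": self.individual,
            "date": self.days.strftime("%Y-%m-%d"),
            "lon": self.lon, "lat": self.lat,
            "p_travel": self.p_travel, "gap_flag": self.gap_flag,
        })
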