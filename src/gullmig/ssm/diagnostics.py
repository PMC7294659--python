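"""MCMC convergence diagnostics: Gelman-Rubin PSRF, Geweke z, autocorrelation.

Implemented directly from the standard definitions (the thinned chains
these run on are short, so no spectral machinery is needed):

* PSRF (potential scale reduction): classic two-chain form,
  sqrt(((n-1)/n * W + B/n) / W).
* Geweke: difference of means of the first 10% and last 50% of one
  chain, standardized by autocovariance-corrected standard errors
  (initial-positive-sequence truncation).
* Lag-k autocorrelations of the pooled chains.

``converged`` summarises all scalar parameters with the conventional
thresholds PSRF < 1.1 and |z| < 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def gelman_rubin(chains: np.ndarray) -> float:
    """PSRF for one scalar parameter, ``chains`` shaped (m, n), m >= 2."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0  # degenerate constant chains
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def _spectral_se(x: np.ndarray) -> float:
    """Std. error of the mean with an initial-positive autocovariance sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    v0 = float(x @ x) / n
    if v0 <= 0:
        return 0.0
    s = v0
    for k in range(1, min(n - 1, n // 2)):
        ck = float(x[:-k] @ x[k:]) / n
        if ck <= 0:
            break
        s += 2.0 * ck
    return np.sqrt(s / n)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for one chain."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    a = chain[: max(2, int(first * n))]
    b = chain[-max(2, int(last * n)):]
    se = np.hypot(_spectral_se(a), _spectral_se(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


def autocorr(chain: np.ndarray, max_lag: int = 10) -> np.ndarray:
    """Lag 1..max_lag sample autocorrelations of one chain."""
    x = np.asarray(chain, dtype=float)
    x = x - x.mean()
    v = float(x @ x)
    if v <= 0:
        return np.zeros(max_lag)
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        out[k - 1] = float(x[:-k] @ x[k:]) / v if k < len(x) else 0.0
    return out


@dataclass
class Diagnostics:
    """Per-parameter convergence summary of a posterior sample."""

    gelman_rubin: dict = field(default_factory=dict)   # name -> PSRF (or None)
    geweke: dict = field(default_factory=dict)         # name -> z per chain (array)
    chain_autocorr: dict = field(default_factory=dict)  # name -> lag-k array
    converged: bool = False
    psrf_threshold: float = 1.1
    geweke_threshold: float = 2.0

    def to_dict(self) -> dict:
        return {
            "gelman_rubin": {k: (None if v is None else float(v))
                             for k, v in self.gelman_rubin.items()},
            "geweke": {k: [float(z) for z in v] for k, v in self.geweke.items()},
            "chain_autocorr": {k: [float(a) for a in v]
                               for k, v in self.chain_autocorr.items()},
            "converged": bool(self.converged),
        }


def diagnose(samples: dict, max_lag: int = 10,
             psrf_threshold: float = 1.1,
             geweke_threshold: float = 2.0) -> Diagnostics:
    """Diagnostics for a dict of name -> (n_chains, n_draws) sample arrays.

    With a single chain the PSRF is reported as ``None`` (unavailable)
    and the convergence summary rests on the Geweke scores alone.
    """
    diag = Diagnostics(psrf_threshold=psrf_threshold,
                       geweke_threshold=geweke_threshold)
    ok = True
    for name, arr in samples.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] >= 2:
            r = gelman_rubin(arr)
            diag.gelman_rubin[name] = r
            ok = ok and (r < psrf_threshold)
        else:
            diag.gelman_rubin[name] = None
        zs = np.array([geweke_z(c) for c in arr])
        diag.geweke[name] = zs
        ok = ok and bool(np.all(np.abs(zs) < geweke_threshold))
        diag.chain_autocorr[name] = np.mean(
            [autocorr(c, max_lag=max_lag) for c in arr], axis=0)
    diag.converged = ok
    return diag
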