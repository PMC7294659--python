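"""Numba kernels for the switching-DCRW Gibbs sampler.

Two forward-filter/backward-sample passes dominate each sweep:

* ``kalman_ffbs`` — joint draw of the daily positions given states,
  per-fix error precisions and movement parameters.  The state vector
  is z_t = (x_t, x_{t-1}) in tangent-plane km, so the DCRW transition
  x_{t+1} = x_t + M (x_t - x_{t-1}) + eta is linear.  Irregular fixes
  enter as scalar observations of w*x_{k+1} + (1-w)*x_k.
* ``state_ffbs`` — joint draw of the discrete behavioural states given
  the displacement sequence.

Randomness is passed in as pre-drawn standard normals / uniforms so the
kernels stay deterministic and the seed policy lives in one place.
The 4x4 linear algebra is written out as explicit loops: these matrices
are tiny and per-call LAPACK dispatch would dominate the runtime.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _chol2(a00, a01, a11):
    """Cholesky factors of a 2x2 SPD matrix with a jitter floor."""
    a = a00 + 1e-12
    l00 = np.sqrt(a)
    l10 = a01 / l00
    d = a11 + 1e-12 - l10 * l10
    if d < 1e-12:
        d = 1e-12
    return l00, l10, np.sqrt(d)


@njit(cache=False)
def _mat4_mul(A, B, out):
    for i in range(4):
        for j in range(4):
            s = 0.0
            for k in range(4):
                s += A[i, k] * B[k, j]
            out[i, j] = s


@njit(cache=False)
def _mat4_mul_t(A, B, out):
    """out = A @ B.T"""
    for i in range(4):
        for j in range(4):
            s = 0.0
            for k in range(4):
                s += A[i, k] * B[j, k]
            out[i, j] = s


@njit(cache=False)
def _build_A(M, out):
    """Transition matrix [[I+M, -M], [I, 0]] for one state."""
    out[:, :] = 0.0
    out[0, 0] = 1.0 + M[0, 0]
    out[0, 1] = M[0, 1]
    out[1, 0] = M[1, 0]
    out[1, 1] = 1.0 + M[1, 1]
    out[0, 2] = -M[0, 0]
    out[0, 3] = -M[0, 1]
    out[1, 2] = -M[1, 0]
    out[1, 3] = -M[1, 1]
    out[2, 0] = 1.0
    out[3, 1] = 1.0


@njit(cache=False)
def _inv4(S, out):
    """Gauss-Jordan inverse of a well-conditioned 4x4 matrix."""
    W = np.empty((4, 8))
    for i in range(4):
        for j in range(4):
            W[i, j] = S[i, j]
            W[i, j + 4] = 1.0 if i == j else 0.0
    for col in range(4):
        piv = col
        best = abs(W[col, col])
        for r in range(col + 1, 4):
            if abs(W[r, col]) > best:
                best = abs(W[r, col])
                piv = r
        if piv != col:
            for j in range(8):
                tmp = W[col, j]
                W[col, j] = W[piv, j]
                W[piv, j] = tmp
        d = W[col, col]
        if d == 0.0:
            d = 1e-30
        inv_d = 1.0 / d
        for j in range(8):
            W[col, j] *= inv_d
        for r in range(4):
            if r != col:
                f = W[r, col]
                if f != 0.0:
                    for j in range(8):
                        W[r, j] -= f * W[col, j]
    for i in range(4):
        for j in range(4):
            out[i, j] = W[i, j + 4]


@njit(cache=False)
def kalman_ffbs(T, m0, C0, Ms, Sigma, b,
                obs_start, obs_w, obs_y, obs_var, randn):
    """Sample the daily position sequence x_0..x_{T-1} (shape (T, 2)).

    Parameters
    ----------
    T : number of daily positions.
    m0, C0 : prior mean (4,) and covariance (4,4) of z_1 = (x_1, x_0).
    Ms : (2, 2, 2) per-state gamma*R(theta) matrices.
    Sigma : (2, 2) process covariance (km^2/day).
    b : (T,) int state per day; b[t] governs the movement into day t.
    obs_start : (T+1,) int pointers; fixes for Kalman step t occupy
        slice obs_start[t]:obs_start[t+1] (steps run 1..T-1).
    obs_w : (n,) interpolation weight of the later bracketing day.
    obs_y : (n, 2) observed planar positions (km).
    obs_var : (n, 2) per-coordinate observation variance (km^2).
    randn : (T, 4) standard normals consumed by the backward pass.
    """
    A_s = np.empty((2, 4, 4))
    _build_A(Ms[0], A_s[0])
    _build_A(Ms[1], A_s[1])

    fm = np.zeros((T, 4))
    fP = np.zeros((T, 4, 4))
    m = m0.copy()
    P = C0.copy()
    AP = np.empty((4, 4))
    APA = np.empty((4, 4))
    Ph = np.empty(4)
    for t in range(1, T):
        if t > 1:
            A = A_s[b[t]]
            # m = A m ; P = A P A' + Q
            m0_, m1_, m2_, m3_ = m[0], m[1], m[2], m[3]
            for i in range(4):
                m[i] = (A[i, 0] * m0_ + A[i, 1] * m1_
                        + A[i, 2] * m2_ + A[i, 3] * m3_)
            _mat4_mul(A, P, AP)
            _mat4_mul_t(AP, A, APA)
            for i in range(4):
                for j in range(4):
                    P[i, j] = APA[i, j]
            P[0, 0] += Sigma[0, 0]
            P[0, 1] += Sigma[0, 1]
            P[1, 0] += Sigma[1, 0]
            P[1, 1] += Sigma[1, 1]
        # sequential scalar observation updates
        for i in range(obs_start[t], obs_start[t + 1]):
            w = obs_w[i]
            for c in range(2):
                for r in range(4):
                    Ph[r] = w * P[r, c] + (1.0 - w) * P[r, c + 2]
                S = w * Ph[c] + (1.0 - w) * Ph[c + 2] + obs_var[i, c]
                resid = obs_y[i, c] - (w * m[c] + (1.0 - w) * m[c + 2])
                inv_s = 1.0 / S
                for r in range(4):
                    m[r] += Ph[r] * inv_s * resid
                for r in range(4):
                    for cc in range(r, 4):
                        v = P[r, cc] - Ph[r] * Ph[cc] * inv_s
                        P[r, cc] = v
                        P[cc, r] = v
        fm[t] = m
        fP[t] = P

    x = np.zeros((T, 2))
    # sample z_{T-1} (4-dim Cholesky, explicit)
    Pl = fP[T - 1].copy()
    for i in range(4):
        Pl[i, i] += 1e-10
    Lc = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1):
            s = Pl[i, j]
            for k in range(j):
                s -= Lc[i, k] * Lc[j, k]
            if i == j:
                Lc[i, i] = np.sqrt(max(s, 1e-12))
            else:
                Lc[i, j] = s / Lc[j, j]
    z_next = np.empty(4)
    for i in range(4):
        s = fm[T - 1][i]
        for k in range(i + 1):
            s += Lc[i, k] * randn[T - 1, k]
        z_next[i] = s
    x[T - 1, 0] = z_next[0]
    x[T - 1, 1] = z_next[1]
    x[T - 2, 0] = z_next[2]
    x[T - 2, 1] = z_next[3]

    S4 = np.empty((4, 4))
    Si = np.empty((4, 4))
    PA = np.empty((4, 4))
    J = np.empty((4, 4))
    Am = np.empty(4)
    mean = np.empty(4)
    for t in range(T - 2, 0, -1):
        # condition z_t on z_{t+1}; only x_{t-1} = z_t[2:4] is new
        A = A_s[b[t + 1]]
        Pt = fP[t]
        _mat4_mul_t(Pt, A, PA)        # PA = P A'
        _mat4_mul(A, PA, S4)          # S = A P A'
        S4[0, 0] += Sigma[0, 0] + 1e-10
        S4[0, 1] += Sigma[0, 1]
        S4[1, 0] += Sigma[1, 0]
        S4[1, 1] += Sigma[1, 1] + 1e-10
        S4[2, 2] += 1e-10
        S4[3, 3] += 1e-10
        _inv4(S4, Si)
        _mat4_mul(PA, Si, J)          # J = P A' S^-1
        for i in range(4):
            Am[i] = (A[i, 0] * fm[t][0] + A[i, 1] * fm[t][1]
                     + A[i, 2] * fm[t][2] + A[i, 3] * fm[t][3])
        for i in range(2, 4):
            s = fm[t][i]
            for k in range(4):
                s += J[i, k] * (z_next[k] - Am[k])
            mean[i] = s
        # conditional covariance of the x_{t-1} block: cov = P - J A P,
        # rows/cols 2..3 only; (A P)[k, j] = PA[j, k] since PA = P A'
        c22 = Pt[2, 2]
        c23 = Pt[2, 3]
        c33 = Pt[3, 3]
        for k in range(4):
            c22 -= J[2, k] * PA[2, k]
            c23 -= J[2, k] * PA[3, k]
            c33 -= J[3, k] * PA[3, k]
        l00, l10, l11 = _chol2(c22, c23, c33)
        e0 = randn[t, 0]
        e1 = randn[t, 1]
        xm0 = mean[2] + l00 * e0
        xm1 = mean[3] + l10 * e0 + l11 * e1
        x[t - 1, 0] = xm0
        x[t - 1, 1] = xm1
        z_next[0] = x[t, 0]
        z_next[1] = x[t, 1]
        z_next[2] = xm0
        z_next[3] = xm1
    return x


@njit(cache=False)
def state_ffbs(d, Ms, Sinv, logdetS, logP, unif):
    """Sample the state sequence b_0..b_{T-1} given displacements.

    d : (T, 2) displacements, d[t] = x_t - x_{t-1} (d[0] unused).
    Emissions exist for t = 2..T-1: N(d_t; M_s d_{t-1}, Sigma).
    b[0] and b[1] are copied from b[2] (no DCRW emission there).
    unif : (T,) uniforms for the backward draw.
    """
    T = d.shape[0]
    loga = np.full((T, 2), -np.inf)
    const = -np.log(2.0 * np.pi) - 0.5 * logdetS
    for s in range(2):
        r0 = d[2, 0] - (Ms[s, 0, 0] * d[1, 0] + Ms[s, 0, 1] * d[1, 1])
        r1 = d[2, 1] - (Ms[s, 1, 0] * d[1, 0] + Ms[s, 1, 1] * d[1, 1])
        q = r0 * (Sinv[0, 0] * r0 + Sinv[0, 1] * r1) \
            + r1 * (Sinv[1, 0] * r0 + Sinv[1, 1] * r1)
        loga[2, s] = np.log(0.5) + const - 0.5 * q
    for t in range(3, T):
        for s in range(2):
            r0 = d[t, 0] - (Ms[s, 0, 0] * d[t - 1, 0] + Ms[s, 0, 1] * d[t - 1, 1])
            r1 = d[t, 1] - (Ms[s, 1, 0] * d[t - 1, 0] + Ms[s, 1, 1] * d[t - 1, 1])
            q = r0 * (Sinv[0, 0] * r0 + Sinv[0, 1] * r1) \
                + r1 * (Sinv[1, 0] * r0 + Sinv[1, 1] * r1)
            e = const - 0.5 * q
            a0 = loga[t - 1, 0] + logP[0, s]
            a1 = loga[t - 1, 1] + logP[1, s]
            hi = a0 if a0 > a1 else a1
            loga[t, s] = hi + np.log(np.exp(a0 - hi) + np.exp(a1 - hi)) + e

    b = np.zeros(T, dtype=np.int64)
    hi = loga[T - 1, 0] if loga[T - 1, 0] > loga[T - 1, 1] else loga[T - 1, 1]
    p0 = np.exp(loga[T - 1, 0] - hi)
    p1 = np.exp(loga[T - 1, 1] - hi)
    b[T - 1] = 0 if unif[T - 1] < p0 / (p0 + p1) else 1
    for t in range(T - 2, 1, -1):
        l0 = loga[t, 0] + logP[0, b[t + 1]]
        l1 = loga[t, 1] + logP[1, b[t + 1]]
        hi = l0 if l0 > l1 else l1
        p0 = np.exp(l0 - hi)
        p1 = np.exp(l1 - hi)
        b[t] = 0 if unif[t] < p0 / (p0 + p1) else 1
    b[0] = b[2]
    b[1] = b[2]
    return b
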