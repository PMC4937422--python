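"""Low-level batched RK4 integration kernels.

The public API lives in :mod:`dcmv0.forward_model`; these kernels exist so
that a whole batch of parameter vectors (e.g. the central-difference stencil
of the inversion module, or thousands of Monte-Carlo draws of the sensitivity
module) can be integrated in one call.  When numba is importable the kernels
are JIT-compiled; otherwise a vectorised NumPy path with identical semantics
is used.

State layout per region: ``(z, s, f, v, q)`` — neuronal state, vasodilatory
signal, normalised inflow, normalised venous volume, normalised
deoxyhemoglobin.  Hemodynamic parameter layout per region (7 columns):
``(epsilon, tau_s, tau_f, tau_0, alpha, E_0, V_0)``.

Non-physical excursions (f, v or q <= 0, overflow) are not raised here: the
offending trajectory is poisoned with NaN and the caller decides whether that
is a hard error (public integration API) or a rejected trial step (inversion).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


# Hemodynamic parameter column indices.
EPS, TAU_S, TAU_F, TAU_0, ALPHA, E0, V0 = range(7)


@njit(cache=True)
def _network_drift(x, ut, A, Bm, C, hemo, dx):  # pragma: no cover - jitted
    P, n, _ = x.shape
    m = ut.shape[0]
    for p in range(P):
        for i in range(n):
            z = x[p, i, 0]
            s = x[p, i, 1]
            f = x[p, i, 2]
            v = x[p, i, 3]
            q = x[p, i, 4]
            acc = 0.0
            for j in range(n):
                aij = A[p, i, j]
                for k in range(m):
                    aij += ut[k] * Bm[p, k, i, j]
                acc += aij * x[p, j, 0]
            for k in range(m):
                acc += C[p, i, k] * ut[k]
            eps = hemo[p, i, 0]
            tau_s = hemo[p, i, 1]
            tau_f = hemo[p, i, 2]
            tau_0 = hemo[p, i, 3]
            alpha = hemo[p, i, 4]
            e0 = hemo[p, i, 5]
            dx[p, i, 0] = acc
            dx[p, i, 1] = eps * z - s / tau_s - (f - 1.0) / tau_f
            dx[p, i, 2] = s
            if f > 0.0 and v > 0.0 and q > 0.0:
                fv = v ** (1.0 / alpha)
                ex = 1.0 - (1.0 - e0) ** (1.0 / f)
                dx[p, i, 3] = (f - fv) / tau_0
                dx[p, i, 4] = (f * ex / e0 - fv * q / v) / tau_0
            else:
                dx[p, i, 3] = np.nan
                dx[p, i, 4] = np.nan


@njit(cache=True)
def _rk4_network_jit(A, Bm, C, u, hemo, dt, out):  # pragma: no cover - jitted
    K = u.shape[1]
    P, n, _ = A.shape
    x = np.zeros((P, n, 5))
    for p in range(P):
        for i in range(n):
            x[p, i, 2] = 1.0
            x[p, i, 3] = 1.0
            x[p, i, 4] = 1.0
    out[0] = x
    k1 = np.empty((P, n, 5))
    k2 = np.empty((P, n, 5))
    k3 = np.empty((P, n, 5))
    k4 = np.empty((P, n, 5))
    xt = np.empty((P, n, 5))
    for step in range(K):
        ut = u[:, step]
        _network_drift(x, ut, A, Bm, C, hemo, k1)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    xt[p, i, c] = x[p, i, c] + 0.5 * dt * k1[p, i, c]
        _network_drift(xt, ut, A, Bm, C, hemo, k2)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    xt[p, i, c] = x[p, i, c] + 0.5 * dt * k2[p, i, c]
        _network_drift(xt, ut, A, Bm, C, hemo, k3)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    xt[p, i, c] = x[p, i, c] + dt * k3[p, i, c]
        _network_drift(xt, ut, A, Bm, C, hemo, k4)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    x[p, i, c] += (
                        dt
                        / 6.0
                        * (
                            k1[p, i, c]
                            + 2.0 * k2[p, i, c]
                            + 2.0 * k3[p, i, c]
                            + k4[p, i, c]
                        )
                    )
        out[step + 1] = x


@njit(cache=True)
def _hemo_drift(x, z, hemo, dx):  # pragma: no cover - jitted
    P = x.shape[0]
    for p in range(P):
        s = x[p, 0]
        f = x[p, 1]
        v = x[p, 2]
        q = x[p, 3]
        eps = hemo[p, 0]
        tau_s = hemo[p, 1]
        tau_f = hemo[p, 2]
        tau_0 = hemo[p, 3]
        alpha = hemo[p, 4]
        e0 = hemo[p, 5]
        dx[p, 0] = eps * z - s / tau_s - (f - 1.0) / tau_f
        dx[p, 1] = s
        if f > 0.0 and v > 0.0 and q > 0.0:
            fv = v ** (1.0 / alpha)
            ex = 1.0 - (1.0 - e0) ** (1.0 / f)
            dx[p, 2] = (f - fv) / tau_0
            dx[p, 3] = (f * ex / e0 - fv * q / v) / tau_0
        else:
            dx[p, 2] = np.nan
            dx[p, 3] = np.nan


@njit(cache=True)
def _rk4_hemo_jit(z_drive, hemo, dt, out):  # pragma: no cover - jitted
    K = z_drive.shape[0]
    P = hemo.shape[0]
    x = np.zeros((P, 4))
    for p in range(P):
        x[p, 1] = 1.0
        x[p, 2] = 1.0
        x[p, 3] = 1.0
    out[0] = x
    k1 = np.empty((P, 4))
    k2 = np.empty((P, 4))
    k3 = np.empty((P, 4))
    k4 = np.empty((P, 4))
    xt = np.empty((P, 4))
    for step in range(K):
        z = z_drive[step]
        _hemo_drift(x, z, hemo, k1)
        for p in range(P):
            for c in range(4):
                xt[p, c] = x[p, c] + 0.5 * dt * k1[p, c]
        _hemo_drift(xt, z, hemo, k2)
        for p in range(P):
            for c in range(4):
                xt[p, c] = x[p, c] + 0.5 * dt * k2[p, c]
        _hemo_drift(xt, z, hemo, k3)
        for p in range(P):
            for c in range(4):
                xt[p, c] = x[p, c] + dt * k3[p, c]
        _hemo_drift(xt, z, hemo, k4)
        for p in range(P):
            for c in range(4):
                x[p, c] += (
                    dt / 6.0 * (k1[p, c] + 2.0 * k2[p, c] + 2.0 * k3[p, c] + k4[p, c])
                )
        out[step + 1] = x


# ---------------------------------------------------------------------------
# NumPy fallback paths (identical maths, vectorised over the batch axis)
# ---------------------------------------------------------------------------


def _np_network_drift(x, ut, A, Bm, C, hemo):
    Au = A + np.einsum("k,pkij->pij", ut, Bm) if Bm.shape[1] else A
    dz = np.einsum("pij,pj->pi", Au, x[..., 0]) + C @ ut
    s, f, v, q = x[..., 1], x[..., 2], x[..., 3], x[..., 4]
    eps, tau_s, tau_f = hemo[..., 0], hemo[..., 1], hemo[..., 2]
    tau_0, alpha, e0 = hemo[..., 3], hemo[..., 4], hemo[..., 5]
    with np.errstate(all="ignore"):
        ok = (f > 0) & (v > 0) & (q > 0)
        fs = np.where(ok, f, 1.0)
        vs = np.where(ok, v, 1.0)
        qs = np.where(ok, q, 1.0)
        fv = vs ** (1.0 / alpha)
        ex = 1.0 - (1.0 - e0) ** (1.0 / fs)
        dv = np.where(ok, (fs - fv) / tau_0, np.nan)
        dq = np.where(ok, (fs * ex / e0 - fv * qs / vs) / tau_0, np.nan)
        ds = eps * x[..., 0] - s / tau_s - (f - 1.0) / tau_f
    return np.stack([dz, ds, s, dv, dq], axis=-1)


def _rk4_network_np(A, Bm, C, u, hemo, dt, out):
    P, n, _ = A.shape
    x = np.zeros((P, n, 5))
    x[..., 2:] = 1.0
    out[0] = x
    with np.errstate(all="ignore"):
        for step in range(u.shape[1]):
            ut = u[:, step]
            k1 = _np_network_drift(x, ut, A, Bm, C, hemo)
            k2 = _np_network_drift(x + 0.5 * dt * k1, ut, A, Bm, C, hemo)
            k3 = _np_network_drift(x + 0.5 * dt * k2, ut, A, Bm, C, hemo)
            k4 = _np_network_drift(x + dt * k3, ut, A, Bm, C, hemo)
            x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            out[step + 1] = x


def _np_hemo_drift(x, z, hemo):
    s, f, v, q = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    eps, tau_s, tau_f = hemo[..., 0], hemo[..., 1], hemo[..., 2]
    tau_0, alpha, e0 = hemo[..., 3], hemo[..., 4], hemo[..., 5]
    with np.errstate(all="ignore"):
        ok = (f > 0) & (v > 0) & (q > 0)
        fs = np.where(ok, f, 1.0)
        vs = np.where(ok, v, 1.0)
        qs = np.where(ok, q, 1.0)
        fv = vs ** (1.0 / alpha)
        ex = 1.0 - (1.0 - e0) ** (1.0 / fs)
        ds = eps * z - s / tau_s - (f - 1.0) / tau_f
        dv = np.where(ok, (fs - fv) / tau_0, np.nan)
        dq = np.where(ok, (fs * ex / e0 - fv * qs / vs) / tau_0, np.nan)
    return np.stack([ds, s.copy(), dv, dq], axis=-1)


def _rk4_hemo_np(z_drive, hemo, dt, out):
    P = hemo.shape[0]
    x = np.zeros((P, 4))
    x[:, 1:] = 1.0
    out[0] = x
    with np.errstate(all="ignore"):
        for step in range(z_drive.shape[0]):
            z = z_drive[step]
            k1 = _np_hemo_drift(x, z, hemo)
            k2 = _np_hemo_drift(x + 0.5 * dt * k1, z, hemo)
            k3 = _np_hemo_drift(x + 0.5 * dt * k2, z, hemo)
            k4 = _np_hemo_drift(x + dt * k3, z, hemo)
            x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            out[step + 1] = x


# ---------------------------------------------------------------------------
# Public (package-internal) entry points
# ---------------------------------------------------------------------------


def integrate_network(A, Bm, C, u, hemo, dt):
    """Integrate a batch of bilinear-neuronal + Balloon systems.

    Parameters are batched on the leading axis: ``A (P,n,n)``, ``Bm
    (P,m,n,n)``, ``C (P,n,m)``, ``hemo (P,n,7)``; ``u (m,K)`` is the shared
    fine-grid input.  Returns states of shape ``(K+1, P, n, 5)`` starting at
    the resting fixed point.
    """
    A = np.ascontiguousarray(A, dtype=np.float64)
    Bm = np.ascontiguousarray(Bm, dtype=np.float64)
    C = np.ascontiguousarray(C, dtype=np.float64)
    u = np.ascontiguousarray(u, dtype=np.float64)
    hemo = np.ascontiguousarray(hemo, dtype=np.float64)
    K = u.shape[1]
    P, n, _ = A.shape
    out = np.empty((K + 1, P, n, 5))
    if HAVE_NUMBA:
        _rk4_network_jit(A, Bm, C, u, hemo, float(dt), out)
    else:
        _rk4_network_np(A, Bm, C, u, hemo, float(dt), out)
    return out


def integrate_hemodynamics(z_drive, hemo, dt):
    """Integrate a batch of single-region Balloon systems under a shared
    neuronal drive ``z_drive (K,)``; returns ``(K+1, P, 4)`` states."""
    z_drive = np.ascontiguousarray(z_drive, dtype=np.float64)
    hemo = np.ascontiguousarray(hemo, dtype=np.float64)
    out = np.empty((z_drive.shape[0] + 1, hemo.shape[0], 4))
    if HAVE_NUMBA:
        _rk4_hemo_jit(z_drive, hemo, float(dt), out)
    else:
        _rk4_hemo_np(z_drive, hemo, float(dt), out)
    return out
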