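"""Deterministic generative model: bilinear neuronal dynamics + Balloon BOLD.

The model has two stages.  A bilinear neuronal state equation couples the
latent activity ``z`` of ``n`` regions,

    dz/dt = (A + sum_j u_j B_j) z + C u,

where ``A`` (1/s) is the fixed effective connectivity, each ``B_j`` encodes
how input ``j`` modulates that connectivity and ``C`` maps exogenous inputs
``u`` directly onto regions.  In each region the neuronal state drives the
four-state Balloon hemodynamic model,

    ds/dt = eps*z - s/tau_s - (f - 1)/tau_f          (vasodilatory signal)
    df/dt = s                                        (normalised inflow)
    tau_0 dv/dt = f - v**(1/alpha)                   (venous volume)
    tau_0 dq/dt = f*E(f, E_0)/E_0 - v**(1/alpha)*q/v (deoxyhemoglobin)

with the oxygen-extraction function ``E(f, E_0) = 1 - (1 - E_0)**(1/f)``.
The measured fractional BOLD signal change is

    y = V_0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)),

so the resting venous blood volume fraction ``V_0`` scales the output exactly
linearly — the property this package is built to study.

Naming caveat: some authors label ``tau_s`` the signal-decay constant and
``tau_f`` the flow-feedback (autoregulation) constant, others swap the two
names.  Here ``tau_s`` always divides ``s`` (decay of the vasodilatory
signal) and ``tau_f`` always divides ``f - 1`` (flow feedback), regardless of
nomenclature; both aliases are documented in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _engine

__all__ = [
    "ConnectivityParameters",
    "HemodynamicParameters",
    "StimulusDesign",
    "StateTrajectory",
    "BOLDTimeSeries",
    "IntegrationDivergedError",
    "DEFAULT_SELF_CONNECTION",
    "bold_coefficients",
    "neuronal_drift",
    "hemodynamic_drift",
    "bold_from_states",
    "integrate_dcm",
]

#: Fixed self-connection (1/s).  Must be more negative than the spectral
#: radius of the off-diagonal coupling for the network to be dissipative;
#: with unit reciprocal couplings on two branches that radius is sqrt(2).
#: The default sits just inside that bound so the network keeps a slow
#: collective mode (~12 s) on the timescale a block design can actually
#: interrogate; a strongly dissipative network relaxes within a single scan
#: and its candidate architectures become observationally equivalent.
DEFAULT_SELF_CONNECTION = -1.5

_STATE_BOUND = 1e6


class IntegrationDivergedError(RuntimeError):
    """Raised when the state trajectory leaves the physical domain."""


def bold_coefficients(e_0: float) -> tuple[float, float, float]:
    """Classical 1.5 T BOLD output coefficients ``(k1, k2, k3)``.

    ``k1 = 7*E_0``, ``k2 = 2``, ``k3 = 2*E_0 - 0.2``.
    """
    return 7.0 * e_0, 2.0, 2.0 * e_0 - 0.2


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-model parameters for one region.

    Defaults mirror the conventional software priors for event-related BOLD:
    signal decay rate 0.64 1/s (``tau_s = 1/0.64 s``), flow feedback rate
    0.32 1/s (``tau_f = 1/0.32 s``), transit time 2 s, stiffness 0.32,
    resting oxygen extraction 0.32, resting venous volume fraction 0.04.
    """

    epsilon: float = 1.0
    tau_s: float = 1.0 / 0.64
    tau_f: float = 1.0 / 0.32
    tau_0: float = 2.0
    alpha: float = 0.32
    E_0: float = 0.32
    V_0: float = 0.04

    def __post_init__(self) -> None:
        if min(self.tau_s, self.tau_f, self.tau_0) <= 0:
            raise ValueError("time constants tau_s, tau_f, tau_0 must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.E_0 < 1:
            raise ValueError(f"E_0 must lie in (0, 1), got {self.E_0}")
        if not 0 < self.V_0 < 1:
            raise ValueError(f"V_0 must lie in (0, 1), got {self.V_0}")

    def with_v0(self, v_0: float) -> "HemodynamicParameters":
        return replace(self, V_0=v_0)

    def as_array(self) -> np.ndarray:
        """Engine layout ``(epsilon, tau_s, tau_f, tau_0, alpha, E_0, V_0)``."""
        return np.array(
            [
                self.epsilon,
                self.tau_s,
                self.tau_f,
                self.tau_0,
                self.alpha,
                self.E_0,
                self.V_0,
            ]
        )


def stack_hemodynamics(hemo: Sequence[HemodynamicParameters]) -> np.ndarray:
    return np.stack([h.as_array() for h in hemo])


@dataclass(frozen=True)
class ConnectivityParameters:
    """Coupling matrices of the bilinear neuronal model (all in 1/s)."""

    A: np.ndarray
    C: np.ndarray
    B: np.ndarray | None = None
    region_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        n = A.shape[0]
        if C.ndim != 2 or C.shape[0] != n:
            raise ValueError(f"C must be (n, m) with n={n}, got shape {C.shape}")
        m = C.shape[1]
        B = self.B
        if B is None:
            B = np.zeros((m, n, n))
        else:
            B = np.asarray(B, dtype=float)
            if B.shape != (m, n, n):
                raise ValueError(
                    f"B must have shape (m, n, n)=({m},{n},{n}), got {B.shape}"
                )
        names = self.region_names or tuple(f"R{i + 1}" for i in range(n))
        if len(names) != n:
            raise ValueError("region_names length must match the region dimension")
        if np.any(np.diag(A) >= 0):
            raise ValueError("diagonal of A must be negative (self-inhibition)")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "region_names", tuple(names))

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]


@dataclass(frozen=True)
class StimulusDesign:
    """Exogenous inputs on a fine integration grid plus the scan grid.

    ``inputs`` has shape ``(m, K)`` where ``K*dt == n_scans*tr``; the value in
    column ``k`` applies on the interval ``[k*dt, (k+1)*dt)``.
    """

    tr: float
    n_scans: int
    dt: float
    inputs: np.ndarray

    def __post_init__(self) -> None:
        inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        if not np.all(np.isfinite(inputs)):
            raise ValueError("stimulus inputs must be finite")
        K = inputs.shape[1]
        if abs(K * self.dt - self.n_scans * self.tr) > 1e-9 * max(1.0, self.tr):
            raise ValueError(
                f"fine grid covers {K * self.dt} s but the scan grid covers "
                f"{self.n_scans * self.tr} s"
            )
        object.__setattr__(self, "inputs", inputs)

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[0]

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr

    @property
    def scan_times(self) -> np.ndarray:
        return self.tr * np.arange(1, self.n_scans + 1)

    def resampled(self, dt: float) -> "StimulusDesign":
        """Return the same piecewise-constant inputs on a new fine grid."""
        if abs(dt - self.dt) < 1e-12:
            return self
        K_new = int(round(self.duration / dt))
        if abs(K_new * dt - self.duration) > 1e-9:
            raise ValueError(f"dt={dt} does not tile the design duration")
        t_mid = (np.arange(K_new) + 0.5) * dt
        idx = np.minimum((t_mid / self.dt).astype(int), self.inputs.shape[1] - 1)
        return StimulusDesign(self.tr, self.n_scans, dt, self.inputs[:, idx])


@dataclass(frozen=True)
class StateTrajectory:
    """Full latent-state time courses on the fine grid."""

    times: np.ndarray
    z: np.ndarray
    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray
    region_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class BOLDTimeSeries:
    """Fractional BOLD signal change sampled on the scan grid."""

    tr: float
    values: np.ndarray
    region_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(values)):
            raise ValueError("BOLD values must be finite")
        names = self.region_names or tuple(
            f"R{i + 1}" for i in range(values.shape[1])
        )
        if len(names) != values.shape[1]:
            raise ValueError("region_names length must match the number of columns")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_names", tuple(names))

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def scan_times(self) -> np.ndarray:
        return self.tr * np.arange(1, self.n_scans + 1)


# ---------------------------------------------------------------------------
# Drift functions (single-evaluation, convenient for tests and exposition)
# ---------------------------------------------------------------------------


def neuronal_drift(
    z: np.ndarray, u: np.ndarray, conn: ConnectivityParameters
) -> np.ndarray:
    """Bilinear neuronal drift ``dz/dt = (A + sum_j u_j B_j) z + C u``."""
    z = np.asarray(z, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if z.shape != (conn.n_regions,):
        raise ValueError(f"z must have shape ({conn.n_regions},), got {z.shape}")
    if u.shape != (conn.n_inputs,):
        raise ValueError(f"u must have shape ({conn.n_inputs},), got {u.shape}")
    A_eff = conn.A + np.einsum("j,jkl->kl", u, conn.B)
    return A_eff @ z + conn.C @ u


def hemodynamic_drift(
    state: Sequence[float], z: float, h: HemodynamicParameters
) -> np.ndarray:
    """Balloon-model drift of ``(s, f, v, q)`` for one region."""
    s, f, v, q = (float(x) for x in state)
    if f <= 0 or v <= 0 or q <= 0:
        raise ValueError("f, v and q must be positive (fractional powers)")
    fv = v ** (1.0 / h.alpha)
    ex = 1.0 - (1.0 - h.E_0) ** (1.0 / f)
    return np.array(
        [
            h.epsilon * z - s / h.tau_s - (f - 1.0) / h.tau_f,
            s,
            (f - fv) / h.tau_0,
            (f * ex / h.E_0 - fv * q / v) / h.tau_0,
        ]
    )


def bold_from_states(
    v: float,
    q: float,
    h: HemodynamicParameters,
    field_coeffs: tuple[float, float, float] | None = None,
) -> float:
    """BOLD output ``y = V_0*(k1*(1-q) + k2*(1-q/v) + k3*(1-v))``."""
    if v <= 0:
        raise ValueError("venous volume v must be positive")
    if q <= 0:
        raise ValueError("deoxyhemoglobin q must be positive")
    k1, k2, k3 = field_coeffs if field_coeffs is not None else bold_coefficients(h.E_0)
    return h.V_0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def bold_from_state_arrays(v: np.ndarray, q: np.ndarray, hemo: np.ndarray) -> np.ndarray:
    """Vectorised BOLD output; ``hemo[..., 5]`` is E_0, ``hemo[..., 6]`` V_0."""
    e0 = hemo[..., 5]
    v0 = hemo[..., 6]
    k1, k2, k3 = bold_coefficients(e0)
    with np.errstate(all="ignore"):
        return v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _scan_stride(design: StimulusDesign, dt: float) -> int:
    stride = design.tr / dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(f"dt={dt} must divide the repetition time {design.tr}")
    return int(round(stride))


def simulate_bold_batch(
    design: StimulusDesign,
    A: np.ndarray,
    C: np.ndarray,
    hemo: np.ndarray,
    dt: float,
    B: np.ndarray | None = None,
) -> np.ndarray:
    """Batched noise-free BOLD at scan times.

    ``A (P,n,n)``, ``C (P,n,m)``, ``hemo (P,n,7)`` → ``(P, n_scans, n)``.
    Diverged batch members come back as NaN rows; the caller decides how to
    treat them.
    """
    design = design.resampled(dt)
    P, n, _ = A.shape
    if B is None:
        B = np.zeros((P, design.n_inputs, n, n))
    states = _engine.integrate_network(A, B, C, design.inputs, hemo, dt)
    stride = _scan_stride(design, dt)
    idx = stride * np.arange(1, design.n_scans + 1)
    sampled = states[idx]  # (n_scans, P, n, 5)
    y = bold_from_state_arrays(sampled[..., 3], sampled[..., 4], hemo)
    return np.transpose(y, (1, 0, 2))


def integrate_dcm(
    design: StimulusDesign,
    conn: ConnectivityParameters,
    hemo: Sequence[HemodynamicParameters],
    dt: float | None = None,
) -> tuple[StateTrajectory, BOLDTimeSeries]:
    """Integrate the full system from rest and sample BOLD at scan times.

    Uses a fixed-step classical Runge-Kutta scheme so that the output is a
    deterministic, bit-reproducible function of the inputs.  Raises
    :class:`IntegrationDivergedError` if any state becomes non-finite or
    exceeds a magnitude bound, naming the offending configuration.
    """
    dt = design.dt if dt is None else float(dt)
    if dt > design.tr:
        raise ValueError("integration step dt must not exceed the repetition time")
    if len(hemo) != conn.n_regions:
        raise ValueError("one HemodynamicParameters per region is required")
    if design.n_inputs != conn.n_inputs:
        raise ValueError("design and connectivity disagree on the input dimension")
    sym = 0.5 * (conn.A + conn.A.T)
    if np.max(np.linalg.eigvalsh(sym)) >= 0:
        warnings.warn(
            "symmetric part of A is not negative definite; the neuronal "
            "system may be unstable",
            stacklevel=2,
        )
    design_f = design.resampled(dt)
    hemo_arr = stack_hemodynamics(hemo)[None]
    states = _engine.integrate_network(
        conn.A[None], conn.B[None], conn.C[None], design_f.inputs, hemo_arr, dt
    )[:, 0]  # (K+1, n, 5)
    if not np.all(np.isfinite(states)) or np.max(np.abs(states)) > _STATE_BOUND:
        raise IntegrationDivergedError(
            "state trajectory diverged (non-finite or |state| > "
            f"{_STATE_BOUND:g}); A diagonal {np.diag(conn.A)}, max |A| off-diag "
            f"{np.max(np.abs(conn.A - np.diag(np.diag(conn.A)))):g}"
        )
    times = dt * np.arange(states.shape[0])
    traj = StateTrajectory(
        times=times,
        z=states[..., 0],
        s=states[..., 1],
        f=states[..., 2],
        v=states[..., 3],
        q=states[..., 4],
        region_names=conn.region_names,
    )
    stride = _scan_stride(design_f, dt)
    idx = stride * np.arange(1, design.n_scans + 1)
    y = bold_from_state_arrays(states[idx][..., 3], states[idx][..., 4], hemo_arr[0])
    bold = BOLDTimeSeries(tr=design.tr, values=y, region_names=conn.region_names)
    return traj, bold
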