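"""Time-resolved variance-based sensitivity analysis of the Balloon model.

For a single region driven by a short (2 s) stimulus, parameters are drawn
from their prior distributions and the noise-free BOLD output is integrated
for every draw.  At each peristimulus time point the total output variance
across draws measures how strongly parameter uncertainty is expressed in
measurement space, and the Jansen total-effect estimator on a Saltelli
cross-sampling design attributes that variance to individual parameters:

    S_Ti(t) = E[(f(A) - f(A_B^i))^2] / (2 Var f(t)),

where ``A`` and ``B`` are two independent sample matrices and ``A_B^i`` is
``A`` with column ``i`` replaced from ``B``.  ``S_Ti`` is the fraction of
output variance attributable to parameter ``i`` including all interactions.
A Saltelli design with ``N`` base samples over ``k`` parameters costs
``(k + 2) * N`` model evaluations.

Sampling distributions: scale-type parameters (epsilon, tau_s, tau_f, tau_0)
are lognormal around the default means; fraction-type parameters (alpha,
E_0, V_0) are logit-normal so draws stay in (0, 1).  The kinetic spreads
equal the tight prior variance used by the inversion module (0.015 on the
log scale); V_0, which the inversion clamps rather than estimates, gets a
broader logit-scale spread (0.5) reflecting its across-region physiological
range (roughly 0.02-0.06 and beyond in venous-dominated voxels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, ndtri
from scipy.stats import qmc

from . import _engine
from .forward_model import HemodynamicParameters, bold_from_state_arrays

__all__ = [
    "ParameterPrior",
    "SaltelliSample",
    "SensitivityResult",
    "default_parameter_priors",
    "sample_parameters",
    "evaluate_bold_responses",
    "variance_timecourse",
    "total_effect_indices",
    "jansen_total_effect",
    "saltelli_uniform_design",
    "timing_summary",
]

#: Engine hemodynamic-parameter order.
PARAM_NAMES = ("epsilon", "tau_s", "tau_f", "tau_0", "alpha", "E_0", "V_0")

_KINETIC_SIGMA = math.sqrt(0.015)
_EPS_MC = 0.05  # Monte-Carlo tolerance for small negative indices


@dataclass(frozen=True)
class ParameterPrior:
    """Marginal sampling distribution for one hemodynamic parameter."""

    name: str
    median: float
    sigma: float  # spread on the log / logit scale
    dist: str = "lognormal"  # or "logitnormal"

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "logitnormal"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dist == "logitnormal" and not 0 < self.median < 1:
            raise ValueError("logit-normal median must lie in (0, 1)")
        if self.dist == "lognormal" and self.median <= 0:
            raise ValueError("lognormal median must be positive")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        z = ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
        if self.dist == "lognormal":
            return self.median * np.exp(self.sigma * z)
        return expit(logit(self.median) + self.sigma * z)


def default_parameter_priors(
    v0_sigma: float = 0.5, kinetic_sigma: float = _KINETIC_SIGMA
) -> tuple[ParameterPrior, ...]:
    """Priors centred on the default Balloon parameters (see module doc)."""
    h = HemodynamicParameters()
    return (
        ParameterPrior("epsilon", h.epsilon, kinetic_sigma, "lognormal"),
        ParameterPrior("tau_s", h.tau_s, kinetic_sigma, "lognormal"),
        ParameterPrior("tau_f", h.tau_f, kinetic_sigma, "lognormal"),
        ParameterPrior("tau_0", h.tau_0, kinetic_sigma, "lognormal"),
        ParameterPrior("alpha", h.alpha, kinetic_sigma, "logitnormal"),
        ParameterPrior("E_0", h.E_0, kinetic_sigma, "logitnormal"),
        ParameterPrior("V_0", h.V_0, v0_sigma, "logitnormal"),
    )


@dataclass(frozen=True)
class SaltelliSample:
    """The A/B/A_B matrices of a Saltelli total-effect design."""

    names: tuple[str, ...]
    A: np.ndarray  # (N, k)
    B: np.ndarray  # (N, k)
    AB: np.ndarray  # (k, N, k)
    scheme: str
    seed: int

    @property
    def n_base(self) -> int:
        return self.A.shape[0]

    @property
    def n_params(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        return (self.n_params + 2) * self.n_base


def saltelli_uniform_design(
    k: int, n_base: int, scheme: str = "sobol", seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform-(0,1) A, B and A_B matrices for ``k`` factors.

    ``n_base`` must be a power of two >= 64 (Sobol' balance).  The same
    routine serves the toy-function oracles in the test-suite.
    """
    if n_base < 64 or (n_base & (n_base - 1)) != 0:
        raise ValueError("n_base must be a power of two and at least 64")
    if scheme == "sobol":
        eng = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
        M = eng.random(n_base)
    elif scheme == "random":
        M = np.random.default_rng(seed).random((n_base, 2 * k))
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    A, B = M[:, :k], M[:, k:]
    AB = np.repeat(A[None], k, axis=0)
    for i in range(k):
        AB[i, :, i] = B[:, i]
    return A, B, AB


def sample_parameters(
    priors: tuple[ParameterPrior, ...] | list[ParameterPrior] | None = None,
    n_base: int = 1024,
    scheme: str = "sobol",
    seed: int = 0,
) -> SaltelliSample:
    """Draw the Saltelli design on the natural parameter scale."""
    priors = tuple(priors) if priors is not None else default_parameter_priors()
    k = len(priors)
    A, B, AB = saltelli_uniform_design(k, n_base, scheme, seed)

    def transform(U: np.ndarray) -> np.ndarray:
        cols = [priors[i].ppf(U[..., i]) for i in range(k)]
        return np.stack(cols, axis=-1)

    return SaltelliSample(
        names=tuple(p.name for p in priors),
        A=transform(A),
        B=transform(B),
        AB=transform(AB),
        scheme=scheme,
        seed=seed,
    )


def evaluate_bold_responses(
    params: np.ndarray,
    stim_duration: float = 2.0,
    t_max: float = 32.0,
    dt: float = 0.125,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free single-region BOLD for each parameter row.

    ``params`` is ``(R, 7)`` in the :data:`PARAM_NAMES` order; the neuronal
    drive is the stimulus itself (``z = u``, 1 during the first
    ``stim_duration`` seconds), so this probes the hemodynamic stage alone.
    Returns ``(times, y)`` with ``y`` of shape ``(R, len(times))``.  Rows
    whose integration leaves the physical domain come back as NaN.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    K = int(round(t_max / dt))
    times = dt * np.arange(K + 1)
    z = (times[:-1] < stim_duration).astype(float)
    out = np.empty((params.shape[0], K + 1))
    for lo in range(0, params.shape[0], chunk):
        block = params[lo : lo + chunk]
        states = _engine.integrate_hemodynamics(z, block[:, :6], dt)
        hemo = block[:, None, :]  # broadcast (R,1,7) against (K+1,R)
        v, q = states[..., 2].T, states[..., 3].T  # (R, K+1)
        out[lo : lo + chunk] = bold_from_state_arrays(
            v, q, np.repeat(hemo, v.shape[1], axis=1)
        )
    return times, out


@dataclass(frozen=True)
class SensitivityResult:
    """Variance decomposition of the BOLD output over peristimulus time."""

    times: np.ndarray
    variance: np.ndarray  # (T,)
    indices: np.ndarray  # (k, T); NaN where the variance is ~0
    names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def time_averaged_index(self, name: str, t_from: float, t_to: float) -> float:
        """Mean total-effect index of one parameter over a time window,
        ignoring time points where the index is undefined."""
        sel = (self.times >= t_from) & (self.times <= t_to)
        row = self.indices[self.names.index(name), sel]
        return float(np.nanmean(row))


def jansen_total_effect(
    fA: np.ndarray, fAB: np.ndarray, variance: np.ndarray
) -> np.ndarray:
    """Jansen estimator ``S_Ti = E[(f(A) - f(A_B^i))^2] / (2 Var f)``.

    ``fA`` is ``(N, T)``, ``fAB`` is ``(k, N, T)``, ``variance`` is ``(T,)``.
    Time points with (near-)zero variance yield NaN — undefined, not zero.
    """
    num = 0.5 * np.mean((fA[None] - fAB) ** 2, axis=1)  # (k, T)
    denom = np.asarray(variance, dtype=float)
    tiny = max(1e-30, 1e-9 * float(np.nanmax(denom, initial=0.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        st = num / np.where(denom > tiny, denom, np.nan)
    return st


def _evaluate_design(sample: SaltelliSample, **sim_kw):
    k, N = sample.n_params, sample.n_base
    rows = np.vstack([sample.A, sample.B, sample.AB.reshape(k * N, k)])
    times, y = evaluate_bold_responses(rows, **sim_kw)
    bad = ~np.all(np.isfinite(y), axis=1)
    if np.any(bad):
        y = y.copy()
        y[bad] = np.nan
    fA, fB = y[:N], y[N : 2 * N]
    fAB = y[2 * N :].reshape(k, N, -1)
    return times, fA, fB, fAB, int(bad.sum())


def variance_timecourse(
    sample: SaltelliSample,
    stim_duration: float = 2.0,
    t_max: float = 32.0,
    dt: float = 0.125,
) -> tuple[np.ndarray, np.ndarray]:
    """Total output variance across draws at each peristimulus time."""
    times, fA, fB, _, _ = _evaluate_design(
        sample, stim_duration=stim_duration, t_max=t_max, dt=dt
    )
    both = np.vstack([fA, fB])
    return times, np.nanvar(both, axis=0, ddof=1)


def total_effect_indices(
    sample: SaltelliSample,
    stim_duration: float = 2.0,
    t_max: float = 32.0,
    dt: float = 0.125,
) -> SensitivityResult:
    """Variance time course plus per-parameter total-effect indices."""
    times, fA, fB, fAB, n_failed = _evaluate_design(
        sample, stim_duration=stim_duration, t_max=t_max, dt=dt
    )
    variance = np.nanvar(np.vstack([fA, fB]), axis=0, ddof=1)
    st = jansen_total_effect(fA, fAB, variance)
    meta = {
        "n_base": sample.n_base,
        "n_evaluations": sample.n_evaluations,
        "n_failed": n_failed,
        "scheme": sample.scheme,
        "seed": sample.seed,
        "stim_duration": stim_duration,
        "dt": dt,
        "eps_mc": _EPS_MC,
    }
    return SensitivityResult(
        times=times, variance=variance, indices=st, names=sample.names, meta=meta
    )


def timing_summary(
    times: np.ndarray,
    variance: np.ndarray,
    onset: float = 0.0,
    offset: float = 2.0,
    frac: float = 0.05,
) -> dict[str, float]:
    """Characteristic times of the variance time course.

    Returns the peristimulus time of peak variance, the first sustained
    crossing above ``frac`` of the peak after stimulus onset (departure from
    baseline), and the time after stimulus offset at which the variance falls
    and stays below that threshold (return to baseline).
    """
    times = np.asarray(times, dtype=float)
    var = np.asarray(variance, dtype=float)
    peak_idx = int(np.nanargmax(var))
    thresh = frac * var[peak_idx]
    above = var > thresh
    t_depart = math.nan
    for i in np.flatnonzero(above & (times >= onset)):
        if i > peak_idx or np.all(above[i : peak_idx + 1]):
            t_depart = float(times[i])
            break
    t_return = math.nan
    candidates = np.flatnonzero(~above & (times >= max(offset, times[peak_idx])))
    for i in candidates:
        if np.all(~above[i:]):
            t_return = float(times[i] - offset)
            break
    return {
        "t_peak": float(times[peak_idx]),
        "t_depart": t_depart,
        "t_return_after_offset": t_return,
        "threshold_fraction": frac,
    }
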