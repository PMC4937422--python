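"""Variational-Laplace inversion of a DCM.

The posterior over free parameters is approximated by a Gaussian
``q(theta) = N(mu, Sigma)`` whose moments are found by Gauss-Newton ascent on
the variational free energy

    F = E_q[log p(y | theta)] - KL(q || prior)
      = sum_r [ N_r/2 (log lambda_r - log 2*pi)
                - lambda_r/2 (RSS_r + tr(J_r Sigma J_r^T)) ]
        - 1/2 [ tr(Pi_0 Sigma) + e0^T Pi_0 e0 - p + log|Sigma_0| - log|Sigma| ],

where ``J`` is the forward-model Jacobian at the posterior mean (central
finite differences, batched through the integration engine), ``lambda_r`` is
an i.i.d. Gaussian noise precision per region (maximised in closed form
between parameter steps), ``e0 = mu - mu_0`` and ``Pi_0`` the prior
precision.  F is a lower bound on the log model evidence and is the quantity
later compared across architectures and V_0 prior sets.

Steps are Levenberg-Marquardt damped and accepted only when they increase F,
so the accepted-step trace is non-decreasing by construction.  The optimiser
contains no randomness: identical inputs give bit-identical posteriors.

Positivity-constrained hemodynamic parameters are parameterised as log
scaling factors around their prior means (``tau_0 = tau_0_bar * exp(theta)``
etc.), which keeps the Gaussian machinery consistent.  V_0 is clamped — never
a free parameter by default — which is precisely the prior belief whose
consequences the study quantifies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .forward_model import (
    DEFAULT_SELF_CONNECTION,
    BOLDTimeSeries,
    HemodynamicParameters,
    StimulusDesign,
    simulate_bold_batch,
    stack_hemodynamics,
)
from .model_space import ArchitectureMask

__all__ = [
    "Priors",
    "Posterior",
    "InversionOptions",
    "default_priors",
    "variational_laplace",
    "fit_nonlinear_gaussian",
    "log_evidence",
]

#: Hemodynamic parameters estimated (as log scaling factors) per region.
DEFAULT_FREE_HEMO = ("epsilon", "tau_s", "tau_0")

_HEMO_COL = {
    "epsilon": 0,
    "tau_s": 1,
    "tau_f": 2,
    "tau_0": 3,
    "alpha": 4,
    "E_0": 5,
}

_PREC_FLOOR = 1e-8
_PREC_CAP = 1e12


@dataclass(frozen=True)
class Priors:
    """Gaussian prior over the free parameters plus the clamped-value map."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        p = mean.shape[0]
        if cov.shape != (p, p):
            raise ValueError("prior covariance shape must match the mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("prior covariance must be positive semidefinite")
        if len(self.names) != p:
            raise ValueError("one name per free parameter is required")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "names", tuple(self.names))


@dataclass(frozen=True)
class Posterior:
    """Gaussian posterior, its free energy and the optimisation trace."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    precisions: np.ndarray
    trace: tuple[float, ...]
    converged: bool
    n_iter: int

    def __getitem__(self, name: str) -> float:
        return float(self.mean[self.names.index(name)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "free_energy": self.free_energy,
            "precisions": self.precisions.tolist(),
            "trace": list(self.trace),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class InversionOptions:
    """Optimiser settings (all recorded with each fit)."""

    dt: float = 0.25  # integration step for model predictions (s)
    tol: float = 1e-2  # stop when an iteration improves F by less (nats)
    max_iter: int = 64
    fd_step: float = 1e-4  # central-difference step on the working scale
    lm_init: float = 0.25  # initial Levenberg-Marquardt damping
    max_trials: int = 8  # damping escalations per iteration
    fixed_precision: float | np.ndarray | None = None
    self_connection: float = DEFAULT_SELF_CONNECTION


def default_priors(
    mask: ArchitectureMask,
    v0_assumption: Sequence[float],
    coupling_var: float = 1.0,
    hemo_var: float = 0.015,
    free_hemo: Sequence[str] = DEFAULT_FREE_HEMO,
    self_connection: float = DEFAULT_SELF_CONNECTION,
) -> Priors:
    """Shrinkage priors for one architecture under a fixed V_0 belief.

    Allowed couplings (and input efficacies) get mean 0 with variance
    ``coupling_var``; disallowed ones are clamped to 0 by omission.  Each
    free hemodynamic parameter is a log scaling factor with mean 0 and the
    tight variance ``hemo_var`` around the default means.  V_0 is clamped to
    ``v0_assumption`` per region and recorded in the fixed map.
    """
    if coupling_var <= 0 or hemo_var <= 0:
        raise ValueError("prior variances must be positive")
    n = mask.n_regions
    if len(v0_assumption) != n:
        raise ValueError(f"expected {n} V_0 values, got {len(v0_assumption)}")
    names: list[str] = []
    variances: list[float] = []
    regions = [f"A{i + 1}" for i in range(n)]
    for i, j in mask.edges():
        names.append(f"A:{regions[j]}->{regions[i]}")
        variances.append(coupling_var)
    for i in range(n):
        for k in range(mask.n_inputs):
            if mask.c_mask[i, k]:
                names.append(f"C:u{k + 1}->{regions[i]}")
                variances.append(coupling_var)
    for r in range(n):
        for h in free_hemo:
            if h not in _HEMO_COL:
                raise KeyError(f"unknown hemodynamic parameter {h!r}")
            names.append(f"log_{h}:{regions[r]}")
            variances.append(hemo_var)
    fixed = {f"V_0:{regions[r]}": float(v0_assumption[r]) for r in range(n)}
    fixed["self_connection"] = float(self_connection)
    return Priors(
        names=tuple(names),
        mean=np.zeros(len(names)),
        cov=np.diag(variances),
        fixed=fixed,
    )


class _DCMPredictor:
    """Maps free-parameter vectors to noise-free BOLD predictions, batched."""

    def __init__(
        self,
        mask: ArchitectureMask,
        priors: Priors,
        design: StimulusDesign,
        opts: InversionOptions,
        base_hemo: HemodynamicParameters | None = None,
    ) -> None:
        self.design = design
        self.dt = opts.dt
        self.n = mask.n_regions
        self.m = mask.n_inputs
        base = base_hemo or HemodynamicParameters()
        regions = [f"A{i + 1}" for i in range(self.n)]
        hemo0 = np.tile(base.as_array(), (self.n, 1))
        for r, name in enumerate(regions):
            hemo0[r, 6] = priors.fixed[f"V_0:{name}"]
        self._hemo0 = hemo0
        self._self = priors.fixed.get("self_connection", opts.self_connection)
        a_rows, a_cols, c_rows, c_cols = [], [], [], []
        hemo_reg, hemo_col = [], []
        self._a_par, self._c_par, self._h_par = [], [], []
        for k, nm in enumerate(priors.names):
            kind, _, rest = nm.partition(":")
            if kind == "A":
                src, dst = rest.split("->")
                a_rows.append(regions.index(dst))
                a_cols.append(regions.index(src))
                self._a_par.append(k)
            elif kind == "C":
                src, dst = rest.split("->")
                c_rows.append(regions.index(dst))
                c_cols.append(int(src[1:]) - 1)
                self._c_par.append(k)
            elif kind.startswith("log_"):
                hemo_reg.append(regions.index(rest))
                hemo_col.append(_HEMO_COL[kind[4:]])
                self._h_par.append(k)
            else:
                raise KeyError(f"unparseable parameter name {nm!r}")
        self._a_idx = (np.array(a_rows, int), np.array(a_cols, int))
        self._c_idx = (np.array(c_rows, int), np.array(c_cols, int))
        self._h_idx = (np.array(hemo_reg, int), np.array(hemo_col, int))

    def __call__(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        P = thetas.shape[0]
        A = np.zeros((P, self.n, self.n))
        A[:, np.arange(self.n), np.arange(self.n)] = self._self
        if self._a_par:
            A[:, self._a_idx[0], self._a_idx[1]] = thetas[:, self._a_par]
        C = np.zeros((P, self.n, self.m))
        if self._c_par:
            C[:, self._c_idx[0], self._c_idx[1]] = thetas[:, self._c_par]
        hemo = np.tile(self._hemo0, (P, 1, 1))
        if self._h_par:
            hemo[:, self._h_idx[0], self._h_idx[1]] *= np.exp(thetas[:, self._h_par])
        return simulate_bold_batch(self.design, A, C, hemo, self.dt)


# ---------------------------------------------------------------------------
# Generic Gaussian nonlinear fitter
# ---------------------------------------------------------------------------


@dataclass
class _Linearization:
    ok: bool
    g: np.ndarray | None = None  # (T, n) prediction at mu
    rss: np.ndarray | None = None  # (n,)
    gram: np.ndarray | None = None  # (n, p, p)  J_r^T J_r
    jtr: np.ndarray | None = None  # (n, p)     J_r^T residual_r


def _linearize(
    predict: Callable[[np.ndarray], np.ndarray],
    mu: np.ndarray,
    y: np.ndarray,
    h: float,
) -> _Linearization:
    p = mu.shape[0]
    stencil = np.vstack([mu, mu + h * np.eye(p), mu - h * np.eye(p)])
    Y = predict(stencil)
    if not np.all(np.isfinite(Y)):
        return _Linearization(ok=False)
    g = Y[0]
    J = (Y[1 : p + 1] - Y[p + 1 :]) / (2.0 * h)  # (p, T, n)
    r = y - g
    n = y.shape[1]
    gram = np.empty((n, p, p))
    jtr = np.empty((n, p))
    rss = np.empty(n)
    for c in range(n):
        Jc = J[:, :, c]  # (p, T)
        gram[c] = Jc @ Jc.T
        jtr[c] = Jc @ r[:, c]
        rss[c] = float(r[:, c] @ r[:, c])
    return _Linearization(ok=True, g=g, rss=rss, gram=gram, jtr=jtr)


def _free_energy(
    lin: _Linearization,
    mu: np.ndarray,
    prec: np.ndarray,
    mu0: np.ndarray,
    pi0: np.ndarray,
    logdet_s0: float,
    n_obs: int,
):
    """Return (F, Sigma_q, H) for a linearisation at mu with noise precisions
    ``prec``; F = -inf when the linearisation failed or H is not SPD."""
    p = mu.shape[0]
    if not lin.ok:
        return -np.inf, None, None
    H = pi0 + np.einsum("r,rij->ij", prec, lin.gram)
    try:
        cf = cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdet_h = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Sq = cho_solve(cf, np.eye(p))
    tr_term = np.einsum("rij,ji->r", lin.gram, Sq)
    e_loglik = float(
        np.sum(
            0.5 * n_obs * (np.log(prec) - math.log(2.0 * math.pi))
            - 0.5 * prec * (lin.rss + tr_term)
        )
    )
    e0 = mu - mu0
    kl = 0.5 * (
        float(np.trace(pi0 @ Sq)) + float(e0 @ pi0 @ e0) - p + logdet_s0 + logdet_h
    )
    return e_loglik - kl, Sq, H


def fit_nonlinear_gaussian(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    priors: Priors,
    opts: InversionOptions | None = None,
) -> Posterior:
    """Gauss-Newton variational Laplace for ``y = predict(theta) + noise``.

    ``predict`` maps a batch of parameter vectors ``(B, p)`` to predictions
    ``(B, T, n)``; ``y`` is the observed ``(T, n)`` matrix with one i.i.d.
    Gaussian noise precision per column, maximised in closed form unless
    ``opts.fixed_precision`` pins it.
    """
    opts = opts or InversionOptions()
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("data contain non-finite values")
    T, n = y.shape
    mu0 = priors.mean
    pi0 = np.linalg.inv(priors.cov)
    sign, logdet_s0 = np.linalg.slogdet(priors.cov)
    if sign <= 0:
        raise ValueError("prior covariance must be positive definite")

    def precisions_for(lin: _Linearization, Sq: np.ndarray | None) -> np.ndarray:
        if opts.fixed_precision is not None:
            return np.broadcast_to(
                np.asarray(opts.fixed_precision, dtype=float), (n,)
            ).copy()
        tr = (
            np.einsum("rij,ji->r", lin.gram, Sq)
            if Sq is not None
            else np.zeros(n)
        )
        return np.clip(T / np.maximum(lin.rss + tr, 1e-300), _PREC_FLOOR, _PREC_CAP)

    mu = mu0.copy()
    lin = _linearize(predict, mu, y, opts.fd_step)
    if not lin.ok:
        raise ValueError("forward model is undefined at the prior mean")
    prec = precisions_for(lin, None)
    F, Sq, H = _free_energy(lin, mu, prec, mu0, pi0, logdet_s0, T)
    # one closed-form precision refinement at the starting point
    if opts.fixed_precision is None and Sq is not None:
        prec_new = precisions_for(lin, Sq)
        F_new, Sq_new, H_new = _free_energy(
            lin, mu, prec_new, mu0, pi0, logdet_s0, T
        )
        if F_new >= F:
            prec, F, Sq, H = prec_new, F_new, Sq_new, H_new
    trace = [F]
    lam = opts.lm_init
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        F_before = F
        grad = np.einsum("r,rp->p", prec, lin.jtr) - pi0 @ (mu - mu0)
        accepted = False
        for _ in range(opts.max_trials):
            H_damped = H + lam * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(H_damped, grad)
            except np.linalg.LinAlgError:
                lam *= 8.0
                continue
            mu_try = mu + step
            lin_try = _linearize(predict, mu_try, y, opts.fd_step)
            F_try, Sq_try, H_try = _free_energy(
                lin_try, mu_try, prec, mu0, pi0, logdet_s0, T
            )
            if F_try > F:
                mu, lin, F, Sq, H = mu_try, lin_try, F_try, Sq_try, H_try
                lam = max(lam / 4.0, 1e-8)
                accepted = True
                break
            lam = min(lam * 8.0, 1e10)
        if accepted:
            trace.append(F)
        # coordinate-ascent noise-precision update
        if opts.fixed_precision is None and Sq is not None:
            prec_new = precisions_for(lin, Sq)
            F_new, Sq_new, H_new = _free_energy(
                lin, mu, prec_new, mu0, pi0, logdet_s0, T
            )
            if F_new > F:
                prec, F, Sq, H = prec_new, F_new, Sq_new, H_new
                trace.append(F)
        if not accepted:
            # no admissible ascent direction left
            converged = True
            break
        if F - F_before < opts.tol:
            converged = True
            break
    return Posterior(
        names=priors.names,
        mean=mu,
        cov=Sq,
        free_energy=F,
        precisions=prec,
        trace=tuple(trace),
        converged=converged,
        n_iter=it,
    )


def variational_laplace(
    data: BOLDTimeSeries,
    design: StimulusDesign,
    mask: ArchitectureMask,
    priors: Priors,
    opts: InversionOptions | None = None,
) -> Posterior:
    """Invert one DCM: returns the Gaussian posterior and its free energy."""
    opts = opts or InversionOptions()
    if data.n_scans != design.n_scans:
        raise ValueError("data length does not match the design scan count")
    predictor = _DCMPredictor(mask, priors, design, opts)
    return fit_nonlinear_gaussian(predictor, data.values, priors, opts)


def log_evidence(posterior: Posterior) -> float:
    """The variational free energy F — the log-evidence bound used for model
    comparison (nats)."""
    return posterior.free_energy
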