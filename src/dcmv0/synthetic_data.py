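"""Synthetic study data: block design, three-region network, calibrated noise.

The generating network has three regions A1, A2, A3.  An exogenous binary
stimulus drives A1 directly; A1 is reciprocally coupled to A2 and to A3, and
every inter-regional coupling (and the input efficacy) equals 1 1/s.  The
stimulus alternates 20-s task and rest blocks, starting with task, over 120
scans at TR = 2 s.  Observation noise is white Gaussian, scaled per region so
that std(clean signal)/std(noise) equals the requested SNR (3 in the study
conditions).  Each region carries its own resting venous blood volume
fraction V_0, which is what the inversion experiments then get right or
wrong on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .forward_model import (
    DEFAULT_SELF_CONNECTION,
    BOLDTimeSeries,
    ConnectivityParameters,
    HemodynamicParameters,
    StimulusDesign,
    integrate_dcm,
)

__all__ = [
    "REGIONS",
    "V0_SETS",
    "SyntheticDatasetSpec",
    "SyntheticDataset",
    "make_block_design",
    "add_noise",
    "generate_study_dataset",
    "true_connectivity",
]

REGIONS = ("A1", "A2", "A3")

#: Candidate beliefs about the per-region resting venous blood volume
#: fraction.  "set1" generates the data by default; the other two are the
#: deliberately misspecified alternatives compared against it.  The triplets
#: span the 0.02-0.06 physiological range and include the canonical
#: 0.04 -> 0.02 misspecification (a doubling of output gain).
V0_SETS: Mapping[str, tuple[float, float, float]] = {
    "set1": (0.02, 0.04, 0.06),
    "set2": (0.04, 0.04, 0.04),
    "set3": (0.06, 0.04, 0.02),
}

#: Sentinel accepted by :func:`add_noise` for the zero-noise limit.
SNR_NOISELESS = np.inf


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Study conditions for one simulated dataset."""

    v0_by_region: tuple[float, float, float] = V0_SETS["set1"]
    snr: float = 3.0
    seed: int = 0
    n_blocks: int = 12
    block_scans: int = 10
    tr: float = 2.0
    start_on: bool = True
    coupling: float = 1.0
    self_connection: float = DEFAULT_SELF_CONNECTION
    dt: float = 0.125

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not all(0 < v < 1 for v in self.v0_by_region):
            raise ValueError("V_0 values must lie in (0, 1)")

    @property
    def n_scans(self) -> int:
        return self.n_blocks * self.block_scans


@dataclass(frozen=True)
class SyntheticDataset:
    clean: BOLDTimeSeries
    noisy: BOLDTimeSeries
    design: StimulusDesign
    connectivity: ConnectivityParameters
    hemodynamics: tuple[HemodynamicParameters, ...]
    spec: SyntheticDatasetSpec

    @property
    def noise(self) -> np.ndarray:
        return self.noisy.values - self.clean.values


def make_block_design(
    n_blocks: int = 12,
    block_scans: int = 10,
    tr: float = 2.0,
    start_on: bool = True,
    dt: float = 0.125,
) -> StimulusDesign:
    """Alternating on/off block stimulus sampled on the fine grid.

    Blocks alternate strictly; with ``start_on`` the first block is the task
    (stimulus = 1) condition.  Defaults give 12 twenty-second blocks over 120
    scans at TR = 2 s.
    """
    if n_blocks < 1 or block_scans < 1:
        raise ValueError("n_blocks and block_scans must be >= 1")
    n_scans = n_blocks * block_scans
    K = int(round(n_scans * tr / dt))
    if abs(K * dt - n_scans * tr) > 1e-9:
        raise ValueError(f"dt={dt} does not tile the design duration")
    t = np.arange(K) * dt
    block_len = block_scans * tr
    on = ((t // block_len).astype(int) % 2) == (0 if start_on else 1)
    return StimulusDesign(tr=tr, n_scans=n_scans, dt=dt, inputs=on.astype(float)[None])


def add_noise(y: BOLDTimeSeries, snr: float, seed: int) -> BOLDTimeSeries:
    """Add per-region white Gaussian noise at a fixed amplitude SNR.

    The noise standard deviation in region ``r`` is ``std(y_r)/snr`` (so SNR
    is the clean-signal-to-noise amplitude ratio).  ``snr = inf`` returns the
    input unchanged.  A constant clean series has no defined SNR and raises.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return y
    sd = y.values.std(axis=0, ddof=0)
    if np.any(sd == 0):
        flat = [y.region_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"SNR undefined: constant clean signal in region(s) {flat}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(y.values.shape) * (sd / snr)
    return BOLDTimeSeries(tr=y.tr, values=y.values + noise, region_names=y.region_names)


def true_connectivity(
    coupling: float = 1.0, self_connection: float = DEFAULT_SELF_CONNECTION
) -> ConnectivityParameters:
    """The generating architecture: input to A1, reciprocal A1<->A2, A1<->A3."""
    c = coupling
    d = self_connection
    A = np.array([[d, c, c], [c, d, 0.0], [c, 0.0, d]])
    C = np.array([[1.0], [0.0], [0.0]])
    return ConnectivityParameters(A=A, C=C, region_names=REGIONS)


def generate_study_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Simulate clean and noisy BOLD under the study conditions in ``spec``."""
    design = make_block_design(
        spec.n_blocks, spec.block_scans, spec.tr, spec.start_on, spec.dt
    )
    conn = true_connectivity(spec.coupling, spec.self_connection)
    hemo = tuple(
        HemodynamicParameters(V_0=v0) for v0 in spec.v0_by_region
    )
    _, clean = integrate_dcm(design, conn, hemo, dt=spec.dt)
    noisy = add_noise(clean, spec.snr, spec.seed)
    return SyntheticDataset(
        clean=clean,
        noisy=noisy,
        design=design,
        connectivity=conn,
        hemodynamics=hemo,
        spec=spec,
    )
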