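"""Fixed-effects Bayesian model selection over architectures and V_0 beliefs.

Free energies approximate log model evidences, so under uniform model priors
the posterior probability of model i is the softmax ``exp(F_i - max F) /
sum_j exp(F_j - max F)``.  Combining the 13 architectures with the three V_0
prior sets yields a 39-entry space in which a belief about V_0 is just
another model attribute; family-wise comparison then sums posterior mass over
all architectures sharing a V_0 set (with uniform-within-family priors so
unequal family sizes do not bias the family posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .inversion import Posterior

__all__ = [
    "ComparisonResult",
    "posterior_model_probs",
    "combined_comparison",
    "family_comparison",
]

ModelId = tuple[int, str]  # (architecture index, prior-set id)


def _as_free_energy(fit) -> float:
    return fit.free_energy if isinstance(fit, Posterior) else float(fit)


def posterior_model_probs(free_energies: Sequence[float]) -> np.ndarray:
    """Softmax of log evidences under uniform model priors.

    Invariant to adding a constant to all free energies.  Raises on
    non-finite entries, naming the offending model.
    """
    F = np.asarray(list(free_energies), dtype=float)
    if F.size < 2:
        raise ValueError("need at least two models to compare")
    bad = np.flatnonzero(~np.isfinite(F))
    if bad.size:
        raise ValueError(f"non-finite free energy for model(s) at position {bad.tolist()}")
    w = np.exp(F - F.max())
    return w / w.sum()


@dataclass(frozen=True)
class ComparisonResult:
    """Ranking of models by free energy with posterior probabilities."""

    ids: tuple[ModelId, ...]
    free_energies: np.ndarray
    probabilities: np.ndarray
    winner: ModelId | None
    tied: bool
    #: per prior set: free energies relative to the worst model of that set
    relative_within_set: dict = field(default_factory=dict)
    family_probabilities: dict = field(default_factory=dict)

    @property
    def winner_architecture(self) -> int | None:
        return self.winner[0] if self.winner is not None else None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "architecture": [i for i, _ in self.ids],
                "prior_set": [s for _, s in self.ids],
                "free_energy": self.free_energies,
                "probability": self.probabilities,
            }
        )


def combined_comparison(
    fits: Mapping[ModelId, object], require_full_grid: bool = True
) -> ComparisonResult:
    """Rank every (architecture, prior set) fit in a single comparison.

    ``fits`` maps ``(architecture_index, prior_set_id)`` to a
    :class:`~dcmv0.inversion.Posterior` (or bare free energy).  With
    ``require_full_grid`` the index set must be a complete product of the
    architectures and prior sets present, and missing combinations are
    reported explicitly.
    """
    if not fits:
        raise ValueError("no fits supplied")
    ids = sorted(fits.keys(), key=lambda k: (k[1], k[0]))
    archs = sorted({i for i, _ in ids})
    sets = sorted({s for _, s in ids})
    if require_full_grid:
        missing = [(i, s) for s in sets for i in archs if (i, s) not in fits]
        if missing:
            raise ValueError(f"missing fits for combinations: {missing}")
    F = np.array([_as_free_energy(fits[k]) for k in ids])
    probs = posterior_model_probs(F)
    fmax = F.max()
    at_max = np.flatnonzero(F == fmax)
    tied = at_max.size > 1
    winner = None if tied else ids[int(at_max[0])]
    rel = {}
    for s in sets:
        sel = [k for k in ids if k[1] == s]
        Fs = np.array([_as_free_energy(fits[k]) for k in sel])
        rel[s] = {k[0]: float(f - Fs.min()) for k, f in zip(sel, Fs)}
    return ComparisonResult(
        ids=tuple(ids),
        free_energies=F,
        probabilities=probs,
        winner=winner,
        tied=tied,
        relative_within_set=rel,
    )


def family_comparison(
    fits: Mapping[ModelId, object],
    partition: Mapping[str, Sequence[ModelId]] | None = None,
) -> dict[str, float]:
    """Posterior probability of each model family.

    By default the families are the V_0 prior sets.  Model priors are uniform
    across families and uniform within each family, so families of unequal
    size are compared on equal footing.  The partition must cover every fit
    exactly once.
    """
    ids = list(fits.keys())
    if partition is None:
        partition = {}
        for i, s in ids:
            partition.setdefault(s, []).append((i, s))
    seen: set[ModelId] = set()
    for fam, members in partition.items():
        dup = seen.intersection(members)
        if dup:
            raise ValueError(f"overlapping families: {sorted(dup)} reappear in {fam!r}")
        seen.update(members)
    uncovered = set(ids) - seen
    if uncovered:
        raise ValueError(f"partition does not cover fits: {sorted(uncovered)}")
    n_fam = len(partition)
    F = {k: _as_free_energy(fits[k]) for k in ids}
    fmax = max(F.values())
    mass = {}
    for fam, members in partition.items():
        if not members:
            raise ValueError(f"family {fam!r} is empty")
        prior = 1.0 / (n_fam * len(members))
        mass[fam] = sum(prior * np.exp(F[k] - fmax) for k in members)
    total = sum(mass.values())
    return {fam: float(m / total) for fam, m in mass.items()}
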