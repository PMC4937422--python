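"""Candidate network architectures compared by Bayesian model selection.

The 13-model space over the three-region network is a canonical
reconstruction: the generating architecture (reciprocal A1<->A2 and A1<->A3,
pinned at index 3) plus feedforward-only, single-branch, pruned-feedback,
lateral-link and fully connected distractors.  Every candidate keeps the
exogenous input on A1 and every self-connection free of the comparison (the
diagonal is always allowed and fixed by convention at inversion time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ArchitectureMask", "enumerate_architectures", "write_manifest"]

_REGIONS3 = ("A1", "A2", "A3")

# Off-diagonal (target, source) pairs, 0-based, for the three-region space.
_EDGE = {
    "A1->A2": (1, 0),
    "A2->A1": (0, 1),
    "A1->A3": (2, 0),
    "A3->A1": (0, 2),
    "A2->A3": (2, 1),
    "A3->A2": (1, 2),
}

# Ordered edge lists defining the canonical 13-model space.  Index 3 is the
# generating architecture.
_STUDY13: tuple[tuple[str, ...], ...] = (
    ("A1->A2", "A1->A3"),                                        # 1 feedforward only
    ("A1->A2", "A2->A1", "A1->A3"),                              # 2 feedback from A2 only
    ("A1->A2", "A2->A1", "A1->A3", "A3->A1"),                    # 3 generating model
    ("A1->A2", "A1->A3", "A3->A1"),                              # 4 feedback from A3 only
    ("A1->A2", "A2->A1"),                                        # 5 A2 branch only
    ("A1->A3", "A3->A1"),                                        # 6 A3 branch only
    ("A1->A2",),                                                 # 7 forward to A2 only
    ("A1->A3",),                                                 # 8 forward to A3 only
    ("A1->A2", "A1->A3", "A3->A1", "A2->A3"),                    # 9 lateral A2->A3, no A2->A1
    ("A1->A2", "A2->A1", "A1->A3", "A3->A1", "A2->A3"),          # 10 generating + lateral
    ("A1->A2", "A2->A1", "A1->A3", "A3->A1", "A3->A2"),          # 11 generating + lateral
    ("A1->A2", "A1->A3", "A2->A3", "A3->A2"),                    # 12 feedforward + both laterals
    ("A1->A2", "A2->A1", "A1->A3", "A3->A1", "A2->A3", "A3->A2"),  # 13 full
)


@dataclass(frozen=True)
class ArchitectureMask:
    """Binary support of the A and C matrices for one candidate model."""

    a_mask: np.ndarray
    c_mask: np.ndarray
    label: str
    index: int

    def __post_init__(self) -> None:
        a = np.asarray(self.a_mask, dtype=bool)
        c = np.asarray(self.c_mask, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("a_mask must be square")
        if not np.all(np.diag(a)):
            raise ValueError("a_mask diagonal must be all ones")
        if c.shape[0] != a.shape[0]:
            raise ValueError("c_mask row count must match a_mask")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "c_mask", c)

    @property
    def n_regions(self) -> int:
        return self.a_mask.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.c_mask.shape[1]

    def edges(self) -> tuple[tuple[int, int], ...]:
        """Allowed off-diagonal (target, source) index pairs, row-major."""
        n = self.n_regions
        return tuple(
            (i, j)
            for i in range(n)
            for j in range(n)
            if i != j and self.a_mask[i, j]
        )


def _mask_from_edges(edges: tuple[str, ...], index: int) -> ArchitectureMask:
    a = np.eye(3, dtype=bool)
    for e in edges:
        i, j = _EDGE[e]
        a[i, j] = True
    c = np.zeros((3, 1), dtype=bool)
    c[0, 0] = True  # input on A1 throughout the space
    return ArchitectureMask(a_mask=a, c_mask=c, label="+".join(edges), index=index)


def enumerate_architectures(space_id: str = "study13") -> list[ArchitectureMask]:
    """Return the ordered, fixed list of candidate masks for a named space."""
    if space_id == "study13":
        return [_mask_from_edges(e, i + 1) for i, e in enumerate(_STUDY13)]
    raise KeyError(f"unknown model space {space_id!r}; registered: 'study13'")


def write_manifest(space_id: str, path: str | Path) -> None:
    """Serialise a model space (masks, labels, 1-based indices) to JSON."""
    masks = enumerate_architectures(space_id)
    payload = {
        "space_id": space_id,
        "regions": list(_REGIONS3),
        "models": [
            {
                "index": m.index,
                "label": m.label,
                "a_mask": m.a_mask.astype(int).tolist(),
                "c_mask": m.c_mask.astype(int).tolist(),
            }
            for m in masks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
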