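"""Report figures: model-comparison bars and sensitivity time courses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .model_comparison import ComparisonResult
from .sensitivity import SensitivityResult

__all__ = ["comparison_bars", "sensitivity_figure"]


def comparison_bars(result: ComparisonResult, path: str | Path) -> None:
    """Relative log evidence and posterior probability over all entries."""
    labels = [f"{i}/{s}" for i, s in result.ids]
    rel = result.free_energies - result.free_energies.min()
    fig, axes = plt.subplots(2, 1, figsize=(max(6, 0.3 * len(labels)), 6), sharex=True)
    x = np.arange(len(labels))
    axes[0].bar(x, rel, color="steelblue")
    axes[0].set_ylabel("log evidence rel. worst (nats)")
    axes[1].bar(x, result.probabilities, color="indianred")
    axes[1].set_ylabel("posterior probability")
    axes[1].set_xticks(x)
    axes[1].set_xticklabels(labels, rotation=90, fontsize=7)
    axes[1].set_xlabel("architecture / V0 prior set")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sensitivity_figure(result: SensitivityResult, path: str | Path) -> None:
    """Variance time course (top) and total-effect indices (bottom)."""
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    axes[0].plot(result.times, result.variance, color="black")
    axes[0].set_ylabel("total output variance")
    stim = result.meta.get("stim_duration", 2.0)
    for ax in axes:
        ax.axvspan(0, stim, color="red", alpha=0.15, lw=0)
    for name, row in zip(result.names, result.indices):
        axes[1].plot(result.times, row, label=name)
    axes[1].set_ylabel("total-effect index $S_T$")
    axes[1].set_xlabel("peristimulus time (s)")
    axes[1].legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
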