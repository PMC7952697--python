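"""Basic plot exports (presentation only).

Box plots of shell height by partner category and kernel-density
overlays of mating vs non-mating size distributions.  These are thin
matplotlib wrappers; the statistics live in :mod:`neritrema.size_stats`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .records import CopulationRecord, IndividualRecord
from .taxonomy import MALE


def boxplot_heights(records: Sequence[CopulationRecord], path: str | Path) -> None:
    """Box plot of copulating snails' shell heights by category (male-male
    pairs excluded on the passive side)."""
    groups: dict[str, list[float]] = {}
    for rec in records:
        if rec.active_height_mm is not None:
            groups.setdefault(rec.active.label, []).append(rec.active_height_mm)
        if rec.passive_height_mm is not None and rec.passive.status != MALE:
            groups.setdefault(rec.passive.label, []).append(rec.passive_height_mm)
    if not groups:
        raise ValueError("no height data to plot")
    labels = sorted(groups)
    fig, ax = plt.subplots(figsize=(max(6, len(labels)), 4))
    ax.boxplot([groups[k] for k in labels], tick_labels=labels)
    ax.set_ylabel("shell height (mm)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def kde_overlay(
    mating_heights: Sequence[float],
    census: Sequence[IndividualRecord],
    path: str | Path,
    label: str = "copulating",
) -> None:
    """Kernel-density overlay of mating vs censused shell heights."""
    mating = np.asarray(mating_heights, dtype=float)
    pop = np.array([r.shell_height_mm for r in census])
    if len(mating) < 2 or len(pop) < 2:
        raise ValueError("need >= 2 heights in each group")
    grid = np.linspace(
        min(mating.min(), pop.min()) - 1, max(mating.max(), pop.max()) + 1, 200
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, stats.gaussian_kde(mating)(grid), label=label)
    ax.plot(grid, stats.gaussian_kde(pop)(grid), label="census")
    ax.set_xlabel("shell height (mm)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
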