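"""Figure-style renderings: banded coverage maps, decile heat maps, simulator
grids, and per-position substitution-effect bars."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mapping import CoverageProfile
from .mutscan import SubstitutionEffectMatrix
from .popsim import SimResult

__all__ = ["coverage_bands", "crosstab_heatmap", "sim_grid_heatmap",
           "mutscan_bars"]

#: coverage fraction band edges used for the banded color map
_BANDS = (0.2, 0.4, 0.6, 0.8, 1.0)


def coverage_bands(profiles: Mapping[str, CoverageProfile], path: str | Path,
                   title: str = "") -> None:
    """Stacked per-bin coverage tracks, color-banded at 0.2/0.4/0.6/0.8/1.0."""
    cmap = plt.get_cmap("YlOrRd", len(_BANDS))
    fig, axes = plt.subplots(len(profiles), 1, sharex=True,
                             figsize=(8, 1.2 * len(profiles) + 1), squeeze=False)
    for ax, (label, prof) in zip(axes[:, 0], profiles.items()):
        pos = np.arange(prof.range.start, prof.range.end + 1)
        band = np.digitize(prof.fractions, _BANDS, right=True)
        ax.imshow(band[None, :], aspect="auto", cmap=cmap, vmin=0,
                  vmax=len(_BANDS) - 1,
                  extent=(pos[0], pos[-1], 0, 1))
        ax.set_yticks([])
        ax.set_ylabel(label, rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("position relative to ORC site (bp)")
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def crosstab_heatmap(grid: np.ndarray, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(grid.T, origin="lower", cmap="viridis")
    ax.set_xlabel("Acen competitive-fitness decile")
    ax.set_ylabel("Cen competitive-fitness decile")
    ax.set_xticks(range(10), range(1, 11))
    ax.set_yticks(range(10), range(1, 11))
    fig.colorbar(im, ax=ax, label="fragments")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def sim_grid_heatmap(result: SimResult, path: str | Path, title: str = "") -> None:
    rfs = sorted({rf for rf, _ in result.totals})
    pfs = sorted({pf for _, pf in result.totals})
    grid = np.array([[result.totals[(rf, pf)] for rf in rfs] for pf in pfs])
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(np.log10(grid + 1), origin="lower", cmap="magma",
                   extent=(min(rfs), max(rfs), min(pfs), max(pfs)), aspect="auto")
    ax.set_xlabel("replication fitness")
    ax.set_ylabel("partitioning fitness")
    fig.colorbar(im, ax=ax, label="log10 final copies")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def mutscan_bars(matrix: SubstitutionEffectMatrix, path: str | Path,
                 title: str = "") -> None:
    """Per-position minimum substitution fitness relative to wild type."""
    vals = matrix.values.copy()
    for i, pos in enumerate(vals.index):
        vals.loc[pos, matrix.reference[i]] = np.nan  # drop wild-type cells
    worst = vals.min(axis=1)
    rel = worst / matrix.wildtype_fitness
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.bar(vals.index, rel, width=1.0, color="steelblue")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("position relative to ORC site (bp)")
    ax.set_ylabel("worst substitution / wild type")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
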