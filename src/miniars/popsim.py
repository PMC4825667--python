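"""Stochastic plasmid copy-number dynamics in dividing budding-yeast lineages.

The model tracks, for a single plasmid species, the copy number in every cell
of a lineage founded by one transformed cell. Each generation every live cell:

1. replicates — each plasmid copy duplicates independently with probability
   ``q = rf_eff * crowding_factor(n, c)`` where ``rf_eff`` is the cell's
   effective replication fitness and ``n`` its copy number before S-phase;
2. divides — each copy moves to the newborn daughter independently with
   probability ``pf_eff / 2``; ``pf_eff = 1`` gives the unbiased binomial
   split, ``pf_eff = 0`` total retention by the mother.

Cells whose copy number drops to zero are removed immediately, emulating
growth under selection for a plasmid-borne marker. Crowding attenuates
replication as copies accumulate in a cell: with crowding penalty ``c = 1`` a
cell holding 100 copies replicates each of them at half its intrinsic
probability. Effective per-cell replication and partitioning fitness are the
lineage parameters plus a Gaussian perturbation drawn once at cell birth and
clipped to [0, 1].

The total plasmid copy number summed over the lineage at the final generation
is the model's proxy for a fragment's competitive fitness in the pooled
growth experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SimParams",
    "LineageResult",
    "SimResult",
    "crowding_factor",
    "replicate_cell",
    "divide_cell",
    "simulate_lineage",
    "run_simulation",
]

#: cells per lineage above which the lineage is subsampled (seed-stable).
POPULATION_CAP = 100_000

ReplicationMode = Literal["per_copy", "all_or_nothing"]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run (one plasmid species)."""

    rf: float  # replication fitness in [0, 1]
    pf: float  # partitioning fitness in [0, 1]
    c: float = 0.0  # crowding penalty, >= 0
    noise_sd: float = 0.0  # s.d. of per-cell Gaussian noise on rf and pf
    generations: int = 12
    init_copies: int = 4
    n_lineages: int = 1
    replication_mode: ReplicationMode = "per_copy"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rf <= 1.0):
            raise ValueError(f"rf {self.rf} outside [0, 1]")
        if not (0.0 <= self.pf <= 1.0):
            raise ValueError(f"pf {self.pf} outside [0, 1]")
        if self.c < 0:
            raise ValueError("crowding penalty must be >= 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.init_copies < 1 or self.n_lineages < 1:
            raise ValueError("init_copies and n_lineages must be >= 1")


@dataclass
class LineageResult:
    """Outcome of one lineage: per-generation total copies (index 0 = start)."""

    copies_per_generation: np.ndarray  # float, length generations + 1
    final_cells: int
    subsampled: bool = False

    @property
    def final_copies(self) -> float:
        return float(self.copies_per_generation[-1])


@dataclass
class SimResult:
    """Per-(rf, pf) grid cell totals from :func:`run_simulation`."""

    params: dict  # shared parameters of the run
    totals: dict  # (rf, pf) -> mean final total copies over lineages
    per_generation: dict = field(default_factory=dict)  # (rf, pf) -> ndarray


def crowding_factor(n: float, c: float) -> float:
    """Replication attenuation in a cell holding ``n`` plasmid copies.

    ``f(n, c) = 1 / (1 + c * n / 100)``: at penalty 1 a cell that has
    acquired 100 copies replicates each at 50% of its intrinsic fitness;
    penalty 0 leaves replication unattenuated at any copy number.
    """
    if n < 0 or c < 0:
        raise ValueError("n and c must be nonnegative")
    return 1.0 / (1.0 + c * n / 100.0)


def replicate_cell(
    n: int,
    rf_eff: float,
    c: float,
    rng: np.random.Generator,
    mode: ReplicationMode = "per_copy",
) -> int:
    """Copy number after one S-phase in a cell starting with ``n`` copies."""
    if n < 0:
        raise ValueError("copy number must be nonnegative")
    if n == 0:
        return 0
    q = rf_eff * crowding_factor(n, c)
    if mode == "per_copy":
        return n + int(rng.binomial(n, q))
    if mode == "all_or_nothing":
        return 2 * n if rng.random() < q else n
    raise ValueError(f"unknown replication mode {mode!r}")


def divide_cell(n: int, pf: float, rng: np.random.Generator) -> tuple[int, int]:
    """Split ``n`` copies between mother and daughter at cytokinesis.

    Each copy goes to the daughter with probability ``pf / 2``; copies are
    conserved exactly.
    """
    if n < 0:
        raise ValueError("copy number must be nonnegative")
    daughter = int(rng.binomial(n, pf / 2.0)) if n else 0
    return n - daughter, daughter


def _effective(params: float, noise_sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0.0:
        return np.full(size, params)
    return np.clip(params + rng.normal(0.0, noise_sd, size), 0.0, 1.0)


def simulate_lineage(params: SimParams, rng: np.random.Generator) -> LineageResult:
    """Run one lineage for ``params.generations`` generations.

    Cells are held in flat arrays (copy number, effective rf, effective pf);
    the whole generation update is vectorized binomial draws. If the lineage
    exceeds :data:`POPULATION_CAP` cells it is subsampled uniformly to the cap
    and the reported totals are rescaled by the survival fraction, so totals
    remain comparable across parameter settings.
    """
    copies = np.array([params.init_copies], dtype=np.int64)
    rf_eff = _effective(params.rf, params.noise_sd, 1, rng)
    pf_eff = _effective(params.pf, params.noise_sd, 1, rng)
    scale = 1.0
    subsampled = False
    totals = np.empty(params.generations + 1)
    totals[0] = copies.sum() * scale

    for gen in range(1, params.generations + 1):
        n = copies
        q = rf_eff / (1.0 + params.c * n / 100.0)
        if params.replication_mode == "per_copy":
            n = n + rng.binomial(n, q)
        else:
            n = np.where(rng.random(n.size) < q, 2 * n, n)
        daughters = rng.binomial(n, pf_eff / 2.0)
        mothers = n - daughters
        d_rf = _effective(params.rf, params.noise_sd, daughters.size, rng)
        d_pf = _effective(params.pf, params.noise_sd, daughters.size, rng)
        copies = np.concatenate([mothers, daughters])
        rf_eff = np.concatenate([rf_eff, d_rf])
        pf_eff = np.concatenate([pf_eff, d_pf])
        alive = copies > 0  # plasmid selection removes empty cells
        copies, rf_eff, pf_eff = copies[alive], rf_eff[alive], pf_eff[alive]
        if copies.size > POPULATION_CAP:
            keep = rng.choice(copies.size, POPULATION_CAP, replace=False)
            keep.sort()
            scale *= copies.size / POPULATION_CAP
            copies, rf_eff, pf_eff = copies[keep], rf_eff[keep], pf_eff[keep]
            subsampled = True
        totals[gen] = copies.sum() * scale
        if copies.size == 0:
            totals[gen:] = 0.0
            break

    return LineageResult(totals, final_cells=int(copies.size), subsampled=subsampled)


def run_simulation(
    grid: Sequence[tuple[float, float]],
    c: float = 0.0,
    generations: int = 12,
    noise_sd: float = 0.0,
    init_copies: int = 4,
    n_lineages: int = 1,
    seed: int | None = None,
    replication_mode: ReplicationMode = "per_copy",
) -> SimResult:
    """Simulate every (rf, pf) pair on a grid and record final copy totals.

    Each grid cell is an independent lineage set founded from
    ``init_copies`` plasmids; ``totals[(rf, pf)]`` is the mean over
    ``n_lineages`` of the lineage-summed copy number at the final generation.
    Deterministic under a fixed seed.
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid))
    totals: dict = {}
    per_gen: dict = {}
    for (rf, pf), child in zip(grid, children):
        rng = np.random.default_rng(child)
        params = SimParams(
            rf=rf, pf=pf, c=c, noise_sd=noise_sd, generations=generations,
            init_copies=init_copies, n_lineages=n_lineages,
            replication_mode=replication_mode,
        )
        runs = [simulate_lineage(params, rng) for _ in range(n_lineages)]
        totals[(rf, pf)] = float(np.mean([r.final_copies for r in runs]))
        per_gen[(rf, pf)] = np.mean([r.copies_per_generation for r in runs], axis=0)
    shared = dict(c=c, generations=generations, noise_sd=noise_sd,
                  init_copies=init_copies, n_lineages=n_lineages, seed=seed)
    return SimResult(params=shared, totals=totals, per_generation=per_gen)
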