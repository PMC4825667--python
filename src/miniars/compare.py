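"""Acen/Cen comparative classification of fragments.

Fragments shared between the centromere-less (Acen) and centromere-containing
(Cen) competitions are ranked into competitive-fitness deciles within each
experiment and cross-tabulated on a 10 x 10 grid. Corner cells of the grid
separate partitioning from replication ability:

* high Acen decile, low Cen decile (bottom-right corner) — strong
  partitioning, weak replication (P+R-): the fragment competes well only when
  partitioning matters;
* low Acen, high Cen (top-left) — weak partitioning, strong replication
  (P-R+);
* low in both (bottom-left) — weak in both (P-R-); high in both — P+R+.

An ARS is called a partitioning ARS when at least one of its fragments lands
in the P+R- corner. Partitioning (or replication) regions are then mapped by
differential nucleotide coverage between corner groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import AnchoredInterval
from .mapping import bin_fragments, coverage_profile

__all__ = [
    "Category",
    "FragmentClassification",
    "DecileCrosstab",
    "DifferentialRegion",
    "decile_rank",
    "crosstab",
    "classify",
    "near_diagonal_fraction",
    "is_partitioning_ars",
    "differential_coverage",
]


class Category(str, Enum):
    P_MINUS_R_MINUS = "PminusRminus"
    P_PLUS_R_MINUS = "PplusRminus"
    P_MINUS_R_PLUS = "PminusRplus"
    P_PLUS_R_PLUS = "PplusRplus"
    UNCALLED = "uncalled"


@dataclass(frozen=True)
class FragmentClassification:
    fragment_id: str
    acen_decile: int  # 1..10, 1 = least competitive
    cen_decile: int
    category: Category
    near_diagonal: bool


@dataclass(frozen=True)
class DecileCrosstab:
    """10 x 10 grid of fragment counts; rows = Acen decile, cols = Cen decile."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != (10, 10):
            raise ValueError("crosstab must be 10 x 10")
        if (self.grid < 0).any():
            raise ValueError("crosstab counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.grid.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(1, 11), name="acen_decile")
        cols = pd.Index(range(1, 11), name="cen_decile")
        return pd.DataFrame(self.grid, index=idx, columns=cols)


@dataclass(frozen=True)
class DifferentialRegion:
    interval: AnchoredInterval
    mean_delta: float  # mean coverage difference over the interval, in [-1, 1]
    kind: str  # "partitioning" or "replication"

    def __post_init__(self) -> None:
        if abs(self.mean_delta) > 1.0 + 1e-12:
            raise ValueError("mean coverage difference must lie in [-1, 1]")


def decile_rank(cf: Mapping[str, float]) -> dict[str, int]:
    """Quantile decile (1..10, 1 = least competitive) per fragment; ties are
    broken by fragment id for determinism."""
    if len(cf) < 10:
        raise ValueError(f"need at least 10 fragments, got {len(cf)}")
    bins = bin_fragments(cf, k=10)
    return {fid: b + 1 for fid, b in bins.assignments.items()}


def crosstab(acen: Mapping[str, int], cen: Mapping[str, int]) -> DecileCrosstab:
    """Cross-tabulate shared fragments by (Acen decile, Cen decile)."""
    if set(acen) != set(cen):
        diff = sorted(set(acen) ^ set(cen))
        raise ValueError(f"fragment id sets differ; symmetric difference: {diff}")
    grid = np.zeros((10, 10), dtype=np.int64)
    for fid, a in acen.items():
        grid[a - 1, cen[fid] - 1] += 1
    return DecileCrosstab(grid)


def _categorize(acen: int, cen: int, corner_size: int) -> Category:
    hi = 11 - corner_size
    a_hi, a_lo = acen >= hi, acen <= corner_size
    c_hi, c_lo = cen >= hi, cen <= corner_size
    if a_hi and c_lo:
        return Category.P_PLUS_R_MINUS
    if a_lo and c_hi:
        return Category.P_MINUS_R_PLUS
    if a_lo and c_lo:
        return Category.P_MINUS_R_MINUS
    if a_hi and c_hi:
        return Category.P_PLUS_R_PLUS
    return Category.UNCALLED


def classify(
    acen: Mapping[str, int],
    cen: Mapping[str, int],
    corner_size: int = 3,
    diag_band: int = 1,
) -> list[FragmentClassification]:
    """Assign each shared fragment its quadrant category.

    ``corner_size`` is the corner extent in deciles per axis (default 3: a
    corner spans deciles 1-3 or 8-10); ``diag_band`` is the |Acen - Cen|
    decile distance counted as near-diagonal.
    """
    if not (1 <= corner_size <= 5):
        raise ValueError("corner_size must lie in 1..5")
    if set(acen) != set(cen):
        raise ValueError("fragment id sets differ")
    out = []
    for fid in sorted(acen):
        a, c = acen[fid], cen[fid]
        if not (1 <= a <= 10 and 1 <= c <= 10):
            raise ValueError(f"fragment {fid}: deciles must lie in 1..10")
        out.append(FragmentClassification(
            fid, a, c, _categorize(a, c, corner_size), abs(a - c) <= diag_band))
    return out


def near_diagonal_fraction(classifications: Sequence[FragmentClassification]) -> float:
    if not classifications:
        raise ValueError("no classifications")
    return sum(c.near_diagonal for c in classifications) / len(classifications)


def is_partitioning_ars(classifications: Iterable[FragmentClassification]) -> bool:
    """True iff at least one fragment of the ARS sits in the P+R- corner."""
    cls = list(classifications)
    if not cls:
        raise ValueError("no fragments for this ARS")
    return any(c.category is Category.P_PLUS_R_MINUS for c in cls)


def differential_coverage(
    group_a: Sequence[AnchoredInterval],
    group_b: Sequence[AnchoredInterval],
    range_: AnchoredInterval,
    delta_threshold: float = 0.4,
    min_len: int = 8,
    kind: str = "partitioning",
) -> list[DifferentialRegion]:
    """Regions where group B's coverage exceeds group A's.

    Computes the per-position difference ``delta(p) = covB(p) - covA(p)`` and
    reports every maximal contiguous run with ``delta >= delta_threshold`` and
    length >= ``min_len``. With B = P+R- and A = P-R- fragments the runs are
    candidate partitioning regions; with B = P-R+ they are replication
    regions.
    """
    if not group_a or not group_b:
        raise ValueError("both fragment groups must be nonempty")
    cov_a = coverage_profile(group_a, range_).fractions
    cov_b = coverage_profile(group_b, range_).fractions
    delta = cov_b - cov_a
    passing = delta >= delta_threshold
    regions = []
    i, n = 0, passing.size
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        if j - i + 1 >= min_len:
            iv = AnchoredInterval(range_.start + i, range_.start + j)
            regions.append(DifferentialRegion(iv, float(delta[i : j + 1].mean()), kind))
        i = j + 1
    return regions
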