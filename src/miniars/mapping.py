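"""Fragment-to-nucleotide mapping: fitness bins, coverage profiles, and
minimal maximal-fitness regions.

Fragments of one locus are ranked by competitive fitness and split into k
near-equal quantile bins (terciles for mapping, deciles for comparative
classification). For each bin, the coverage profile gives, per anchored
position, the fraction of the bin's fragments whose interval contains that
position. The minimal fragment needed for maximal fitness is read off the top
bin's profile as the longest contiguous run of positions covered by at least
80% of its fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import AnchoredInterval

__all__ = [
    "RankedBins",
    "CoverageProfile",
    "bin_fragments",
    "coverage_profile",
    "minimal_region",
    "TERCILE_LABELS",
]

TERCILE_LABELS = ("+", "++", "+++")


@dataclass(frozen=True)
class RankedBins:
    """Quantile bins of fragments by competitive fitness, ascending."""

    k: int
    assignments: Mapping[str, int]  # fragment_id -> bin index 0..k-1 (0 lowest)
    bin_means: tuple[float, ...]  # mean CF per bin, ascending

    def members(self, bin_index: int) -> list[str]:
        return sorted(i for i, b in self.assignments.items() if b == bin_index)

    def label(self, bin_index: int) -> str:
        if self.k == 3:
            return TERCILE_LABELS[bin_index]
        return str(bin_index + 1)


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position fraction of a fragment set containing each nucleotide."""

    bin_id: str
    range: AnchoredInterval
    fractions: np.ndarray  # float in [0, 1], length = range.length

    def at(self, pos: int) -> float:
        if pos not in self.range:
            raise IndexError(f"position {pos} outside profile range {self.range}")
        return float(self.fractions[pos - self.range.start])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(self.range.start, self.range.end + 1),
            "fraction": self.fractions,
        })


def bin_fragments(cf: Mapping[str, float], k: int = 3) -> RankedBins:
    """Split fragments into ``k`` quantile bins of near-equal size by CF.

    Fragments are sorted by (CF, id) — the id breaks ties deterministically —
    and chunked so bin sizes differ by at most one, with any larger bins at
    the low-CF end. Bin 0 has the lowest mean CF.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cf) < k:
        raise ValueError(f"need at least {k} fragments, got {len(cf)}")
    order = sorted(cf, key=lambda i: (cf[i], i))
    chunks = np.array_split(np.array(order, dtype=object), k)
    assignments = {str(fid): b for b, chunk in enumerate(chunks) for fid in chunk}
    means = tuple(float(np.mean([cf[f] for f in chunk])) for chunk in chunks)
    return RankedBins(k, assignments, means)


def coverage_profile(
    intervals: Sequence[AnchoredInterval],
    range_: AnchoredInterval,
    bin_id: str = "",
) -> CoverageProfile:
    """Fraction of fragments containing each position of ``range_``."""
    if not intervals:
        raise ValueError("empty fragment bin")
    counts = np.zeros(range_.length, dtype=np.int64)
    for iv in intervals:
        lo = max(iv.start, range_.start) - range_.start
        hi = min(iv.end, range_.end) - range_.start
        if hi >= lo:
            counts[lo : hi + 1] += 1
    return CoverageProfile(bin_id, range_, counts / len(intervals))


def minimal_region(
    profile: CoverageProfile, threshold: float = 0.80
) -> AnchoredInterval | None:
    """Longest contiguous run of positions covered by >= ``threshold`` of the
    bin's fragments; ties go to the run with greater mean coverage. Returns
    None when no position reaches the threshold."""
    passing = profile.fractions >= threshold
    best: AnchoredInterval | None = None
    best_len, best_mean = 0, -1.0
    i, n = 0, passing.size
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        run_len = j - i + 1
        run_mean = float(profile.fractions[i : j + 1].mean())
        if run_len > best_len or (run_len == best_len and run_mean > best_mean):
            best = AnchoredInterval(profile.range.start + i, profile.range.start + j)
            best_len, best_mean = run_len, run_mean
        i = j + 1
    return best
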