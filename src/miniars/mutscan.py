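"""Deep-mutational-scanning analysis: per-position, per-substitution fitness
effect matrices.

Each oligo in a mutagenized pool carries zero or more substitutions relative
to the full-fragment reference. The substitution-effect matrix assigns to each
(position, base) cell the mean endpoint fitness over *all* oligos carrying
that substitution; multi-mutant oligos contribute to every cell they carry (a
single-mutant-only mode restricts attribution to oligos with exactly one
substitution). Reference-base cells carry the wild-type fitness, the mean over
oligos with no substitutions. Cells with no carriers are flagged absent (NaN
with support 0), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import AnchoredInterval
from .synthetic import MutantOligo

__all__ = ["SubstitutionEffectMatrix", "substitution_matrix", "site_profile"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SubstitutionEffectMatrix:
    reference: str
    span: AnchoredInterval  # anchored coordinates of the reference
    values: pd.DataFrame  # index = anchored position, columns = A/C/G/T, NaN = absent
    support: pd.DataFrame  # carrier counts, same shape
    wildtype_fitness: float
    wildtype_support: int

    def __post_init__(self) -> None:
        if len(self.reference) != self.span.length:
            raise ValueError("reference length does not match span")
        if self.values.shape != (self.span.length, 4):
            raise ValueError("matrix width must equal reference length")

    def cell(self, pos: int, base: str) -> tuple[float, int]:
        return float(self.values.at[pos, base]), int(self.support.at[pos, base])


def substitution_matrix(
    oligos: Sequence[MutantOligo],
    fitness: Mapping[str, float],
    reference: str,
    span: AnchoredInterval,
    single_mutant_only: bool = False,
) -> SubstitutionEffectMatrix:
    """Aggregate per-oligo endpoint fitness into a position x base grid.

    ``fitness`` maps oligo id to endpoint fitness ratio. Every oligo must have
    a fitness value and a sequence of the reference length; substitutions are
    validated against the reference.
    """
    if len(reference) != span.length:
        raise ValueError("reference length does not match span")
    positions = np.arange(span.start, span.end + 1)
    sums = pd.DataFrame(0.0, index=positions, columns=list(_BASES))
    supp = pd.DataFrame(0, index=positions, columns=list(_BASES))
    wt_sum, wt_n = 0.0, 0
    for o in oligos:
        if len(o.sequence) != len(reference):
            raise ValueError(f"oligo {o.id}: length {len(o.sequence)} != "
                             f"reference length {len(reference)}")
        fit = fitness[o.id]
        if np.isnan(fit):
            continue  # undefined endpoint ratio (zero start frequency)
        if not o.substitutions:
            wt_sum += fit
            wt_n += 1
            continue
        if single_mutant_only and len(o.substitutions) > 1:
            continue
        for pos, ref, alt in o.substitutions:
            idx = pos - span.start
            if reference[idx] != ref:
                raise ValueError(f"oligo {o.id}: substitution at {pos} claims "
                                 f"ref {ref} but reference has {reference[idx]}")
            sums.at[pos, alt] += fit
            supp.at[pos, alt] += 1
    with np.errstate(invalid="ignore"):
        values = sums / supp.replace(0, np.nan)
    wt_fit = wt_sum / wt_n if wt_n else float("nan")
    # reference-base cells carry the wild-type fitness
    for i, pos in enumerate(positions):
        values.at[pos, reference[i]] = wt_fit
        supp.at[pos, reference[i]] = wt_n
    return SubstitutionEffectMatrix(reference, span, values, supp, wt_fit, wt_n)


def site_profile(
    matrix: SubstitutionEffectMatrix, site: AnchoredInterval
) -> SubstitutionEffectMatrix:
    """Column-slice the matrix to ``site``, preserving anchored coordinates."""
    if not matrix.span.contains_interval(site):
        raise ValueError(f"site {site} outside matrix span {matrix.span}")
    lo = site.start - matrix.span.start
    return SubstitutionEffectMatrix(
        matrix.reference[lo : lo + site.length],
        site,
        matrix.values.loc[site.start : site.end],
        matrix.support.loc[site.start : site.end],
        matrix.wildtype_fitness,
        matrix.wildtype_support,
    )
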