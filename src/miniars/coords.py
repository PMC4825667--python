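"""ORC-anchored signed coordinates.

Throughout the package, positions along an ARS locus are expressed relative to
the origin recognition complex (ORC) binding site: position 0 is the first
nucleotide of the T-rich strand of the ORC site, negative positions lie 5' of
it along the T-rich strand, positive positions 3'. Intervals are CLOSED on both
ends and position 0 is counted, so the interval -56..+96 spans 153 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = ["AnchoredInterval", "anchor"]


@dataclass(frozen=True, order=True)
class AnchoredInterval:
    """A closed interval [start, end] in ORC-anchored coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "AnchoredInterval") -> bool:
        """True iff *other* lies fully inside this interval (closed ends)."""
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "AnchoredInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersection(self, other: "AnchoredInterval") -> "AnchoredInterval | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return AnchoredInterval(lo, hi) if lo <= hi else None

    def positions(self) -> Iterator[int]:
        return iter(range(self.start, self.end + 1))

    def shift(self, offset: int) -> "AnchoredInterval":
        return AnchoredInterval(self.start + offset, self.end + offset)


def anchor(
    frag_start: int,
    frag_end: int,
    orc_start: int,
    *,
    locus_length: int,
    t_rich_on_top: bool = True,
) -> AnchoredInterval:
    """Translate a locus-relative fragment interval into anchored coordinates.

    Parameters
    ----------
    frag_start, frag_end
        Closed, 0-based locus-relative interval of the fragment.
    orc_start
        Locus-relative position of the first nucleotide of the T-rich strand
        of the ORC site *as read on the T-rich strand*. When the T-rich strand
        is the top strand this is the leftmost base of the site; when it is
        the bottom strand it is the rightmost base of the site's footprint on
        the top strand.
    locus_length
        Length of the locus; required to validate ``orc_start`` and to reflect
        bottom-strand loci.
    t_rich_on_top
        Whether the T-rich strand of the ORC site is the top (given) strand.

    Returns
    -------
    AnchoredInterval
        Interval with ``orc_start`` mapped to 0 and the positive direction
        running 5'->3' along the T-rich strand.
    """
    if not (0 <= orc_start < locus_length):
        raise ValueError(f"orc_start {orc_start} outside locus of length {locus_length}")
    if frag_start > frag_end:
        raise ValueError("fragment start > end")
    if t_rich_on_top:
        return AnchoredInterval(frag_start - orc_start, frag_end - orc_start)
    # Bottom strand: reflect so that downstream of the T-rich 5'->3' direction
    # is positive. A top-strand position p maps to orc_start - p.
    return AnchoredInterval(orc_start - frag_end, orc_start - frag_start)
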