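"""Synthetic miniARS loci, fragment libraries, mutagenized oligo pools, and
sequencing-count time courses.

The generator emulates the structure of a pooled plasmid competition: an ARS
locus is a random background sequence with functional elements (an ORC binding
site, optionally a RAP1-like partitioning element 5' of it and an FKH-like
element 3' of it) embedded at fixed ORC-anchored intervals. Fragments are
uniform random subsequences in a configurable 100-200 bp size range, as
produced by DNaseI digestion and gel size selection. Each fragment's ground
truth replication fitness (RF) and partitioning fitness (PF) is additive over
the elements it contains *in full* — an element truncated by a single base
contributes nothing.

Count tables over a time course are drawn multinomially at a fixed sequencing
depth from fragment abundances that follow either an exact log-linear
expectation (for validating the slope estimator) or the mechanistic
plasmid-population simulator in :mod:`miniars.popsim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import AnchoredInterval
from .popsim import SimParams, simulate_lineage

__all__ = [
    "Element",
    "LocusSpec",
    "Locus",
    "Fragment",
    "FitnessTruth",
    "MutantOligo",
    "CountMatrix",
    "ACEN_TIMEPOINTS",
    "CEN_TIMEPOINTS",
    "HOURS_PER_GENERATION",
    "build_locus",
    "fragment_library",
    "true_fitness",
    "mutagenize_library",
    "simulate_counts",
]

BASES = np.array(["A", "C", "G", "T"])

#: sampling times (hours) of the centromere-less (Acen) competition
ACEN_TIMEPOINTS = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 25.0)
#: the centromere-containing (Cen) competition is sampled at start and 30 hr
CEN_TIMEPOINTS = (0.0, 30.0)
#: budding-yeast doubling time assumed when converting hours to generations
HOURS_PER_GENERATION = 2.0


@dataclass(frozen=True)
class Element:
    """A functional element embedded in a locus at a fixed anchored interval."""

    label: str
    interval: AnchoredInterval
    consensus: str
    rf_effect: float = 0.0
    pf_effect: float = 0.0

    def __post_init__(self) -> None:
        if len(self.consensus) != self.interval.length:
            raise ValueError(
                f"element {self.label}: consensus length {len(self.consensus)} "
                f"!= interval length {self.interval.length}"
            )
        if not (0.0 <= self.rf_effect <= 1.0 and 0.0 <= self.pf_effect <= 1.0):
            raise ValueError(f"element {self.label}: effects must lie in [0, 1]")


@dataclass(frozen=True)
class LocusSpec:
    """Declarative description of a synthetic ARS locus.

    ``upstream`` bases precede anchored position 0, so the locus spans
    ``[-upstream, length - upstream - 1]``. The ORC site (T-rich strand)
    always begins at position 0 and is carried as an implicit element with
    its own RF/PF contributions.
    """

    name: str
    length: int
    upstream: int
    orc_site: str = "TTTTATGTTTAGTTTTA"  # 17 nt, T-rich strand
    orc_rf_effect: float = 0.0
    orc_pf_effect: float = 0.0
    elements: tuple[Element, ...] = ()
    rf_base: float = 0.0
    pf_base: float = 0.0

    def __post_init__(self) -> None:
        if self.length < len(self.orc_site):
            raise ValueError("locus shorter than its ORC site")
        if not (0 <= self.upstream <= self.length - len(self.orc_site)):
            raise ValueError("ORC site does not fit inside the locus")
        span = self.span
        for el in self.elements:
            if not span.contains_interval(el.interval):
                raise ValueError(f"element {el.label} outside locus span {span}")
        if self.rf_base + sum(e.rf_effect for e in self.all_elements) > 1.0 + 1e-12:
            raise ValueError("rf_base plus summed rf_effects exceeds 1")
        if self.pf_base + sum(e.pf_effect for e in self.all_elements) > 1.0 + 1e-12:
            raise ValueError("pf_base plus summed pf_effects exceeds 1")

    @property
    def span(self) -> AnchoredInterval:
        return AnchoredInterval(-self.upstream, self.length - self.upstream - 1)

    @property
    def orc_element(self) -> Element:
        return Element(
            "ORC",
            AnchoredInterval(0, len(self.orc_site) - 1),
            self.orc_site,
            rf_effect=self.orc_rf_effect,
            pf_effect=self.orc_pf_effect,
        )

    @property
    def all_elements(self) -> tuple[Element, ...]:
        return (self.orc_element,) + tuple(self.elements)


@dataclass(frozen=True)
class Locus:
    """A realized locus: concrete sequence plus its element annotations."""

    name: str
    sequence: str
    upstream: int  # bases 5' of anchored position 0
    elements: tuple[Element, ...]

    @property
    def span(self) -> AnchoredInterval:
        return AnchoredInterval(-self.upstream, len(self.sequence) - self.upstream - 1)

    def subsequence(self, interval: AnchoredInterval) -> str:
        if not self.span.contains_interval(interval):
            raise ValueError(f"interval {interval} outside locus span {self.span}")
        lo = interval.start + self.upstream
        return self.sequence[lo : lo + interval.length]


@dataclass(frozen=True)
class Fragment:
    """A library fragment: a contiguous subsequence of one locus."""

    id: str
    locus: str
    interval: AnchoredInterval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.interval.length:
            raise ValueError(
                f"fragment {self.id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.interval.length}"
            )


@dataclass(frozen=True)
class FitnessTruth:
    """Ground-truth replication / partitioning fitness of one fragment."""

    fragment_id: str
    rep_fitness: float
    part_fitness: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rep_fitness <= 1.0 and 0.0 <= self.part_fitness <= 1.0):
            raise ValueError("fitness values must lie in [0, 1]")


@dataclass(frozen=True)
class MutantOligo:
    """One synthesized oligo: the mutated sequence and its substitutions."""

    id: str
    sequence: str
    substitutions: tuple[tuple[int, str, str], ...]  # (anchored pos, ref, alt)


@dataclass
class CountMatrix:
    """Fragment read counts over time points (rows = fragments, cols = hours)."""

    counts: pd.DataFrame  # integer, columns are hours (floats)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate fragment id {dup!r}")

    @property
    def timepoints(self) -> tuple[float, ...]:
        return tuple(float(t) for t in self.counts.columns)

    @property
    def depth(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def fragment_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)


# ---------------------------------------------------------------------------
# generation


def build_locus(spec: LocusSpec, seed: int) -> Locus:
    """Materialize a locus: uniform random background with elements embedded.

    Elements (including the implicit ORC site) must not overlap; an
    overlapping pair is rejected by name. Deterministic under a fixed seed.
    """
    els = spec.all_elements
    for i, a in enumerate(els):
        for b in els[i + 1 :]:
            if a.interval.overlaps(b.interval):
                raise ValueError(
                    f"elements {a.label!r} and {b.label!r} overlap "
                    f"({a.interval} vs {b.interval})"
                )
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=spec.length)
    for el in els:
        lo = el.interval.start + spec.upstream
        seq[lo : lo + el.interval.length] = list(el.consensus)
    return Locus(spec.name, "".join(seq), spec.upstream, els)


def fragment_library(
    locus: Locus,
    n: int,
    len_range: tuple[int, int] = (100, 200),
    seed: int = 0,
) -> list[Fragment]:
    """Sample ``n`` fragments with uniform lengths and uniform start positions."""
    lo, hi = len_range
    if n <= 0:
        raise ValueError("n must be positive")
    if not (1 <= lo <= hi <= len(locus.sequence)):
        raise ValueError(f"invalid length range {len_range} for locus of "
                         f"length {len(locus.sequence)}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    span = locus.span
    frags = []
    width = len(str(n - 1)) if n > 1 else 1
    for i, length in enumerate(lengths):
        start = int(rng.integers(span.start, span.end - length + 2))
        iv = AnchoredInterval(start, start + int(length) - 1)
        frags.append(
            Fragment(f"{locus.name}_f{i:0{max(width, 4)}d}", locus.name, iv,
                     locus.subsequence(iv))
        )
    return frags


def true_fitness(fragment: Fragment, locus: Locus, rf_base: float = 0.0,
                 pf_base: float = 0.0) -> FitnessTruth:
    """Ground-truth RF/PF of a fragment: base plus effects of the elements it
    contains in full. Partial containment contributes zero."""
    if fragment.locus != locus.name:
        raise ValueError(f"fragment {fragment.id} is not from locus {locus.name}")
    if not locus.span.contains_interval(fragment.interval):
        raise ValueError(f"fragment {fragment.id} outside locus span")
    rf, pf = rf_base, pf_base
    for el in locus.elements:
        if fragment.interval.contains_interval(el.interval):
            rf += el.rf_effect
            pf += el.pf_effect
    return FitnessTruth(fragment.id, rf, pf)


def truths_for_library(
    fragments: Iterable[Fragment], locus: Locus, spec: LocusSpec
) -> list[FitnessTruth]:
    """Convenience: ground truth for every fragment of one locus."""
    return [true_fitness(f, locus, spec.rf_base, spec.pf_base) for f in fragments]


def mutagenize_library(
    reference: str, rate: float, n: int, seed: int = 0, id_prefix: str = "oligo",
    anchor_offset: int = 0,
) -> list[MutantOligo]:
    """Doped-synthesis oligo pool: every position of every oligo is substituted
    independently with probability ``rate``; the alternative base is uniform
    over the three non-reference bases.

    ``anchor_offset`` is the anchored coordinate of the reference's first base
    (e.g. -56 for a full fragment spanning -56..+96), recorded in each
    substitution triple.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    ref = np.array(list(reference))
    if not np.isin(ref, BASES).all():
        raise ValueError("reference must be over A/C/G/T")
    rng = np.random.default_rng(seed)
    L = ref.size
    hit = rng.random((n, L)) < rate
    # index among the 3 alternatives to the reference base
    alt_idx = rng.integers(0, 3, size=(n, L))
    ref_code = np.searchsorted(BASES, ref)  # BASES is sorted
    alt_code = (ref_code[None, :] + 1 + alt_idx) % 4
    oligos = []
    width = len(str(n - 1))
    for i in range(n):
        seq = ref.copy()
        pos = np.nonzero(hit[i])[0]
        subs = []
        for p in pos:
            alt = BASES[alt_code[i, p]]
            seq[p] = alt
            subs.append((int(p) + anchor_offset, str(ref[p]), str(alt)))
        oligos.append(MutantOligo(f"{id_prefix}_{i:0{max(width, 4)}d}",
                                  "".join(seq), tuple(subs)))
    return oligos


def oligo_rates(
    oligos: Sequence[MutantOligo],
    critical: Sequence[AnchoredInterval],
    base_rate: float = 0.2,
    penalty: float = 0.15,
) -> dict[str, float]:
    """Ground-truth growth rate (log2/hr) per mutant oligo.

    Each designated critical element hit by at least one substitution costs
    ``penalty``; substitutions outside every critical element are neutral —
    the generating model behind synthetic mutational-scanning pools.
    """
    rates = {}
    for o in oligos:
        hit = sum(1 for iv in critical
                  if any(pos in iv for pos, _, _ in o.substitutions))
        rates[o.id] = base_rate - penalty * hit
    return rates


def _mechanistic_abundances(
    truths: Sequence[FitnessTruth],
    timepoints: Sequence[float],
    c: float,
    noise_sd: float,
    hours_per_generation: float,
    n_lineages: int,
    init_copies: int,
    seed_seq: np.random.SeedSequence,
    pf_floor: float | None,
) -> np.ndarray:
    generations = max(1, int(round(max(timepoints) / hours_per_generation)))
    gen_idx = [min(generations, int(round(t / hours_per_generation)))
               for t in timepoints]
    out = np.empty((len(truths), len(timepoints)))
    for row, (truth, child) in enumerate(zip(truths, seed_seq.spawn(len(truths)))):
        pf = truth.part_fitness if pf_floor is None else max(truth.part_fitness, pf_floor)
        params = SimParams(rf=truth.rep_fitness, pf=pf, c=c, noise_sd=noise_sd,
                           generations=generations, init_copies=init_copies)
        rng = np.random.default_rng(child)
        per_gen = np.mean(
            [simulate_lineage(params, rng).copies_per_generation
             for _ in range(n_lineages)], axis=0)
        out[row] = per_gen[gen_idx]
    return out


def simulate_counts(
    truths: Sequence[FitnessTruth],
    timepoints: Sequence[float] = ACEN_TIMEPOINTS,
    depth: int = 1_000_000,
    mode: Literal["expectation", "mechanistic"] = "mechanistic",
    seed: int = 0,
    *,
    rates: Mapping[str, float] | None = None,
    c: float = 1.0,
    noise_sd: float = 0.05,
    hours_per_generation: float = HOURS_PER_GENERATION,
    n_lineages: int = 8,
    init_copies: int = 4,
    pf_floor: float | None = None,
) -> CountMatrix:
    """Simulate a sequencing count table for a pooled competition.

    ``expectation`` mode drives fragment abundance as ``2**(rate * t)`` using
    the per-fragment rates in ``rates`` (log2 frequency change per hour) — an
    exact log-linear population used to validate the slope estimator.
    ``mechanistic`` mode runs the plasmid-population simulator per fragment
    with its ground-truth (RF, PF), a shared crowding penalty ``c`` and
    per-cell Gaussian noise; ``pf_floor`` raises every fragment's effective PF
    to at least that value, emulating a centromere-containing backbone whose
    active segregation makes partitioning non-limiting.

    Counts at each time point are a multinomial draw of ``depth`` reads from
    the abundance-derived frequencies; column sums equal ``depth`` exactly.
    """
    truths = list(truths)
    if not truths:
        raise ValueError("empty truth set")
    tps = [float(t) for t in timepoints]
    if tps != sorted(set(tps)) or tps[0] != 0.0:
        raise ValueError("timepoints must be strictly increasing and start at 0")
    if depth <= 0:
        raise ValueError("depth must be positive")
    ss = np.random.SeedSequence(seed)
    ids = [t.fragment_id for t in truths]
    if mode == "expectation":
        if rates is None:
            raise ValueError("expectation mode requires per-fragment rates")
        r = np.array([rates[i] for i in ids])
        abundance = np.power(2.0, np.outer(r, tps))
    elif mode == "mechanistic":
        abundance = _mechanistic_abundances(
            truths, tps, c, noise_sd, hours_per_generation, n_lineages,
            init_copies, ss.spawn(1)[0], pf_floor)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(ss.spawn(2)[1])
    counts = np.empty((len(ids), len(tps)), dtype=np.int64)
    for j in range(len(tps)):
        col = abundance[:, j]
        total = col.sum()
        if total <= 0:
            counts[:, j] = 0
            counts[0, j] = depth  # degenerate: everything extinct
        else:
            counts[:, j] = rng.multinomial(depth, col / total)
    df = pd.DataFrame(counts, index=pd.Index(ids, name="fragment_id"), columns=tps)
    return CountMatrix(df)
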