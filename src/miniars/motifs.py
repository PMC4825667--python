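"""PFM motif scanning with exact null p-values, window tiling, and
binder-annotation fold enrichment.

Windows of 50 nt tiled every 25 nt across a region (by default -50 to +175,
skipping windows that touch the ORC site) are scanned on both strands against
a collection of position frequency matrices. The match statistic is the log2
odds of the pseudocount-regularized PFM frequencies against an i.i.d.
background; its null distribution is computed *exactly* by dynamic programming
over the discretized per-column score distribution, so the reported p-value is
Pr(score >= observed) under the background with no asymptotic approximation.

Motifs hitting a partitioning region in at least ``min_ars`` ARSs are called
high-frequency partitioning motifs. Fold enrichment of the proteins predicted
to bind a motif set is computed per annotation term against a background
protein set (by default all sequence-specific DNA binders) with a
hypergeometric upper-tail p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coords import AnchoredInterval

__all__ = [
    "PFM",
    "MotifHit",
    "EnrichmentResult",
    "tile_windows",
    "scan_pfm",
    "best_hit_per_window",
    "high_frequency",
    "fold_enrichment",
]

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: score discretization granularity (log2-odds units) for the exact null DP
SCORE_EPS = 1e-3


@dataclass(frozen=True)
class PFM:
    """A position frequency (count) matrix over A/C/G/T."""

    id: str
    name: str
    counts: np.ndarray  # shape (4, w), rows in A, C, G, T order
    pseudocount: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError(f"PFM {self.id}: counts must be 4 x w with w >= 1")
        if (c < 0).any():
            raise ValueError(f"PFM {self.id}: negative counts")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError(f"PFM {self.id}: background must sum to 1")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2 of regularized column frequencies over the background."""
        c = self.counts + self.pseudocount
        freqs = c / c.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background)[:, None]
        return np.log2(freqs / bg)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    pfm_id: str
    window: AnchoredInterval
    offset: int  # leftmost base of the match within the window, forward strand
    strand: str  # "+" or "-"
    score: float  # log2-odds
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    query_count: int
    query_total: int
    background_count: int
    background_total: int
    fold: float
    p_value: float

    @property
    def query_fraction(self) -> float:
        return self.query_count / self.query_total

    @property
    def background_fraction(self) -> float:
        return self.background_count / self.background_total


def tile_windows(
    region: AnchoredInterval,
    width: int = 50,
    step: int = 25,
    mask: Sequence[AnchoredInterval] | None = None,
) -> list[AnchoredInterval]:
    """Fixed-width windows advanced by ``step`` while fully inside ``region``;
    windows overlapping any mask interval (e.g. the ORC site) are dropped."""
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    windows = []
    s = region.start
    while s + width - 1 <= region.end:
        w = AnchoredInterval(s, s + width - 1)
        if not mask or not any(w.overlaps(m) for m in mask):
            windows.append(w)
        s += step
    return windows


def _int_scores(pfm: PFM, eps: float) -> np.ndarray:
    """Per-column log-odds scores on the integer grid (units of ``eps``)."""
    return np.rint(pfm.log_odds() / eps).astype(np.int64)


def null_distribution(pfm: PFM, eps: float = SCORE_EPS) -> dict[int, float]:
    """Exact null distribution of the total integer score under i.i.d.
    background, by column-wise convolution."""
    table = _int_scores(pfm, eps)
    bg = np.asarray(pfm.background)
    dist: dict[int, float] = {0: 1.0}
    for col in range(pfm.width):
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(table[b, col])
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    return dist


def _survival(dist: Mapping[int, float]):
    """Map integer score -> Pr(S >= score), as a step lookup."""
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    # tail[i] = P(S >= scores[i])
    tail = probs[::-1].cumsum()[::-1]

    def sf(s: int) -> float:
        i = np.searchsorted(scores, s, side="left")
        if i >= scores.size:
            return 0.0
        return float(min(tail[i], 1.0))

    return sf


def scan_pfm(
    sequence: str,
    pfm: PFM,
    alpha: float = 0.05,
    window: AnchoredInterval | None = None,
    eps: float = SCORE_EPS,
) -> list[MotifHit]:
    """Scan both strands of a window sequence at every offset.

    Returns hits with exact p-value <= ``alpha``. The hit offset is the
    leftmost base of the matched word on the forward strand.
    """
    seq = sequence.upper()
    bad = [i for i, b in enumerate(seq) if b not in _BASE_INDEX]
    if bad:
        raise ValueError(f"degenerate base {seq[bad[0]]!r} at position {bad[0]}")
    w = pfm.width
    if w > len(seq):
        return []
    if window is None:
        window = AnchoredInterval(0, len(seq) - 1)
    table = _int_scores(pfm, eps)
    sf = _survival(null_distribution(pfm, eps))
    hits = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
        codes = np.fromiter((_BASE_INDEX[b] for b in s), dtype=np.int64)
        for off in range(len(s) - w + 1):
            score_int = int(table[codes[off : off + w], np.arange(w)].sum())
            p = sf(score_int)
            if p <= alpha:
                fwd_off = off if strand == "+" else len(s) - w - off
                hits.append(MotifHit(pfm.id, window, fwd_off, strand,
                                     score_int * eps, p))
    return hits


def best_hit_per_window(hits: Iterable[MotifHit]) -> dict[tuple[str, AnchoredInterval], MotifHit]:
    """Keep the best-p (ties: highest score) hit per (pfm, window)."""
    best: dict[tuple[str, AnchoredInterval], MotifHit] = {}
    for h in hits:
        key = (h.pfm_id, h.window)
        cur = best.get(key)
        if cur is None or (h.p_value, -h.score) < (cur.p_value, -cur.score):
            best[key] = h
    return best


def high_frequency(
    hits_by_ars: Mapping[str, Iterable[str]], min_ars: int = 10
) -> set[str]:
    """Motifs hitting partitioning regions of at least ``min_ars`` ARSs."""
    return {m for m, arss in hits_by_ars.items() if len(set(arss)) >= min_ars}


def fold_enrichment(
    query: Iterable[str],
    term_table: pd.DataFrame,
    background: Iterable[str],
    p_cutoff: float = 0.01,
    min_fold: float = 2.0,
) -> list[EnrichmentResult]:
    """Per-term fold enrichment of a query protein set against a background.

    ``term_table`` has columns ``protein`` and ``term``. Fold is the ratio of
    the query fraction annotated with the term to the background fraction;
    significance is the hypergeometric upper tail. Terms passing both the
    fold and p-value thresholds are returned, sorted by descending fold.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query proteins must be a subset of the background")
    if not {"protein", "term"} <= set(term_table.columns):
        raise ValueError("term table needs 'protein' and 'term' columns")
    M, n = len(background), len(query)
    results = []
    for term, sub in term_table.groupby("term"):
        members = set(sub["protein"]) & background
        if not members:
            logger.warning("term %r has no members in the background; skipped", term)
            continue
        K = len(members)
        k = len(members & query)
        fold = (k / n) / (K / M)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        if fold >= min_fold and p <= p_cutoff:
            results.append(EnrichmentResult(str(term), k, n, K, M, fold, p))
    results.sort(key=lambda r: -r.fold)
    return results
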