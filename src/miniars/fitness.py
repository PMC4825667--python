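"""Competitive-fitness estimation from pooled sequencing counts.

Two estimators are provided, matching the two library designs:

* slope fitness — for time-course competitions, the ordinary least-squares
  slope of log2 fragment frequency against time in hours. Since
  log2(f_t / f_0) differs from log2(f_t) by a constant, regressing either
  gives the same slope.
* endpoint fitness — for deep-mutational-scanning pools sequenced only at the
  start and end of the competition, the ratio of end frequency to start
  frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CountMatrix

__all__ = [
    "FitnessRecord",
    "EndpointFitness",
    "to_frequencies",
    "competitive_fitness",
    "fitness_table",
    "endpoint_fitness",
    "endpoint_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessRecord:
    fragment_id: str
    cf_slope: float  # log2 frequency change per hour
    r_squared: float
    n_timepoints: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or np.isnan(self.r_squared)):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")


@dataclass(frozen=True)
class EndpointFitness:
    fragment_id: str
    ratio: float  # end frequency / start frequency; NaN when start is 0
    defined: bool = True


def to_frequencies(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Column-normalized fragment frequencies, ``(count + pc) / sum``."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    df = counts.counts.astype(float) + pseudocount
    sums = df.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero column at time point {zero.index[0]} "
                         "with pseudocount 0")
    return df / sums


def competitive_fitness(
    freqs: np.ndarray | pd.Series, timepoints: np.ndarray, fragment_id: str = ""
) -> FitnessRecord:
    """OLS slope of log2 frequency against hours, with r² of the fit."""
    f = np.asarray(freqs, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if f.size != t.size or f.size < 2:
        raise ValueError("need matching frequencies for >= 2 time points")
    if (f <= 0).any():
        raise ValueError(
            f"fragment {fragment_id or '?'}: zero frequency in series; "
            "use a positive pseudocount")
    y = np.log2(f)
    if np.allclose(y, y[0]):
        # flat series: slope 0, r^2 reported as 0 by convention
        return FitnessRecord(fragment_id, 0.0, 0.0, f.size)
    res = stats.linregress(t, y)
    return FitnessRecord(fragment_id, float(res.slope),
                         float(res.rvalue ** 2), f.size)


def fitness_table(counts: CountMatrix, pseudocount: float = 0.5,
                  min_r2: float | None = None) -> pd.DataFrame:
    """Slope fitness for every fragment of a count table.

    Fragments with zero counts at every time point are dropped with a warning
    (they carry no information beyond the pseudocount). Returns a DataFrame
    indexed by fragment id with columns ``cf_slope``, ``r_squared``,
    ``n_timepoints``.
    """
    present = counts.counts.sum(axis=1) > 0
    if (~present).any():
        logger.warning("dropping %d fragment(s) absent at every time point",
                       int((~present).sum()))
        counts = CountMatrix(counts.counts.loc[present])
    freqs = to_frequencies(counts, pseudocount)
    t = np.array(counts.timepoints)
    records = [competitive_fitness(freqs.loc[fid].to_numpy(), t, fid)
               for fid in freqs.index]
    df = pd.DataFrame(
        {"cf_slope": [r.cf_slope for r in records],
         "r_squared": [r.r_squared for r in records],
         "n_timepoints": [r.n_timepoints for r in records]},
        index=pd.Index(freqs.index, name="fragment_id"),
    )
    if min_r2 is not None:
        df = df[df["r_squared"] >= min_r2]
    return df


def endpoint_fitness(start_freq: float, end_freq: float,
                     fragment_id: str = "") -> EndpointFitness:
    """Endpoint fitness ratio; a zero start frequency yields a flagged-undefined
    record rather than an exception."""
    if start_freq < 0 or end_freq < 0:
        raise ValueError("frequencies must be nonnegative")
    if start_freq == 0:
        return EndpointFitness(fragment_id, float("nan"), defined=False)
    return EndpointFitness(fragment_id, end_freq / start_freq)


def endpoint_table(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Endpoint fitness for every fragment from the first and last columns."""
    freqs = to_frequencies(counts, pseudocount)
    first, last = freqs.columns[0], freqs.columns[-1]
    recs = [endpoint_fitness(freqs.at[fid, first], freqs.at[fid, last], fid)
            for fid in freqs.index]
    return pd.DataFrame(
        {"ratio": [r.ratio for r in recs], "defined": [r.defined for r in recs]},
        index=pd.Index(freqs.index, name="fragment_id"),
    )
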