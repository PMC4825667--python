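#!/usr/bin/env python
"""Estimate competitive fitness for both competitions.

Reads the cohort count tables from results/cohort/ and fits, per fragment,
the OLS slope of log2 frequency against hours (pseudocount 0.5). Reports how
well the Acen slopes separate the planted fragment archetypes and writes
fitness tables under results/fitness/.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from miniars import io as mio
from miniars.fitness import fitness_table

IN, OUT = Path("results/cohort"), Path("results/fitness")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truths = pd.read_csv(IN / "truths.tsv", sep="\t", index_col="fragment_id")
    for comp in ("acen", "cen"):
        cm = mio.read_count_table(IN / f"{comp}_counts.tsv")
        fit = fitness_table(cm, pseudocount=0.5)
        mio.write_fitness_table(fit, OUT / f"{comp}_fitness.tsv")
        shared = fit.index.intersection(truths.index)
        rho_rf = stats.spearmanr(fit.loc[shared, "cf_slope"],
                                 truths.loc[shared, "rep_fitness"]).statistic
        rho_pf = stats.spearmanr(fit.loc[shared, "cf_slope"],
                                 truths.loc[shared, "part_fitness"]).statistic
        print(f"{comp}: {len(fit)} fragments, slope range "
              f"[{fit.cf_slope.min():.3f}, {fit.cf_slope.max():.3f}] /hr; "
              f"Spearman vs true RF {rho_rf:.2f}, vs true PF {rho_pf:.2f}")


if __name__ == "__main__":
    main()
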