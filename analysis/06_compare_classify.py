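#!/usr/bin/env python
"""Acen vs Cen comparison: decile crosstab, quadrant calls, and
partitioning-region mapping.

Reads both fitness tables from results/fitness/, ranks the shared fragments
into competitive-fitness deciles per competition, cross-tabulates them on the
10 x 10 grid, classifies corner fragments (corner = 3 deciles, diagonal band
= 1), calls partitioning ARSs (at least one P+R- fragment), and maps
partitioning regions by differential coverage (delta >= 0.4 over >= 8 bp)
between the P-R- and P+R- groups of each locus. Writes tables and the
crosstab heat map under results/compare/.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from miniars import io as mio
from miniars.compare import (Category, classify, crosstab, decile_rank,
                             differential_coverage, is_partitioning_ars,
                             near_diagonal_fraction)
from miniars.coords import AnchoredInterval
from miniars.plots import crosstab_heatmap

IN_C, IN_F, OUT = Path("results/cohort"), Path("results/fitness"), Path("results/compare")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    acen = mio.read_fitness_table(IN_F / "acen_fitness.tsv")
    cen = mio.read_fitness_table(IN_F / "cen_fitness.tsv")
    frags = mio.read_fragments_bed(IN_C / "fragments.bed")
    locus_of = {fid: locus for locus, _, fid in frags}
    interval_of = {fid: iv for _, iv, fid in frags}

    shared = sorted(set(acen.index) & set(cen.index))
    a_dec = decile_rank({i: float(acen.at[i, "cf_slope"]) for i in shared})
    c_dec = decile_rank({i: float(cen.at[i, "cf_slope"]) for i in shared})
    xtab = crosstab(a_dec, c_dec)
    cls = classify(a_dec, c_dec, corner_size=3, diag_band=1)
    xtab.to_frame().to_csv(OUT / "crosstab.tsv", sep="\t")
    crosstab_heatmap(xtab.grid, OUT / "crosstab.png")
    pd.DataFrame(
        [(c.fragment_id, locus_of[c.fragment_id], c.acen_decile, c.cen_decile,
          c.category.value, c.near_diagonal) for c in cls],
        columns=["fragment_id", "locus", "acen_decile", "cen_decile",
                 "category", "near_diagonal"]
    ).to_csv(OUT / "classifications.tsv", sep="\t", index=False)

    counts = Counter(c.category.value for c in cls)
    print(f"{len(cls)} shared fragments; category counts: {dict(counts)}")
    print(f"near-diagonal fraction (|Δdecile| <= 1): "
          f"{near_diagonal_fraction(cls):.2f}")

    regions_out = []
    for locus in sorted(set(locus_of.values())):
        locus_cls = [c for c in cls if locus_of[c.fragment_id] == locus]
        call = is_partitioning_ars(locus_cls)
        n_corner = sum(c.category is Category.P_PLUS_R_MINUS for c in locus_cls)
        print(f"  {locus}: partitioning ARS = {call} "
              f"({n_corner} P+R- fragment(s))")
        group_a = [interval_of[c.fragment_id] for c in locus_cls
                   if c.category is Category.P_MINUS_R_MINUS]
        group_b = [interval_of[c.fragment_id] for c in locus_cls
                   if c.category is Category.P_PLUS_R_MINUS]
        if group_a and group_b:
            span = AnchoredInterval(
                min(iv.start for iv in group_a + group_b),
                max(iv.end for iv in group_a + group_b))
            for r in differential_coverage(group_a, group_b, span, 0.4, 8,
                                           kind="partitioning"):
                regions_out.append(r)
                print(f"    partitioning region {r.interval.start}.."
                      f"{r.interval.end} (mean Δcoverage {r.mean_delta:.2f})")
    mio.write_regions_bed(regions_out, OUT / "partitioning_regions.bed")


if __name__ == "__main__":
    main()
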