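#!/usr/bin/env python
"""Tercile coverage mapping of the ARS317-like locus.

Ranks the locus's fragments by Acen competitive fitness, splits them into
terciles (+/++/+++), computes per-nucleotide coverage per tercile, and
extracts the minimal fragment as the longest run of positions present in at
least 80% of the top tercile. Writes coverage tables, the called interval,
and a banded coverage figure under results/mapping/.
"""

from pathlib import Path

from miniars import io as mio
from miniars.coords import AnchoredInterval
from miniars.mapping import bin_fragments, coverage_profile, minimal_region
from miniars.plots import coverage_bands

IN_C, IN_F, OUT = Path("results/cohort"), Path("results/fitness"), Path("results/mapping")
LOCUS = "ars317_like"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fit = mio.read_fitness_table(IN_F / "acen_fitness.tsv")
    frags = [(iv, fid) for locus, iv, fid in
             mio.read_fragments_bed(IN_C / "fragments.bed") if locus == LOCUS]
    intervals = dict((fid, iv) for iv, fid in frags)
    cf = {fid: float(fit.at[fid, "cf_slope"]) for fid in intervals
          if fid in fit.index}
    span = AnchoredInterval(min(iv.start for iv in intervals.values()),
                            max(iv.end for iv in intervals.values()))
    bins = bin_fragments(cf, 3)
    profiles = {}
    for b in range(3):
        label = bins.label(b)
        prof = coverage_profile([intervals[i] for i in bins.members(b)],
                                span, label)
        profiles[label] = prof
        prof.to_frame().to_csv(OUT / f"coverage_tercile{b + 1}.tsv",
                               sep="\t", index=False)
    region = minimal_region(profiles["+++"], threshold=0.80)
    with open(OUT / "minimal_region.bed", "w") as fh:
        fh.write("start\tend\n")
        if region:
            fh.write(f"{region.start}\t{region.end}\n")
    coverage_bands(profiles, OUT / "coverage_bands.png",
                   title=f"{LOCUS}: tercile coverage")
    print(f"{LOCUS}: tercile mean CF {', '.join(f'{m:.3f}' for m in bins.bin_means)}")
    if region:
        print(f"minimal fragment at 80% coverage of the top tercile: "
              f"{region.start}..{region.end} ({region.length} bp)")
    else:
        print("no position reached 80% coverage in the top tercile")


if __name__ == "__main__":
    main()
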