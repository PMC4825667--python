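#!/usr/bin/env python
"""Motif scanning of partitioning regions across a 26-ARS synthetic cohort
and binder-annotation fold enrichment.

Builds 26 synthetic partitioning ARS loci; 14 of them carry the RAP1-like
element and 12 carry the FKH-like element inside their partitioning regions.
Each locus is tiled with 50-nt windows every 25 nt from -50 to +175
(windows touching the 17-bp ORC site are dropped), windows overlapping the
locus's partitioning region are scanned against the packaged PFM collection
at exact p <= 0.05, motifs hitting >= 10 of the 26 ARSs are called
high-frequency, and the binders behind all partitioning-region motifs are
tested for term enrichment (>= 2-fold, hypergeometric p <= 0.01) against the
full synthetic DNA-binder background. Writes hits, high-frequency calls, and
the enrichment table under results/motifs/.
"""

from importlib import resources
from pathlib import Path

import pandas as pd

from miniars import io as mio
from miniars.coords import AnchoredInterval
from miniars.motifs import (best_hit_per_window, fold_enrichment,
                            high_frequency, scan_pfm, tile_windows)
from miniars.pipeline import stage_seed, synthetic_term_table
from miniars.presets import preset
from miniars.synthetic import Element, LocusSpec, build_locus

OUT = Path("results/motifs")
SEED = 1
N_ARS = 26


def partitioning_cohort():
    """26 synthetic partitioning ARSs; the planted element marks each locus's
    partitioning region."""
    base = preset("ars317_like")
    rap1 = Element("RAP1", AnchoredInterval(-30, -18), "ACACCCATACATT",
                   pf_effect=0.9)
    fkh = Element("FKH", AnchoredInterval(60, 67), "GTAAACAA", pf_effect=0.9)
    for i in range(N_ARS):
        el = rap1 if i < 14 else fkh
        spec = LocusSpec(name=f"ars{i:02d}", length=base.length,
                         upstream=base.upstream, orc_site=base.orc_site,
                         orc_rf_effect=base.orc_rf_effect, rf_base=base.rf_base,
                         pf_base=base.pf_base, elements=(el,))
        locus = build_locus(spec, stage_seed(SEED, f"motif_locus:{i}"))
        # partitioning region: the planted element plus 10 bp of flank
        region = AnchoredInterval(el.interval.start - 10, el.interval.end + 10)
        yield locus, region


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with resources.as_file(resources.files("miniars")
                           .joinpath("data/synthetic_pfms.jaspar")) as p:
        pfms = mio.read_pfm_collection(p)
    orc_mask = [AnchoredInterval(0, 16)]
    scan_iv = AnchoredInterval(-50, 175)

    hits_by_ars: dict[str, set[str]] = {}
    rows = []
    for locus, region in partitioning_cohort():
        windows = [w for w in tile_windows(scan_iv, 50, 25, mask=orc_mask)
                   if w.overlaps(region)]
        for w in windows:
            seq = locus.subsequence(w)
            for pfm in pfms:
                for h in best_hit_per_window(scan_pfm(seq, pfm, 0.05,
                                                      window=w)).values():
                    hits_by_ars.setdefault(pfm.name, set()).add(locus.name)
                    rows.append((locus.name, pfm.id, pfm.name, w.start, w.end,
                                 h.offset, h.strand, round(h.score, 3),
                                 h.p_value))
    pd.DataFrame(rows, columns=["ars", "pfm_id", "pfm_name", "window_start",
                                "window_end", "offset", "strand", "score",
                                "p_value"]).to_csv(OUT / "motif_hits.tsv",
                                                   sep="\t", index=False)
    hf = sorted(high_frequency(hits_by_ars, min_ars=10))
    (OUT / "high_frequency_motifs.txt").write_text(
        "\n".join(hf) + ("\n" if hf else ""))
    per_motif = {m: len(s) for m, s in sorted(hits_by_ars.items())}
    print(f"motif -> ARS counts (of {N_ARS}): {per_motif}")
    print(f"high-frequency partitioning motifs (>= 10 ARSs): {hf}")

    table, background = synthetic_term_table(pfms, stage_seed(SEED, "terms"))
    query = sorted(hits_by_ars)
    results = fold_enrichment(query, table, background, p_cutoff=0.01,
                              min_fold=2.0)
    pd.DataFrame(
        [(r.term, r.query_count, r.query_total, r.background_count,
          r.background_total, round(r.fold, 2), r.p_value) for r in results],
        columns=["term", "query_count", "query_total", "background_count",
                 "background_total", "fold", "p_value"]
    ).to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    for r in results:
        print(f"  {r.term}: {r.fold:.1f}-fold "
              f"({r.query_count}/{r.query_total} vs "
              f"{r.background_count}/{r.background_total}), p={r.p_value:.2g}")


if __name__ == "__main__":
    main()
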