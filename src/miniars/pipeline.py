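"""End-to-end orchestration of the synthetic miniARS analysis.

``run_pipeline`` executes simulate -> estimate (Acen, Cen) -> map -> mutscan
-> compare -> motifscan -> enrich on a :class:`~miniars.config.PipelineConfig`
and writes every artifact as plain text plus a ``manifest.json`` listing each
output with its SHA-256 hash; identical config and seed give identical
hashes. One global seed fans out to per-stage seeds through a CRC-32 keyed
seed sequence, so any stage can be re-run standalone and reproduce its part.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import (Category, classify, crosstab, decile_rank,
                      differential_coverage, is_partitioning_ars,
                      near_diagonal_fraction)
from .config import PipelineConfig
from .coords import AnchoredInterval
from .fitness import endpoint_table, fitness_table
from .mapping import bin_fragments, coverage_profile, minimal_region
from .motifs import best_hit_per_window, fold_enrichment, high_frequency, scan_pfm, tile_windows
from .mutscan import SubstitutionEffectMatrix, substitution_matrix
from .presets import load_presets
from .synthetic import (CountMatrix, Fragment, FitnessTruth, Locus,
                        build_locus, fragment_library, mutagenize_library,
                        oligo_rates, simulate_counts, truths_for_library)
from . import io as mio

__all__ = ["stage_seed", "Cohort", "simulate_cohort", "CohortAnalysis",
           "analyze_cohort", "run_mutscan", "synthetic_term_table",
           "run_pipeline"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence keyed by the global seed and
    the CRC-32 of the stage name, folded below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class Cohort:
    """Everything the generator knows about one synthetic competition."""

    specs: dict  # locus name -> LocusSpec
    loci: dict  # locus name -> Locus
    fragments: dict  # locus name -> list[Fragment]
    truths: dict  # fragment id -> FitnessTruth
    acen: CountMatrix
    cen: CountMatrix

    def all_fragments(self) -> list[Fragment]:
        return [f for frags in self.fragments.values() for f in frags]

    def fragment_locus(self) -> dict:
        return {f.id: name for name, frags in self.fragments.items() for f in frags}


def simulate_cohort(cfg: PipelineConfig) -> Cohort:
    """Build loci, fragment libraries, ground truths, and both count tables."""
    cfg.validate()
    presets = load_presets()
    specs, loci, fragments, truths = {}, {}, {}, {}
    for i, (name, n_frag) in enumerate(sorted(cfg.loci.items())):
        spec = presets[name]
        specs[name] = spec
        locus = build_locus(spec, stage_seed(cfg.seed, f"locus:{name}"))
        loci[name] = locus
        frags = fragment_library(locus, n_frag, cfg.fragment_length_range,
                                 stage_seed(cfg.seed, f"fragments:{name}"))
        fragments[name] = frags
        for t in truths_for_library(frags, locus, spec):
            truths[t.fragment_id] = t
    ordered = [truths[f.id] for f in
               sorted((f for fs in fragments.values() for f in fs), key=lambda f: f.id)]
    acen = simulate_counts(
        ordered, cfg.acen_timepoints, cfg.depth, "mechanistic",
        stage_seed(cfg.seed, "acen_counts"), c=cfg.crowding_penalty,
        noise_sd=cfg.noise_sd, hours_per_generation=cfg.hours_per_generation,
        n_lineages=cfg.n_lineages, init_copies=cfg.init_copies)
    cen = simulate_counts(
        ordered, cfg.cen_timepoints, cfg.depth, "mechanistic",
        stage_seed(cfg.seed, "cen_counts"), c=cfg.crowding_penalty,
        noise_sd=cfg.noise_sd, hours_per_generation=cfg.hours_per_generation,
        n_lineages=cfg.n_lineages, init_copies=cfg.init_copies,
        pf_floor=cfg.cen_pf_floor)
    return Cohort(specs, loci, fragments, truths, acen, cen)


@dataclass
class CohortAnalysis:
    acen_fitness: pd.DataFrame
    cen_fitness: pd.DataFrame
    acen_deciles: dict
    cen_deciles: dict
    xtab: object
    classifications: list
    near_diagonal: float
    partitioning_call: dict  # locus name -> bool
    regions: dict  # locus name -> list[DifferentialRegion] (partitioning kind)
    coverage: dict = field(default_factory=dict)  # locus -> bin label -> profile
    minimal_regions: dict = field(default_factory=dict)  # locus -> interval | None


def analyze_cohort(cohort: Cohort, cfg: PipelineConfig) -> CohortAnalysis:
    """Estimate fitness, map coverage, and cross-classify Acen vs Cen."""
    acen_fit = fitness_table(cohort.acen, cfg.pseudocount)
    cen_fit = fitness_table(cohort.cen, cfg.pseudocount)
    shared = sorted(set(acen_fit.index) & set(cen_fit.index))
    acen_cf = {i: float(acen_fit.at[i, "cf_slope"]) for i in shared}
    cen_cf = {i: float(cen_fit.at[i, "cf_slope"]) for i in shared}

    acen_dec = decile_rank(acen_cf)
    cen_dec = decile_rank(cen_cf)
    xtab = crosstab(acen_dec, cen_dec)
    cls = classify(acen_dec, cen_dec, cfg.corner_size, cfg.diag_band)
    by_id = {c.fragment_id: c for c in cls}

    frag_locus = cohort.fragment_locus()
    intervals = {f.id: f.interval for f in cohort.all_fragments()}
    partitioning_call, regions = {}, {}
    coverage, minimal = {}, {}
    for name, frags in cohort.fragments.items():
        ids = [f.id for f in frags if f.id in by_id]
        locus_cls = [by_id[i] for i in ids]
        partitioning_call[name] = is_partitioning_ars(locus_cls) if locus_cls else False

        # per-locus tercile coverage map of the Acen competition
        locus_cf = {i: acen_cf[i] for i in ids if i in acen_cf}
        span = cohort.loci[name].span
        if len(locus_cf) >= cfg.n_bins:
            bins = bin_fragments(locus_cf, cfg.n_bins)
            profs = {}
            for b in range(cfg.n_bins):
                members = bins.members(b)
                profs[bins.label(b)] = coverage_profile(
                    [intervals[i] for i in members], span, bins.label(b))
            coverage[name] = profs
            minimal[name] = minimal_region(profs[bins.label(cfg.n_bins - 1)],
                                           cfg.coverage_threshold)

        # partitioning regions: P-R- (A) vs P+R- (B) fragments of this locus
        group_a = [intervals[c.fragment_id] for c in locus_cls
                   if c.category is Category.P_MINUS_R_MINUS]
        group_b = [intervals[c.fragment_id] for c in locus_cls
                   if c.category is Category.P_PLUS_R_MINUS]
        if group_a and group_b:
            regions[name] = differential_coverage(
                group_a, group_b, span, cfg.delta_threshold,
                cfg.min_region_len, kind="partitioning")
        else:
            regions[name] = []
    return CohortAnalysis(acen_fit, cen_fit, acen_dec, cen_dec, xtab, cls,
                          near_diagonal_fraction(cls), partitioning_call,
                          regions, coverage, minimal)


def run_mutscan(cfg: PipelineConfig, locus: Locus, spec) -> tuple:
    """Mutational scanning of the locus's full fragment: mutagenize, compete
    (expectation-mode counts at start and end), and build the effect matrix."""
    span = AnchoredInterval(*cfg.mutscan_span)
    reference = locus.subsequence(span)
    oligos = mutagenize_library(reference, cfg.mutscan_rate, cfg.mutscan_n_oligos,
                                stage_seed(cfg.seed, f"mutscan:{locus.name}"),
                                id_prefix=f"{locus.name}_mut",
                                anchor_offset=span.start)
    critical = [el.interval for el in locus.elements
                if span.contains_interval(el.interval)]
    rates = oligo_rates(oligos, critical)
    truths = [FitnessTruth(o.id, 0.5, 0.5) for o in oligos]
    counts = simulate_counts(truths, (0.0, 25.0), cfg.depth, "expectation",
                             stage_seed(cfg.seed, f"mutscan_counts:{locus.name}"),
                             rates=rates)
    ep = endpoint_table(counts, cfg.pseudocount)
    fitness = dict(zip(ep.index, ep["ratio"]))
    matrix = substitution_matrix(oligos, fitness, reference, span)
    return oligos, ep, matrix


def synthetic_term_table(pfms, seed: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """A synthetic protein -> annotation-term table for the enrichment demo.

    The background is the PFM-derived binder names plus filler DNA binders;
    partitioning-associated binders carry negative-regulation and G2/M terms
    so that a query hitting them shows the expected enrichment signature.
    """
    rng = np.random.default_rng(seed)
    binders = [p.name for p in pfms]
    fillers = [f"TF{i:03d}" for i in range(40)]
    background = binders + fillers
    rows = [(p, "sequence_specific_DNA_binding") for p in background]
    negreg = {"RAP1_like", "FKH_like", "YHP1_like", "ABF1_like"}
    for p in background:
        if p in negreg or rng.random() < 0.1:
            rows.append((p, "negative_regulation_of_transcription"))
        if p in {"FKH_like", "YHP1_like"} or rng.random() < 0.08:
            rows.append((p, "G2M_phase_regulation"))
        if rng.random() < 0.25:
            rows.append((p, "metabolic_process"))
    table = pd.DataFrame(rows, columns=["protein", "term"])
    return table, background


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, pfms=None) -> dict:
    """Execute every stage and write artifacts plus ``manifest.json``.

    Returns the manifest (relative path -> SHA-256). Any stage failure
    propagates after the partial manifest is written.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stage = "simulate"

    def record(name: str) -> None:
        manifest[name] = _sha256(outdir / name)

    try:
        cohort = simulate_cohort(cfg)
        mio.write_fasta([(n, l.sequence) for n, l in sorted(cohort.loci.items())],
                        outdir / "loci.fasta")
        mio.write_fragments_bed(sorted(cohort.all_fragments(), key=lambda f: f.id),
                                outdir / "fragments.bed")
        pd.DataFrame(
            {"rep_fitness": {i: t.rep_fitness for i, t in cohort.truths.items()},
             "part_fitness": {i: t.part_fitness for i, t in cohort.truths.items()}}
        ).rename_axis("fragment_id").sort_index().to_csv(
            outdir / "truths.tsv", sep="\t")
        mio.write_count_table(cohort.acen, outdir / "acen_counts.tsv")
        mio.write_count_table(cohort.cen, outdir / "cen_counts.tsv")
        for name in ("loci.fasta", "fragments.bed", "truths.tsv",
                     "acen_counts.tsv", "cen_counts.tsv"):
            record(name)

        stage = "estimate/map/compare"
        analysis = analyze_cohort(cohort, cfg)
        mio.write_fitness_table(analysis.acen_fitness, outdir / "acen_fitness.tsv")
        mio.write_fitness_table(analysis.cen_fitness, outdir / "cen_fitness.tsv")
        analysis.xtab.to_frame().to_csv(outdir / "crosstab.tsv", sep="\t")
        pd.DataFrame(
            [(c.fragment_id, c.acen_decile, c.cen_decile, c.category.value,
              c.near_diagonal) for c in analysis.classifications],
            columns=["fragment_id", "acen_decile", "cen_decile", "category",
                     "near_diagonal"],
        ).to_csv(outdir / "classifications.tsv", sep="\t", index=False)
        all_regions = [r for rs in analysis.regions.values() for r in rs]
        mio.write_regions_bed(all_regions, outdir / "partitioning_regions.bed")
        with open(outdir / "partitioning_calls.tsv", "w") as fh:
            fh.write("locus\tis_partitioning_ars\n")
            for name, call in sorted(analysis.partitioning_call.items()):
                fh.write(f"{name}\t{call}\n")
        for name in ("acen_fitness.tsv", "cen_fitness.tsv", "crosstab.tsv",
                     "classifications.tsv", "partitioning_regions.bed",
                     "partitioning_calls.tsv"):
            record(name)

        stage = "mutscan"
        mut_locus = sorted(cohort.loci)[0]
        oligos, ep, matrix = run_mutscan(cfg, cohort.loci[mut_locus],
                                         cohort.specs[mut_locus])
        mio.write_substitutions(oligos, outdir / "mutscan_substitutions.tsv")
        matrix.values.rename_axis("position").to_csv(
            outdir / "mutscan_matrix.tsv", sep="\t")
        record("mutscan_substitutions.tsv")
        record("mutscan_matrix.tsv")

        stage = "motifscan"
        if pfms is None:
            from importlib import resources
            with resources.as_file(resources.files("miniars")
                                   .joinpath("data/synthetic_pfms.jaspar")) as p:
                pfms = mio.read_pfm_collection(p)
        scan_lo, scan_hi = cfg.scan_range
        orc_mask = [AnchoredInterval(0, len(cohort.specs[n].orc_site) - 1)
                    for n in cohort.loci][:1]
        hits_by_ars: dict[str, set[str]] = {}
        hit_rows = []
        for name, locus in sorted(cohort.loci.items()):
            if not analysis.partitioning_call.get(name):
                continue
            scan_iv = AnchoredInterval(max(scan_lo, locus.span.start),
                                       min(scan_hi, locus.span.end))
            windows = tile_windows(scan_iv, cfg.window_width, cfg.window_step,
                                   mask=orc_mask)
            part_regions = [r.interval for r in analysis.regions.get(name, [])]
            windows = [w for w in windows
                       if any(w.overlaps(r) for r in part_regions)]
            for w in windows:
                seq = locus.subsequence(w)
                for pfm in pfms:
                    hits = scan_pfm(seq, pfm, cfg.alpha, window=w)
                    for h in best_hit_per_window(hits).values():
                        hits_by_ars.setdefault(pfm.name, set()).add(name)
                        hit_rows.append((name, pfm.id, pfm.name, w.start, w.end,
                                         h.offset, h.strand, h.score, h.p_value))
        pd.DataFrame(hit_rows, columns=["locus", "pfm_id", "pfm_name",
                                        "window_start", "window_end", "offset",
                                        "strand", "score", "p_value"]
                     ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        hf = sorted(high_frequency(hits_by_ars, cfg.min_ars))
        (outdir / "high_frequency_motifs.txt").write_text(
            "\n".join(hf) + ("\n" if hf else ""))
        record("motif_hits.tsv")
        record("high_frequency_motifs.txt")

        stage = "enrich"
        table, background = synthetic_term_table(pfms,
                                                 stage_seed(cfg.seed, "terms"))
        query = sorted(hits_by_ars) or [pfms[0].name]
        results = fold_enrichment(query, table, background,
                                  cfg.enrich_p_cutoff, cfg.min_fold)
        pd.DataFrame(
            [(r.term, r.query_count, r.query_total, r.background_count,
              r.background_total, r.fold, r.p_value) for r in results],
            columns=["term", "query_count", "query_total", "background_count",
                     "background_total", "fold", "p_value"],
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record("enrichment.tsv")
    except Exception:
        logger.exception("pipeline failed at stage %s", stage)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"stage_failed": stage, "artifacts": manifest}, fh, indent=1)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"artifacts": manifest}, fh, indent=1, sort_keys=True)
    return manifest
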