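# Methods

## Coordinate conventions

All positions are anchored to the ORC binding site: position 0 is the first
nucleotide of the T-rich strand of the site, positive coordinates run 5'→3'
along that strand. Intervals are closed on both ends and position 0 is
counted, so −56..+96 spans 153 bp. When the T-rich strand is the bottom
strand of a locus, anchoring reflects the coordinates so that "downstream of
the T-rich strand" stays positive; this equals anchoring on the
reverse-complemented locus and is tested against that double transform.

The ARS301-like preset's full-fragment reference spans −42..+92 (135 bp).
Its 5' boundary and length are fixed first and the 3' end follows from the
closed-interval arithmetic; the preset's element layout mirrors the
ARS317-like one with weaker effects.

## The plasmid-population model

Each lineage starts as one cell holding `init_copies` plasmids (default 4).
Per generation every live cell:

1. **replicates**: each copy duplicates independently with probability
   `q = rf_eff · f(n, c)`, where `n` is the cell's copy number and
   `f(n, c) = 1/(1 + c·n/100)` is the crowding attenuation. This form is the
   simplest one satisfying the two anchors that define the penalty: no
   attenuation at `c = 0`, and a 50% reduction once a cell has acquired 100
   copies at `c = 1`. It is a plain function (`crowding_factor`) and can be
   swapped. An alternative all-or-nothing rule (all copies duplicate
   together with probability `q`) is available behind
   `replication_mode="all_or_nothing"`; the per-copy Bernoulli rule is the
   default because it is the simplest generative rule consistent with the
   narrative extremes and reproduces the "all copies duplicated" event with
   probability `q^n`.
2. **divides**: each copy moves to the newborn daughter independently with
   probability `pf_eff / 2` — `pf = 1` is the unbiased binomial split,
   `pf = 0` total mother retention; copies are conserved exactly at every
   division.
3. **selection**: cells with zero copies are removed immediately, emulating
   growth in medium that demands a plasmid-borne marker.

Effective parameters are `clip(param + N(0, noise_sd), 0, 1)`, drawn once
per cell at birth (not per generation); the default `noise_sd = 0.05`
represents cell-to-cell variability, and the pf-dependence ranking at
`c = 1` is verified to be stable across noise 0–0.1. Lineages exceeding
10⁵ cells are subsampled uniformly to the cap with the reported totals
rescaled by the survival fraction (seed-stable), so totals remain comparable
across parameter settings. The lineage-summed copy number at the final
generation (default 12 generations, matching a 100-lineage, 12-generation
grid sweep) is the competitive-fitness proxy.

Model behavior: without crowding the expected final total is
`init · (1 + rf)^generations` regardless of pf (division conserves copies);
with crowding, poor partitioning concentrates copies in mothers where
`f(n, c)` throttles replication, so partitioning fitness becomes a strong
determinant of the total. Fragment accumulation per cell saturates under
`c > 0`.

## Synthetic cohort

The generator is the study-conditions definition, not a tuning surface. A
locus is a uniform-composition random background (25% each base; no
composition bias is modeled) with consensus elements embedded at fixed
anchored intervals; fragments are sampled with uniform lengths in 100–200 bp
and uniform starts (DNaseI bias is not modeled). Ground-truth replication
(RF) and partitioning fitness (PF) are additive over elements *fully*
contained in a fragment — truncation by one base voids the contribution.

Default effect sizes: `rf_base = 0.6`, ORC site `+0.2` RF, FKH-like element
`+0.05` RF; `pf_base = 0.05`, RAP1-like element `+0.9` PF. These were chosen
once so the four fragment archetypes reproduce the qualitative structure of
the pooled experiment under crowding penalty 1: partitioning-only fragments
(RF 0.6 / PF 0.95) out-accumulate replication-only fragments
(RF 0.8 / PF 0.05) — the silencer-fragment phenomenon — while both trail the
complete fragments and lead the empty ones. At `c = 0` the ordering
collapses onto RF alone.

Count tables draw a multinomial of `depth` reads (default 10⁶) per time
point from the abundances, so column sums equal the declared depth exactly.
Two abundance models exist: `expectation` (exact log-linear growth at
supplied per-fragment rates, used to validate the estimators) and
`mechanistic` (the population model per fragment, 8 lineages each, hours
converted at 2 hr/generation — the typical budding-yeast doubling time,
configurable). The Cen competition is emulated by flooring every fragment's
effective PF at 0.95: the centromere supplies distribution, making
partitioning non-limiting, so Cen fitness isolates replication.

The mutagenized-oligo generator substitutes every position independently at
the configured rate (1.2% or 1.8%), with the alternative base uniform over
the three non-reference bases (the synthesis chemistry is unspecified, so no
transition bias is modeled). The mut-scan ground truth assigns a growth-rate
penalty to any oligo with at least one substitution inside a designated
critical element and leaves other substitutions neutral; epistasis is out of
scope.

What the generator does *not* emulate: sequencing error, PCR bias,
read-level artifacts, replicate cultures, and the graded per-nucleotide
effects of real binding sites (elements are all-or-nothing). Passing tests
therefore demonstrate that the analysis chain recovers planted structure
under the stated noise model, not that it is robust to every artifact of
real sequencing data — real count tables prepared to the same TSV schema can
be substituted at any stage boundary.

## Estimation and mapping

Frequencies are `(count + pseudocount) / column sum`; the default
pseudocount of 0.5 reads protects zero counts (the choice is a standard
half-read regularizer; zero frequencies are refused with instructions rather
than silently dropped, and all-zero fragments are dropped with a warning).
CF is the OLS slope of log₂ frequency on hours; regressing log₂(f_t/f_0)
would give the identical slope since the offset cancels. r² is reported but
not filtered on by default (`min_r2` exists). Because column normalization
subtracts the common log₂-total-abundance term, absolute slopes carry one
shared population-mean-fitness offset; slope *differences* are exact, and CF
is interpreted as a relative fitness throughout. Endpoint fitness
(mutational-scanning pools) is end frequency / start frequency; a zero start
frequency yields a flagged-undefined record.

Fitness bins are quantile chunks of near-equal size (difference ≤ 1, larger
bins at the low end), sorted by (CF, fragment id) so ties resolve
deterministically. Coverage profiles are exact rationals (fragments
containing a position / bin size). The minimal fragment is the longest
contiguous run of positions at ≥ 80% coverage of the top tercile; among
equal-length runs the higher mean coverage wins, and "no qualifying
position" returns an empty marker. Contiguity is the package's
disambiguation of extracting a single interval from the ≥ 80% position set.

The substitution-effect matrix attributes each oligo's endpoint fitness to
every substitution it carries (multi-mutant oligos contribute to each cell);
`single_mutant_only=True` restricts to single mutants. Cells with no
carriers are NaN with support 0, never silently zero.

## Comparative classification

Deciles (1 = least competitive) are quantile ranks with id tie-breaking.
The corner extent is 3 deciles per axis (the quadrant rule needs a
definition of "corner"; 3 of 10 is exposed as a parameter) and the
near-diagonal band is |Δdecile| ≤ 1. An ARS is a partitioning ARS iff at
least one fragment is P+R−. Differential regions are maximal runs of
coverage difference ≥ 0.4 lasting ≥ 8 bp between corner groups (P−R− vs
P+R− for partitioning, P−R− vs P−R+ for replication); both thresholds are
parameters, chosen once as the smallest contrast that a ~10-fragment corner
group can support without single-fragment artifacts.

## Motif scanning and enrichment

Windows of 50 nt are tiled every 25 nt across −50..+175; windows
*intersecting* the ORC site are dropped (the strictest reading of "skipping
the ORC site"; a containment mode is available). Scanning is sequence
against PFM on both strands at every offset. The score is the log₂ odds of
pseudocount-regularized column frequencies (0.5 per cell) over an i.i.d.
background (uniform by default, overridable); the null distribution of the
total score is computed exactly by convolving the per-column score
distributions on an integer grid (granularity 10⁻³ log₂-odds units — the
same discretization is applied to observed scores, so DP and enumeration
agree identically), and the p-value is the exact upper tail. Hits at
p ≤ 0.05 are kept, deduplicated to the best-p hit per (PFM, window). No
multiple-testing correction is applied by default, matching the
per-window-cutoff design of the analysis. High-frequency motifs are those
hitting partitioning regions of ≥ 10 ARSs.

Fold enrichment of the binders behind a motif set is query fraction /
background fraction per term with a hypergeometric upper-tail p-value
(thresholds ≥ 2-fold, p ≤ 0.01), against a background of all
sequence-specific DNA binders. The packaged PFM collection
(`data/synthetic_pfms.jaspar`) and the term table generated by
`synthetic_term_table` are synthetic stand-ins written from field-standard
consensus sequences so the pipeline runs without any database download.

## Reproducibility and problem sizes

One global seed fans out to per-stage seeds through a seed sequence keyed by
the CRC-32 of the stage name; every stage is independently reproducible and
the full pipeline is hash-identical under a fixed config and seed. The
shipped cohort sizes (2 loci × 150 fragments, 8 lineages per fragment,
10,000 mut-scan oligos, depth 10⁶, 20-replicate recovery sweeps) were chosen
as the smallest sizes at which the decile classification and region calling
are stable; all are configuration fields.

## Known limitations

* The population model abstracts nuclear geometry: no morpho-kinetic bud-neck
  blockade, SAGA/nuclear-pore retention, centromere replication-timing
  effects, or mother-cell aging; partitioning is a single per-copy
  probability.
* Fragment sampling is unbiased; real DNaseI libraries are not.
* The end-to-end recovery rate is a property of the planted effect sizes;
  weaker elements or smaller corner groups reduce it.
* Enrichment statistics use a plain hypergeometric test rather than a
  genome-database term finder; term tables must be supplied (or synthesized).
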