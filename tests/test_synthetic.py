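"""Generator behavior: locus construction, fragment sampling, ground-truth
fitness, mutagenesis statistics, and count-table simulation."""

import numpy as np
import pytest

from miniars.coords import AnchoredInterval
from miniars.synthetic import (
    Element, LocusSpec, build_locus, fragment_library, mutagenize_library,
    oligo_rates, simulate_counts, true_fitness, FitnessTruth,
)


def minimal_spec(**kw):
    defaults = dict(name="test", length=200, upstream=80, orc_rf_effect=0.5)
    defaults.update(kw)
    return LocusSpec(**defaults)


class TestBuildLocus:
    def test_orc_consensus_embedded_at_zero(self):
        spec = minimal_spec()
        locus = build_locus(spec, seed=7)
        assert locus.subsequence(AnchoredInterval(0, 16)) == spec.orc_site

    def test_seed_determinism(self):
        spec = minimal_spec()
        assert build_locus(spec, 7).sequence == build_locus(spec, 7).sequence
        assert build_locus(spec, 7).sequence != build_locus(spec, 8).sequence

    def test_element_found_by_independent_string_search(self):
        rap1 = Element("RAP1", AnchoredInterval(-30, -18), "ACACCCATACATT",
                       pf_effect=0.5)
        locus = build_locus(minimal_spec(elements=(rap1,)), seed=3)
        assert locus.subsequence(AnchoredInterval(-30, -18)) == "ACACCCATACATT"
        # brute-force substring scan: the consensus occurs at the planted offset
        offsets = [i for i in range(len(locus.sequence) - 12)
                   if locus.sequence[i:i + 13] == "ACACCCATACATT"]
        assert locus.upstream - 30 in offsets

    def test_overlapping_elements_rejected_by_name(self):
        a = Element("A", AnchoredInterval(-10, 0), "A" * 11)
        with pytest.raises(ValueError, match="'A'.*'ORC'|'ORC'.*'A'"):
            build_locus(minimal_spec(elements=(a,)), seed=0)


class TestFragmentLibrary:
    def test_lengths_within_requested_range(self, ars317_locus):
        frags = fragment_library(ars317_locus, 500, (100, 200), seed=1)
        assert len(frags) == 500
        assert all(100 <= f.interval.length <= 200 for f in frags)
        assert len({f.id for f in frags}) == 500

    def test_degenerate_range_returns_whole_locus(self, ars317_locus):
        L = len(ars317_locus.sequence)
        frags = fragment_library(ars317_locus, 5, (L, L), seed=1)
        assert all(f.sequence == ars317_locus.sequence for f in frags)

    def test_dense_library_covers_every_interior_position(self):
        """2000 fragments on a 1 kb locus tile it completely, save possibly
        the outermost couple of bases: covering the extreme position needs a
        fragment ending exactly there (a few expected per library), so the
        guarantee holds for the interior."""
        locus = build_locus(minimal_spec(length=1000, upstream=400), seed=2)
        frags = fragment_library(locus, 2000, (100, 200), seed=3)
        # brute-force coverage enumeration
        covered = np.zeros(1000, dtype=bool)
        for f in frags:
            covered[f.interval.start + 400 : f.interval.end + 401] = True
        assert covered[3:-3].all()
        assert (~covered).sum() <= 6

    @pytest.mark.parametrize("n,rng_", [(0, (100, 200)), (5, (0, 50)),
                                        (5, (150, 100))])
    def test_invalid_arguments_rejected(self, ars317_locus, n, rng_):
        with pytest.raises(ValueError):
            fragment_library(ars317_locus, n, rng_, seed=0)


class TestTrueFitness:
    def test_additive_when_element_fully_contained(self):
        spec = minimal_spec(rf_base=0.2, orc_rf_effect=0.6)
        locus = build_locus(spec, 0)
        frag = fragment_library(locus, 1, (150, 150), seed=4)[0]
        truth = true_fitness(frag, locus, spec.rf_base, spec.pf_base)
        expected = 0.8 if frag.interval.contains_interval(
            AnchoredInterval(0, 16)) else 0.2
        assert truth.rep_fitness == pytest.approx(expected)

    def test_truncated_element_contributes_nothing(self):
        rap1 = Element("RAP1", AnchoredInterval(-30, -18), "ACACCCATACATT",
                       pf_effect=0.5)
        spec = minimal_spec(pf_base=0.1, elements=(rap1,))
        locus = build_locus(spec, 0)
        # fragment missing the last base of the RAP1 element
        iv = AnchoredInterval(-80, -19)
        from miniars.synthetic import Fragment
        frag = Fragment("x", locus.name, iv, locus.subsequence(iv))
        truth = true_fitness(frag, locus, spec.rf_base, spec.pf_base)
        assert truth.part_fitness == pytest.approx(0.1)

    def test_matches_brute_force_containment_oracle(
            self, ars317_fragments, ars317_locus, ars317_spec):
        for frag in ars317_fragments[:50]:
            truth = true_fitness(frag, ars317_locus, ars317_spec.rf_base,
                                 ars317_spec.pf_base)
            rf, pf = ars317_spec.rf_base, ars317_spec.pf_base
            for el in ars317_locus.elements:
                positions = set(range(el.interval.start, el.interval.end + 1))
                frag_positions = set(range(frag.interval.start,
                                           frag.interval.end + 1))
                if positions <= frag_positions:
                    rf += el.rf_effect
                    pf += el.pf_effect
            assert truth.rep_fitness == pytest.approx(rf)
            assert truth.part_fitness == pytest.approx(pf)


class TestMutagenize:
    REF = "ACGTTGCA" * 19 + "A"  # 153 nt

    def test_rate_zero_reproduces_reference(self):
        oligos = mutagenize_library(self.REF, 0.0, 20, seed=0)
        assert all(o.sequence == self.REF and not o.substitutions
                   for o in oligos)

    def test_mean_substitutions_matches_binomial_mean(self):
        oligos = mutagenize_library(self.REF, 0.012, 20_000, seed=1)
        mean = np.mean([len(o.substitutions) for o in oligos])
        expect = 153 * 0.012  # 1.836
        se = np.sqrt(153 * 0.012 * 0.988 / 20_000)
        assert abs(mean - expect) < 3 * se

    def test_substitution_lists_consistent_with_sequences(self):
        for o in mutagenize_library(self.REF, 0.05, 200, seed=2,
                                    anchor_offset=-56):
            seq = list(self.REF)
            for pos, ref, alt in o.substitutions:
                assert seq[pos + 56] == ref and alt != ref
                seq[pos + 56] = alt
            assert "".join(seq) == o.sequence

    def test_per_position_rate_recovered_within_family_binomial_bounds(self):
        n = 10_000
        oligos = mutagenize_library(self.REF, 0.018, n, seed=3)
        counts = np.zeros(153)
        for o in oligos:
            for pos, _, _ in o.substitutions:
                counts[pos] += 1
        freq = counts / n
        se = np.sqrt(0.018 * 0.982 / n)
        z = (freq - 0.018) / se
        # pooled rate within 3 s.e. of the pooled binomial
        pooled_se = se / np.sqrt(153)
        assert abs(freq.mean() - 0.018) < 3 * pooled_se
        # per-position outliers no more frequent than the 3-sigma null allows
        assert int(np.sum(np.abs(z) > 3)) <= 4


class TestSimulateCounts:
    def test_column_sums_equal_depth(self, ars317_truths):
        cm = simulate_counts(ars317_truths[:20], (0.0, 3.0, 6.0), 10_000,
                             "mechanistic", seed=0, n_lineages=2)
        assert (cm.depth == 10_000).all()

    def test_equal_rates_split_evenly(self):
        truths = [FitnessTruth("a", 0.5, 0.5), FitnessTruth("b", 0.5, 0.5)]
        cm = simulate_counts(truths, (0.0, 5.0, 10.0), 1_000_000,
                             "expectation", seed=1, rates={"a": 0.1, "b": 0.1})
        freq = cm.counts / 1_000_000
        se = np.sqrt(0.25 / 1_000_000)
        assert (np.abs(freq - 0.5) < 3 * se).all().all()

    def test_expectation_mode_reproduces_closed_form_slope(self):
        from miniars.fitness import fitness_table
        truths = [FitnessTruth("fast", 0.5, 0.5), FitnessTruth("slow", 0.5, 0.5)]
        rates = {"fast": 0.2, "slow": 0.0}
        cm = simulate_counts(truths, (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 25.0),
                             10_000_000, "expectation", seed=2, rates=rates)
        fit = fitness_table(cm, pseudocount=0.5)
        # relative slopes: estimator sees frequencies, so slopes are shifted
        # by the common mean-fitness term but their difference is exact
        diff = fit.at["fast", "cf_slope"] - fit.at["slow", "cf_slope"]
        assert diff == pytest.approx(0.2, abs=0.002)

    def test_seed_determinism(self, ars317_truths):
        a = simulate_counts(ars317_truths[:10], (0.0, 4.0), 1000,
                            "mechanistic", seed=9, n_lineages=2)
        b = simulate_counts(ars317_truths[:10], (0.0, 4.0), 1000,
                            "mechanistic", seed=9, n_lineages=2)
        assert a.counts.equals(b.counts)

    def test_empty_truths_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts([], (0.0, 3.0), 100, "expectation", seed=0,
                            rates={})

    def test_oligo_rates_penalize_critical_hits_only(self):
        from miniars.synthetic import MutantOligo
        crit = [AnchoredInterval(0, 16)]
        inside = MutantOligo("i", "A", (( 5, "A", "C"),))
        outside = MutantOligo("o", "A", ((40, "A", "C"),))
        wt = MutantOligo("w", "A", ())
        rates = oligo_rates([inside, outside, wt], crit, 0.2, 0.15)
        assert rates == {"i": pytest.approx(0.05), "o": 0.2, "w": 0.2}
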