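"""Window tiling, exact-p-value PFM scanning, high-frequency motif calls, and
fold enrichment."""

import itertools
from importlib import resources

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miniars.coords import AnchoredInterval
from miniars.io import read_pfm_collection
from miniars.motifs import (PFM, SCORE_EPS, fold_enrichment, high_frequency,
                            null_distribution, scan_pfm, tile_windows,
                            _int_scores)


@pytest.fixture(scope="module")
def fixture_pfms():
    with resources.as_file(resources.files("miniars")
                           .joinpath("data/synthetic_pfms.jaspar")) as p:
        return read_pfm_collection(p)


class TestTileWindows:
    REGION = AnchoredInterval(-50, 175)

    def test_matches_brute_force_enumeration(self):
        windows = tile_windows(self.REGION, 50, 25)
        starts = [w.start for w in windows]
        # oracle: every start s while [s, s+49] fits in [-50, 175]
        assert starts == [s for s in range(-50, 176, 25) if s + 49 <= 175]
        assert starts == [-50, -25, 0, 25, 50, 75, 100, 125]

    def test_too_wide_gives_empty_list(self):
        assert tile_windows(AnchoredInterval(-50, 174), 300, 25) == []

    def test_orc_mask_drops_exactly_intersecting_windows(self):
        orc = AnchoredInterval(0, 16)
        unmasked = tile_windows(self.REGION, 50, 25)
        masked = tile_windows(self.REGION, 50, 25, mask=[orc])
        dropped = set(unmasked) - set(masked)
        assert dropped == {w for w in unmasked if w.overlaps(orc)}
        assert all(not w.overlaps(orc) for w in masked)


class TestScan:
    def tata_pfm(self):
        counts = np.zeros((4, 4))
        for i, b in enumerate("TATA"):
            counts["ACGT".index(b), i] = 1.0
        return PFM("TATA", "indicator", counts)

    def test_indicator_word_has_closed_form_pvalue(self):
        pfm = self.tata_pfm()
        hits = scan_pfm("TATA", pfm, alpha=1.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd[0].p_value == pytest.approx((1 / 4) ** 4)
        # any single mismatch scores lower, so its p-value is larger
        miss = [h for h in scan_pfm("TATC", pfm, alpha=1.0) if h.strand == "+"]
        assert miss[0].p_value > (1 / 4) ** 4

    def test_alpha_zero_returns_nothing(self):
        assert scan_pfm("TATATATA", self.tata_pfm(), alpha=0.0) == []

    def test_degenerate_base_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            scan_pfm("TANA", self.tata_pfm())

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_dp_null_matches_exhaustive_enumeration(self, fixture_pfms, width):
        """The DP null distribution must agree with brute-force enumeration
        over all 4**w background words, at every achievable score."""
        pfms = [p for p in fixture_pfms if p.width == width]
        assert pfms, f"no fixture PFM of width {width}"
        for pfm in pfms:
            table = _int_scores(pfm, SCORE_EPS)
            brute: dict[int, float] = {}
            for word in itertools.product(range(4), repeat=width):
                s = int(sum(table[b, i] for i, b in enumerate(word)))
                brute[s] = brute.get(s, 0.0) + (1 / 4) ** width
            dp = null_distribution(pfm)
            assert set(dp) == set(brute)
            for s in brute:
                assert dp[s] == pytest.approx(brute[s], abs=1e-12)

    def test_reverse_complement_symmetry(self, fixture_pfms, rng):
        pfm = next(p for p in fixture_pfms if p.id == "SYN001")
        seq = "".join(rng.choice(list("ACGT"), 60))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_pfm(seq, pfm, alpha=1.0)
        rev = scan_pfm(rc, pfm, alpha=1.0)
        key = lambda hs: sorted((round(h.score, 9), round(h.p_value, 12))
                                for h in hs)
        assert key(fwd) == key(rev)


class TestHighFrequency:
    def test_threshold_boundary(self):
        hits = {"m_all": {f"ars{i}" for i in range(26)},
                "m_nine": {f"ars{i}" for i in range(9)},
                "m_ten": {f"ars{i}" for i in range(10)}}
        hf = high_frequency(hits, min_ars=10)
        assert hf == {"m_all", "m_ten"}

    def test_matches_cardinality_oracle(self, rng):
        hits = {f"m{i}": {f"ars{j}" for j in rng.integers(0, 26, size=k)}
                for i, k in enumerate(rng.integers(0, 30, size=40))}
        hf = high_frequency(hits, min_ars=10)
        assert hf == {m for m, s in hits.items() if len(s) >= 10}

    def test_planted_consensus_becomes_high_frequency(self, fixture_pfms, rng):
        """Embedding the RAP1-like consensus into 12 of 20 synthetic
        partitioning regions makes it (and only it) a high-frequency motif."""
        rap1 = next(p for p in fixture_pfms if p.name == "RAP1_like")
        hits_by_ars: dict[str, set[str]] = {}
        for a in range(20):
            seq = list(rng.choice(list("ACGT"), 50))
            if a < 12:
                seq[10:10 + rap1.width] = list(rap1.consensus())
            for h in scan_pfm("".join(seq), rap1, alpha=0.001):
                hits_by_ars.setdefault(rap1.name, set()).add(f"ars{a}")
        assert rap1.name in high_frequency(hits_by_ars, min_ars=10)
        assert len(hits_by_ars[rap1.name]) >= 12


class TestEnrichment:
    def table(self):
        rows = [("p1", "t"), ("p2", "t"), ("p3", "t"), ("p4", "t"), ("p5", "t"),
                ("p6", "other")]
        rows += [(f"q{i}", "t") for i in range(5)]
        return pd.DataFrame(rows, columns=["protein", "term"])

    def test_background_against_itself_is_unit_fold(self):
        bg = [f"p{i}" for i in range(1, 7)]
        res = fold_enrichment(bg, self.table(), bg, p_cutoff=1.0, min_fold=0.0)
        assert res and all(r.fold == pytest.approx(1.0) for r in res)

    def test_fold_arithmetic(self):
        # query of 10 with 5 annotated; background fraction 10/100
        rows = ([(f"q{i}", "t") for i in range(5)] +
                [(f"b{i}", "t") for i in range(5)])
        table = pd.DataFrame(rows, columns=["protein", "term"])
        query = [f"q{i}" for i in range(10)]
        background = query + [f"b{i}" for i in range(90)]
        res = fold_enrichment(query, table, background, p_cutoff=1.0,
                              min_fold=0.0)
        assert res[0].fold == pytest.approx(5.0)

    def test_hypergeometric_matches_enumeration(self):
        """Small universe: the reported p equals brute-force enumeration of
        all equally likely query draws."""
        import math
        background = [f"p{i}" for i in range(8)]
        annotated = set(background[:3])
        query = ["p0", "p1", "p4"]
        k = len(annotated & set(query))
        table = pd.DataFrame([(p, "t") for p in annotated],
                             columns=["protein", "term"])
        res = fold_enrichment(query, table, background, p_cutoff=1.0,
                              min_fold=0.0)
        total = math.comb(8, 3)
        brute = sum(
            1 for combo in itertools.combinations(background, 3)
            if len(annotated & set(combo)) >= k) / total
        assert res[0].p_value == pytest.approx(brute, abs=1e-12)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(["zz"], self.table(), ["p1"])
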