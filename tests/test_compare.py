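"""Decile cross-classification of Acen vs Cen competitions."""

import numpy as np
import pytest

from miniars.compare import (Category, classify, crosstab, decile_rank,
                             differential_coverage, is_partitioning_ars,
                             near_diagonal_fraction)
from miniars.coords import AnchoredInterval


class TestDecileRank:
    def test_ten_values_rank_one_to_ten(self):
        cf = {f"f{i}": float(i) for i in range(1, 11)}
        dec = decile_rank(cf)
        assert all(dec[f"f{i}"] == i for i in range(1, 11))

    def test_hundred_values_ten_per_decile(self, rng):
        cf = {f"f{i:03d}": float(v) for i, v in enumerate(rng.normal(size=100))}
        dec = decile_rank(cf)
        counts = np.bincount(list(dec.values()), minlength=11)[1:]
        assert (counts == 10).all()

    def test_matches_sort_and_chunk_oracle(self, rng):
        cf = {f"f{i:03d}": float(v) for i, v in enumerate(rng.normal(size=73))}
        dec = decile_rank(cf)
        order = sorted(cf, key=lambda i: (cf[i], i))
        start = 0
        for d in range(1, 11):
            size = (73 - start + (10 - d)) // (11 - d)
            for fid in order[start:start + size]:
                assert dec[fid] == d
            start += size

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            decile_rank({f"f{i}": 1.0 for i in range(9)})


class TestCrosstab:
    def test_identical_ranks_fill_diagonal(self):
        ranks = {f"f{i}": (i % 10) + 1 for i in range(50)}
        x = crosstab(ranks, ranks)
        assert x.grid.sum() == 50
        assert np.all(x.grid == np.diag(np.diag(x.grid)))

    def test_grid_has_100_cells_and_conserves_total(self, rng):
        a = {f"f{i}": int(r) for i, r in
             enumerate(rng.integers(1, 11, size=137))}
        c = {f"f{i}": int(r) for i, r in
             enumerate(rng.integers(1, 11, size=137))}
        x = crosstab(a, c)
        assert x.grid.size == 100
        assert x.total == 137

    def test_matches_pair_counting_oracle(self, rng):
        a = {f"f{i}": int(r) for i, r in enumerate(rng.integers(1, 11, 200))}
        c = {f"f{i}": int(r) for i, r in enumerate(rng.integers(1, 11, 200))}
        x = crosstab(a, c)
        for i in range(1, 11):
            for j in range(1, 11):
                want = sum(1 for f in a if a[f] == i and c[f] == j)
                assert x.grid[i - 1, j - 1] == want

    def test_id_mismatch_lists_symmetric_difference(self):
        with pytest.raises(ValueError, match="extra"):
            crosstab({"a": 1, "extra": 2}, {"a": 1, "other": 2})


class TestClassify:
    def test_corner_rules(self):
        a = {"x": 10, "y": 5}
        c = {"x": 1, "y": 5}
        cls = {r.fragment_id: r for r in classify(a, c, corner_size=3)}
        assert cls["x"].category is Category.P_PLUS_R_MINUS
        assert cls["y"].category is Category.UNCALLED
        assert cls["y"].near_diagonal

    def test_every_pair_matches_exhaustive_rule_table(self):
        corner = 3
        a = {f"p{i}_{j}": i for i in range(1, 11) for j in range(1, 11)}
        c = {f"p{i}_{j}": j for i in range(1, 11) for j in range(1, 11)}
        cls = {r.fragment_id: r.category for r in classify(a, c, corner)}
        for i in range(1, 11):
            for j in range(1, 11):
                lo_a, hi_a = i <= corner, i >= 11 - corner
                lo_c, hi_c = j <= corner, j >= 11 - corner
                if hi_a and lo_c:
                    want = Category.P_PLUS_R_MINUS
                elif lo_a and hi_c:
                    want = Category.P_MINUS_R_PLUS
                elif lo_a and lo_c:
                    want = Category.P_MINUS_R_MINUS
                elif hi_a and hi_c:
                    want = Category.P_PLUS_R_PLUS
                else:
                    want = Category.UNCALLED
                assert cls[f"p{i}_{j}"] is want

    def test_classification_is_a_partition(self, rng):
        a = {f"f{i}": int(r) for i, r in enumerate(rng.integers(1, 11, 100))}
        c = {f"f{i}": int(r) for i, r in enumerate(rng.integers(1, 11, 100))}
        cls = classify(a, c)
        assert len(cls) == 100
        assert all(isinstance(r.category, Category) for r in cls)

    def test_near_diagonal_fraction_monotone_in_band(self, rng):
        a = {f"f{i}": int(r) for i, r in enumerate(rng.integers(1, 11, 200))}
        c = {f"f{i}": int(r) for i, r in enumerate(rng.integers(1, 11, 200))}
        fracs = [near_diagonal_fraction(classify(a, c, diag_band=b))
                 for b in range(0, 10)]
        assert all(x <= y for x, y in zip(fracs, fracs[1:]))

    def test_invalid_corner_rejected(self):
        with pytest.raises(ValueError):
            classify({"a": 1}, {"a": 1}, corner_size=7)


class TestPartitioningCall:
    def make(self, cats):
        return [type("C", (), {"category": c})() for c in cats]

    def test_all_uncalled_is_false(self):
        cls = classify({f"f{i}": 5 for i in range(10)},
                       {f"f{i}": 5 for i in range(10)})
        assert not is_partitioning_ars(cls)

    def test_single_corner_fragment_suffices(self):
        a = {f"f{i}": 5 for i in range(9)} | {"hit": 10}
        c = {f"f{i}": 5 for i in range(9)} | {"hit": 1}
        assert is_partitioning_ars(classify(a, c))

    def test_matches_existence_oracle(self, rng):
        for _ in range(10):
            a = {f"f{i}": int(r) for i, r in
                 enumerate(rng.integers(1, 11, 30))}
            c = {f"f{i}": int(r) for i, r in
                 enumerate(rng.integers(1, 11, 30))}
            cls = classify(a, c)
            want = any(x.category is Category.P_PLUS_R_MINUS for x in cls)
            assert is_partitioning_ars(cls) == want


class TestDifferentialCoverage:
    RANGE = AnchoredInterval(-100, 150)

    def test_identical_groups_yield_no_regions(self):
        group = [AnchoredInterval(0, 50), AnchoredInterval(-40, 30)]
        assert differential_coverage(group, group, self.RANGE) == []

    def test_constructed_block_difference(self):
        b = [AnchoredInterval(50, 100)] * 4
        a = [AnchoredInterval(-100, -50)] * 4
        regions = differential_coverage(a, b, self.RANGE, 0.4, 8)
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end) == (50, 100)
        assert r.mean_delta == pytest.approx(1.0)

    def test_matches_run_scan_oracle(self, rng):
        def random_group(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(-100, 100))
                out.append(AnchoredInterval(s, s + int(rng.integers(10, 60))))
            return out
        a, b = random_group(12), random_group(12)
        got = differential_coverage(a, b, self.RANGE, 0.25, 5)
        # oracle: per-position membership delta, then run scan
        delta = []
        for pos in range(self.RANGE.start, self.RANGE.end + 1):
            ca = sum(1 for iv in a if pos in iv) / len(a)
            cb = sum(1 for iv in b if pos in iv) / len(b)
            delta.append(cb - ca)
        runs, cur = [], None
        for i, d in enumerate(delta + [-9.9]):
            if d >= 0.25:
                cur = i if cur is None else cur
            elif cur is not None:
                if i - cur >= 5:
                    runs.append((cur + self.RANGE.start, i - 1 + self.RANGE.start))
                cur = None
        assert [(r.interval.start, r.interval.end) for r in got] == runs

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            differential_coverage([], [AnchoredInterval(0, 5)], self.RANGE)
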