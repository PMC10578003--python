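"""Example construction: merging, windows, tiling, encoding, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromaccess import peakdata, synthio
from chromaccess.peakdata import (build_negative_examples, build_positive_examples,
                                  decode_one_hot, merge_tissue_peaks, one_hot,
                                  proximal_negative_subset, split_examples)


def brute_force_merge(intervals):
    """Transitive closure of the >=1-bp-overlap relation (union-find).

    Adjacent half-open intervals share no base and must stay separate, so
    the oracle tests the overlap predicate pairwise rather than marking
    covered points.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    return sorted((min(s for s, _ in g), max(e for _, e in g))
                  for g in groups.values())


class TestMergeTissuePeaks:
    def test_overlap_union_with_both_flags(self):
        merged = merge_tissue_peaks({"head": [("2L", 100, 400)],
                                     "testis": [("2L", 300, 600)]})
        assert len(merged) == 1
        r = merged.iloc[0]
        assert (r.start, r.end, r["head"], r["testis"]) == (100, 600, 1, 1)

    def test_disjoint_peaks_stay_separate_single_flagged(self):
        merged = merge_tissue_peaks({"head": [("2L", 0, 100)],
                                     "testis": [("2L", 200, 300)]})
        assert len(merged) == 2
        assert merged[["head", "testis"]].to_numpy().tolist() == [[1, 0], [0, 1]]

    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)),
                    min_size=1, max_size=15),
           st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)),
                    min_size=0, max_size=15))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_brute_force_union(self, head, testis):
        h = [("c", s, s + w) for s, w in head]
        t = [("c", s, s + w) for s, w in testis]
        merged = merge_tissue_peaks({"head": h, "testis": t})
        expect = brute_force_merge([(s, e) for _, s, e in h + t])
        assert list(zip(merged.start, merged.end)) == expect
        # flags: overlap with >=1 source interval of that tissue
        for r in merged.itertuples():
            assert r.head == int(any(s < r.end and r.start < e for _, s, e in h))
            assert r.testis == int(any(s < r.end and r.start < e for _, s, e in t))


class TestOneHot:
    def test_acgt_pattern_and_n_column(self):
        m = one_hot("ACGTN")
        np.testing.assert_array_equal(m[:, :4], np.eye(4, dtype=np.uint8))
        assert m[:, 4].sum() == 0

    def test_invalid_base_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            one_hot("ACXGT")

    @given(st.text(alphabet="ACGTacgt", min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_decode_inverts_encode(self, seq):
        assert decode_one_hot(one_hot(seq)) == seq.upper()

    def test_decode_restores_n_for_zero_columns(self):
        assert decode_one_hot(one_hot("ANGT")) == "ANGT"


class TestPositiveExamples:
    GENOME = {"2L": "ACGT" * 1000}  # 4 kb

    def test_window_is_midpoint_plus_minus_flank(self):
        merged = pd.DataFrame([{"chrom": "2L", "start": 1000, "end": 1400,
                                "head": 1, "testis": 0}])
        X, y, origins, dropped = build_positive_examples(merged, self.GENOME,
                                                         ("head", "testis"))
        assert origins.iloc[0].tolist() == ["2L", 700, 1700]
        assert X.shape == (1, 4, 1000)
        assert y.tolist() == [[1, 0]]

    def test_peak_too_close_to_chrom_start_dropped(self):
        merged = pd.DataFrame([{"chrom": "2L", "start": 100, "end": 300,
                                "head": 1, "testis": 0}])
        X, _, _, dropped = build_positive_examples(merged, self.GENOME,
                                                   ("head", "testis"))
        assert len(X) == 0 and dropped["bounds"] == 1

    def test_missing_chromosome_is_hard_error(self):
        merged = pd.DataFrame([{"chrom": "4", "start": 1000, "end": 1400,
                                "head": 1, "testis": 0}])
        with pytest.raises(KeyError, match="'4'"):
            build_positive_examples(merged, self.GENOME, ("head", "testis"))


class TestNegativeExamples:
    def test_tile_count_without_peaks(self):
        genome = {"2L": "A" * 10_000}
        merged = pd.DataFrame(columns=["chrom", "start", "end"])
        X, y, origins = build_negative_examples(genome, merged, ("head", "testis"))
        assert len(X) == 10 and (y == 0).all()

    def test_trailing_partial_tile_dropped(self):
        genome = {"2L": "A" * 10_500}
        merged = pd.DataFrame(columns=["chrom", "start", "end"])
        X, _, origins = build_negative_examples(genome, merged, ("head", "testis"))
        assert len(X) == 10 and origins.end.max() == 10_000

    @given(st.lists(st.tuples(st.integers(0, 9_000), st.integers(1, 900)),
                    min_size=0, max_size=5))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_exclusion_matches_brute_force_overlap_scan(self, peaks):
        genome = {"c": "G" * 10_000}
        merged = pd.DataFrame([{"chrom": "c", "start": s, "end": s + w}
                               for s, w in peaks],
                              columns=["chrom", "start", "end"])
        _, _, origins = build_negative_examples(genome, merged, ("head",))
        expect = [t for t in range(0, 10_000, 1000)
                  if not any(s < t + 1000 and t < s + w for s, w in peaks)]
        assert origins.start.tolist() == expect


class TestProximalNegatives:
    def test_adjacent_kept_and_501_excluded(self):
        neg = pd.DataFrame([{"chrom": "c", "start": 2000, "end": 3000},
                            {"chrom": "c", "start": 4501, "end": 5501}])
        pos = pd.DataFrame([{"chrom": "c", "start": 1000, "end": 2000},
                            {"chrom": "c", "start": 6002, "end": 7002}])
        keep = proximal_negative_subset(neg, pos, max_gap=500)
        # first: gap 0 to peak 1 -> kept; second: gaps 501 both sides -> dropped
        assert keep.tolist() == [True, False]

    def test_membership_matches_exhaustive_distances(self, rng):
        neg = pd.DataFrame([{"chrom": "c", "start": s, "end": s + 1000}
                            for s in range(0, 20_000, 1000)])
        pos = pd.DataFrame([{"chrom": "c", "start": 4600, "end": 5600},
                            {"chrom": "c", "start": 12_345, "end": 13_345}])
        keep = proximal_negative_subset(neg, pos, max_gap=500)
        for i, r in neg.iterrows():
            dists = []
            for _, p in pos.iterrows():
                if p.start < r.end and r.start < p.end:
                    dists.append(0)
                else:
                    dists.append(max(p.start - r.end, r.start - p.end))
            assert keep[i] == (min(dists) <= 500)


class TestSplitExamples:
    def _toy(self, n=1100, test_n=100):
        origins = pd.DataFrame({
            "chrom": ["3L"] * test_n + ["2L"] * (n - test_n),
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
        })
        X = np.zeros((n, 4, 10), dtype=np.uint8)
        y = np.zeros((n, 2), dtype=np.int8)
        return X, y, origins

    def test_partition_exact_and_val_floor(self):
        X, y, origins = self._toy()
        es = split_examples(X, y, origins, ("head", "testis"), seed=3)
        counts = pd.Series(es.split).value_counts()
        assert counts["test"] == 100
        assert counts["val"] == 100  # floor(0.1 * 1000)
        assert counts["train"] == 900

    def test_split_reproducible_and_test_is_chromosome(self):
        X, y, origins = self._toy()
        a = split_examples(X, y, origins, ("head", "testis"), seed=5)
        b = split_examples(X, y, origins, ("head", "testis"), seed=5)
        assert (a.split == b.split).all()
        assert set(origins.chrom[a.split == "test"]) == {"3L"}
        assert "3L" not in set(origins.chrom[a.split != "test"])

    def test_missing_test_chromosome_errors(self):
        X, y, origins = self._toy()
        with pytest.raises(ValueError, match="absent"):
            split_examples(X, y, origins, ("head", "testis"), test_chrom="chrX")


def test_labels_match_truth_on_synthetic_genome(small_genome):
    """End-to-end: example labels equal the generator's truth table."""
    genome, truth = small_genome
    gs = {c: synthio.codes_to_str(s) for c, s in genome.items()}
    pbt = {"head": [(r.chrom, r.start, r.end) for r in truth.peaks.itertuples() if r.head],
           "testis": [(r.chrom, r.start, r.end) for r in truth.peaks.itertuples() if r.testis]}
    es = peakdata.build_example_set(gs, pbt, seed=0)
    origins = es.origins
    pos = origins[origins.is_peak == 1]
    assert len(pos) == len(truth.peaks)  # peaks are isolated by construction
    truth_by_mid = {(r.chrom, (r.start + r.end) // 2): (r.head, r.testis)
                    for r in truth.peaks.itertuples()}
    for i, r in zip(pos.index, pos.itertuples()):
        mid = (r.start + r.end) // 2
        assert tuple(es.y[i]) == truth_by_mid[(r.chrom, mid)]
    # negatives never overlap a truth peak
    neg = origins[origins.is_peak == 0]
    for r in neg.itertuples():
        sel = truth.peaks[(truth.peaks.chrom == r.chrom)
                          & (truth.peaks.start < r.end)
                          & (r.start < truth.peaks.end)]
        assert len(sel) == 0
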