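"""Multi-context orthology: interval merging vs a single-linkage oracle,
reciprocal filtering, classification rules, and parsimony loss calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromaccess import orthomap, synthio
from chromaccess.orthomap import (classify_orthology, conservation_summary,
                                  merge_mapped, nearest_end_distance,
                                  reciprocal_filter, species_specific_loss_calls)


def single_linkage_oracle(intervals, gap):
    """Brute-force transitive clustering at nearest-end distance <= gap."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        (s1, e1), (s2, e2) = intervals[i], intervals[j]
        d = nearest_end_distance(s1, e1, s2, e2)
        if d <= gap:
            parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(intervals[i])
    return sorted((min(s for s, _ in c), max(e for _, e in c))
                  for c in clusters.values())


def _df(intervals, pid="p1", chrom="2L"):
    return pd.DataFrame([{"peak_id": pid, "dst_chrom": chrom,
                          "dst_start": s, "dst_end": e} for s, e in intervals])


class TestMergeMapped:
    def test_within_gap_merges(self):
        m = merge_mapped(_df([(100, 200), (250, 300)]), gap=100)
        assert list(zip(m.dst_start, m.dst_end)) == [(100, 300)]

    def test_boundary_101_does_not_merge(self):
        m = merge_mapped(_df([(100, 200), (301, 400)]), gap=100)
        assert len(m) == 2
        m2 = merge_mapped(_df([(100, 200), (300, 400)]), gap=100)
        assert len(m2) == 1  # distance exactly 100: inclusive

    def test_chain_of_four_closes_transitively(self):
        ivs = [(0, 50), (130, 180), (260, 310), (390, 440)]  # gaps of 80
        m = merge_mapped(_df(ivs), gap=100)
        assert list(zip(m.dst_start, m.dst_end)) == [(0, 440)]

    def test_matches_single_linkage_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(1, 15)
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 2000))
                ivs.append((s, s + int(rng.integers(10, 200))))
            m = merge_mapped(_df(ivs), gap=100)
            got = sorted(zip(m.dst_start, m.dst_end))
            assert got == single_linkage_oracle(ivs, 100)

    def test_groups_by_peak_and_context(self):
        df = pd.concat([_df([(0, 100)], pid="a"), _df([(50, 150)], pid="b")])
        m = merge_mapped(df, gap=100)
        assert len(m) == 2  # different peaks never merge


class TestReciprocalFilter:
    def _orig(self):
        return pd.DataFrame([{"peak_id": "p1", "chrom": "2L",
                              "start": 1000, "end": 1400}])

    def test_exact_roundtrip_retained(self):
        fwd = _df([(5000, 5400)])
        back = pd.DataFrame([{"peak_id": "p1", "dst_chrom": "2L",
                              "dst_start": 1000, "dst_end": 1400}])
        kept = reciprocal_filter(fwd, back, self._orig())
        assert len(kept) == 1

    def test_backmap_150bp_away_dropped_and_100_kept(self):
        fwd = _df([(5000, 5400)])
        for offset, expect in ((150, 0), (100, 1)):
            back = pd.DataFrame([{"peak_id": "p1", "dst_chrom": "2L",
                                  "dst_start": 1400 + offset,
                                  "dst_end": 1800 + offset}])
            kept = reciprocal_filter(fwd, back, self._orig())
            assert len(kept) == expect

    def test_missing_backmap_record_dropped(self):
        fwd = _df([(5000, 5400)])
        kept = reciprocal_filter(fwd, pd.DataFrame(columns=fwd.columns), self._orig())
        assert len(kept) == 0


def _peaks(species_intervals):
    out = {}
    for sp, ivs in species_intervals.items():
        out[sp] = pd.DataFrame([{"chrom": "2L", "start": s, "end": e,
                                 "peak_id": f"{sp}_{i}"}
                                for i, (s, e) in enumerate(ivs)])
    return out


def _identity_maps(peak_sets):
    maps = {}
    species = list(peak_sets)
    for src in species:
        for dst in species:
            if src == dst:
                continue
            maps[(src, dst)] = peak_sets[src].rename(
                columns={"chrom": "dst_chrom", "start": "dst_start",
                         "end": "dst_end"})[["peak_id", "dst_chrom",
                                             "dst_start", "dst_end"]]
    return maps


class TestClassify:
    def test_identical_peak_everywhere_conserved(self):
        ps = _peaks({"mel": [(100, 500)], "sim": [(100, 500)], "yak": [(100, 500)]})
        calls = classify_orthology(ps, _identity_maps(ps))
        assert all(c.status == "conserved" for c in calls)

    def test_no_liftover_in_one_species_is_ambiguous(self):
        ps = _peaks({"mel": [(100, 500)], "sim": [(100, 500)], "yak": [(100, 500)]})
        maps = _identity_maps(ps)
        maps[("mel", "sim")] = maps[("mel", "sim")].iloc[:0]
        calls = classify_orthology(ps, maps)
        mel = [c for c in calls if c.species == "mel"][0]
        assert mel.status == "ambiguous_excluded"

    def test_isolated_peak_is_species_specific(self):
        ps = _peaks({"mel": [(100, 500), (9000, 9400)],
                     "sim": [(100, 500)], "yak": [(100, 500)]})
        calls = classify_orthology(ps, _identity_maps(ps))
        by_id = {c.peak_id: c for c in calls}
        assert by_id["mel_1"].status == "species_specific"
        assert by_id["mel_0"].status == "conserved"

    def test_proximity_is_inclusive_100(self):
        for gap, status in ((100, "conserved"), (101, "species_specific")):
            ps = _peaks({"mel": [(1000, 1400)], "sim": [(1400 + gap, 1800 + gap)],
                         "yak": [(50_000, 50_400)]})
            calls = classify_orthology(ps, _identity_maps(ps))
            mel = [c for c in calls if c.species == "mel"][0]
            assert mel.status == status

    def test_multi_mapping_peak_excluded_from_specific_calls(self):
        ps = _peaks({"mel": [(100, 500)], "sim": [(50_000, 50_400)],
                     "yak": [(90_000, 90_400)]})
        maps = _identity_maps(ps)
        dup = maps[("mel", "sim")]
        maps[("mel", "sim")] = pd.concat([dup, dup.assign(dst_start=70_000,
                                                          dst_end=70_400)])
        calls = classify_orthology(ps, maps)
        mel = [c for c in calls if c.species == "mel"][0]
        assert mel.status == "ambiguous_excluded"

    def test_species_relabelling_permutes_calls(self):
        ps = _peaks({"mel": [(100, 500), (9000, 9400)],
                     "sim": [(120, 520)], "yak": [(80, 480)]})
        calls = classify_orthology(ps, _identity_maps(ps))
        ren = {"mel": "yak", "sim": "mel", "yak": "sim"}
        ps2 = {ren[sp]: df for sp, df in ps.items()}
        calls2 = classify_orthology(ps2, _identity_maps(ps2))
        st1 = {(c.peak_id.split("_")[1], ren[c.species]): c.status for c in calls}
        st2 = {(c.peak_id.split("_")[1], c.species): c.status for c in calls2}
        assert st1 == st2


class TestSummaryAndLosses:
    def test_counts_partition_total(self):
        ps = _peaks({"mel": [(100, 500), (9000, 9400)],
                     "sim": [(100, 500)], "yak": [(100, 500)]})
        calls = classify_orthology(ps, _identity_maps(ps))
        s = conservation_summary(calls)
        mel = s[s.species == "mel"].iloc[0]
        assert mel.n_total == mel.n_conserved + mel.n_specific + mel.n_ambiguous

    def test_loss_assigned_to_absent_ingroup(self):
        # yak peak present in mel, absent in sim
        ps = _peaks({"mel": [(100, 500)], "sim": [(50_000, 50_400)],
                     "yak": [(100, 500)]})
        calls = classify_orthology(ps, _identity_maps(ps))
        losses = species_specific_loss_calls(calls, phylogeny=(("mel", "sim"), "yak"))
        assert len(losses) == 1
        assert losses.iloc[0].lost_in == "sim"
        assert losses.iloc[0].retained_in == "mel"

    def test_absent_in_both_ingroups_not_called(self):
        ps = _peaks({"mel": [(50_000, 50_400)], "sim": [(70_000, 70_400)],
                     "yak": [(100, 500)]})
        calls = classify_orthology(ps, _identity_maps(ps))
        losses = species_specific_loss_calls(calls, phylogeny=(("mel", "sim"), "yak"))
        assert len(losses) == 0


def test_end_to_end_scenario_recovers_truth_small():
    """Calls on a small generated 3-species scenario match planted truth."""
    spec = synthio.SyntheticGenomeSpec(n_chromosomes=1, chrom_length=400_000, seed=21)
    scen = synthio.three_species_scenario(spec, conserve_fraction=0.7, seed=22)
    locs = {}
    for (src, dst), m in scen.maps.items():
        merged = merge_mapped(m)
        locs[(src, dst)] = reciprocal_filter(merged, merged, scen.peak_sets[src])
    calls = classify_orthology(scen.peak_sets, locs)
    truth = scen.status_truth.set_index(["peak_id", "species"])["status"]
    n = 0
    for c in calls:
        if c.status == "ambiguous_excluded":
            continue
        assert c.status == truth.loc[(c.peak_id, c.species)]
        n += 1
    assert n > 50
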