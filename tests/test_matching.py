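"""Atomic Sort distances, medians, classification, and ranking."""

import math

import numpy as np
import pytest

from atomsort import (
    MatchConfig,
    NormalizationRanges,
    Peak2D,
    PeakList,
    ReferenceCompound,
    ReferenceDatabase,
    atomic_sort_match,
    classify_match,
    nearest_distance,
    peak_distance,
    rank_compounds,
    shift_ranges,
    SimParams,
    simulate_extract,
    simulate_reference_db,
)
from conftest import random_peak_list


def brute_force_nearest(query, targets, ranges):
    """Independent oracle: exhaustive python-loop all-pairs search."""
    best_idx, best_d = None, math.inf
    for i, t in enumerate(targets):
        d = math.sqrt(
            ((query.h_shift - t.h_shift) / ranges.h_range) ** 2
            + ((query.c_shift - t.c_shift) / ranges.c_range) ** 2
        )
        if d < best_d:
            best_idx, best_d = i, d
    return best_idx, best_d


class TestShiftRanges:
    def test_hand_case(self, three_peak_extract):
        r = shift_ranges(three_peak_extract)
        assert r.h_range == pytest.approx(2.0)
        assert r.c_range == pytest.approx(20.0)

    def test_single_peak_uses_floors(self):
        r = shift_ranges(PeakList([Peak2D(3.31, 49.0)]))
        assert (r.h_range, r.c_range) == (10.0, 160.0)

    def test_permutation_invariant(self, three_peak_extract):
        shuffled = PeakList(list(reversed(three_peak_extract.peaks)))
        assert shift_ranges(shuffled) == shift_ranges(three_peak_extract)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            shift_ranges(PeakList([]))


class TestPeakDistance:
    def test_hand_arithmetic(self):
        r = NormalizationRanges(2.0, 20.0)
        d = peak_distance(Peak2D(1.1, 11.0), Peak2D(1.0, 10.0), r)
        assert d == pytest.approx(math.sqrt(2 * 0.05**2), abs=1e-6)  # 0.070711

    def test_identical_peaks_zero(self):
        r = NormalizationRanges(2.0, 20.0)
        assert peak_distance(Peak2D(1.0, 10.0), Peak2D(1.0, 10.0), r) == 0.0

    def test_symmetric(self):
        r = NormalizationRanges(3.0, 40.0)
        a, b = Peak2D(1.2, 14.0), Peak2D(2.7, 33.0)
        assert peak_distance(a, b, r) == pytest.approx(peak_distance(b, a, r))


class TestNearestDistance:
    def test_hand_case(self, three_peak_extract):
        r = NormalizationRanges(2.0, 20.0)
        m = nearest_distance(Peak2D(1.1, 11.0), three_peak_extract, r)
        assert m.target_index == 0
        assert m.d_as == pytest.approx(0.070711, abs=1e-6)

    def test_exact_hit_zero(self, three_peak_extract):
        r = shift_ranges(three_peak_extract)
        assert nearest_distance(Peak2D(2.0, 20.0), three_peak_extract, r).d_as == 0.0

    def test_tie_breaks_to_lowest_index(self):
        targets = PeakList([Peak2D(1.0, 10.0), Peak2D(5.0, 50.0), Peak2D(3.0, 10.0)])
        r = NormalizationRanges(1.0, 1.0)
        m = nearest_distance(Peak2D(2.0, 10.0), targets, r)  # equidistant to 0 and 2
        assert m.target_index == 0

    def test_empty_targets_error(self):
        with pytest.raises(ValueError):
            nearest_distance(Peak2D(1, 10), PeakList([]), NormalizationRanges(1, 1))

    def test_matches_brute_force_oracle(self):
        # 100 random (compound, extract) instances vs the exhaustive search
        rng = np.random.default_rng(123)
        for _ in range(100):
            extract = random_peak_list(rng, int(rng.integers(1, 300)))
            compound = random_peak_list(rng, int(rng.integers(1, 30)))
            ranges = shift_ranges(extract)
            comp = ReferenceCompound("c", compound)
            result = atomic_sort_match(comp, extract)
            for q, m in zip(compound, result.per_peak):
                idx, d = brute_force_nearest(q, extract, ranges)
                assert m.target_index == idx
                assert m.d_as == pytest.approx(d, abs=1e-12)


class TestAtomicSortMatch:
    def test_containment_gives_zero_median_full_fraction(self, three_peak_extract):
        comp = ReferenceCompound("sub", PeakList(list(three_peak_extract.peaks[:2])))
        m = atomic_sort_match(comp, three_peak_extract)
        assert m.median_das == 0.0
        assert (m.n_matched, m.n_total) == (2, 2)
        assert m.label == "present"

    def test_hand_arithmetic_median_and_fraction(self, three_peak_extract):
        comp = ReferenceCompound("c", PeakList([Peak2D(1.1, 11.0), Peak2D(2.9, 29.0)]))
        m = atomic_sort_match(comp, three_peak_extract)
        assert m.median_das == pytest.approx(0.070711, abs=1e-6)
        assert m.fraction == "2/2"
        assert m.label == "present"

    def test_report_row_format(self, three_peak_extract):
        comp = ReferenceCompound("c", PeakList([Peak2D(1.1, 11.0), Peak2D(2.9, 29.0)]))
        assert atomic_sort_match(comp, three_peak_extract).report_row() == "0.071, 2/2"

    def test_self_match_is_exactly_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pl = random_peak_list(rng, int(rng.integers(2, 50)))
            m = atomic_sort_match(ReferenceCompound("x", pl), pl)
            assert m.median_das == 0.0
            assert m.n_matched == m.n_total == len(pl)

    def test_even_count_median_is_mean_of_central_pair(self):
        extract = PeakList([Peak2D(0.0, 0.0), Peak2D(10.0, 160.0)])
        comp = ReferenceCompound(
            "c", PeakList([Peak2D(0.0, 0.0), Peak2D(1.0, 0.0)])
        )
        m = atomic_sort_match(comp, extract)
        assert m.median_das == pytest.approx(0.05)  # (0 + 0.1) / 2

    def test_affine_invariance(self):
        # h' = a*h + b, c' = s*c + d leaves all d_AS unchanged when the
        # normalization ranges are recomputed from the transformed extract
        rng = np.random.default_rng(99)
        for a, b, s, d in [(2.0, 1.0, 0.5, -3.0), (-1.5, 0.3, 3.0, 10.0)]:
            extract = random_peak_list(rng, 120)
            compound = random_peak_list(rng, 20)
            tx = lambda pl: PeakList(
                [Peak2D(a * p.h_shift + b, s * p.c_shift + d) for p in pl]
            )
            m1 = atomic_sort_match(ReferenceCompound("c", compound), extract)
            m2 = atomic_sort_match(ReferenceCompound("c", tx(compound)), tx(extract))
            for p1, p2 in zip(m1.per_peak, m2.per_peak):
                assert p2.d_as == pytest.approx(p1.d_as, abs=1e-9)

    def test_direction_is_compound_to_extract(self):
        # one compound peak vs a crowded extract scores near zero; the
        # reverse comparison (extract as compound) does not
        crowded = PeakList([Peak2D(float(h), float(10 * h)) for h in np.linspace(1, 9, 41)])
        single = PeakList([Peak2D(5.0, 50.0)])
        forward = atomic_sort_match(ReferenceCompound("c", single), crowded)
        reverse = atomic_sort_match(ReferenceCompound("c", crowded), single)
        assert forward.median_das == pytest.approx(0.0)
        assert reverse.median_das > forward.median_das

    def test_compound_range_source_switch(self):
        extract = PeakList([Peak2D(0.0, 0.0), Peak2D(4.0, 40.0)])
        compound = PeakList([Peak2D(0.0, 0.0), Peak2D(2.0, 20.0)])
        cfg = MatchConfig(range_source="compound")
        m = atomic_sort_match(ReferenceCompound("c", compound), extract, cfg)
        # nearest to (2, 20) is either extract peak at normalized distance
        # sqrt(1 + 1) with compound ranges (2, 20)
        assert max(p.d_as for p in m.per_peak) == pytest.approx(math.sqrt(2.0))

    def test_jitter_monotonicity_in_median(self):
        # mean median over seeds is nondecreasing in jitter sd
        means = []
        for sigma_h, sigma_c in [(0.0, 0.0), (0.01, 0.1), (0.05, 0.5)]:
            medians = []
            for seed in range(50):
                params = SimParams(
                    n_compounds=3,
                    jitter_h=sigma_h,
                    jitter_c=sigma_c,
                    dropout_prob=0.0,
                    n_decoys=0,
                    seed=seed,
                )
                db = simulate_reference_db(params)
                extract, _ = simulate_extract(db, db.names()[:1], params)
                m = atomic_sort_match(db[db.names()[0]], extract)
                medians.append(m.median_das)
            means.append(float(np.mean(medians)))
        assert means[0] <= means[1] <= means[2]


class TestClassifyMatch:
    @pytest.mark.parametrize(
        "median,expected",
        [
            (0.056, "present"),
            (0.142, "related"),
            (0.587, "nonspecific"),
            (0.0, "present"),
            (0.1, "related"),  # boundary: "less than 0.1" is present
            (0.2, "related"),  # boundary: 0.1 to 0.2 inclusive
            (0.2000001, "nonspecific"),
        ],
    )
    def test_thresholds(self, median, expected):
        assert classify_match(median) == expected

    def test_negative_median_rejected(self):
        with pytest.raises(ValueError):
            classify_match(-0.01)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(present_threshold=0.3, related_threshold=0.2)


class TestRankCompounds:
    def test_singleton_db(self, three_peak_extract):
        db = ReferenceDatabase(
            [ReferenceCompound("only", PeakList([Peak2D(1.0, 10.0)]))]
        )
        ranking = rank_compounds(db, three_peak_extract)
        assert [m.compound_name for m in ranking] == ["only"]

    def test_exact_copy_ranks_above_jittered_copy(self, three_peak_extract):
        rng = np.random.default_rng(3)
        jittered = PeakList(
            [
                Peak2D(p.h_shift + rng.normal(0, 0.05), p.c_shift + rng.normal(0, 0.5))
                for p in three_peak_extract
            ]
        )
        db = ReferenceDatabase(
            [
                ReferenceCompound("jittered", jittered),
                ReferenceCompound("exact", PeakList(list(three_peak_extract))),
            ]
        )
        ranking = rank_compounds(db, three_peak_extract)
        assert [m.compound_name for m in ranking] == ["exact", "jittered"]

    def test_present_compounds_rank_above_absent_at_sigma_zero(self):
        params = SimParams(
            n_compounds=6, jitter_h=0.0, jitter_c=0.0, dropout_prob=0.0,
            n_decoys=0, seed=17,
        )
        db = simulate_reference_db(params)
        present = db.names()[:3]
        extract, truth = simulate_extract(db, present, params)
        ranking = rank_compounds(db, extract)
        top = [m.compound_name for m in ranking[:3]]
        assert set(top) == set(present)
        assert all(m.median_das == 0.0 for m in ranking[:3])
        assert all(m.median_das > 0.0 for m in ranking[3:])

    def test_tie_breaks_by_fraction_then_name(self):
        extract = PeakList([Peak2D(1.0, 10.0), Peak2D(2.0, 20.0), Peak2D(8.0, 150.0)])
        db = ReferenceDatabase(
            [
                # both medians are 0; "b" matches 1/1, "a" only 2/3
                ReferenceCompound(
                    "a",
                    PeakList([Peak2D(1.0, 10.0), Peak2D(2.0, 20.0), Peak2D(9.9, 159.0)]),
                ),
                ReferenceCompound("b", PeakList([Peak2D(1.0, 10.0)])),
            ]
        )
        ranking = rank_compounds(db, extract)
        assert [m.median_das for m in ranking] == [0.0, 0.0]
        assert [m.compound_name for m in ranking] == ["b", "a"]
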