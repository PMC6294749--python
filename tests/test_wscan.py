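"""Valid-base masking, interval construction (with independent oracle),
enrichment scoring and candidate calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wchrom.covprof import Limits
from wchrom.wscan import (
    CandidateInterval,
    call_candidates,
    filter_intervals,
    scan_intervals,
    score_interval,
    score_intervals,
    valid_mask,
)

from conftest import profile_from_arrays

LIMITS = Limits(min_f=8, min_m=9, max_f=75, max_m=87)


def naive_scan(cf, cm, mask, V):
    """Independent single-pass reference: walk the boolean array, close an
    interval at V accumulated valid bases, trim to first/last valid base."""
    intervals = []
    current = []
    for i, ok in enumerate(mask):
        if ok:
            current.append(i)
        if len(current) == V:
            intervals.append(current)
            current = []
    if current:
        intervals.append(current)
    out = []
    for sites in intervals:
        out.append(
            dict(
                start=sites[0],
                end=sites[-1] + 1,
                n_valid=len(sites),
                mean_f=float(np.mean([cf[i] for i in sites])),
                mean_m=float(np.mean([cm[i] for i in sites])),
            )
        )
    return out


class TestValidMask:
    @pytest.mark.parametrize(
        "cf,cm,expected",
        [
            (30, 30, True),  # inside all limits
            (0, 0, False),  # below both lower limits
            (80, 10, False),  # above female upper limit: repeat exclusion
            (0, 10, True),  # condition 2 is an OR
            (10, 90, False),  # male upper limit is strict
            (8, 9, False),  # lower limits are strict (must exceed)
            (9, 0, True),
        ],
    )
    def test_validity_rule(self, cf, cm, expected):
        profile = profile_from_arrays([cf], [cm])
        assert bool(valid_mask(profile, LIMITS)["s"][0]) is expected


class TestScanIntervals:
    def test_valid_bases_partition_into_runs_of_v(self):
        cf = np.full(4000, 30)
        cm = np.full(4000, 30)
        mask = np.zeros(4000, dtype=bool)
        mask[1000:3500] = True  # 2500 valid bases
        profile = profile_from_arrays(cf, cm)
        ivs = scan_intervals(profile, {"s": mask}, V=1000)
        assert [iv.n_valid for iv in ivs] == [1000, 1000, 500]
        assert ivs[0].start == 1000 and ivs[-1].end == 3500

    def test_no_valid_bases_yields_no_intervals(self):
        profile = profile_from_arrays(np.zeros(100), np.zeros(100))
        assert scan_intervals(profile, {"s": np.zeros(100, dtype=bool)}, V=10) == []

    def test_boundaries_trimmed_to_valid_bases(self):
        mask = np.zeros(100, dtype=bool)
        mask[[10, 50, 90]] = True
        profile = profile_from_arrays(np.full(100, 30), np.full(100, 30))
        (iv,) = scan_intervals(profile, {"s": mask}, V=5)
        assert (iv.start, iv.end, iv.n_valid) == (10, 91, 3)

    @given(
        mask=st.lists(st.booleans(), min_size=1, max_size=400),
        V=st.integers(1, 50),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_oracle(self, mask, V, seed):
        rng = np.random.default_rng(seed)
        n = len(mask)
        cf = rng.integers(0, 100, n)
        cm = rng.integers(0, 100, n)
        profile = profile_from_arrays(cf, cm)
        got = scan_intervals(profile, {"s": np.array(mask)}, V=V)
        expected = naive_scan(cf, cm, mask, V)
        assert len(got) == len(expected)
        for iv, exp in zip(got, expected):
            assert (iv.start, iv.end, iv.n_valid) == (exp["start"], exp["end"], exp["n_valid"])
            assert iv.mean_f == pytest.approx(exp["mean_f"])
            assert iv.mean_m == pytest.approx(exp["mean_m"])

    @given(
        mask=st.lists(st.booleans(), min_size=1, max_size=400),
        V=st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_property(self, mask, V):
        # sum of n_valid over scanned intervals equals the valid-base count
        n = len(mask)
        profile = profile_from_arrays(np.full(n, 30), np.full(n, 30))
        ivs = scan_intervals(profile, {"s": np.array(mask)}, V=V)
        assert sum(iv.n_valid for iv in ivs) == sum(mask)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start  # non-overlapping, ordered


def test_means_over_all_bases_alternative():
    cf = np.array([10, 0, 10, 0, 10])
    cm = np.array([2, 0, 2, 0, 2])
    mask = np.array([True, False, True, False, True])
    profile = profile_from_arrays(cf, cm)
    (valid_iv,) = scan_intervals(profile, {"s": mask}, V=5)
    (all_iv,) = scan_intervals(profile, {"s": mask}, V=5, means_over="all")
    assert valid_iv.mean_f == pytest.approx(10.0)
    assert all_iv.mean_f == pytest.approx(6.0)  # zeros at invalid bases included
    with pytest.raises(ValueError):
        scan_intervals(profile, {"s": mask}, V=5, means_over="bogus")


def interval(mean_f, mean_m, span=1000, n_valid=1000):
    return CandidateInterval("s", 0, span, n_valid, mean_f, mean_m)


class TestScoreInterval:
    def test_fourfold_enrichment_scores_two(self):
        assert score_interval(interval(4, 1), adjustment=1.0).score == pytest.approx(2.0)

    def test_equal_means_score_zero(self):
        assert score_interval(interval(7, 7), adjustment=1.0).score == pytest.approx(0.0)

    def test_zero_male_substitution_half_read_over_span(self):
        iv = score_interval(interval(10, 0), adjustment=1.0, read_length=100)
        assert iv.zero_male
        assert iv.mean_m_adj == pytest.approx(0.05)
        assert iv.score == pytest.approx(math.log2(200))

    def test_adjustment_rescales_male_mean(self):
        iv = score_interval(interval(4, 2), adjustment=0.5)
        assert iv.score == pytest.approx(2.0)

    def test_both_means_zero_is_impossible_for_valid_interval(self):
        with pytest.raises(AssertionError):
            score_interval(interval(0, 0), adjustment=1.0)

    def test_antisymmetry_under_sex_exchange(self):
        # swapping the sex means and inverting the adjustment negates the score
        rng = np.random.default_rng(2)
        for _ in range(50):
            f, m = rng.uniform(0.5, 50, size=2)
            adj = rng.uniform(0.5, 2.0)
            fwd = score_interval(interval(f, m), adjustment=adj).score
            rev = score_interval(interval(m, f), adjustment=1 / adj).score
            assert fwd == pytest.approx(-rev)


class TestFilterIntervals:
    @pytest.mark.parametrize(
        "span,n_valid,kept",
        [
            (499, 400, False),  # fewer than 500 bases
            (10_000, 199, False),  # fewer than 200 valid bases
            (500, 200, True),  # boundary inclusive
            (501, 201, True),
        ],
    )
    def test_exclusion_rule(self, span, n_valid, kept):
        ivs = filter_intervals([interval(5, 5, span=span, n_valid=n_valid)])
        assert bool(ivs) is kept

    def test_order_preserved_and_subset(self):
        items = [interval(5, 5, span=s, n_valid=300) for s in (600, 499, 700, 800)]
        kept = filter_intervals(items)
        assert kept == [items[0], items[2], items[3]]


class TestCallCandidates:
    def scored(self, score, scaffold="s"):
        iv = CandidateInterval(scaffold, 0, 1000, 1000, 2**score, 1.0)
        return score_interval(iv, adjustment=1.0)

    def test_threshold_is_strict(self):
        report = call_candidates([self.scored(2.0)], threshold=2)
        assert report.n_intervals == 0
        report = call_candidates([self.scored(2.01)], threshold=2)
        assert report.n_intervals == 1

    def test_report_bookkeeping(self):
        ivs = [self.scored(3, "a"), self.scored(4, "a"), self.scored(5, "a"), self.scored(3, "b")]
        report = call_candidates(ivs)
        assert report.n_intervals == 4
        assert report.n_scaffolds == 2
        assert report.n_scaffolds_multi == 1
        assert report.total_span == sum(iv.span for iv in ivs)
        assert report.per_scaffold == {"a": 3, "b": 1}

    def test_zero_male_count_tracked(self):
        iv = score_interval(interval(10, 0), adjustment=1.0)
        assert call_candidates([iv]).n_zero_male == 1

    def test_unscored_intervals_rejected(self):
        with pytest.raises(ValueError):
            call_candidates([interval(4, 1)])


def test_score_intervals_maps_over_list():
    ivs = score_intervals([interval(4, 1), interval(2, 2)], adjustment=1.0)
    assert [iv.score for iv in ivs] == pytest.approx([2.0, 0.0])
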