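import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taprhythm as tr
from taprhythm.alignment import BeatState, UndefinedSummaryError
from conftest import make_onsets


def align(beats, taps, n_ready=0, **kw):
    train = tr.TapTrain("t", "tempo_change", np.asarray(taps, float))
    return tr.match_taps_to_beats(train, make_onsets(beats), n_ready_cue=n_ready, **kw)


class TestMatching:
    def test_unambiguous_nearest_beats(self):
        a = align([0, 500, 1000], [-60, 450, 1010])
        assert np.allclose(a.asynchrony, [-60, -50, 10])
        assert len(a.unmatched_taps) == 0

    def test_competing_taps_resolved_globally(self):
        # both taps sit 240 ms from beat 0; greedy assignment must agree with
        # the minimal-total-distance matching enumerated by brute force
        a = align([0, 500, 1000], [240, 260])
        assert a.asynchrony[0] == pytest.approx(240)
        assert a.asynchrony[1] == pytest.approx(-240)
        # brute-force oracle: all one-to-one eligible pairings
        beats, taps = [0, 500, 1000], [240, 260]
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(3), 2):
            if all(abs(taps[i] - beats[b]) <= 250 for i, b in enumerate(perm)):
                cost = sum(abs(taps[i] - beats[b]) for i, b in enumerate(perm))
                if cost < best_cost:
                    best, best_cost = perm, cost
        assert best == (0, 1)

    def test_taps_on_every_beat(self):
        beats = np.arange(0, 5000, 500)
        a = align(beats, beats)
        assert np.allclose(a.asynchrony, 0)
        assert len(a.unmatched_taps) == 0

    def test_window_excludes_distant_taps(self):
        a = align([0, 500, 1000], [1400.0])
        # 1400 is beyond half the 500-ms local IOI of every beat
        assert not a.matched.any()
        assert list(a.unmatched_taps) == [1400.0]

    def test_tie_broken_toward_earlier_beat(self):
        a = align([0, 500], [250.0])
        assert a.matched[0] and not a.matched[1]

    def test_empty_tap_list(self):
        a = align([0, 500, 1000], [])
        assert not a.matched.any()

    def test_ready_cue_beats_never_scored(self):
        beats = np.arange(0, 3000, 500)
        a = align(beats, beats, n_ready=4)
        assert list(a.state[:4]) == [BeatState.READY_CUE] * 4
        assert len(a.scored_asynchronies) == 2

    @given(shift=st.floats(-1e5, 1e5, allow_nan=False))
    @settings(max_examples=25, derandomize=True)
    def test_time_shift_invariance(self, shift):
        beats = np.arange(0, 5000, 500.0)
        taps = beats[1:] - 30.0
        a0 = align(beats, taps)
        a1 = align(beats + shift, taps + shift)
        valid = ~np.isnan(a0.asynchrony)
        assert np.allclose(a0.asynchrony[valid], a1.asynchrony[valid], atol=1e-6)


class TestOmitLeadingTaps:
    def test_first_k_matched_removed_from_scoring(self):
        beats = np.arange(0, 24000, 500.0)
        a = align(beats, beats - 20.0, n_ready=4)
        assert len(a.scored_asynchronies) == 44
        out = tr.omit_leading_taps(a, 3)
        assert len(out.scored_asynchronies) == 41
        assert (out.state == BeatState.OMITTED).sum() == 3
        assert not out.degenerate

    def test_k_zero_is_identity(self):
        beats = np.arange(0, 3000, 500.0)
        a = align(beats, beats)
        out = tr.omit_leading_taps(a, 0)
        assert np.array_equal(out.state, a.state)

    def test_underflow_flags_degenerate(self):
        a = align([0, 500, 1000, 1500], [0.0, 510.0])
        out = tr.omit_leading_taps(a, 3)
        assert out.degenerate
        assert len(out.scored_asynchronies) == 0

    def test_spurious_unmatched_tap_keeps_omission_budget(self):
        # an early tap far from any beat must not consume the omission count
        beats = np.arange(0, 4000, 500.0)
        taps = np.concatenate([[260.0], beats[1:] - 10.0])
        a = align(beats, taps)
        out = tr.omit_leading_taps(a, 3)
        assert (out.state == BeatState.OMITTED).sum() == 3
        assert np.isclose(out.scored_asynchronies, -10.0).all()


class TestAsynchronyStats:
    def test_constant_asynchronies(self):
        beats = np.arange(0, 2500, 500.0)
        a = align(beats, beats - 100.0)
        s = tr.trial_asynchrony_stats(a)
        assert s.mean_asynchrony == pytest.approx(-100.0)
        assert s.sd_asynchrony == pytest.approx(0.0)

    def test_two_point_sample_sd(self):
        a = align([0.0, 500.0], [-120.0, 420.0])
        s = tr.trial_asynchrony_stats(a)
        assert s.mean_asynchrony == pytest.approx(-100.0)
        assert s.sd_asynchrony == pytest.approx(28.284271247, abs=1e-6)

    def test_all_missing_raises(self):
        a = align([0, 500, 1000], [])
        with pytest.raises(UndefinedSummaryError):
            tr.trial_asynchrony_stats(a)

    def test_condition_grouping_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        summaries = [
            tr.AsynchronySummary(f"t{i}", cond, rng.normal(-90, 10), rng.uniform(5, 30), 40)
            for i, cond in enumerate(
                ["isochronous", "tempo_change", "random", "isochronous", "tempo_change"] * 3
            )
        ]
        got = tr.participant_condition_summary(summaries)
        for cond in ("isochronous", "tempo_change", "random"):
            grp = [s for s in summaries if s.condition == cond]
            assert got[cond]["mean_asynchrony"] == pytest.approx(
                sum(s.mean_asynchrony for s in grp) / len(grp)
            )
            assert got[cond]["sd_asynchrony"] == pytest.approx(
                sum(s.sd_asynchrony for s in grp) / len(grp)
            )
            assert got[cond]["n_trials"] == len(grp)

    def test_single_trial_identity(self):
        s = tr.AsynchronySummary("t", "isochronous", -90.0, 12.0, 40)
        got = tr.participant_condition_summary([s])
        assert got["isochronous"]["mean_asynchrony"] == -90.0
        assert "tempo_change" not in got


def aligned_with_gaps(miss_pattern, base=500.0, asyn=-20.0):
    """AlignedTrial over len(pattern) scored beats, missing where pattern is 1."""
    n = len(miss_pattern)
    beats = np.arange(n, dtype=float) * base
    taps = np.array(
        [beats[i] + asyn for i in range(n) if not miss_pattern[i]], dtype=float
    )
    return align(beats, taps)


class TestITISeries:
    def test_no_missing_is_tap_differences(self):
        a = aligned_with_gaps([0] * 10)
        s = tr.build_iti_series(a, None)
        assert not s.excluded and s.n_interpolated == 0
        assert np.allclose(s.itis, 500.0)
        assert len(s.itis) == len(s.scored_iois) == 9

    def test_single_gap_midpoint(self):
        # taps at 1000 and 2000 around one missing beat at 1500
        a = align([1000, 1500, 2000], [1000.0, 2000.0])
        s = tr.build_iti_series(a, None)
        assert s.n_interpolated == 1
        assert np.allclose(s.itis, [500.0, 500.0])

    def test_gap_interpolation_is_conservative(self):
        for pattern in ([0, 1, 1, 0, 0], [0, 1, 1, 1, 0, 0]):
            a = aligned_with_gaps(pattern)
            s = tr.build_iti_series(a, None)
            i0 = pattern.index(1) - 1
            i1 = len(pattern) - list(reversed(pattern)).index(1)
            gap_itis = s.itis[i0:i1]
            flank_diff = a.tap_onset[~np.isnan(a.tap_onset)][i0 + 1] - a.tap_onset[i0]
            assert gap_itis.sum() == pytest.approx(flank_diff)

    def test_leading_and_trailing_fills_copy_asynchrony(self):
        s = tr.build_iti_series(aligned_with_gaps([1, 1, 0, 0, 0, 1]), None)
        assert not s.excluded
        assert np.allclose(s.itis, 500.0)
        assert s.n_interpolated == 3

    def test_four_consecutive_misses_exclude(self):
        s = tr.build_iti_series(aligned_with_gaps([0, 1, 1, 1, 1, 0, 0]), None)
        assert s.excluded
        assert "4" in s.exclusion_reason

    def test_zero_matched_taps_excluded_with_reason(self):
        a = align([0, 500, 1000], [])
        s = tr.build_iti_series(a, None)
        assert s.excluded and s.exclusion_reason

    def test_length_matches_scored_iois(self):
        for pattern in ([0] * 8, [0, 1, 0, 0, 1, 1, 0, 0], [1, 0, 0, 0, 1, 0, 0, 1]):
            s = tr.build_iti_series(aligned_with_gaps(pattern), None)
            assert len(s.itis) == len(s.scored_iois) == len(pattern) - 1

    def test_exclusion_rule_exhaustive_over_patterns(self):
        # every miss pattern over 10 scored beats: excluded iff a run >= 4
        for bits in itertools.product([0, 1], repeat=10):
            s = tr.build_iti_series(aligned_with_gaps(list(bits)), None)
            runs = [len(r) for r in "".join(map(str, bits)).split("0") if r]
            expect = (max(runs) if runs else 0) > 3 or all(bits)
            assert s.excluded == expect, bits
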