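import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taprhythm as tr
from taprhythm.alignment import ITISeries
from taprhythm.prediction import UndefinedCorrelationError


def naive_pearson(x, y):
    """Independent two-pass covariance/variance oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def make_itis(iti, ioi, trial_id="t"):
    return ITISeries(trial_id, np.asarray(iti, float), 0, False,
                     scored_iois=np.asarray(ioi, float))


class TestPearsonAtLag:
    def test_self_correlation_is_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert tr.pearson_at_lag(x, x, 0) == pytest.approx(1.0)

    def test_lag_one_pairs_with_previous(self):
        # x[n] against y[n-1]: [2,3,4] vs [0,1,2] -> exactly linear
        assert tr.pearson_at_lag([1, 2, 3, 4], [0, 1, 2, 3], 1) == pytest.approx(1.0)

    def test_negative_lag_pairs_with_future(self):
        x, y = [0, 1, 2, 3], [1, 2, 3, 10]
        got = tr.pearson_at_lag(x, y, -1)
        assert got == pytest.approx(naive_pearson(x[:3], y[1:]))

    @pytest.mark.parametrize("x, y, lag", [
        ([1, 2, 3], [3, 3, 3], 0),       # constant y
        ([5, 5, 5, 5], [1, 2, 3, 4], 0),  # constant x
        ([1, 2, 3], [1, 2, 3], 1),        # only 2 overlapping pairs
    ])
    def test_degenerate_inputs_raise(self, x, y, lag):
        with pytest.raises(UndefinedCorrelationError):
            tr.pearson_at_lag(x, y, lag)

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(5, 30)
            x, y = rng.normal(size=n), rng.normal(size=n)
            lag = int(rng.integers(0, 3))
            got = tr.pearson_at_lag(x, y, lag)
            exp = naive_pearson(x[lag:], y[: n - lag] if lag else y)
            assert got == pytest.approx(exp, abs=1e-12)

    @given(scale=st.floats(0.1, 100), shift=st.floats(-1e4, 1e4))
    @settings(max_examples=30, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = tr.pearson_at_lag(x, y, 1)
        assert tr.pearson_at_lag(scale * x + shift, scale * y + shift, 1) == pytest.approx(
            base, abs=1e-9
        )


class TestLag1Autocorrelation:
    def test_linear_trend_is_one(self):
        assert tr.lag1_autocorrelation(np.arange(10.0)) == pytest.approx(1.0)

    def test_alternating_is_minus_one(self):
        got = tr.lag1_autocorrelation([400, 600, 400, 600, 400, 600])
        assert got == pytest.approx(-1.0)

    def test_constant_series_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            tr.lag1_autocorrelation([500.0] * 10)

    def test_short_series_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            tr.lag1_autocorrelation([1.0, 2.0, 3.0])


class TestPredictionTrackingRatio:
    def test_perfect_prediction(self, tempo_seq):
        ioi = tempo_seq.non_ready_iois
        pt = tr.prediction_tracking_ratio(make_itis(ioi, ioi))
        assert pt.r_lag0 == pytest.approx(1.0)
        assert pt.r_lag1 == pytest.approx(pt.ioi_lag1_autocorr, abs=1e-12)
        assert pt.ratio == pytest.approx(1.0 / pt.ioi_lag1_autocorr, abs=1e-9)
        assert pt.valid and pt.ratio > 1

    def test_pure_tracking(self, tempo_seq):
        ioi = tempo_seq.non_ready_iois
        iti = np.concatenate([[ioi[0]], ioi[:-1]])  # ITI echoes previous IOI
        pt = tr.prediction_tracking_ratio(make_itis(iti, ioi))
        assert pt.r_lag1 == pytest.approx(1.0)
        assert pt.valid and pt.ratio < 1

    def test_nonpositive_lag1_marked_invalid(self):
        ioi = np.array([400, 500, 600, 500, 400, 500, 600, 500.0])
        iti = -np.concatenate([[ioi[0]], ioi[:-1]])  # anti-tracking
        pt = tr.prediction_tracking_ratio(make_itis(iti, ioi))
        assert not pt.valid and np.isnan(pt.ratio)
        assert "lag-1" in pt.invalid_reason

    def test_uncorrelated_iti_usually_invalid(self, tempo_seq):
        # with random ITIs the lag-1 cross-correlation is a null statistic
        # whose sign is a fair coin, so roughly half the draws are invalid
        rng = np.random.default_rng(0)
        ioi = tempo_seq.non_ready_iois
        n_invalid = sum(
            not tr.prediction_tracking_ratio(
                make_itis(rng.normal(500, 25, len(ioi)), ioi)
            ).valid
            for _ in range(1000)
        )
        assert 400 <= n_invalid <= 600

    def test_excluded_trial_refused(self):
        s = ITISeries("t", np.empty(0), 0, True, "missed 5 consecutive taps")
        with pytest.raises(ValueError, match="excluded"):
            tr.prediction_tracking_ratio(s)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="count"):
            tr.prediction_tracking_ratio(make_itis([1, 2, 3], [1, 2, 3, 4]))

    def test_scale_shift_invariance(self, tempo_seq):
        ioi = tempo_seq.non_ready_iois
        rng = np.random.default_rng(3)
        iti = ioi + rng.normal(0, 5, len(ioi))
        a = tr.prediction_tracking_ratio(make_itis(iti, ioi))
        b = tr.prediction_tracking_ratio(make_itis(2.0 * iti + 50, 2.0 * ioi + 50))
        assert b.r_lag0 == pytest.approx(a.r_lag0, abs=1e-12)
        assert b.r_lag1 == pytest.approx(a.r_lag1, abs=1e-12)
        assert b.ratio == pytest.approx(a.ratio, abs=1e-9)


class TestParticipantRatio:
    def pt(self, ratio, valid=True, r0=0.9, r1=0.8):
        return tr.PTResult("t", r0, r1, 0.9, ratio, valid, 40, 39)

    def test_mean_and_median_modes(self):
        results = [self.pt(1.2), self.pt(1.4), self.pt(2.0)]
        assert tr.participant_ratio(results, "mean").ratio == pytest.approx(46 / 30)
        assert tr.participant_ratio(results, "median").ratio == pytest.approx(1.4)

    def test_ratio_of_means_mode(self):
        results = [self.pt(np.nan, r0=0.9, r1=0.6), self.pt(np.nan, r0=0.3, r1=0.6)]
        got = tr.participant_ratio(results, "ratio_of_means")
        assert got.ratio == pytest.approx(0.6 / 0.6)

    def test_single_valid_trial_identity(self):
        got = tr.participant_ratio([self.pt(0.9)], "median")
        assert got.ratio == pytest.approx(0.9) and got.usable

    def test_invalid_trials_ignored_and_all_invalid_unusable(self):
        mixed = [self.pt(1.2), self.pt(np.nan, valid=False)]
        assert tr.participant_ratio(mixed, "median").n_valid_trials == 1
        out = tr.participant_ratio([self.pt(np.nan, valid=False)], "median")
        assert not out.usable and np.isnan(out.ratio)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            tr.participant_ratio([self.pt(1.0)], "mode_of_ratios")
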