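"""Tap-to-beat alignment, asynchrony statistics, and the inter-tap-interval series.

A tap is scored against the *closest* pacing beat.  Because "closest" is
ill-posed when taps double up or fall between beats, matching is a greedy
global assignment over all tap-beat pairs within half a local IOI of each
other, taken in order of increasing absolute time difference (ties go to the
earlier beat).  Ready-cue beats are never scored: listeners receive a visual
countdown and do not tap to them.  The first few matched taps of a trial are
dropped to discard the rest-to-tapping transient.

For the prediction/tracking ratio the inter-tap-interval (ITI) series must
match the scored IOI series in length, so short runs of missed taps are filled
by linearly interpolating tap onsets between the flanking real taps; a trial
with more than ``max_interp_run`` (3) consecutive misses is excluded instead,
because interpolation over such a gap is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import OnsetTrain

__all__ = [
    "TapTrain",
    "BeatState",
    "AlignedTrial",
    "AsynchronySummary",
    "ITISeries",
    "UndefinedSummaryError",
    "match_taps_to_beats",
    "omit_leading_taps",
    "trial_asynchrony_stats",
    "participant_condition_summary",
    "build_iti_series",
]


class UndefinedSummaryError(ValueError):
    """Raised when a trial has too few scored asynchronies for a summary."""


@dataclass
class TapTrain:
    """Tap-onset times (ms from trial start) for one trial."""

    trial_id: str
    condition: str
    taps: np.ndarray
    participant_id: str | None = None
    run: int | None = None

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if len(self.taps) and np.any(np.diff(self.taps) <= 0):
            raise ValueError(f"trial {self.trial_id}: tap times not strictly increasing")


class BeatState:
    """Scoring status of one beat."""

    READY_CUE = "ready_cue"  # never scored
    OMITTED = "omitted"      # matched tap dropped by the leading-tap rule
    SCORED = "scored"


@dataclass
class AlignedTrial:
    """Taps matched to beats with per-beat asynchronies.

    ``tap_onset``/``asynchrony`` are NaN where the beat has no matched tap.
    ``state`` distinguishes ready-cue and omitted beats (unscored by rule)
    from scored beats, which may be matched or missing.
    """

    trial_id: str
    condition: str
    beat_onset: np.ndarray
    local_ioi: np.ndarray
    tap_onset: np.ndarray
    asynchrony: np.ndarray
    state: np.ndarray  # of BeatState strings
    unmatched_taps: np.ndarray
    n_omitted_leading_taps: int = 0
    degenerate: bool = False

    @property
    def n_beats(self) -> int:
        return len(self.beat_onset)

    @property
    def matched(self) -> np.ndarray:
        return ~np.isnan(self.tap_onset)

    @property
    def scored_mask(self) -> np.ndarray:
        return self.state == BeatState.SCORED

    @property
    def scored_asynchronies(self) -> np.ndarray:
        a = self.asynchrony[self.scored_mask]
        return a[~np.isnan(a)]


@dataclass
class AsynchronySummary:
    trial_id: str
    condition: str
    mean_asynchrony: float
    sd_asynchrony: float
    n_matched: int
    participant_id: str | None = None


@dataclass
class ITISeries:
    """Length-matched ITI series for one trial, after gap interpolation."""

    trial_id: str
    itis: np.ndarray
    n_interpolated: int
    excluded: bool
    exclusion_reason: str | None = None
    scored_iois: np.ndarray = field(default_factory=lambda: np.empty(0))


def match_taps_to_beats(
    taps: TapTrain,
    onsets: OnsetTrain,
    n_ready_cue: int = 4,
    window_fraction: float = 0.5,
) -> AlignedTrial:
    """Greedy global nearest-beat matching.

    Candidate pairs are (tap, beat) with |tap - beat| <= ``window_fraction``
    times the beat's local IOI; pairs are consumed in order of increasing
    distance, ties broken toward the earlier beat, and each tap and beat is
    used at most once.  Ready-cue beats can still capture stray taps (so such
    taps do not distort pacing-beat scoring) but are never scored.
    """
    beats = onsets.onsets
    local = onsets.local_ioi
    n_beats = len(beats)
    tap_times = taps.taps

    cand: list[tuple[float, int, int]] = []
    for ti, t in enumerate(tap_times):
        dists = np.abs(t - beats)
        for bi in np.flatnonzero(dists <= window_fraction * local):
            cand.append((dists[bi], bi, ti))
    cand.sort()

    tap_of_beat = np.full(n_beats, -1, dtype=int)
    beat_of_tap = np.full(len(tap_times), -1, dtype=int)
    for _, bi, ti in cand:
        if tap_of_beat[bi] == -1 and beat_of_tap[ti] == -1:
            tap_of_beat[bi] = ti
            beat_of_tap[ti] = bi

    tap_onset = np.full(n_beats, np.nan)
    matched = tap_of_beat >= 0
    tap_onset[matched] = tap_times[tap_of_beat[matched]]
    asynchrony = tap_onset - beats

    state = np.full(n_beats, BeatState.SCORED, dtype=object)
    state[:n_ready_cue] = BeatState.READY_CUE
    unmatched = tap_times[beat_of_tap == -1]
    return AlignedTrial(
        trial_id=taps.trial_id,
        condition=taps.condition,
        beat_onset=beats.astype(float),
        local_ioi=local.astype(float),
        tap_onset=tap_onset,
        asynchrony=asynchrony,
        state=state,
        unmatched_taps=unmatched,
    )


def omit_leading_taps(aligned: AlignedTrial, k: int = 3) -> AlignedTrial:
    """Drop the first ``k`` matched pacing taps from scoring.

    The omitted beats are marked distinct from missing ones; if fewer than
    ``k`` matched taps exist the trial is flagged degenerate.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    state = aligned.state.copy()
    candidates = np.flatnonzero(aligned.matched & (state == BeatState.SCORED))
    to_omit = candidates[:k]
    state[to_omit] = BeatState.OMITTED
    out = AlignedTrial(
        trial_id=aligned.trial_id,
        condition=aligned.condition,
        beat_onset=aligned.beat_onset,
        local_ioi=aligned.local_ioi,
        tap_onset=aligned.tap_onset,
        asynchrony=aligned.asynchrony,
        state=state,
        unmatched_taps=aligned.unmatched_taps,
        n_omitted_leading_taps=len(to_omit),
        degenerate=len(candidates) < k,
    )
    return out


def trial_asynchrony_stats(aligned: AlignedTrial) -> AsynchronySummary:
    """Mean and sample SD (n-1 denominator) of the scored asynchronies."""
    a = aligned.scored_asynchronies
    if len(a) < 2:
        raise UndefinedSummaryError(
            f"trial {aligned.trial_id}: {len(a)} scored asynchronies (< 2)"
        )
    return AsynchronySummary(
        trial_id=aligned.trial_id,
        condition=aligned.condition,
        mean_asynchrony=float(np.mean(a)),
        sd_asynchrony=float(np.std(a, ddof=1)),
        n_matched=int(len(a)),
    )


def participant_condition_summary(
    summaries: list[AsynchronySummary],
) -> dict[str, dict[str, float]]:
    """Unweighted per-condition average of trial means and SDs.

    Conditions with no usable trial are absent from the result, not zero.
    """
    out: dict[str, dict[str, float]] = {}
    by_cond: dict[str, list[AsynchronySummary]] = {}
    for s in summaries:
        by_cond.setdefault(s.condition, []).append(s)
    for cond, group in by_cond.items():
        out[cond] = {
            "mean_asynchrony": float(np.mean([s.mean_asynchrony for s in group])),
            "sd_asynchrony": float(np.mean([s.sd_asynchrony for s in group])),
            "n_trials": len(group),
        }
    return out


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True in ``missing``."""
    runs = []
    i = 0
    n = len(missing)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def build_iti_series(
    aligned: AlignedTrial,
    onsets: OnsetTrain | None = None,
    max_interp_run: int = 3,
) -> ITISeries:
    """ITI series over the scored beats, with missed-tap interpolation.

    Interior runs of <= ``max_interp_run`` missing taps are filled by equal
    spacing between the flanking real tap onsets; leading/trailing runs copy
    the adjacent matched beat's asynchrony onto the beat onset.  Any missing
    run longer than ``max_interp_run`` excludes the trial.  The resulting ITI
    count equals the scored IOI count, the precondition for the
    prediction/tracking ratio.
    """
    scored = np.flatnonzero(aligned.scored_mask)
    if len(scored) < 2:
        return ITISeries(
            aligned.trial_id, np.empty(0), 0, True, "fewer than 2 scored beats"
        )
    tap = aligned.tap_onset[scored].copy()
    beat = aligned.beat_onset[scored]
    missing = np.isnan(tap)

    if missing.all():
        return ITISeries(aligned.trial_id, np.empty(0), 0, True, "no matched taps")

    runs = _missing_runs(missing)
    too_long = [r for r in runs if r[1] > max_interp_run]
    if too_long:
        longest = max(r[1] for r in too_long)
        return ITISeries(
            aligned.trial_id,
            np.empty(0),
            0,
            True,
            f"missed {longest} consecutive taps (> {max_interp_run})",
        )

    n_interp = int(missing.sum())
    m = len(tap)
    for start, length in runs:
        stop = start + length  # first index after the run
        if start == 0:
            # leading: copy the first matched asynchrony onto the beat onsets
            asyn = tap[stop] - beat[stop]
            tap[:stop] = beat[:stop] + asyn
        elif stop == m:
            asyn = tap[start - 1] - beat[start - 1]
            tap[start:] = beat[start:] + asyn
        else:
            filled = np.linspace(tap[start - 1], tap[stop], length + 2)[1:-1]
            tap[start:stop] = filled

    itis = np.diff(tap)
    scored_iois = np.diff(beat)
    return ITISeries(
        aligned.trial_id,
        itis,
        n_interp,
        False,
        None,
        scored_iois=scored_iois,
    )
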