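"""Lagged cross-correlations and the prediction/tracking ratio.

The ratio of the lag-0 to the lag-1 cross-correlation between the inter-tap
interval (ITI) and inter-onset interval (IOI) series indexes whether a tapper
*predicts* upcoming intervals (current ITI matches current IOI; ratio > 1) or
*tracks* past ones (current ITI echoes the previous IOI; ratio < 1).  Both raw
correlations share the sequence's lag-1 autocorrelation as their theoretical
lower limit — under optimal prediction the lag-1 cross-correlation approaches
it, under maximal tracking the lag-0 does — so the ratio cancels the
sequence-specific limit and is comparable across trials with different tempo
patterns.  It is only defined for tempo-change trials: an isochronous IOI
series is constant (correlations undefined) and a shuffled one carries no
lag-1 structure to track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import ITISeries

__all__ = [
    "UndefinedCorrelationError",
    "PTResult",
    "ParticipantRatio",
    "pearson_at_lag",
    "lag1_autocorrelation",
    "prediction_tracking_ratio",
    "participant_ratio",
]

AGGREGATION_MODES = ("mean", "median", "ratio_of_means")


class UndefinedCorrelationError(ValueError):
    """Constant input or too few overlapping pairs for a Pearson correlation."""


@dataclass
class PTResult:
    """Per-trial prediction/tracking correlations and their ratio."""

    trial_id: str
    r_lag0: float
    r_lag1: float
    ioi_lag1_autocorr: float
    ratio: float  # NaN when invalid
    valid: bool
    n_pairs_lag0: int
    n_pairs_lag1: int
    invalid_reason: str | None = None


@dataclass
class ParticipantRatio:
    participant_id: str | None
    ratio: float  # NaN when unusable
    usable: bool
    n_valid_trials: int
    n_trials: int
    aggregation: str


def pearson_at_lag(x, y, lag: int = 0) -> float:
    """Pearson correlation of ``x[n]`` with ``y[n - lag]`` over the overlap.

    Positive ``lag`` correlates x against an earlier (right-shifted) y.
    Requires >= 3 overlapping pairs and non-constant windows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if lag >= 0:
        xw, yw = x[lag:], y[: len(y) - lag if lag else len(y)]
    else:
        xw, yw = x[: len(x) + lag], y[-lag:]
    n = min(len(xw), len(yw))
    xw, yw = xw[:n], yw[:n]
    if n < 3:
        raise UndefinedCorrelationError(f"only {n} overlapping pairs (< 3)")
    if np.ptp(xw) == 0 or np.ptp(yw) == 0:
        raise UndefinedCorrelationError("constant series in the overlap window")
    xc = xw - xw.mean()
    yc = yw - yw.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def lag1_autocorrelation(s) -> float:
    """Lag-1 autocorrelation: ``pearson_at_lag(s, s, 1)``."""
    s = np.asarray(s, dtype=float)
    if len(s) < 4:
        raise UndefinedCorrelationError("need >= 4 elements for lag-1 autocorrelation")
    return pearson_at_lag(s, s, 1)


def prediction_tracking_ratio(itis: ITISeries, iois=None) -> PTResult:
    """Lag-0 / lag-1 cross-correlation ratio for one tempo-change trial.

    ``iois`` defaults to the scored IOIs stored on the ITI series.  Trials
    with a non-positive lag-1 correlation (no tracking structure to normalise
    by) are marked invalid rather than yielding a negative or exploding ratio.
    """
    if itis.excluded:
        raise ValueError(
            f"trial {itis.trial_id} is excluded ({itis.exclusion_reason}); "
            "no ratio can be computed"
        )
    iti = np.asarray(itis.itis, dtype=float)
    ioi = np.asarray(itis.scored_iois if iois is None else iois, dtype=float)
    if len(iti) != len(ioi):
        raise ValueError(
            f"trial {itis.trial_id}: ITI count {len(iti)} != IOI count {len(ioi)}"
        )

    def guarded(f, *args):
        try:
            return f(*args), None
        except UndefinedCorrelationError as e:
            return np.nan, str(e)

    r0, err0 = guarded(pearson_at_lag, iti, ioi, 0)
    r1, err1 = guarded(pearson_at_lag, iti, ioi, 1)
    ac1, _ = guarded(lag1_autocorrelation, ioi)

    reason = None
    if err0 or err1:
        reason = err0 or err1
    elif r1 <= 0:
        reason = f"lag-1 cross-correlation {r1:.3f} <= 0"
    valid = reason is None
    ratio = r0 / r1 if valid else np.nan
    return PTResult(
        trial_id=itis.trial_id,
        r_lag0=r0,
        r_lag1=r1,
        ioi_lag1_autocorr=ac1,
        ratio=ratio,
        valid=valid,
        n_pairs_lag0=len(iti),
        n_pairs_lag1=max(len(iti) - 1, 0),
        invalid_reason=reason,
    )


def participant_ratio(
    results: list[PTResult],
    aggregation: str = "median",
    participant_id: str | None = None,
) -> ParticipantRatio:
    """Aggregate valid per-trial ratios into one per-participant value.

    Modes: ``median`` (default; the per-trial ratio is a heavy-tailed
    quotient, so the median is robust), ``mean``, or ``ratio_of_means`` (mean lag-0
    correlation over mean lag-1 correlation of the valid trials).
    """
    if aggregation not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    valid = [r for r in results if r.valid]
    if not valid:
        return ParticipantRatio(participant_id, np.nan, False, 0, len(results), aggregation)
    if aggregation == "mean":
        value = float(np.mean([r.ratio for r in valid]))
    elif aggregation == "median":
        value = float(np.median([r.ratio for r in valid]))
    else:
        value = float(np.mean([r.r_lag0 for r in valid]) / np.mean([r.r_lag1 for r in valid]))
    return ParticipantRatio(participant_id, value, True, len(valid), len(results), aggregation)
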