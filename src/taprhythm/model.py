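"""Model/results interface tying the pipeline together.

:class:`SynchronyModel` holds tap logs and their pacing sequences plus the
scoring policy; :meth:`SynchronyModel.fit` runs alignment, asynchrony
statistics, ITI construction, and the prediction/tracking ratio for every
trial and returns a :class:`SynchronyResults` carrying per-trial and
per-participant tables, condition ANOVAs, ratio-asynchrony correlations, a
text ``summary()``, and scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import group_stats
from .alignment import (
    TapTrain,
    UndefinedSummaryError,
    build_iti_series,
    match_taps_to_beats,
    omit_leading_taps,
    trial_asynchrony_stats,
)
from .io import SessionConfig, read_sequences, read_tap_log
from .prediction import participant_ratio, prediction_tracking_ratio
from .stimulus import IOISequence, beat_onsets

__all__ = ["SynchronyModel", "SynchronyResults"]

CONDITION_ORDER = ["isochronous", "tempo_change", "random"]


class SynchronyModel:
    """Tapping-synchronization analysis model.

    Parameters
    ----------
    taps
        Tap trains, one per trial.
    sequences
        Mapping from trial_id to the trial's pacing sequence.
    config
        Scoring policy (matching window fraction, leading-tap omission count,
        maximum interpolated gap, ratio aggregation mode).
    """

    def __init__(
        self,
        taps: list[TapTrain],
        sequences: dict[str, IOISequence],
        config: SessionConfig | None = None,
    ):
        self.taps = taps
        self.sequences = sequences
        self.config = config or SessionConfig()
        missing = [t.trial_id for t in taps if t.trial_id not in sequences]
        if missing:
            raise ValueError(f"no pacing sequence for trials: {missing[:5]}")

    @classmethod
    def from_csv(
        cls,
        tap_path,
        sequence_path,
        config: SessionConfig | None = None,
    ) -> "SynchronyModel":
        return cls(read_tap_log(tap_path), read_sequences(sequence_path), config)

    @classmethod
    def from_dataset(cls, dataset, config: SessionConfig | None = None) -> "SynchronyModel":
        """Build from a :class:`~taprhythm.simulate.SyntheticDataset`."""
        return cls(list(dataset.taps), dict(dataset.sequences), config)

    def fit(self) -> "SynchronyResults":
        cfg = self.config
        trial_rows = []
        ratio_inputs: dict[str, list] = {}
        summaries: dict[str, list] = {}
        n_excluded = n_degenerate = 0
        for tap in self.taps:
            seq = self.sequences[tap.trial_id]
            onsets = beat_onsets(seq)
            aligned = match_taps_to_beats(
                tap, onsets, n_ready_cue=seq.n_ready_cue, window_fraction=cfg.window_fraction
            )
            aligned = omit_leading_taps(aligned, cfg.omit_first_k)
            pid = tap.participant_id or "P"
            row = {
                "participant_id": pid,
                "trial_id": tap.trial_id,
                "condition": tap.condition,
                "n_matched": int(aligned.matched.sum()),
                "n_unmatched_taps": len(aligned.unmatched_taps),
                "degenerate": aligned.degenerate,
                "excluded": False,
                "exclusion_reason": "",
                "mean_asynchrony": np.nan,
                "sd_asynchrony": np.nan,
                "r_lag0": np.nan,
                "r_lag1": np.nan,
                "autocorr1": np.nan,
                "ratio": np.nan,
                "ratio_valid": False,
                "iti_ioi_matched": np.nan,
            }
            try:
                s = trial_asynchrony_stats(aligned)
                s.participant_id = pid
                summaries.setdefault(pid, []).append(s)
                row["mean_asynchrony"] = s.mean_asynchrony
                row["sd_asynchrony"] = s.sd_asynchrony
            except UndefinedSummaryError:
                row["degenerate"] = True
            if tap.condition == "tempo_change":
                itis = build_iti_series(aligned, onsets, cfg.max_interp_run)
                # a trial needed no interpolation iff the raw ITI count
                # already matched the scored IOI count
                row["iti_ioi_matched"] = (not itis.excluded) and itis.n_interpolated == 0
                if itis.excluded:
                    row["excluded"] = True
                    row["exclusion_reason"] = itis.exclusion_reason or ""
                else:
                    pt = prediction_tracking_ratio(itis)
                    ratio_inputs.setdefault(pid, []).append(pt)
                    row.update(
                        r_lag0=pt.r_lag0,
                        r_lag1=pt.r_lag1,
                        autocorr1=pt.ioi_lag1_autocorr,
                        ratio=pt.ratio,
                        ratio_valid=pt.valid,
                    )
            # exclusion accounting: each trial counts exactly once
            if row["excluded"]:
                n_excluded += 1
            elif row["degenerate"]:
                n_degenerate += 1
            trial_rows.append(row)

        trial_table = pd.DataFrame(trial_rows)
        part_rows = []
        for pid in sorted({r["participant_id"] for r in trial_rows}):
            pr = participant_ratio(
                ratio_inputs.get(pid, []), cfg.aggregation, participant_id=pid
            )
            prow = {
                "participant_id": pid,
                "ratio": pr.ratio,
                "ratio_usable": pr.usable,
                "n_valid_ratio_trials": pr.n_valid_trials,
            }
            by_cond: dict[str, list] = {}
            for s in summaries.get(pid, []):
                by_cond.setdefault(s.condition, []).append(s)
            for cond in CONDITION_ORDER:
                group = by_cond.get(cond, [])
                prow[f"mean_asynchrony_{cond}"] = (
                    float(np.mean([s.mean_asynchrony for s in group])) if group else np.nan
                )
                prow[f"sd_asynchrony_{cond}"] = (
                    float(np.mean([s.sd_asynchrony for s in group])) if group else np.nan
                )
            part_rows.append(prow)
        participant_table = pd.DataFrame(part_rows)

        n_input = len(self.taps)
        return SynchronyResults(
            model=self,
            trial_table=trial_table,
            participant_table=participant_table,
            n_input_trials=n_input,
            n_excluded=n_excluded,
            n_degenerate=n_degenerate,
            n_scored=n_input - n_excluded - n_degenerate,
            config_hash=cfg.config_hash(),
        )


@dataclass
class SynchronyResults:
    """Fitted results: per-trial and per-participant tables plus group tests."""

    model: SynchronyModel
    trial_table: pd.DataFrame
    participant_table: pd.DataFrame
    n_input_trials: int
    n_excluded: int
    n_degenerate: int
    n_scored: int
    config_hash: str = ""

    def condition_matrix(self, metric: str = "sd_asynchrony") -> pd.DataFrame:
        """Complete participants x conditions matrix of a per-participant metric."""
        cols = [f"{metric}_{c}" for c in CONDITION_ORDER]
        m = self.participant_table.set_index("participant_id")[cols].dropna()
        m.columns = CONDITION_ORDER
        return m

    def anova(self, metric: str = "sd_asynchrony", **kwargs) -> group_stats.AnovaResult:
        """One-way RM-ANOVA of ``metric`` across the three conditions."""
        return group_stats.rm_anova_gg(self.condition_matrix(metric), **kwargs)

    def correlation(
        self, metric: str = "mean_asynchrony", condition: str = "isochronous"
    ) -> group_stats.CorrelationResult:
        """Pearson test of the prediction/tracking ratio against a metric."""
        t = self.participant_table
        mask = t["ratio_usable"] & t[f"{metric}_{condition}"].notna()
        return group_stats.pearson_test(
            t.loc[mask, "ratio"], t.loc[mask, f"{metric}_{condition}"]
        )

    def exclusion_report(self) -> str:
        n_tc = int((self.trial_table["condition"] == "tempo_change").sum())
        pct = 100.0 * self.n_excluded / n_tc if n_tc else 0.0
        matched = self.trial_table["iti_ioi_matched"].dropna()
        pct_matched = 100.0 * matched.mean() if len(matched) else np.nan
        return (
            f"{self.n_excluded} out of {n_tc} tempo-change trials ({pct:.1f}%) "
            f"excluded (>3 consecutive missed taps); "
            f"{pct_matched:.1f}% of tempo-change trials had matched ITI/IOI "
            f"counts without interpolation; "
            f"{self.n_input_trials} trials = {self.n_scored} scored + "
            f"{self.n_excluded} excluded + {self.n_degenerate} degenerate"
        )

    def summary(self) -> str:
        lines = [
            "Auditory-motor synchronization analysis",
            "=" * 54,
            f"participants: {len(self.participant_table)}   "
            f"trials: {self.n_input_trials}   config: {self.config_hash}",
            self.exclusion_report(),
            "",
            "Per-condition asynchrony (cohort means):",
        ]
        for cond in CONDITION_ORDER:
            m = self.participant_table[f"mean_asynchrony_{cond}"].mean()
            s = self.participant_table[f"sd_asynchrony_{cond}"].mean()
            if np.isfinite(m):
                lines.append(f"  {cond:13s} mean = {m:8.1f} ms   SD = {s:6.1f} ms")
        usable = self.participant_table[self.participant_table["ratio_usable"]]
        if len(usable):
            lines += [
                "",
                f"Prediction/tracking ratio ({self.model.config.aggregation} over "
                f"valid tempo-change trials):",
                f"  median {usable['ratio'].median():.3f}   "
                f"range [{usable['ratio'].min():.3f}, {usable['ratio'].max():.3f}]   "
                f"n = {len(usable)}",
            ]
        try:
            a = self.anova("sd_asynchrony")
            lines += ["", f"SD of asynchronies across conditions: {a}"]
        except ValueError:
            pass
        for metric, label in (
            ("mean_asynchrony", "ratio vs isochronous mean asynchrony"),
            ("sd_asynchrony", "ratio vs isochronous SD of asynchronies"),
        ):
            try:
                c = self.correlation(metric)
                lines.append(f"{label}: {c}")
            except ValueError:
                pass
        return "\n".join(lines)

    def plot_ratio_scatter(self, metric: str = "mean_asynchrony", ax=None):
        """Scatter of per-participant ratio against an isochronous metric,
        with the least-squares trend line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3.2))
        t = self.participant_table
        mask = t["ratio_usable"] & t[f"{metric}_isochronous"].notna()
        x = t.loc[mask, "ratio"].to_numpy()
        y = t.loc[mask, f"{metric}_isochronous"].to_numpy()
        ax.scatter(x, y, s=24, color="tab:blue")
        if len(x) >= 2 and np.ptp(x) > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 2)
            ax.plot(xs, a + b * xs, color="tab:red", lw=1)
        ax.set_xlabel("prediction/tracking ratio")
        ax.set_ylabel(f"isochronous {metric.replace('_', ' ')} (ms)")
        return ax

    def plot_condition_sd(self, ax=None):
        """Per-participant SD of asynchronies by condition (study Fig. 2C layout)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3.6, 3.2))
        m = self.condition_matrix("sd_asynchrony")
        for _, row in m.iterrows():
            ax.plot(range(len(CONDITION_ORDER)), row.values, color="0.8", lw=0.7)
        ax.errorbar(
            range(len(CONDITION_ORDER)),
            m.mean(),
            yerr=m.std(ddof=1) / np.sqrt(len(m)),
            fmt="o-",
            color="tab:red",
        )
        ax.set_xticks(range(len(CONDITION_ORDER)), ["I", "T", "R"])
        ax.set_ylabel("SD of asynchronies (ms)")
        return ax

    def tables(self) -> dict[str, pd.DataFrame]:
        """Result tables in the shapes the CSV writers expect."""
        return {
            "trial_results": self.trial_table,
            "participant_summary": self.participant_table,
        }
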