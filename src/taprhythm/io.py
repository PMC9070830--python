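"""File formats and configuration.

All times are real-valued milliseconds from trial start (trial start = onset
of the first ready-cue tone).  CSVs are comma-delimited UTF-8 with a header
row and '.' decimal separator.

Schemas
-------
sequences.csv : one row per IOI
    trial_id, condition, index, ioi_ms, segment_kind
    (a JSON sidecar ``sequences.json`` stores the stimulus spec and seeds)
taps.csv : one row per tap
    participant_id, run, trial_id, condition, tap_time_ms
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import TapTrain
from .stimulus import IOISequence, Segment, TempoChangeSpec

__all__ = [
    "SessionConfig",
    "TapLogError",
    "write_sequences",
    "read_sequences",
    "write_tap_log",
    "read_tap_log",
    "write_results",
    "load_config",
]

log = logging.getLogger("taprhythm")

SEQ_COLUMNS = ["trial_id", "condition", "index", "ioi_ms", "segment_kind"]
TAP_COLUMNS = ["participant_id", "run", "trial_id", "condition", "tap_time_ms"]


class TapLogError(ValueError):
    """Malformed tap-log file (bad schema or unparseable rows)."""


@dataclasses.dataclass
class SessionConfig:
    """Analysis/session configuration; round-trips losslessly through YAML."""

    stimulus: TempoChangeSpec = dataclasses.field(default_factory=TempoChangeSpec)
    window_fraction: float = 0.5
    omit_first_k: int = 3
    max_interp_run: int = 3
    aggregation: str = "median"
    root_seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        stim = d.pop("stimulus", {})
        if isinstance(stim, dict):
            if "ramp_lengths_allowed" in stim:
                stim["ramp_lengths_allowed"] = tuple(stim["ramp_lengths_allowed"])
            for key in ("initial_beats_range", "final_beats_range"):
                if key in stim:
                    stim[key] = tuple(stim[key])
            stim = TempoChangeSpec(**stim)
        return cls(stimulus=stim, **d)

    def config_hash(self) -> str:
        """Stable short hash embedded in every analysis output."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> SessionConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return SessionConfig.from_dict(data or {})


def save_config(config: SessionConfig, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        else:
            json.dump(config.to_dict(), fh, indent=2, default=list)


def _segment_kind_per_ioi(seq: IOISequence) -> list[str]:
    kinds = [""] * len(seq.iois)
    for seg in seq.segments:
        for i in range(seg.start, seg.stop):
            kinds[i] = seg.kind
    return kinds


def write_sequences(
    sequences: dict[str, IOISequence], out_dir: str | Path, meta: dict | None = None
) -> Path:
    """Write sequences.csv plus a JSON sidecar with spec/seed metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    sidecar: dict[str, dict] = {"trials": {}, "meta": meta or {}}
    for trial_id, seq in sequences.items():
        kinds = _segment_kind_per_ioi(seq)
        for i, (ioi, kind) in enumerate(zip(seq.iois, kinds)):
            rows.append(
                {
                    "trial_id": trial_id,
                    "condition": seq.condition,
                    "index": i,
                    "ioi_ms": ioi,
                    "segment_kind": kind,
                }
            )
        sidecar["trials"][trial_id] = {
            "condition": seq.condition,
            "seed": seq.seed,
            "base_ioi": seq.base_ioi,
            "segments": [dataclasses.asdict(s) for s in seq.segments],
        }
    pd.DataFrame(rows, columns=SEQ_COLUMNS).to_csv(out_dir / "sequences.csv", index=False)
    with open(out_dir / "sequences.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out_dir / "sequences.csv"


def read_sequences(path: str | Path) -> dict[str, IOISequence]:
    """Read sequences.csv (+ sidecar when present) back into IOISequence objects."""
    path = Path(path)
    if path.is_dir():
        path = path / "sequences.csv"
    df = pd.read_csv(path)
    missing = set(SEQ_COLUMNS) - set(df.columns)
    if missing:
        raise TapLogError(f"{path}: missing required columns {sorted(missing)}")
    sidecar_path = path.with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh).get("trials", {})
    out: dict[str, IOISequence] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("index")
        meta = sidecar.get(str(trial_id), {})
        if "segments" in meta:
            segments = [Segment(**s) for s in meta["segments"]]
        else:
            segments = _segments_from_kinds(list(g["segment_kind"]))
        out[str(trial_id)] = IOISequence(
            condition=str(g["condition"].iloc[0]),
            iois=g["ioi_ms"].to_numpy(dtype=float),
            segments=segments,
            base_ioi=float(meta.get("base_ioi", 500.0)),
            seed=meta.get("seed"),
            trial_id=str(trial_id),
        )
    return out


def _segments_from_kinds(kinds: list[str]) -> list[Segment]:
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            segments.append(Segment(kinds[start], start, i - start))
            start = i
    return segments


def write_tap_log(taps: list[TapTrain], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tt in taps:
        for t in tt.taps:
            rows.append(
                {
                    "participant_id": tt.participant_id or "",
                    "run": tt.run if tt.run is not None else 0,
                    "trial_id": tt.trial_id,
                    "condition": tt.condition,
                    "tap_time_ms": t,
                }
            )
    pd.DataFrame(rows, columns=TAP_COLUMNS).to_csv(path, index=False)
    return path


def read_tap_log(path: str | Path) -> list[TapTrain]:
    """Read a tap log, rejecting (with a logged reason) non-monotonic trials.

    Unknown columns are preserved in the DataFrame read; missing required
    columns or unparseable rows raise :class:`TapLogError` with the offending
    line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TAP_COLUMNS) - set(df.columns)
    if missing:
        raise TapLogError(f"{path}: missing required columns {sorted(missing)}")
    bad = pd.to_numeric(df["tap_time_ms"], errors="coerce").isna() & df["tap_time_ms"].notna()
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header + 1-based
        raise TapLogError(f"{path}:{lineno}: unparseable tap_time_ms value")
    df["tap_time_ms"] = pd.to_numeric(df["tap_time_ms"])
    out: list[TapTrain] = []
    for (pid, trial_id), g in df.groupby(["participant_id", "trial_id"], sort=False):
        times = g["tap_time_ms"].to_numpy(dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            log.warning(
                "trial %s/%s rejected: tap times not strictly increasing", pid, trial_id
            )
            continue
        out.append(
            TapTrain(
                trial_id=str(trial_id),
                condition=str(g["condition"].iloc[0]),
                taps=times,
                participant_id=str(pid),
                run=int(g["run"].iloc[0]) if "run" in g else None,
            )
        )
    return out


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
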