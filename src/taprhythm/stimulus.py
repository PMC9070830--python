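"""Pacing-stimulus generation for auditory-motor synchronization trials.

Three metronome conditions are supported:

* ``isochronous`` — a constant inter-onset interval (IOI), 500 ms by default.
* ``tempo_change`` — the IOI ramps linearly up and down between 400 and 600 ms,
  tracing a sampled triangle wave.  A trial contains a fixed number of tempo
  changes (six by default); consecutive changes alternate direction, and the
  trial both starts and ends with a *decrease*, which is achieved by splitting
  one decreasing change into a 500→400 ms first half and a 600→500 ms last
  half.  The point at which the changes start is jittered by varying the
  number of initial isochronous pacing beats, with the final isochronous beats
  compensating so every trial has the same number of tap opportunities.
* ``random`` — the variable (ramp) IOIs of a paired tempo-change sequence in a
  uniformly random order; the ready-cue and the initial/final isochronous
  beats stay in place, so the IOI multiset and mean are preserved.

Every sequence begins with a short isochronous ready cue that listeners do not
tap to.  The mean of all non-ready-cue IOIs equals the base IOI exactly in all
three conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "TempoChangeSpec",
    "Segment",
    "IOISequence",
    "OnsetTrain",
    "generate_isochronous",
    "generate_tempo_change",
    "generate_random",
    "beat_onsets",
]

CONDITIONS = ("isochronous", "tempo_change", "random")

SEGMENT_KINDS = ("ready_cue", "initial_iso", "ramp_down", "ramp_up", "final_iso")


class ConfigurationError(ValueError):
    """Raised when a stimulus spec violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when no constraint-satisfying sequence exists for a spec."""


@dataclass(frozen=True)
class TempoChangeSpec:
    """Constants defining one pacing trial.

    Defaults reproduce the study conditions: 48 tones per trial (4 of them a
    ready cue), base IOI 500 ms, tempo excursions between 400 and 600 ms, six
    tempo changes over 4, 6 or 8 beats each, 4–7 initial and a complementary
    1–4 final isochronous pacing beats.
    """

    base_ioi: float = 500.0
    ioi_min: float = 400.0
    ioi_max: float = 600.0
    n_tones: int = 48
    n_ready_cue: int = 4
    ramp_lengths_allowed: tuple[int, ...] = (4, 6, 8)
    n_tempo_changes: int = 6
    initial_beats_range: tuple[int, int] = (4, 7)
    final_beats_range: tuple[int, int] = (1, 4)
    integer_ms: bool = False
    exact_mean: bool = True

    def validate(self) -> None:
        if not (self.ioi_min <= self.base_ioi <= self.ioi_max):
            raise ConfigurationError(
                f"need ioi_min <= base_ioi <= ioi_max, got "
                f"{self.ioi_min}, {self.base_ioi}, {self.ioi_max}"
            )
        if self.n_ready_cue >= self.n_tones:
            raise ConfigurationError("n_ready_cue must be < n_tones")
        if self.n_ready_cue < 1 or self.n_tones < 2:
            raise ConfigurationError("need at least one ready-cue tone and two tones")
        if any(k < 2 for k in self.ramp_lengths_allowed):
            raise ConfigurationError("every allowed ramp length must be >= 2")
        if not self.ramp_lengths_allowed:
            raise ConfigurationError("ramp_lengths_allowed must be non-empty")
        lo, hi = self.initial_beats_range
        flo, fhi = self.final_beats_range
        if lo > hi or flo > fhi or lo < 0 or flo < 0:
            raise ConfigurationError("invalid initial/final beat ranges")
        if lo + fhi != hi + flo:
            raise ConfigurationError(
                "initial and final beat ranges must be complementary so the "
                "total pacing-beat budget is constant"
            )

    @property
    def iso_budget(self) -> int:
        """Total initial + final isochronous pacing beats (constant per spec)."""
        return self.initial_beats_range[0] + self.final_beats_range[1]

    @property
    def n_iois(self) -> int:
        return self.n_tones - 1

    @property
    def n_ready_iois(self) -> int:
        return self.n_ready_cue - 1

    @property
    def variable_budget(self) -> int:
        """Number of IOIs available to the ramp segments."""
        return self.n_iois - self.n_ready_iois - self.iso_budget


@dataclass(frozen=True)
class Segment:
    kind: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class IOISequence:
    """One pacing trial: an ordered IOI list with segment annotations.

    ``iois[k]`` is the interval preceding tone ``k + 1``; tone 0 starts the
    trial.  Segments tile the IOI list without gap or overlap.
    """

    condition: str
    iois: np.ndarray
    segments: list[Segment]
    base_ioi: float = 500.0
    seed: int | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.iois = np.asarray(self.iois, dtype=float)
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")

    @property
    def n_tones(self) -> int:
        return len(self.iois) + 1

    @property
    def n_ready_cue(self) -> int:
        ready = [s for s in self.segments if s.kind == "ready_cue"]
        return ready[0].length + 1 if ready else 1

    def segment_indices(self, *kinds: str) -> np.ndarray:
        """Indices of IOIs belonging to segments of the given kinds."""
        idx: list[int] = []
        for seg in self.segments:
            if seg.kind in kinds:
                idx.extend(range(seg.start, seg.stop))
        return np.asarray(sorted(idx), dtype=int)

    @property
    def non_ready_iois(self) -> np.ndarray:
        return self.iois[self.n_ready_cue - 1 :]

    def count_tempo_changes(self) -> int:
        """Number of tempo changes, counting the split first+last halves as one."""
        ramps = [s for s in self.segments if s.kind in ("ramp_up", "ramp_down")]
        if not ramps:
            return 0
        # split halves are the first and the last ramp segment
        return max(len(ramps) - 1, 0)


@dataclass
class OnsetTrain:
    """Cumulative form of an :class:`IOISequence`: tone-onset times from trial start.

    ``local_ioi[k]`` is the IOI preceding beat ``k`` (the base IOI for beat 0),
    used as the reference interval when windowing tap-beat matches.
    """

    onsets: np.ndarray
    local_ioi: np.ndarray

    def __len__(self) -> int:
        return len(self.onsets)


def _ramp(start: float, stop: float, k: int) -> np.ndarray:
    """k IOIs linearly interpolated from ``start`` (exclusive) to ``stop`` (inclusive)."""
    return np.linspace(start, stop, k + 1)[1:]


def generate_isochronous(spec: TempoChangeSpec = TempoChangeSpec()) -> IOISequence:
    """All-constant pacing sequence at the base IOI."""
    spec.validate()
    n = spec.n_iois
    iois = np.full(n, float(spec.base_ioi))
    nready = spec.n_ready_iois
    segments = []
    if nready:
        segments.append(Segment("ready_cue", 0, nready))
    segments.append(Segment("initial_iso", nready, n - nready))
    return IOISequence("isochronous", iois, segments, base_ioi=spec.base_ioi)


def _draw_change_lengths(
    spec: TempoChangeSpec, rng: np.random.Generator, max_tries: int = 20_000
) -> list[int]:
    """Lengths (in IOIs) for the tempo changes: each allowed length appears at
    least once, the rest drawn uniformly, resampled until the budget fits and
    the split change (first element) has even length."""
    allowed = list(spec.ramp_lengths_allowed)
    n_changes = spec.n_tempo_changes
    if n_changes < len(allowed):
        raise GenerationError(
            "fewer tempo changes than allowed ramp lengths: cannot use each "
            "length at least once"
        )
    budget = spec.variable_budget
    for _ in range(max_tries):
        lengths = allowed + [
            int(rng.choice(allowed)) for _ in range(n_changes - len(allowed))
        ]
        rng.shuffle(lengths)
        if sum(lengths) != budget:
            continue
        if lengths[0] % 2 != 0:
            # the split change needs an even length; try rotating one in
            evens = [i for i, k in enumerate(lengths) if k % 2 == 0]
            if not evens:
                continue
            j = evens[0]
            lengths[0], lengths[j] = lengths[j], lengths[0]
        return lengths
    raise GenerationError(
        f"no ramp-length assignment from {allowed} with each length used at "
        f"least once sums to the variable-IOI budget {budget}"
    )


def generate_tempo_change(spec: TempoChangeSpec, seed: int) -> IOISequence:
    """Triangle-wave pacing sequence under the alternation constraints.

    The variable portion is: a 500→400 half-decrease, an alternating series of
    full ramps between the IOI extremes (starting upward, ending at the
    maximum), and a 600→500 half-decrease; the split halves together count as
    one tempo change.  Initial isochronous pacing beats are drawn uniformly
    from ``initial_beats_range`` and the final isochronous beats make the
    total constant.
    """
    spec.validate()
    if not (spec.ioi_min < spec.base_ioi < spec.ioi_max):
        raise ConfigurationError(
            "tempo-change generation needs ioi_min < base_ioi < ioi_max"
        )
    rng = np.random.default_rng(seed)
    n_full = spec.n_tempo_changes - 1
    if n_full < 1 or n_full % 2 == 0:
        raise GenerationError(
            "n_tempo_changes - 1 full ramps must be a positive odd number so "
            "the sequence can start and end with a decrease"
        )
    lengths = _draw_change_lengths(spec, rng)
    split_len, full_lens = lengths[0], lengths[1:]

    n_i = int(rng.integers(spec.initial_beats_range[0], spec.initial_beats_range[1] + 1))
    n_f = spec.iso_budget - n_i
    if not (spec.final_beats_range[0] <= n_f <= spec.final_beats_range[1]):
        raise GenerationError("final isochronous beat count fell outside its range")

    base, lo, hi = float(spec.base_ioi), float(spec.ioi_min), float(spec.ioi_max)
    nready = spec.n_ready_iois

    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    pos = 0

    def push(kind: str, arr: np.ndarray) -> None:
        nonlocal pos
        pieces.append(arr)
        segments.append(Segment(kind, pos, len(arr)))
        pos += len(arr)

    if nready:
        push("ready_cue", np.full(nready, base))
    push("initial_iso", np.full(n_i, base))
    push("ramp_down", _ramp(base, lo, split_len // 2))
    level = lo
    for j, k in enumerate(full_lens):
        if j % 2 == 0:
            push("ramp_up", _ramp(lo, hi, k))
            level = hi
        else:
            push("ramp_down", _ramp(hi, lo, k))
            level = lo
    if level != hi:  # pragma: no cover - excluded by the odd-ramp-count check
        raise GenerationError("ramp series did not end at the IOI maximum")
    push("ramp_down", _ramp(hi, base, split_len - split_len // 2))
    push("final_iso", np.full(n_f, base))

    iois = np.concatenate(pieces)
    if spec.integer_ms:
        iois = np.round(iois)
    if spec.exact_mean and n_f > 0:
        # absorb any residual into the final isochronous IOIs (micro-adjustment,
        # <= 1 ms each; a no-op for equal split halves up to float rounding)
        non_ready = iois[nready:]
        residual = non_ready.sum() - base * len(non_ready)
        step = residual / n_f
        if abs(step) > 1.0:
            raise GenerationError(
                f"mean-IOI residual {residual:.3f} ms too large to absorb in "
                f"{n_f} final isochronous IOIs"
            )
        iois[len(iois) - n_f :] -= step

    seq = IOISequence("tempo_change", iois, segments, base_ioi=base, seed=seed)
    assert len(seq.iois) == spec.n_iois
    return seq


def generate_random(tempo_seq: IOISequence, seed: int) -> IOISequence:
    """Random condition: permute the ramp IOIs of a tempo-change sequence.

    Ready-cue and initial/final isochronous IOIs keep their positions, so the
    IOI multiset (and hence the mean) is exactly preserved.
    """
    if tempo_seq.condition != "tempo_change":
        raise ValueError(
            f"random condition is derived from a tempo_change sequence, got "
            f"{tempo_seq.condition!r}"
        )
    rng = np.random.default_rng(seed)
    iois = tempo_seq.iois.copy()
    ramp_idx = tempo_seq.segment_indices("ramp_up", "ramp_down")
    iois[ramp_idx] = iois[rng.permutation(ramp_idx)]
    return IOISequence(
        "random",
        iois,
        list(tempo_seq.segments),
        base_ioi=tempo_seq.base_ioi,
        seed=seed,
    )


def beat_onsets(seq: IOISequence) -> OnsetTrain:
    """Cumulative onset times (ms from trial start) and per-beat local IOIs."""
    onsets = np.concatenate([[0.0], np.cumsum(seq.iois)])
    local = np.concatenate([[float(seq.base_ioi)], seq.iois])
    return OnsetTrain(onsets=onsets, local_ioi=local)
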