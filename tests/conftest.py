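import numpy as np
import pytest

import taprhythm as tr


@pytest.fixture(scope="session")
def default_spec():
    return tr.TempoChangeSpec()


@pytest.fixture(scope="session")
def tempo_seq(default_spec):
    seq = tr.generate_tempo_change(default_spec, seed=7)
    seq.trial_id = "T07"
    return seq


def score_trial(params, seq, seed, omit_k=3):
    """Run simulate -> match -> omit -> ITI -> ratio for one trial."""
    onsets = tr.beat_onsets(seq)
    tap = tr.simulate_trial(params, seq, seed)
    aligned = tr.match_taps_to_beats(tap, onsets, n_ready_cue=seq.n_ready_cue)
    aligned = tr.omit_leading_taps(aligned, omit_k)
    itis = tr.build_iti_series(aligned, onsets)
    pt = tr.prediction_tracking_ratio(itis) if not itis.excluded else None
    return aligned, itis, pt


def make_onsets(beats, base_ioi=500.0):
    """OnsetTrain from explicit beat times."""
    beats = np.asarray(beats, dtype=float)
    local = np.concatenate([[base_ioi], np.diff(beats)]) if len(beats) else np.array([])
    return tr.OnsetTrain(onsets=beats, local_ioi=local)
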