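import numpy as np
import pandas as pd
import pytest

from vnspupil import GeneratorConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One default synthetic recording (5 units, 20 trials/phase), shared."""
    cfg = GeneratorConfig(seed=11, n_units=5)
    trials, units, pupil, licks, truth = simulate_session(cfg)
    return trials, units, pupil, licks, truth


def make_trials(onsets, label="T1", tone_dur=1.0, **extra):
    """Minimal schema-valid trial table with tones at the given onsets."""
    onsets = np.asarray(onsets, dtype=float)
    base = dict(
        trial_id=np.arange(len(onsets)),
        sound_onset=onsets,
        sound_offset=onsets + tone_dur,
        sound_label=[label] * len(onsets) if isinstance(label, str) else list(label),
        is_rewarded=False,
        vns_condition="none",
        vns_onset=np.nan,
        session_phase="pre",
        day=1,
        block_id=0,
    )
    base.update(extra)
    return pd.DataFrame(base)
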