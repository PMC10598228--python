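import numpy as np
import pandas as pd
import pytest

from semint.preprocess import EVENT_COLUMNS, Recording, validate_events
from semint.synthetic import make_mesh


@pytest.fixture(scope="session")
def small_mesh():
    return make_mesh(200, radius=50.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_event_table(
    n_trials: int = 10,
    n_words: int = 4,
    word_dur: float = 0.5,
    conditions=("referential", "non_referential"),
    correct=None,
    trial_gap: float = 4.0,
) -> pd.DataFrame:
    """Minimal valid event table with evenly spaced trials."""
    rows = []
    for tid in range(n_trials):
        cond = conditions[tid % len(conditions)]
        t0 = 2.0 + tid * trial_gap
        ok = True if correct is None else correct[tid]
        for w in range(n_words):
            rows.append(
                {
                    "trial_id": tid,
                    "word_index": w,
                    "onset": t0 + w * word_dur,
                    "duration": word_dur,
                    "condition": cond,
                    "coherence": "coherent" if cond == "non_referential" else "n/a",
                    "narrowing": "strong" if cond == "referential" else "n/a",
                    "is_final_word": w == n_words - 1,
                    "response_onset": t0 + n_words * word_dur + 1.5,
                    "correct": ok,
                }
            )
    return validate_events(pd.DataFrame(rows, columns=EVENT_COLUMNS))


@pytest.fixture()
def event_table():
    return make_event_table()


@pytest.fixture()
def noise_recording(rng):
    """60 s of white noise, 4 channels at 2 kHz."""
    data = rng.standard_normal((4, 120000))
    return Recording(data, 2000.0, ["c1", "c2", "c3", "c4"])
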