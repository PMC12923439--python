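import numpy as np
import pandas as pd
import pytest

from dyadalign import (
    CleaningConfig,
    NormLexicon,
    fixture_lexicon,
    mark_turns,
)
from dyadalign.turn_series import OBSERVED, TurnSeries


@pytest.fixture(scope="session")
def lexicon():
    return fixture_lexicon()


@pytest.fixture()
def tiny_lexicon():
    return NormLexicon(pd.DataFrame({
        "headword": ["happy", "sad", "dog", "cat", "sleep", "house"],
        "valence": [9.0, 1.0, 7.0, 6.5, 5.0, 5.5],
        "concreteness": [2.0, 2.1, 4.9, 4.8, 3.5, 4.7],
    }))


@pytest.fixture()
def valence_config():
    return CleaningConfig(dimensions=("valence",))


def write_corpus_files(directory, conversations):
    """Write ``{name: (speakers, texts)}`` to CSV transcript files."""
    directory.mkdir(parents=True, exist_ok=True)
    for name, (speakers, texts) in conversations.items():
        pd.DataFrame({"participant_id": speakers, "text": texts}).to_csv(
            directory / f"{name}.csv", index=False)
    return directory


@pytest.fixture()
def corpus_dir(tmp_path):
    """Two 4-utterance conversations: one CSV, one colon-delimited TXT."""
    d = tmp_path / "corpus"
    d.mkdir()
    pd.DataFrame({
        "participant_id": ["A", "B", "A", "B"],
        "text": ["The dog slept.", "My cat is happy!",
                 "Dogs sleep a lot.", "Cats sleep more."],
        "session": [1, 1, 1, 1],
    }).to_csv(d / "a.csv", index=False)
    (d / "b.txt").write_text(
        "Ann: The house is happy.\n"
        "Ben: A sad dog slept.\n"
        "Ann: Happy cats sleep.\n"
        "Ben: The sad house.\n")
    return d


def utterance_frame(speakers, texts, event_id="e1"):
    frame = pd.DataFrame({
        "event_id": event_id,
        "participant_id": list(speakers),
        "text": list(texts),
        "row_order": range(1, len(texts) + 1),
    })
    return mark_turns(frame)


def token_frame(turn_values, event_id="e1", dim="valence"):
    """Build a minimal joined token table from per-turn value lists.

    ``turn_values`` is a list of lists: item ``t`` holds the token values
    (floats or NaN) of turn ``t + 1``; speakers alternate A, B, A, ...
    """
    rows = []
    order = 0
    for t, values in enumerate(turn_values, start=1):
        speaker = "A" if t % 2 == 1 else "B"
        for v in values:
            order += 1
            rows.append({
                "event_id": event_id, "participant_id": speaker,
                "row_order": order, "turn_index": t,
                "exchange_index": (t + 1) // 2,
                "token_raw": f"w{order}",
                "token_clean": f"w{order}" if not np.isnan(v) else np.nan,
                "is_stopword": bool(np.isnan(v)),
                dim: v,
            })
    return pd.DataFrame(rows)


def make_series(values_a, values_b, event_id="e1", dim="valence",
                turn_count=None):
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    return TurnSeries(
        event_id=event_id, dimension=dim, speaker_a="A", speaker_b="B",
        values_a=a, values_b=b,
        fill_flags_a=np.where(np.isnan(a), None, OBSERVED),
        fill_flags_b=np.where(np.isnan(b), None, OBSERVED),
        turn_count_observed=turn_count if turn_count is not None
        else 2 * len(a),
    )
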