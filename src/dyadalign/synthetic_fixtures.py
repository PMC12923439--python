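"""Synthetic coupled dyads and transcript realizations for testing.

The generative model is the minimal one with separately tunable global
similarity and turn-wise synchrony: the leader is an AR(1) process and the
follower is linearly coupled to the leader at a fixed delay,

    a[t] = rho * a[t-1] + eps[t]
    b[t] = beta * a[t - delay] + eta[t]

with iid normal noise of standard deviation ``noise_sd``.  A dyad can also
be *realized* as a word-level transcript by sampling fixture-lexicon words
whose dimension values are nearest each slot's target, so the full cleaning
and lookup pipeline can be exercised end to end.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _resources
from .norm_lexicon import NormLexicon, fixture_lexicon
from .turn_series import OBSERVED, TurnSeries

BACKCHANNEL_TEXT = "oh yeah"


@dataclass(frozen=True)
class DyadSimSpec:
    """Parameters of one simulated dyad."""

    n_slots: int
    rho: float = 0.3
    beta: float = 0.0
    delay: int = 1
    noise_sd: float = 1.0
    seed: int = 0
    backchannel_rate: float = 0.0
    words_per_turn: int = 5
    #: follower noise scale; None -> same as noise_sd.  A separate knob is
    #: needed for the exact-echo limit: with shared noise the offset-1
    #: coefficient tends to 1/sqrt(2 - rho^2), not 1, as noise shrinks.
    follower_noise_sd: float | None = None

    def __post_init__(self):
        if self.n_slots < 2:
            raise ValueError("n_slots must be >= 2")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.backchannel_rate < 1.0:
            raise ValueError("backchannel_rate must lie in [0, 1)")
        if self.words_per_turn < 1:
            raise ValueError("words_per_turn must be >= 1")
        if self.follower_noise_sd is not None and self.follower_noise_sd <= 0:
            raise ValueError("follower_noise_sd must be positive")

    def stationary_variance(self) -> float:
        """Closed-form AR(1) stationary variance of the leader."""
        return self.noise_sd ** 2 / (1.0 - self.rho ** 2)


def simulate_dyad(spec: DyadSimSpec, dimension: str = "valence",
                  event_id: str = "sim") -> TurnSeries:
    """Draw one leader/follower series pair under *spec*."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_slots
    eps = rng.normal(0.0, spec.noise_sd, n)
    eta_sd = spec.noise_sd if spec.follower_noise_sd is None \
        else spec.follower_noise_sd
    eta = rng.normal(0.0, eta_sd, n)
    a = np.empty(n)
    a[0] = rng.normal(0.0, np.sqrt(spec.stationary_variance()))
    for t in range(1, n):
        a[t] = spec.rho * a[t - 1] + eps[t]
    b = eta.copy()
    if spec.delay < n:
        sl = slice(spec.delay, None)
        b[sl] = spec.beta * a[:n - spec.delay] + eta[sl]
    flags = np.full(n, OBSERVED, dtype=object)
    return TurnSeries(
        event_id=event_id, dimension=dimension,
        speaker_a="P1", speaker_b="P2",
        values_a=a, values_b=b,
        fill_flags_a=flags.copy(), fill_flags_b=flags.copy(),
        turn_count_observed=2 * n,
    )


def _usable_headwords(lexicon: NormLexicon, dimension: str) -> pd.DataFrame:
    """Lexicon entries that survive default-tier cleaning unchanged."""
    stop = _resources.stopword_set("default")
    lemmas = _resources.lemma_map()
    frame = lexicon.frame.dropna(subset=[dimension])
    keep = [
        w for w in frame["headword"]
        if w not in stop and lemmas.get(w, w) == w and "'" not in w
    ]
    return frame[frame["headword"].isin(keep)].reset_index(drop=True)


def realize_transcript(series: TurnSeries, spec: DyadSimSpec,
                       lexicon: NormLexicon | None = None,
                       center: float | None = None):
    """Render a series as a word-level transcript.

    Slot values (roughly zero-centered under the simulation model) are
    shifted by *center* — by default the midpoint of the lexicon's value
    range — and each shifted target is approximated by the
    ``words_per_turn`` lexicon words with nearest dimension values.
    Follower turns are replaced by a pure-stopword backchannel at
    ``spec.backchannel_rate``.

    Returns ``(utterances, quantization_error)`` where ``utterances`` has
    ``participant_id`` and ``text`` columns and ``quantization_error`` is
    the largest absolute difference between a realized turn mean and its
    shifted target.  Running the full pipeline on the transcript recovers
    ``center + value`` per slot to within that bound.
    """
    lexicon = lexicon if lexicon is not None else fixture_lexicon()
    pool = _usable_headwords(lexicon, series.dimension)
    if len(pool) < spec.words_per_turn:
        raise ValueError("lexicon too small for requested words_per_turn")
    values = pool[series.dimension].to_numpy(dtype=float)
    words = pool["headword"].to_numpy()
    if center is None:
        center = float(values.min() + values.max()) / 2.0
    rng = np.random.default_rng(spec.seed + 1)

    rows = []
    worst = 0.0
    for i in range(series.n_slots):
        for speaker, raw_target, is_follower in (
                (series.speaker_a, series.values_a[i], False),
                (series.speaker_b, series.values_b[i], True)):
            target = center + raw_target
            if is_follower and rng.random() < spec.backchannel_rate:
                rows.append({"participant_id": speaker,
                             "text": BACKCHANNEL_TEXT})
                continue
            nearest = np.argsort(np.abs(values - target),
                                 kind="stable")[:spec.words_per_turn]
            chosen = list(words[nearest])
            rng.shuffle(chosen)
            worst = max(worst, abs(values[nearest].mean() - target))
            rows.append({"participant_id": speaker,
                         "text": " ".join(chosen)})
    return pd.DataFrame(rows), worst


def write_corpus(dir_path, specs: dict[str, DyadSimSpec],
                 dimension: str = "valence",
                 lexicon: NormLexicon | None = None) -> dict[str, float]:
    """Write one transcript CSV per ``{event_id: spec}`` entry.

    Returns the per-event quantization error bound reported by
    :func:`realize_transcript`.
    """
    directory = Path(dir_path)
    directory.mkdir(parents=True, exist_ok=True)
    errors = {}
    for event_id, spec in specs.items():
        series = simulate_dyad(spec, dimension=dimension, event_id=event_id)
        utterances, err = realize_transcript(series, spec, lexicon=lexicon)
        utterances.to_csv(directory / f"{event_id}.csv", index=False)
        errors[event_id] = err
    return errors
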