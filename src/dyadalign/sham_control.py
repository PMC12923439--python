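"""Permutation ("sham") controls: shuffle each speaker's turn order.

Within every conversation, each interlocutor's sequence of turns is
independently permuted, destroying turn-to-turn contingency while preserving
each speaker's marginal distribution of turn contents.  Slot speaker
identity and alternation structure are untouched.

Randomness is derived per event from the master seed and a stable hash of
the event identifier, so adding or removing one conversation never changes
another conversation's permutation.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .turn_series import TurnSeries


@dataclass(frozen=True)
class ShamSpec:
    """Number of permutations and (optional) master seed."""

    seed: int | None = None
    n_shams: int = 1

    def __post_init__(self):
        if self.n_shams < 1:
            raise ValueError("n_shams must be >= 1")


def _event_rng(seed: int | None, event_id: str, sham_id: int) -> np.random.Generator:
    digest = hashlib.sha256(str(event_id).encode("utf-8")).digest()
    event_key = int.from_bytes(digest[:8], "big")
    entropy = [event_key, sham_id] if seed is None \
        else [int(seed), event_key, sham_id]
    ss = np.random.SeedSequence(entropy)
    if seed is None:
        # no seed supplied: fold in OS entropy for non-reproducible shams
        ss = np.random.SeedSequence([np.random.SeedSequence().entropy,
                                     event_key, sham_id])
    return np.random.default_rng(ss)


def sham_series(series: TurnSeries, spec: ShamSpec) -> list[TurnSeries]:
    """Sham copies of one turn series (speaker vectors permuted
    independently)."""
    out = []
    for sham_id in range(1, spec.n_shams + 1):
        rng = _event_rng(spec.seed, series.event_id, sham_id)
        if series.n_slots < 2:
            warnings.warn(
                f"event {series.event_id!r}: fewer than 2 turns per "
                "speaker; returned unshuffled", UserWarning, stacklevel=2)
            perm_a = np.arange(series.n_slots)
            perm_b = np.arange(series.n_slots)
        else:
            perm_a = rng.permutation(series.n_slots)
            perm_b = rng.permutation(series.n_slots)
        out.append(replace(
            series,
            values_a=series.values_a[perm_a],
            values_b=series.values_b[perm_b],
            fill_flags_a=series.fill_flags_a[perm_a],
            fill_flags_b=series.fill_flags_b[perm_b],
            is_sham=True, sham_id=sham_id,
        ))
    return out


def generate_shams(tokens: pd.DataFrame, spec: ShamSpec) -> pd.DataFrame:
    """Sham token tables: permute each speaker's turn contents per event.

    The returned frame stacks ``spec.n_shams`` permuted copies of the
    input with a ``sham_id`` column.  Turn slots keep their original
    speaker and position; the *contents* (token rows) of each speaker's
    turns are permuted among that speaker's slots, so the per-speaker
    multiset of turns is conserved exactly.
    """
    required = {"event_id", "participant_id", "turn_index"}
    if not required <= set(tokens.columns):
        raise ValueError(f"token table must have columns {sorted(required)}")
    shams = []
    for sham_id in range(1, spec.n_shams + 1):
        parts = []
        for event, grp in tokens.groupby("event_id", sort=False):
            grp = grp.sort_values(["turn_index", "row_order"])
            rng = _event_rng(spec.seed, event, sham_id)
            turn_speaker = grp.groupby("turn_index")["participant_id"].first()
            new_parts = []
            for speaker in turn_speaker.unique():
                slots = turn_speaker.index[turn_speaker == speaker].to_numpy()
                if len(slots) < 2:
                    warnings.warn(
                        f"event {event!r}: speaker {speaker!r} has fewer "
                        "than 2 turns; left unshuffled",
                        UserWarning, stacklevel=2)
                    perm = slots
                else:
                    perm = slots[rng.permutation(len(slots))]
                for dest, src in zip(slots, perm):
                    rows = grp[grp["turn_index"] == src].copy()
                    rows["turn_index"] = dest
                    new_parts.append(rows)
            ev = pd.concat(new_parts).sort_values(["turn_index", "row_order"])
            ev["exchange_index"] = (ev["turn_index"] + 1) // 2
            parts.append(ev)
        sham = pd.concat(parts, ignore_index=True)
        sham["sham_id"] = sham_id
        shams.append(sham)
    return pd.concat(shams, ignore_index=True)
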