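"""Aggregate token norms to per-turn time series, paired by exchange.

Each conversation x dimension yields a :class:`TurnSeries`: two equal-length
vectors (first speaker / second speaker), one slot per exchange.  Turns whose
tokens carry no norm values produce missing slots, later filled by edge fill
(leading/trailing) and linear interpolation (interior).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

OBSERVED = "observed"
EDGE_FILLED = "edge_filled"
INTERPOLATED = "interpolated"


@dataclass
class TurnSeries:
    """Per-exchange values for both speakers on one dimension."""

    event_id: str
    dimension: str
    speaker_a: str  # first to speak
    speaker_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    fill_flags_a: np.ndarray
    fill_flags_b: np.ndarray
    turn_count_observed: int
    is_sham: bool = False
    sham_id: int | None = field(default=None)

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        self.fill_flags_a = np.asarray(self.fill_flags_a, dtype=object)
        self.fill_flags_b = np.asarray(self.fill_flags_b, dtype=object)
        if self.values_a.shape != self.values_b.shape:
            raise ValueError("speaker vectors must have equal length")

    @property
    def n_slots(self) -> int:
        return len(self.values_a)

    def is_filled(self) -> bool:
        return not (np.isnan(self.values_a).any()
                    or np.isnan(self.values_b).any())


def _turn_speaker(turn: int, speaker_a: str, speaker_b: str) -> str:
    return speaker_a if turn % 2 == 1 else speaker_b


def aggregate_turns(tokens: pd.DataFrame, dims) -> list[TurnSeries]:
    """Build one :class:`TurnSeries` per event x dimension.

    Slot ``i`` holds the mean non-missing token value of each speaker's
    turn in exchange ``i + 1``; a turn with no values (all stopwords or no
    lexicon matches) yields a missing slot, as does the partner slot of a
    trailing unpaired turn.
    """
    dims = list(dims)
    out: list[TurnSeries] = []
    for event, grp in tokens.groupby("event_id", sort=False):
        grp = grp.sort_values(["turn_index", "row_order"])
        first_turn = grp[grp["turn_index"] == grp["turn_index"].min()]
        speaker_a = first_turn["participant_id"].iloc[0]
        others = grp.loc[grp["participant_id"] != speaker_a, "participant_id"]
        if others.empty:
            raise ValueError(
                f"event {event!r} has only one speaker after preparation; "
                "not a dyad")
        speaker_b = others.iloc[0]
        n_turns = int(grp["turn_index"].max())
        n_slots = (n_turns + 1) // 2
        for dim in dims:
            turn_means = grp.groupby("turn_index")[dim].mean()
            a = np.full(n_slots, np.nan)
            b = np.full(n_slots, np.nan)
            for turn, value in turn_means.items():
                slot = (int(turn) - 1) // 2
                if int(turn) % 2 == 1:
                    a[slot] = value
                else:
                    b[slot] = value
            for vec, who in ((a, speaker_a), (b, speaker_b)):
                if np.isnan(vec).all():
                    raise ValueError(
                        f"event {event!r}: speaker {who!r} has no observed "
                        f"values on dimension {dim!r}")
            out.append(TurnSeries(
                event_id=event, dimension=dim,
                speaker_a=speaker_a, speaker_b=speaker_b,
                values_a=a, values_b=b,
                fill_flags_a=np.where(np.isnan(a), None, OBSERVED),
                fill_flags_b=np.where(np.isnan(b), None, OBSERVED),
                turn_count_observed=n_turns,
            ))
    return out


def _fill_vector(values: np.ndarray, flags: np.ndarray):
    missing = np.isnan(values)
    if not missing.any():
        return values.copy(), flags.copy()
    obs = np.flatnonzero(~missing)
    if obs.size == 0:
        raise ValueError("cannot fill an all-missing vector")
    idx = np.arange(len(values))
    # np.interp clamps to the nearest observed value outside [first, last]
    # (the edge rule) and is linear between observed values (the interior
    # rule).
    filled = np.interp(idx, obs, values[obs])
    new_flags = flags.copy()
    edge = missing & ((idx < obs[0]) | (idx > obs[-1]))
    new_flags[edge] = EDGE_FILLED
    new_flags[missing & ~edge] = INTERPOLATED
    return filled, new_flags


def fill_missing(series: TurnSeries) -> TurnSeries:
    """Fill missing slots: edges by nearest observed value, interior by
    linear interpolation.  Observed values and existing flags untouched;
    idempotent."""
    a, fa = _fill_vector(series.values_a, series.fill_flags_a)
    b, fb = _fill_vector(series.values_b, series.fill_flags_b)
    return replace(series, values_a=a, values_b=b,
                   fill_flags_a=fa, fill_flags_b=fb)


def _row_is_na(tokens: pd.DataFrame, dims) -> pd.Series:
    return tokens[list(dims)].isna().all(axis=1)


def count_na_turns(tokens: pd.DataFrame, dims) -> dict[str, int]:
    """Per-event count of turns consisting entirely of missing-value tokens
    (the interpolation-burden diagnostic)."""
    na_row = _row_is_na(tokens, dims)
    out = {}
    for event, grp in tokens.groupby("event_id", sort=False):
        turn_all_na = na_row.loc[grp.index].groupby(grp["turn_index"]).all()
        out[event] = int(turn_all_na.sum())
    return out


def drop_backchannel_turns(tokens: pd.DataFrame, dims,
                           log=None) -> pd.DataFrame:
    """Remove turns whose every token is missing on all selected dimensions
    (typically pure-stopword backchannels), merging the flanking
    same-speaker turns and recomputing turn/exchange indices."""
    na_row = _row_is_na(tokens, dims)
    parts = []
    for event, grp in tokens.groupby("event_id", sort=False):
        grp = grp.sort_values(["turn_index", "row_order"])
        turn_all_na = na_row.loc[grp.index].groupby(grp["turn_index"]).all()
        drop_turns = set(turn_all_na[turn_all_na].index)
        kept = grp[~grp["turn_index"].isin(drop_turns)].copy()
        if kept.empty:
            raise ValueError(
                f"event {event!r}: no turns left after backchannel removal")
        changed = kept["participant_id"].ne(kept["participant_id"].shift())
        kept["turn_index"] = changed.cumsum()
        kept["exchange_index"] = (kept["turn_index"] + 1) // 2
        if log is not None and drop_turns:
            log.add("prep", "backchannel turns removed", event_id=event,
                    removed=len(drop_turns))
        parts.append(kept)
    return pd.concat(parts, ignore_index=True)


def series_to_frame(series_list) -> pd.DataFrame:
    """Long-format export: one row per event x dimension x speaker x slot."""
    rows = []
    for s in series_list:
        for speaker, values, flags in (
                (s.speaker_a, s.values_a, s.fill_flags_a),
                (s.speaker_b, s.values_b, s.fill_flags_b)):
            for i, (v, f) in enumerate(zip(values, flags), start=1):
                rows.append({
                    "event_id": s.event_id, "dimension": s.dimension,
                    "speaker": speaker, "exchange": i,
                    "value": v, "fill_flag": f,
                    "is_sham": s.is_sham, "sham_id": s.sham_id,
                })
    return pd.DataFrame(rows)
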