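"""Read dyadic transcript files into one ordered utterance table.

A corpus is a directory of ``.csv`` / ``.txt`` files, one conversation per
file.  CSV files carry a header row with a speaker-identifier column and an
utterance-text column (any extra columns are passed through as metadata).
TXT files use ``Speaker: utterance`` lines, split on the first colon; lines
without a colon continue the previous utterance.

The filename stem becomes the conversation identifier (``event_id``).
"""
from __future__ import annotations

import io
import warnings
from math import ceil
from pathlib import Path

import pandas as pd

from ._log import PipelineLog

#: Columns assigned by this module; metadata may not collide with them.
RESERVED_COLUMNS = frozenset(
    {"event_id", "row_order", "turn_index", "exchange_index"}
)

_ENCODING_CANDIDATES = ("utf-8", "utf-8-sig", "cp1252", "latin-1")


class TranscriptError(ValueError):
    """Raised for malformed transcript input."""


def _decode(path: Path, log: PipelineLog | None) -> str:
    raw = path.read_bytes()
    for enc in _ENCODING_CANDIDATES:
        try:
            text = raw.decode(enc)
        except UnicodeDecodeError:
            continue
        if "\x00" in text:
            raise TranscriptError(f"undecodable bytes in {path.name}")
        if enc != "utf-8" and log is not None:
            log.add("read", f"non-UTF-8 encoding for {path.name}",
                    level="warning", file=path.name, encoding=enc)
        elif log is not None:
            log.add("read", f"decoded {path.name}", file=path.name,
                    encoding=enc)
        return text
    raise TranscriptError(f"undecodable bytes in {path.name}")


def _parse_csv(path: Path, text: str, id_column: str,
               text_column: str) -> pd.DataFrame:
    frame = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    for col in (id_column, text_column):
        if col not in frame.columns:
            raise TranscriptError(
                f"{path.name}: missing required column {col!r}"
            )
    frame = frame.rename(columns={id_column: "participant_id",
                                  text_column: "text"})
    collisions = (set(frame.columns) - {"participant_id", "text"}) \
        & RESERVED_COLUMNS
    if collisions:
        raise TranscriptError(
            f"{path.name}: metadata column(s) {sorted(collisions)} collide "
            "with reserved names"
        )
    return frame


def _parse_txt(path: Path, text: str,
               log: PipelineLog | None) -> pd.DataFrame:
    speakers: list[str] = []
    utterances: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        speaker, colon, utterance = line.partition(":")
        if colon and speaker.strip():
            speakers.append(speaker.strip())
            utterances.append(utterance.strip())
        else:
            # Continuation line: append to the previous utterance.
            if not utterances:
                raise TranscriptError(
                    f"{path.name}: line {lineno} has no 'speaker:' delimiter "
                    "and no preceding utterance"
                )
            utterances[-1] = (utterances[-1] + " " + line.strip()).strip()
            if log is not None:
                log.add("read", f"continuation line in {path.name}",
                        level="warning", file=path.name, line=lineno)
    if not speakers:
        raise TranscriptError(f"{path.name}: no utterances parsed")
    return pd.DataFrame({"participant_id": speakers, "text": utterances})


def read_dyads(dir_path, id_column: str = "participant_id",
               text_column: str = "text",
               log: PipelineLog | None = None) -> pd.DataFrame:
    """Read every ``.csv``/``.txt`` transcript under *dir_path*.

    Returns one concatenated table with columns ``event_id``,
    ``participant_id``, ``text``, ``row_order`` plus any metadata columns,
    preserving within-file row order.  ``turn_index`` / ``exchange_index``
    are assigned separately by :func:`mark_turns`.
    """
    directory = Path(dir_path)
    if not directory.is_dir():
        raise TranscriptError(f"not a directory: {directory}")
    files = sorted(
        (p for p in directory.iterdir()
         if p.suffix.lower() in {".csv", ".txt"} and p.is_file()),
        key=lambda p: p.name,
    )
    if not files:
        raise TranscriptError("no transcripts found")

    stems: dict[str, str] = {}
    for path in files:
        if path.stem in stems:
            raise TranscriptError(
                f"duplicate transcript name {path.stem!r} "
                f"({stems[path.stem]} and {path.name})"
            )
        stems[path.stem] = path.name

    parts = []
    for path in files:
        text = _decode(path, log)
        if path.suffix.lower() == ".csv":
            frame = _parse_csv(path, text, id_column, text_column)
        else:
            frame = _parse_txt(path, text, log)
        if frame["participant_id"].astype(str).str.strip().eq("").any():
            raise TranscriptError(f"{path.name}: empty participant_id value")
        frame = frame.copy()
        frame.insert(0, "event_id", path.stem)
        frame["row_order"] = range(1, len(frame) + 1)
        parts.append(frame)
        if log is not None:
            log.add("read", f"parsed {path.name}", file=path.name,
                    rows=len(frame))

    table = pd.concat(parts, ignore_index=True, sort=False)
    lead = ["event_id", "participant_id", "text", "row_order"]
    meta = [c for c in table.columns if c not in lead]
    return table[lead + meta]


def mark_turns(table: pd.DataFrame) -> pd.DataFrame:
    """Assign ``turn_index`` and ``exchange_index`` within each event.

    A turn is a maximal run of rows by the same speaker; the counter
    increments at every change of ``participant_id`` and restarts at 1 per
    event.  ``exchange_index`` is ``ceil(turn_index / 2)``.
    """
    bad = [
        event for event, grp in table.groupby("event_id", sort=False)
        if grp["participant_id"].nunique() != 2
    ]
    if bad:
        raise TranscriptError(
            f"events without exactly 2 speakers: {bad}"
        )
    out = table.copy()
    turn = pd.Series(0, index=out.index, dtype=int)
    for _, grp in out.groupby("event_id", sort=False):
        grp = grp.sort_values("row_order")
        changed = grp["participant_id"].ne(grp["participant_id"].shift())
        turn.loc[grp.index] = changed.cumsum()
    out["turn_index"] = turn
    out["exchange_index"] = (out["turn_index"] + 1) // 2
    return out


def warn_short(table: pd.DataFrame, threshold: int = 50,
               log: PipelineLog | None = None) -> list[tuple[str, int]]:
    """Return ``(event_id, turn_count)`` for events with fewer than
    *threshold* turns, emitting a :class:`UserWarning` per event."""
    if "turn_index" not in table.columns:
        raise TranscriptError("turn_index not assigned; call mark_turns first")
    short = []
    for event, grp in table.groupby("event_id", sort=False):
        n_turns = int(grp["turn_index"].max())
        if n_turns < threshold:
            short.append((event, n_turns))
            msg = (f"conversation {event!r} has only {n_turns} turns "
                   f"(< {threshold}); alignment indices may be unstable")
            warnings.warn(msg, UserWarning, stacklevel=2)
            if log is not None:
                log.add("read", msg, level="warning", event_id=event,
                        turns=n_turns)
    return short


def turn_count_oracle(speakers) -> int:
    """Run-length turn count: number of maximal same-speaker runs."""
    count = 0
    prev = object()
    for s in speakers:
        if s != prev:
            count += 1
            prev = s
    return count


def write_utterances(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def exchange_of(turn_index: int) -> int:
    return ceil(turn_index / 2)
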