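"""Descriptive corpus analytics over raw and cleaned transcripts.

Produces a near publication-ready table: corpus totals plus per-conversation
mean / sd / min / max for exchange count, word counts, cleaning retention
rate, morphemes-per-word, letters-per-word, log lexical frequency,
words-per-turn and type-token ratio.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .norm_lexicon import NormLexicon
from .text_prep import normalize_string

#: measure name -> acceptable lexicon dimension names, tried in order
_LEXICON_MEASURES = {
    "morphemes_per_word": ("morphemes", "morpheme_count", "n_morphemes"),
    "letters_per_word": ("letters", "letter_count", "length"),
    "lexical_frequency_lg10": ("frequency_lg10", "frequency", "freq_lg10"),
}

TOTAL_MEASURES = ("n_conversations", "total_raw_tokens", "total_clean_tokens")


def _raw_token_lists(raw: pd.DataFrame) -> pd.Series:
    """Whitespace tokens of the normalized utterance text, per event."""
    toks = raw["text"].map(lambda t: normalize_string(t).split())
    return toks.groupby(raw["event_id"], sort=False).agg(
        lambda lists: [t for lst in lists for t in lst])


def describe_corpus(raw: pd.DataFrame, clean: pd.DataFrame,
                    lexicon: NormLexicon | None = None) -> pd.DataFrame:
    """Build the analytics table.

    ``raw`` is the utterance table with turn indices assigned; ``clean``
    is the token table (norms optional).  Returns a frame indexed by
    measure with columns ``mean``, ``sd``, ``min``, ``max`` (sd is the
    sample standard deviation; totals leave sd/min/max empty).
    """
    if raw.empty:
        raise ValueError("no events in corpus")
    if "turn_index" not in raw.columns:
        raise ValueError("raw table needs turn_index; call mark_turns first")
    events = list(raw["event_id"].drop_duplicates())

    raw_tokens = _raw_token_lists(raw)
    if any(len(t) == 0 for t in raw_tokens):
        empty = [e for e in events if len(raw_tokens[e]) == 0]
        raise ValueError(f"event(s) with no text content: {empty}")

    turn_counts = raw.groupby("event_id", sort=False)["turn_index"].max()
    exch_counts = raw.groupby("event_id", sort=False)["exchange_index"].max()

    clean_grp = clean.groupby("event_id", sort=False)["token_clean"]
    clean_counts = clean_grp.count().reindex(events).fillna(0)
    clean_types = clean_grp.nunique().reindex(events).fillna(0)

    per_event = pd.DataFrame(index=pd.Index(events, name="event_id"))
    per_event["exchange_count"] = exch_counts
    per_event["raw_word_count"] = raw_tokens.map(len)
    per_event["clean_word_count"] = clean_counts
    per_event["cleaning_retention_rate"] = (
        clean_counts / per_event["raw_word_count"])
    per_event["words_per_turn_raw"] = (
        per_event["raw_word_count"] / turn_counts)
    per_event["words_per_turn_clean"] = clean_counts / turn_counts
    per_event["type_token_ratio_raw"] = raw_tokens.map(
        lambda t: len(set(t)) / len(t))
    per_event["type_token_ratio_clean"] = np.where(
        clean_counts > 0, clean_types / clean_counts.replace(0, np.nan),
        np.nan)

    lex_cols = _lexicon_measures(clean, lexicon)
    for name, values in lex_cols.items():
        per_event[name] = values

    order = ["exchange_count", "raw_word_count", "clean_word_count",
             "cleaning_retention_rate", "morphemes_per_word",
             "letters_per_word", "lexical_frequency_lg10",
             "words_per_turn_raw", "words_per_turn_clean",
             "type_token_ratio_raw", "type_token_ratio_clean"]
    order = [m for m in order if m in per_event.columns]

    rows = {
        "n_conversations": (float(len(events)), np.nan, np.nan, np.nan),
        "total_raw_tokens": (float(per_event["raw_word_count"].sum()),
                             np.nan, np.nan, np.nan),
        "total_clean_tokens": (float(clean_counts.sum()),
                               np.nan, np.nan, np.nan),
    }
    for m in order:
        col = per_event[m].astype(float)
        rows[m] = (col.mean(), col.std(ddof=1), col.min(), col.max())

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "sd", "min", "max"])
    table.index.name = "measure"
    return table


def _lexicon_measures(clean: pd.DataFrame,
                      lexicon: NormLexicon | None) -> dict[str, pd.Series]:
    """Per-event means of lexicon-backed measures over matched tokens."""
    out: dict[str, pd.Series] = {}
    if lexicon is None:
        warnings.warn("no lexicon supplied; lexicon-backed measures omitted",
                      UserWarning, stacklevel=3)
        return out
    matched = clean.dropna(subset=["token_clean"]).copy()
    for measure, candidates in _LEXICON_MEASURES.items():
        dim = next((d for d in candidates if d in lexicon.dimensions), None)
        if dim is None:
            warnings.warn(
                f"lexicon lacks a dimension for {measure!r} "
                f"(looked for {candidates}); reported as NA",
                UserWarning, stacklevel=3)
            out[measure] = pd.Series(np.nan,
                                     index=clean["event_id"].unique())
            continue
        if dim in matched.columns:
            vals = matched[dim]
        else:
            lex = lexicon.frame.set_index("headword")[dim]
            vals = matched["token_clean"].map(lex)
        out[measure] = vals.groupby(matched["event_id"], sort=False).mean()
    return out


def format_table(table: pd.DataFrame, floatfmt: str = "{:.2f}") -> str:
    """Aligned plain-text / markdown rendering of the analytics table."""
    def fmt(x):
        return "" if pd.isna(x) else floatfmt.format(x)

    header = ["measure", "mean", "sd", "min", "max"]
    body = [[str(m)] + [fmt(table.loc[m, c]) for c in header[1:]]
            for m in table.index]
    widths = [max(len(r[i]) for r in [header] + body)
              for i in range(len(header))]

    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) \
            + " |"

    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(header), sep] + [line(r) for r in body])
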