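"""Deterministic text cleaning and one-token-per-row explosion.

Cleaning order, applied per utterance:

1. :func:`normalize_string` — lowercase, apostrophe normalization, hidden
   character removal, punctuation stripping, whitespace collapse.
2. Multiword greeting/idiom matching on the normalized utterance (flagged as
   stopwords before any token-level rewriting).
3. :func:`expand_contractions` — token-wise static map (``don't`` →
   ``do not``), including common apostrophe-less variants.
4. Possessive ``'s`` stripping.
5. Optional lemmatization via a packaged static lemma dictionary; unknown
   forms pass through unchanged.
6. Stopword flagging against a named tier; flagged rows keep their surface
   form in ``token_raw`` but have ``token_clean`` set to missing.

Stopwords are flagged, never dropped, so token counts are conserved.
"""
from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _resources

_APOSTROPHES = dict.fromkeys(map(ord, "’‘ʼ´`"), "'")
_HYPHENS = re.compile(r"[-‐‑‒–—]+")
_NOT_WORDCHAR = re.compile(r"[^a-z0-9'\s]+")
_WS = re.compile(r"\s+")


def normalize_string(text: str) -> str:
    """Lowercase and strip *text* down to word characters and apostrophes.

    Typographic apostrophes become ASCII ``'``; hidden characters (zero
    width, control, format) are removed; hyphens split words; every other
    non-alphanumeric symbol is replaced by a space; whitespace collapses.
    Idempotent by construction.
    """
    text = str(text).translate(_APOSTROPHES)
    text = "".join(
        ch for ch in text
        if unicodedata.category(ch) not in ("Cc", "Cf") or ch in "\t\n\r"
    )
    text = text.lower()
    text = _HYPHENS.sub(" ", text)
    text = _NOT_WORDCHAR.sub(" ", text)
    return _WS.sub(" ", text).strip()


def expand_contractions(text: str) -> str:
    """Expand contractions token-wise using the packaged static map."""
    cmap = _resources.contraction_map()
    return " ".join(cmap.get(tok, tok) for tok in text.split())


def _strip_possessive(token: str) -> str:
    if token.endswith("'s"):
        return token[:-2]
    return token.strip("'")


@dataclass(frozen=True)
class CleaningConfig:
    """Options controlling cleaning, tokenization, and norm selection."""

    dimensions: tuple[str, ...]
    stopword_list: str = "default"
    lemmatize: bool = True
    remove_backchanneling: bool = False
    stopword_file: Path | None = field(default=None)

    def __post_init__(self):
        dims = tuple(self.dimensions)
        object.__setattr__(self, "dimensions", dims)
        if not 1 <= len(dims) <= 3:
            raise ValueError(
                f"between 1 and 3 dimensions required, got {len(dims)}"
            )
        if self.stopword_file is None \
                and self.stopword_list not in _resources.STOPWORD_TIERS:
            raise ValueError(
                f"unknown stopword tier {self.stopword_list!r}"
            )

    def stopwords(self) -> frozenset[str]:
        if self.stopword_file is not None:
            lines = Path(self.stopword_file).read_text("utf-8").splitlines()
            return frozenset(w.strip() for w in lines if w.strip())
        return _resources.stopword_set(self.stopword_list)

    def multiword_stopwords(self) -> tuple[str, ...]:
        # Greetings/idioms belong to the default tier and above.
        if self.stopword_file is None \
                and self.stopword_list in ("none", "minimal"):
            return ()
        return _resources.multiword_stopwords()


def _multiword_flags(tokens: list[str], phrases: tuple[str, ...]) -> list[bool]:
    """Flag token positions covered by a multiword stopword phrase."""
    flags = [False] * len(tokens)
    for phrase in phrases:  # longest first (resource ordering)
        ptoks = phrase.replace("'", "'").split()
        ptoks = [normalize_string(p) for p in ptoks]
        n = len(ptoks)
        i = 0
        while i + n <= len(tokens):
            if tokens[i:i + n] == ptoks and not any(flags[i:i + n]):
                flags[i:i + n] = [True] * n
                i += n
            else:
                i += 1
    return flags


def tokenize(table: pd.DataFrame, config: CleaningConfig) -> pd.DataFrame:
    """Explode an utterance table into one token per row.

    Returns a frame with the utterance keys (``event_id``,
    ``participant_id``, ``row_order``, and ``turn_index`` /
    ``exchange_index`` when present) plus ``token_raw``, ``token_clean``
    and ``is_stopword``.  ``token_clean`` is missing exactly where
    ``is_stopword`` is true.
    """
    stopwords = config.stopwords()
    phrases = config.multiword_stopwords()
    lemmas = _resources.lemma_map() if config.lemmatize else {}

    keys = ["event_id", "participant_id", "row_order"]
    keys += [c for c in ("turn_index", "exchange_index")
             if c in table.columns]

    records: list[tuple] = []
    for row in table.itertuples(index=False):
        key = tuple(getattr(row, k) for k in keys)
        norm = normalize_string(row.text)
        if not norm:
            continue
        norm_tokens = norm.split()
        mw = _multiword_flags(norm_tokens, phrases) if phrases \
            else [False] * len(norm_tokens)
        for tok, in_phrase in zip(norm_tokens, mw):
            cmap_hit = _resources.contraction_map().get(tok)
            expanded = [tok] if (in_phrase or cmap_hit is None) \
                else cmap_hit.split()
            for part in expanded:
                surface = _strip_possessive(part)
                if not surface:
                    continue
                lemma = lemmas.get(surface, surface)
                stop = in_phrase or lemma in stopwords \
                    or surface in stopwords
                records.append(
                    key + (surface, None if stop else lemma, stop)
                )

    cols = keys + ["token_raw", "token_clean", "is_stopword"]
    out = pd.DataFrame.from_records(records, columns=cols)
    if not out.empty:
        out["token_clean"] = out["token_clean"].astype(object)
        out.loc[out["is_stopword"], "token_clean"] = np.nan
    return out


def prep_dyads(table: pd.DataFrame, lexicon, config: CleaningConfig,
               log=None) -> pd.DataFrame:
    """Clean, tokenize and join norms: the full preparation stage.

    Requires turn indices (see :func:`dyadalign.transcript_io.mark_turns`).
    When ``config.remove_backchanneling`` is true, fully missing turns are
    dropped and flanking same-speaker turns merged.
    """
    from .norm_lexicon import join_norms
    from .turn_series import drop_backchannel_turns

    tokens = tokenize(table, config)
    tokens = join_norms(tokens, lexicon, config.dimensions, log=log)
    if config.remove_backchanneling:
        tokens = drop_backchannel_turns(tokens, config.dimensions, log=log)
    return tokens
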