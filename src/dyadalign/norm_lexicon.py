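"""Psycholinguistic norm lexicon: load, validate, and join onto tokens.

The lexicon is a delimited text table with a ``headword`` column (called
``word`` or ``token`` is also accepted) plus one numeric column per
dimension.  Joining is an exact left join on ``token_clean``: stopword rows
and out-of-vocabulary tokens receive missing values.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import _resources

_HEADWORD_ALIASES = ("headword", "word", "token")

MAX_DIMENSIONS = 3


class NormLexicon:
    """Headword -> numeric-dimension lookup table.

    Parameters
    ----------
    table:
        Frame with a ``headword`` column (unique, lowercase) and one or
        more numeric dimension columns.  Missing values are allowed per
        word and dimension.
    """

    def __init__(self, table: pd.DataFrame):
        if "headword" not in table.columns:
            raise ValueError("lexicon requires a 'headword' column")
        dims = [c for c in table.columns if c != "headword"]
        if not dims:
            raise ValueError("lexicon requires at least one dimension column")
        table = table.copy()
        table["headword"] = table["headword"].astype(str).str.lower()
        dup = table["headword"].duplicated()
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} duplicate headword(s) collapsed by first "
                "occurrence", UserWarning, stacklevel=2)
            table = table[~dup]
        for col in dims:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna() \
                & (table[col].astype(str).str.strip() != "")
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} non-numeric cell(s) in dimension "
                    f"{col!r} set to NA", UserWarning, stacklevel=2)
            table[col] = coerced
        self._table = table.set_index("headword")
        self.dimensions: tuple[str, ...] = tuple(dims)

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, headword: str) -> bool:
        return headword in self._table.index

    @property
    def frame(self) -> pd.DataFrame:
        return self._table.reset_index()

    def catalog(self) -> pd.DataFrame:
        """Per-dimension coverage and observed range."""
        rows = []
        for dim in self.dimensions:
            col = self._table[dim]
            rows.append({
                "dimension": dim,
                "n_words": int(col.notna().sum()),
                "min": float(col.min()) if col.notna().any() else np.nan,
                "max": float(col.max()) if col.notna().any() else np.nan,
            })
        return pd.DataFrame(rows)

    def lookup(self, headword: str, dim: str) -> float:
        try:
            return float(self._table.at[headword, dim])
        except KeyError:
            return float("nan")


def load_lexicon(path) -> NormLexicon:
    """Load a CSV/TSV lexicon; the delimiter is sniffed from the suffix."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    for alias in _HEADWORD_ALIASES:
        if alias in frame.columns:
            frame = frame.rename(columns={alias: "headword"})
            break
    return NormLexicon(frame)


def join_norms(tokens: pd.DataFrame, lexicon: NormLexicon,
               dims, log=None) -> pd.DataFrame:
    """Left-join the selected dimensions onto ``token_clean``.

    Row count and order are preserved; stopword and out-of-vocabulary rows
    get NA.  Between 1 and 3 dimensions may be selected.
    """
    dims = list(dims)
    if not 1 <= len(dims) <= MAX_DIMENSIONS:
        raise ValueError(
            f"between 1 and {MAX_DIMENSIONS} dimensions required, "
            f"got {len(dims)}")
    unknown = [d for d in dims if d not in lexicon.dimensions]
    if unknown:
        raise ValueError(
            f"unknown dimension(s) {unknown}; available: "
            f"{sorted(lexicon.dimensions)}")
    lex = lexicon.frame.set_index("headword")[dims]
    out = tokens.merge(lex, how="left", left_on="token_clean",
                       right_index=True)
    assert len(out) == len(tokens)
    if log is not None:
        for event, frac in missingness_report(out, dims).items():
            log.add("join", "missingness by event", event_id=event, **frac)
    return out


def missingness_report(tokens: pd.DataFrame, dims) -> dict[str, dict]:
    """Fraction of non-stopword tokens with NA per event and dimension."""
    report: dict[str, dict] = {}
    content = tokens[~tokens["is_stopword"]]
    for event, grp in content.groupby("event_id", sort=False):
        report[event] = {
            dim: float(grp[dim].isna().mean()) if len(grp) else float("nan")
            for dim in dims
        }
    return report


def fixture_lexicon(seed: int = 20240501) -> NormLexicon:
    """Small synthetic lexicon for tests, docs and simulations.

    Roughly 300 common English words with *synthetic* (clearly labeled,
    deterministic) values for valence (1-9), concreteness (1-5),
    frequency_lg10 (1-7), letters, and morphemes.  Not real published
    norms; suitable only for exercising the pipeline.
    """
    words = sorted(_resources.fixture_words())
    rng = np.random.default_rng(seed)
    n = len(words)
    suffixes = ("ness", "ful", "less", "ing", "tion", "ous", "ly")
    frame = pd.DataFrame({
        "headword": words,
        "valence": np.round(rng.uniform(1.0, 9.0, n), 2),
        "concreteness": np.round(rng.uniform(1.0, 5.0, n), 2),
        "frequency_lg10": np.round(rng.uniform(1.0, 7.0, n), 2),
        "letters": [float(len(w)) for w in words],
        "morphemes": [
            1.0 + sum(w.endswith(s) for s in suffixes) for w in words
        ],
    })
    return NormLexicon(frame)


def write_fixture_lexicon(path, seed: int = 20240501) -> None:
    fixture_lexicon(seed).frame.to_csv(path, index=False)
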