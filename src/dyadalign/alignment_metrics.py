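"""Alignment indices for a filled turn series.

Two complementary families:

* **dAUC** (proximity): trapezoidal area under the absolute per-slot
  difference curve, reported raw, standardized to a 50-turn length, and
  recomputed under the lag-1 re-pairing (the second speaker's turn paired
  with the first speaker's *next* turn).
* **Lead/lag correlations** (synchrony): Pearson or Spearman coefficients
  between the two speakers' vectors with the first speaker's series shifted
  by each requested offset.  Positive offsets lag the first speaker (their
  later turns pair with the partner's earlier turns, emphasizing the first
  speaker's responses); negative offsets are leads.  Non-overlapping ends
  are trimmed, never wrapped or padded.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .turn_series import TurnSeries, fill_missing

STANDARD_TURN_LENGTH = 50
DEFAULT_OFFSETS = tuple(range(-3, 4))
CORR_METHODS = ("spearman", "pearson")
MIN_OVERLAP = 3


def dauc_raw(values_a, values_b) -> float:
    """Trapezoidal area under ``|a - b|`` with unit slot spacing."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if len(a) < 2:
        raise ValueError("insufficient turns for area (need >= 2 slots)")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("vectors must be filled (no missing values)")
    return float(np.trapezoid(np.abs(a - b)))


def dauc_normalized(raw: float, turn_count: int) -> float:
    """Standardize a raw area to a 50-turn conversation length."""
    if turn_count <= 0:
        raise ValueError("turn_count must be positive")
    return raw * STANDARD_TURN_LENGTH / turn_count


def lag1_pairing(values_a, values_b):
    """Re-pair so the second speaker precedes the first within exchanges.

    Slot ``i`` of the result pairs the first speaker's turn from exchange
    ``i + 1`` with the second speaker's turn from exchange ``i``; the two
    unpaired end turns are trimmed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    return a[1:], b[:-1]


def dauc_lag1(series: TurnSeries) -> tuple[float, float]:
    """(raw, normalized) dAUC under the lag-1 re-pairing."""
    a, b = lag1_pairing(series.values_a, series.values_b)
    raw = dauc_raw(a, b)
    return raw, dauc_normalized(raw, series.turn_count_observed)


def shifted_overlap(values_a, values_b, offset: int):
    """Overlapping segments after shifting the first vector by *offset*.

    ``offset > 0`` (lag): the first speaker's slot ``i + offset`` pairs
    with the partner's slot ``i``.  ``offset < 0`` (lead): slot
    ``i - |offset|`` pairs with slot ``i``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n = len(a)
    if offset >= n or -offset >= n:
        return a[:0], b[:0]
    if offset >= 0:
        return a[offset:], b[:n - offset]
    return a[:n + offset], b[-offset:]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)  # average ranks for ties
        y = stats.rankdata(y)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance overlap; correlation undefined",
                      UserWarning, stacklevel=3)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def lagged_correlations(series: TurnSeries, offsets=DEFAULT_OFFSETS,
                        method: str = "spearman") -> dict[int, float]:
    """Correlation coefficient at each offset of the first speaker.

    Overlaps shorter than 3 slots or with zero variance yield NA with a
    warning rather than an exception.
    """
    if method not in CORR_METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {CORR_METHODS}")
    if not series.is_filled():
        raise ValueError("series must be filled before correlation")
    out: dict[int, float] = {}
    for k in offsets:
        x, y = shifted_overlap(series.values_a, series.values_b, int(k))
        if len(x) < MIN_OVERLAP:
            warnings.warn(
                f"offset {k}: overlap of {len(x)} slots is too short",
                UserWarning, stacklevel=2)
            out[int(k)] = float("nan")
            continue
        out[int(k)] = _corr(x, y, method)
    return out


def summarize_series(series: TurnSeries, offsets=DEFAULT_OFFSETS,
                     corr_type: str = "spearman",
                     average_dauc: bool = False) -> dict:
    """All alignment indices for one conversation x dimension."""
    if not series.is_filled():
        series = fill_missing(series)
    raw = dauc_raw(series.values_a, series.values_b)
    norm = dauc_normalized(raw, series.turn_count_observed)
    raw_l1, norm_l1 = dauc_lag1(series)
    corrs = lagged_correlations(series, offsets=offsets, method=corr_type)
    row = {
        "event_id": series.event_id,
        "dimension": series.dimension,
        "first_speaker": series.speaker_a,
        "turn_count_observed": series.turn_count_observed,
        "n_exchanges": series.n_slots,
        "is_sham": series.is_sham,
        "sham_id": series.sham_id,
        "dauc_raw": raw,
        "dauc_normalized": norm,
        "dauc_raw_lag1": raw_l1,
        "dauc_norm_lag1": norm_l1,
        "corr_type": corr_type,
    }
    if average_dauc:
        row["dauc_norm_mean"] = (norm + norm_l1) / 2.0
    for k in offsets:
        row[f"corr_lag{int(k)}"] = corrs[int(k)]
    return row


def summarize_dyads(series_list, offsets=DEFAULT_OFFSETS,
                    corr_type: str = "spearman",
                    average_dauc: bool = False) -> pd.DataFrame:
    """One wide row per conversation x dimension (see
    :func:`summarize_series`)."""
    rows = [summarize_series(s, offsets=offsets, corr_type=corr_type,
                             average_dauc=average_dauc)
            for s in series_list]
    return pd.DataFrame(rows)
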