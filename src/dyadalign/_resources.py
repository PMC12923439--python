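"""Loaders for packaged plain-text word-list resources."""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

STOPWORD_TIERS = ("none", "minimal", "default", "strict")


def _read_lines(name: str) -> list[str]:
    ref = resources.files("dyadalign").joinpath("data", name)
    text = ref.read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


@lru_cache(maxsize=None)
def stopword_set(tier: str) -> frozenset[str]:
    """Return the stopword set for a named tier.

    Tiers are nested by strictness: minimal <= default <= strict.
    """
    if tier == "none":
        return frozenset()
    if tier not in STOPWORD_TIERS:
        raise ValueError(
            f"unknown stopword tier {tier!r}; expected one of {STOPWORD_TIERS}"
        )
    return frozenset(_read_lines(f"stopwords_{tier}.txt"))


@lru_cache(maxsize=None)
def multiword_stopwords() -> tuple[str, ...]:
    """Multiword greetings/idioms, longest first so greedy matching is safe."""
    phrases = _read_lines("stopwords_multiword.txt")
    return tuple(sorted(phrases, key=len, reverse=True))


@lru_cache(maxsize=None)
def contraction_map() -> dict[str, str]:
    out = {}
    for line in _read_lines("contractions.tsv"):
        key, _, value = line.partition("\t")
        out[key] = value
    return out


@lru_cache(maxsize=None)
def lemma_map() -> dict[str, str]:
    out = {}
    for line in _read_lines("lemmas.tsv"):
        key, _, value = line.partition("\t")
        out[key] = value
    return out


@lru_cache(maxsize=None)
def fixture_words() -> tuple[str, ...]:
    return tuple(_read_lines("fixture_words.txt"))
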