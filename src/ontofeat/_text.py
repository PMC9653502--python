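"""Shared text normalization used by the label index and the mapping cascade."""

from __future__ import annotations

import re

#: Fillers that carry no terminological content in short clinical phrases.
DEFAULT_STOPWORDS = frozenset({"of", "in", "at", "the", "with", "and"})

#: Adjectival suffixes stripped during stem-level (semantic) matching.
DEFAULT_STRIP_SUFFIXES = ("ial", "ous", "ic", "al")

_PUNCT = re.compile(r"[^\w]+", flags=re.UNICODE)


def tokenize(text: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS) -> list[str]:
    """Lowercase, map punctuation to spaces, collapse whitespace, drop stopwords.

    Deterministic; empty input yields an empty sequence.
    """
    lowered = _PUNCT.sub(" ", text.lower())
    return [tok for tok in lowered.split() if tok and tok not in stopwords]


def normalize(text: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS) -> str:
    """Canonical single-string form of a phrase: normalized tokens joined by one space."""
    return " ".join(tokenize(text, stopwords))


def singularize(token: str) -> str:
    """Naive depluralization: strip one trailing 's' from tokens longer than 3 chars.

    Never touches short tokens (``ca2``, ``hs``) or double-s endings (``gliosis``).
    """
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def stem(token: str, suffixes: tuple[str, ...] = DEFAULT_STRIP_SUFFIXES) -> str:
    """Light suffix-stripping stem for semantic anchor matching.

    Strips the longest matching adjectival suffix, then trailing vowels, so that
    morphological variants collapse onto a shared stem (``astroglial`` and
    ``astroglia`` both become ``astrogl``).
    """
    token = singularize(token)
    for suffix in sorted(suffixes, key=len, reverse=True):
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            token = token[: -len(suffix)]
            break
    return token.rstrip("aeiou") or token
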