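"""Deterministic text primitives shared across the package.

Tokenization, sentence segmentation and fuzzy token-set similarity are the
substrate for chunking, BM25 scoring, grounding verification and every
text-quality metric, so they are rule-based and fully deterministic: the
same input always yields byte-identical output, with no model downloads.

The central similarity primitive is the *fuzzy Jaccard*: set Jaccard where
two tokens count as matching when their normalized edit-distance similarity
``1 - lev(a, b) / max(|a|, |b|)`` reaches a threshold.  This tolerates
inflectional variants ("dressing" ~ "dressings") without equating unrelated
words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

try:  # fast C Levenshtein; pure-Python DP fallback keeps behaviour identical
    import edlib as _edlib

    def _levenshtein(a: str, b: str) -> int:
        return _edlib.align(a, b, task="distance")["editDistance"]

except ImportError:  # pragma: no cover - exercised only without edlib

    def _levenshtein(a: str, b: str) -> int:
        if len(a) < len(b):
            a, b = b, a
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]


# numerals first so "3.5" survives as one token; words may contain internal
# hyphens/apostrophes ("pain-free", "can't") but never leading/trailing ones
_TOKEN_RE = re.compile(r"\d+(?:\.\d+)*|[^\W\d_]+(?:['’-][^\W\d_]+)*")

# terminal punctuation runs that *may* end a sentence
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")

# if the text before a period ends in one of these, it is an abbreviation,
# not a sentence end
_ABBREVIATIONS = (
    "dr", "mr", "mrs", "ms", "prof", "st", "vs", "etc", "approx",
    "fig", "no", "e.g", "i.e", "cf", "al",
)
_ABBREV_RE = re.compile(
    r"(?:^|[\s(])(?:" + "|".join(re.escape(a) for a in _ABBREVIATIONS) + r")$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class TokenSequence:
    """Lowercased word tokens with their character offsets in the source."""

    tokens: tuple[str, ...]
    spans: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def unique(self) -> frozenset[str]:
        return frozenset(self.tokens)


@dataclass(frozen=True)
class SentenceList:
    """Ordered sentences with half-open character spans into the source."""

    sentences: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


def tokenize(text: str) -> TokenSequence:
    """Split ``text`` into lowercased word/numeral tokens.

    Tokens are maximal runs of letters (with internal hyphens/apostrophes)
    or digit groups (with internal decimal points); everything else is a
    boundary.  Empty input yields an empty sequence.
    """
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append(m.group(0).lower())
        spans.append((m.start(), m.end()))
    return TokenSequence(tuple(tokens), tuple(spans))


def _is_boundary(text: str, end: int) -> bool:
    """Decide whether the punctuation run ending at ``end`` closes a sentence."""
    rest = text[end:]
    if rest.strip() == "":
        return True
    # require whitespace then an upper-case letter, digit or opening quote
    m = re.match(r"\s+([\"'“‘(]?)(.)", rest)
    if not m:
        return False
    nxt = m.group(2)
    if not (nxt.isupper() or nxt.isdigit()):
        return False
    # "Dr. Smith", "e.g. Apples" — abbreviation before the period
    before = text[:end].rstrip(".!?")
    if _ABBREV_RE.search(before):
        return False
    return True


def split_sentences(text: str) -> SentenceList:
    """Rule-based sentence segmentation.

    Splits on ``.!?`` runs followed by whitespace plus a capital/digit (or
    end of text); decimal numbers never split (no whitespace after the
    period) and a small abbreviation list ("Dr.", "e.g.", ...) is honoured.
    """
    sentences: list[str] = []
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if _is_boundary(text, m.end()):
            raw = text[start:m.end()]
            stripped = raw.strip()
            if stripped:
                left = start + (len(raw) - len(raw.lstrip()))
                sentences.append(stripped)
                spans.append((left, left + len(stripped)))
            start = m.end()
    tail = text[start:]
    if tail.strip():
        left = start + (len(tail) - len(tail.lstrip()))
        stripped = tail.strip()
        sentences.append(stripped)
        spans.append((left, left + len(stripped)))
    return SentenceList(tuple(sentences), tuple(spans))


@lru_cache(maxsize=1_000_000)
def token_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity ``1 - lev/max(len)`` in [0, 1]."""
    if a == b:
        return 1.0
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - _levenshtein(a, b) / m


def _as_token_set(seq: TokenSequence | Sequence[str] | Iterable[str]) -> frozenset[str]:
    if isinstance(seq, TokenSequence):
        return seq.unique
    return frozenset(seq)


def fuzzy_jaccard(
    a: TokenSequence | Sequence[str],
    b: TokenSequence | Sequence[str],
    match_threshold: float = 0.85,
) -> float:
    """Fuzzy set Jaccard over unique tokens.

    Exact matches pair first; remaining tokens are greedily paired in
    descending edit-distance similarity, each token used at most once, and a
    pair counts iff its similarity reaches ``match_threshold``.  The score is
    ``|matched pairs| / |fuzzy union|``.  Two empty sequences score 1.0 (the
    degenerate identity case).
    """
    if not 0.0 <= match_threshold <= 1.0:
        raise ValueError("match_threshold must be in [0, 1]")
    set_a = _as_token_set(a)
    set_b = _as_token_set(b)
    if not set_a and not set_b:
        return 1.0
    if not set_a or not set_b:
        return 0.0
    exact = set_a & set_b
    rest_a = sorted(set_a - exact)
    rest_b = sorted(set_b - exact)
    matched = len(exact)
    if rest_a and rest_b and match_threshold < 1.0:
        pairs: list[tuple[float, str, str]] = []
        for ta in rest_a:
            la = len(ta)
            for tb in rest_b:
                lb = len(tb)
                # length bound: similarity <= 1 - |la-lb|/max(la,lb)
                if abs(la - lb) > (1.0 - match_threshold) * max(la, lb):
                    continue
                sim = token_similarity(ta, tb)
                if sim >= match_threshold:
                    pairs.append((sim, ta, tb))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        used_a: set[str] = set()
        used_b: set[str] = set()
        for sim, ta, tb in pairs:
            if ta in used_a or tb in used_b:
                continue
            used_a.add(ta)
            used_b.add(tb)
            matched += 1
    union = len(set_a) + len(set_b) - matched
    return matched / union
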