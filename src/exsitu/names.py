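"""Botanical name canonicalization and bounded fuzzy matching primitives.

Collection records carry taxon names typed by many hands over a century, so the
standardization cascade has to recognise the common failure modes: stray case
and whitespace, the multiplication sign of hybrids written as ``x``,
infraspecific rank tokens used interchangeably (``var.`` vs ``subsp.`` vs
``f.``), and single-character typos. Anything fancier (synonym graphs) is out
of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

# Rank tokens treated as interchangeable when comparing names at the
# "rank-normalized" cascade step.
RANK_TOKENS = {
    "var.", "var", "subsp.", "subsp", "ssp.", "ssp", "f.", "fo.", "forma",
    "subvar.", "subvar",
}

_HYBRID_SIGNS = ("×", "✕")  # multiplication sign, heavy ×

_CULTIVAR_RE = re.compile(r"'([^']+)'|‘([^’]+)’")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class ParsedName:
    """A botanical name split into its structural parts."""

    genus: str
    epithet: Optional[str]
    rank: Optional[str]
    infra_epithet: Optional[str]
    cultivar: Optional[str]
    hybrid: bool

    @property
    def is_horticultural(self) -> bool:
        return self.hybrid or self.cultivar is not None

    def canonical(self) -> str:
        parts = [self.genus.capitalize()]
        if self.hybrid:
            parts.insert(0, "x")
        if self.epithet:
            parts.append(self.epithet)
        if self.rank and self.infra_epithet:
            parts.append(self.rank)
            parts.append(self.infra_epithet)
        if self.cultivar:
            parts.append(f"'{self.cultivar}'")
        return " ".join(parts)


def strip_cultivar(name: str) -> str:
    """Remove quoted cultivar epithets (backbones are species-level)."""
    return _CULTIVAR_RE.sub(" ", name)


def canonical_tokens(name: str) -> list[str]:
    """Lower-cased, whitespace-collapsed tokens with hybrid signs normalized."""
    s = name.strip()
    for sign in _HYBRID_SIGNS:
        s = s.replace(sign, " x ")
    s = _WS_RE.sub(" ", s).strip().lower()
    return s.split(" ") if s else []


def canonical_name(name: str) -> str:
    return " ".join(canonical_tokens(name))


def rank_normalized_tokens(tokens: Sequence[str]) -> list[str]:
    """Replace interchangeable infraspecific rank tokens with a placeholder."""
    return ["<rank>" if t in RANK_TOKENS else t for t in tokens]


def parse_name(raw: str) -> ParsedName:
    """Parse a raw taxon name; tolerant of cultivar quotes and hybrid signs."""
    text = raw.strip()
    cultivar = None
    m = _CULTIVAR_RE.search(text)
    if m:
        cultivar = m.group(1) or m.group(2)
        text = _CULTIVAR_RE.sub(" ", text)
    tokens = canonical_tokens(text)
    hybrid = "x" in tokens
    tokens = [t for t in tokens if t != "x"]
    genus = tokens[0] if tokens else ""
    epithet = tokens[1] if len(tokens) > 1 else None
    rank = None
    infra = None
    rest = tokens[2:]
    for i, tok in enumerate(rest):
        if tok in RANK_TOKENS and i + 1 < len(rest):
            rank = tok if tok.endswith(".") else tok + "."
            infra = rest[i + 1]
            break
    return ParsedName(genus=genus, epithet=epithet, rank=rank,
                      infra_epithet=infra, cultivar=cultivar, hybrid=hybrid)


def levenshtein(a: str, b: str, bound: int | None = None) -> int:
    """Edit distance with an optional early-exit bound.

    Returns ``bound + 1`` as soon as the distance provably exceeds ``bound``.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if bound is not None and abs(la - lb) > bound:
        return bound + 1
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        row_min = cur[0]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            row_min = min(row_min, cur[j])
        if bound is not None and row_min > bound:
            return bound + 1
        prev = cur
    return prev[lb]


def token_sequence_distance(
    query: Sequence[str],
    candidate: Sequence[str],
    per_token_bound: int = 1,
    total_bound: int = 2,
) -> Optional[int]:
    """Total edit distance between token sequences under the typo bounds.

    Token counts must agree; each token may differ by at most
    ``per_token_bound`` edits and the sum by at most ``total_bound``.
    Returns ``None`` when the bounds are violated.
    """
    if len(query) != len(candidate):
        return None
    total = 0
    for q, c in zip(query, candidate):
        d = levenshtein(q, c, bound=per_token_bound)
        if d > per_token_bound:
            return None
        total += d
        if total > total_bound:
            return None
    return total


_AUTHOR_SPLIT_RE = re.compile(r"[\s,.&()\[\]]+")


def author_tokens(authority: str) -> frozenset[str]:
    """Authority string tokenized on punctuation and whitespace."""
    toks = {t.lower() for t in _AUTHOR_SPLIT_RE.split(authority or "") if t}
    toks.discard("ex")  # linking word, not an author
    return frozenset(toks)
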