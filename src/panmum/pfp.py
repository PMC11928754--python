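"""Prefix-free parsing (PFP) of sequences into ranked phrases.

A rolling Karp-Rabin hash slides a window of size ``w`` over the input; a
window whose hash is divisible by the modulus ``p`` is a *trigger string*.
The sequence is cut after every trigger, yielding a list of phrases whose
concatenation reproduces the input exactly.  Phrases are collected into a
lexicographically sorted dictionary and each phrase is replaced by its rank
(1-based meta-symbol), giving the *parse*.

The dictionary is built jointly over all sequences of an input set so that
two parse symbols are equal if and only if their phrases are base-identical
-- the property that makes parse-level multiMUMs meaningful across
sequences.

The expected phrase length grows with the modulus: roughly one window in
``p`` triggers, so phrases average about ``p`` symbols (plus edge effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence as TSequence

__all__ = [
    "PfpParams",
    "PhraseDictionary",
    "Parse",
    "parse",
    "parse_collection",
    "expand",
    "base_weight",
]

#: 61-bit Mersenne prime; reduction is cheap and collisions are negligible
#: for window sizes used here.
HASH_MOD_DEFAULT = (1 << 61) - 1
#: odd multiplier close to the byte-alphabet size.
HASH_BASE_DEFAULT = 257


@dataclass(frozen=True)
class PfpParams:
    """Parameters of the prefix-free parser.

    ``window`` and ``modulus`` control the expected phrase length; the hash
    constants are fixed configuration so runs are reproducible.  ``trigger``
    optionally replaces the hash predicate with an arbitrary function of the
    window text (used by tests and worked examples).
    """

    window: int = 10
    modulus: int = 100
    hash_base: int = HASH_BASE_DEFAULT
    hash_mod: int = HASH_MOD_DEFAULT
    trigger: Optional[Callable[[str], bool]] = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.modulus < 1:
            raise ValueError("modulus must be >= 1")


@dataclass(frozen=True)
class PhraseDictionary:
    """Lexicographically sorted distinct phrases; ranks are 1..|D|."""

    phrases: tuple[str, ...]
    _rank: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    @classmethod
    def from_phrases(cls, phrases) -> "PhraseDictionary":
        ordered = tuple(sorted(set(phrases)))
        return cls(ordered, {ph: r + 1 for r, ph in enumerate(ordered)})

    def rank(self, phrase: str) -> int:
        return self._rank[phrase]

    def phrase(self, rank: int) -> str:
        if not 1 <= rank <= len(self.phrases):
            raise ValueError(f"unknown phrase rank {rank}")
        return self.phrases[rank - 1]

    def __len__(self) -> int:
        return len(self.phrases)


@dataclass(frozen=True)
class Parse:
    """Parse of one sequence: meta-symbol ranks plus base-level coordinates.

    ``phrase_starts`` has one entry per parse position plus a final
    past-the-end entry equal to ``total_bases``, so the phrase at parse
    position ``i`` covers the base interval
    ``[phrase_starts[i], phrase_starts[i+1])``.
    """

    symbols: tuple[int, ...]
    phrase_starts: tuple[int, ...]
    total_bases: int

    def __len__(self) -> int:
        return len(self.symbols)


def _trigger_ends(text: str, params: PfpParams) -> list[int]:
    """Positions i such that the window ending at i is a trigger string."""
    w = params.window
    n = len(text)
    if n < w:
        return []
    if params.trigger is not None:
        pred = params.trigger
        return [i for i in range(w - 1, n) if pred(text[i - w + 1 : i + 1])]
    b, mod, p = params.hash_base, params.hash_mod, params.modulus
    out: list[int] = []
    h = 0
    for c in text[:w]:
        h = (h * b + ord(c)) % mod
    if h % p == 0:
        out.append(w - 1)
    bw = pow(b, w - 1, mod)
    for i in range(w, n):
        h = ((h - ord(text[i - w]) * bw) * b + ord(text[i])) % mod
        if h % p == 0:
            out.append(i)
    return out


def _phrases_of(text: str, params: PfpParams) -> list[str]:
    if not text:
        raise ValueError("cannot parse an empty sequence")
    phrases: list[str] = []
    start = 0
    for end in _trigger_ends(text, params):
        phrases.append(text[start : end + 1])
        start = end + 1
    if start < len(text):  # trailing phrase without a trigger end
        phrases.append(text[start:])
    return phrases


def parse_collection(
    texts: TSequence[str], params: PfpParams | None = None
) -> tuple[PhraseDictionary, list[Parse]]:
    """Parse several sequences against one shared, jointly ranked dictionary.

    Sharing the rank space across sequences guarantees that equal parse
    symbols expand to identical base strings, which downstream anchor
    finding relies on.
    """
    params = params or PfpParams()
    per_text = [_phrases_of(t, params) for t in texts]
    dictionary = PhraseDictionary.from_phrases(
        ph for phrases in per_text for ph in phrases
    )
    parses = []
    for phrases in per_text:
        starts = [0]
        for ph in phrases:
            starts.append(starts[-1] + len(ph))
        parses.append(
            Parse(
                symbols=tuple(dictionary.rank(ph) for ph in phrases),
                phrase_starts=tuple(starts),
                total_bases=starts[-1],
            )
        )
    return dictionary, parses


def parse(text: str, params: PfpParams | None = None) -> tuple[PhraseDictionary, Parse]:
    """Prefix-free parse a single sequence."""
    dictionary, parses = parse_collection([text], params)
    return dictionary, parses[0]


def expand(p: Parse, dictionary: PhraseDictionary) -> str:
    """Inverse of :func:`parse`: replace every rank with its phrase."""
    return "".join(dictionary.phrase(sym) for sym in p.symbols)


def base_weight(p: Parse, i: int, j: int) -> int:
    """Number of bases covered by the parse positions ``[i, j)``."""
    if not 0 <= i <= j <= len(p.symbols):
        raise ValueError(f"parse range [{i}, {j}) out of bounds for length {len(p)}")
    return p.phrase_starts[j] - p.phrase_starts[i]
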