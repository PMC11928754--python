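"""multiMUM detection from the enhanced GSA via the lcp-interval test.

A multiMUM of sequences ``S_1..S_m`` is a substring that occurs exactly
once in every sequence and cannot be extended simultaneously left or right
in all sequences without a mismatch.  multiMUMs correspond one-to-one to
lcp-intervals ``ell-[lb..rb]`` of the enhanced GSA satisfying

1. width ``rb - lb + 1 == m``,
2. the document-array values on ``[lb..rb]`` are pairwise distinct,
3. the BWT values on ``[lb..rb]`` are not all equal (left-maximality;
   sentinel BWT symbols are pairwise distinct and distinct from every
   regular symbol, so a suffix starting at position 0 always witnesses
   left-maximality).

Right-maximality is implied by lcp-interval-hood (the minimum internal LCP
equals ``ell`` exactly), and the interval width equals the total number of
occurrences of the interval's prefix string across all sequences, so
condition 2 certifies both per-sequence uniqueness and absence elsewhere.

A *partial* multiMUM is a multiMUM of a subset of the sequences: the width
condition relaxes to ``min_occ <= width <= m`` and sequences outside the
interval get position ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .esa import EnhancedGSA, enumerate_lcp_intervals

__all__ = ["MultiMUM", "find_multimums", "find_partial_multimums"]


@dataclass(frozen=True)
class MultiMUM:
    """A (partial) multiMUM: match length plus one start per sequence.

    ``positions`` holds 0-based starts, ``None`` marking sequences the
    match is absent from.  ``level`` records whether the coordinates refer
    to parse symbols or bases.
    """

    length: int
    positions: tuple[Optional[int], ...]
    level: str = "base"  # "parse" or "base"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("multiMUM length must be positive")
        if all(p is None for p in self.positions):
            raise ValueError("multiMUM must occur in at least one sequence")

    @property
    def occurrence_count(self) -> int:
        return sum(p is not None for p in self.positions)

    def occurs_in(self, k: int) -> bool:
        return self.positions[k] is not None

    def with_position(self, k: int, pos: int) -> "MultiMUM":
        ps = list(self.positions)
        ps[k] = pos
        return replace(self, positions=tuple(ps))


def _interval_mum(gsa: EnhancedGSA, ell: int, lb: int, rb: int) -> MultiMUM:
    positions: list[Optional[int]] = [None] * gsa.m
    for i in range(lb, rb + 1):
        positions[int(gsa.da[i])] = int(gsa.sa[i])
    return MultiMUM(length=ell, positions=tuple(positions))


def find_partial_multimums(
    gsa: EnhancedGSA, min_occ: int | None = None
) -> list[MultiMUM]:
    """All partial multiMUMs occurring in at least ``min_occ`` sequences.

    The default ``min_occ = floor(m/2) + 1`` (strictly more than half) is
    what makes chains of partial matches totally orderable downstream.
    """
    m = gsa.m
    if min_occ is None:
        min_occ = m // 2 + 1
    out: list[MultiMUM] = []
    da, bwt = gsa.da, gsa.bwt
    for iv in enumerate_lcp_intervals(gsa, min_ell=1):
        w = iv.width
        if not min_occ <= w <= m:
            continue
        ds = da[iv.lb : iv.rb + 1]
        if np.unique(ds).size != w:  # some sequence occurs twice
            continue
        bs = bwt[iv.lb : iv.rb + 1]
        if np.all(bs == bs[0]):  # not left-maximal
            continue
        out.append(_interval_mum(gsa, iv.ell, iv.lb, iv.rb))
    return out


def find_multimums(gsa: EnhancedGSA) -> list[MultiMUM]:
    """multiMUMs occurring in all ``m`` sequences."""
    return find_partial_multimums(gsa, min_occ=gsa.m)
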