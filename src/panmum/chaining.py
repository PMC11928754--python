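"""Colinear fragment chaining.

Fragments are (partial) multiMUMs with a weight (covered bases).  Fragment
``f`` *precedes* ``g`` (written ``f << g``) when ``f`` ends strictly before
``g`` starts in every sequence both occur in; a *chain* is a ``<<``-ordered
sequence of fragments and its score is the sum of the weights.

Provided here:

* :func:`chain_dp` -- exact O(m k^2) dynamic program for the optimal
  global chain;
* :func:`chain_heuristic` -- processes fragments by position and scans
  already-processed fragments in decreasing score order, picking the first
  valid predecessor (near-optimal when nearly all fragments are mutually
  colinear, which is the expected regime for highly similar genomes);
* :func:`select_subset_chain` -- the k-subset heuristic for partial
  fragments: for every k from ``floor(m/2)+1`` to ``m``, chain only the
  fragments occurring in all of the k sequences best covered by fragments,
  and keep the chain covering the most bases;
* :func:`his_augment` -- per-sequence heaviest-increasing-subsequence
  selection that re-adds fragment occurrences (or mapper hits) consistent
  with a fixed chain order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence as TSequence

from .multimum import MultiMUM

__all__ = [
    "Fragment",
    "Chain",
    "Candidate",
    "precedes",
    "chain_dp",
    "chain_heuristic",
    "select_subset_chain",
    "his_augment",
]


@dataclass(frozen=True)
class Fragment:
    """A weighted (partial) multiMUM ready for chaining.

    ``base_length`` is the number of bases one occurrence spans (equals
    ``mum.length`` at base level, the expanded phrase length at parse
    level).  ``weight`` is the chaining weight: ``base_length`` for full
    fragments, ``base_length * occurrence_count`` for partial ones.
    """

    mum: MultiMUM
    weight: int
    base_length: int
    id: int = 0
    mandatory: bool = False  # pre-existing anchor a chain must keep

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("fragment weight must be positive")

    @property
    def length(self) -> int:
        return self.mum.length

    @property
    def positions(self) -> tuple[Optional[int], ...]:
        return self.mum.positions

    def occurs_in(self, k: int) -> bool:
        return self.mum.positions[k] is not None


@dataclass(frozen=True)
class Chain:
    """A ``<<``-ordered list of fragments with its total score."""

    fragments: tuple[Fragment, ...]
    score: int

    def __len__(self) -> int:
        return len(self.fragments)


def precedes(f: Fragment, g: Fragment) -> bool:
    """True iff ``f`` ends strictly before ``g`` starts in every sequence
    where both occur (at least one such sequence is required)."""
    if f is g:
        return False
    fp, gp = f.mum.positions, g.mum.positions
    common = False
    for pf, pg in zip(fp, gp):
        if pf is None or pg is None:
            continue
        common = True
        if pf + f.length > pg:  # 0-based: p_f + ell - 1 < p_g
            return False
    return common


def _sort_key(frag: Fragment, ref: int) -> tuple:
    p = frag.mum.positions[ref]
    return (p, p + frag.length, frag.id)


def _reference_sequence(frags: TSequence[Fragment]) -> int:
    """Lowest sequence index in which every fragment occurs."""
    if not frags:
        return 0
    m = len(frags[0].mum.positions)
    for k in range(m):
        if all(f.occurs_in(k) for f in frags):
            return k
    raise ValueError("fragments share no common sequence; cannot order them")


def _better_predecessor(a: Optional[Fragment], b: Fragment, scores, ref: int) -> bool:
    """Deterministic tie-break: higher score, then smaller end position in
    the reference sequence, then smaller fragment id."""
    if a is None:
        return True
    sa, sb = scores[a.id], scores[b.id]
    if sa != sb:
        return sb > sa
    ea = a.mum.positions[ref] + a.length
    eb = b.mum.positions[ref] + b.length
    if ea != eb:
        return eb < ea
    return b.id < a.id


def _assign_ids(frags: Iterable[Fragment]) -> list[Fragment]:
    return [replace(f, id=i) for i, f in enumerate(frags)]


def chain_dp(frags: TSequence[Fragment]) -> Chain:
    """Optimal global chain by dynamic programming over the << order.

    Requires all fragments to occur in one common sequence (true for full
    multiMUMs and for each k-subset of partial ones), which yields a
    processing order compatible with <<.  Mandatory fragments are forced
    into the chain by inflating their effective weight.
    """
    if not frags:
        return Chain(fragments=(), score=0)
    frags = _assign_ids(frags)
    ref = _reference_sequence(frags)
    order = sorted(frags, key=lambda f: _sort_key(f, ref))
    total_w = sum(f.weight for f in frags) + 1
    eff = {f.id: (f.weight + total_w if f.mandatory else f.weight) for f in frags}

    scores: dict[int, int] = {}
    back: dict[int, Optional[Fragment]] = {}
    for g in order:
        best: Optional[Fragment] = None
        for f in order:
            if f.mum.positions[ref] >= g.mum.positions[ref]:
                break
            if precedes(f, g) and _better_predecessor(best, f, scores, ref):
                best = f
        scores[g.id] = eff[g.id] + (scores[best.id] if best else 0)
        back[g.id] = best

    end: Optional[Fragment] = None
    for f in order:
        if _better_predecessor(end, f, scores, ref):
            end = f
    out: list[Fragment] = []
    cur = end
    while cur is not None:
        out.append(cur)
        cur = back[cur.id]
    out.reverse()
    return Chain(fragments=tuple(out), score=sum(f.weight for f in out))


def chain_heuristic(frags: TSequence[Fragment]) -> Chain:
    """Sorted-by-score predecessor search.

    Fragments are processed by increasing position in the reference
    sequence; already processed fragments are kept sorted by decreasing
    chain score and the first one that precedes the current fragment is
    taken as predecessor.  Always returns a valid chain; may be suboptimal
    on adversarial inputs.
    """
    if not frags:
        return Chain(fragments=(), score=0)
    frags = _assign_ids(frags)
    ref = _reference_sequence(frags)
    order = sorted(frags, key=lambda f: _sort_key(f, ref))
    total_w = sum(f.weight for f in frags) + 1
    eff = {f.id: (f.weight + total_w if f.mandatory else f.weight) for f in frags}

    scores: dict[int, int] = {}
    back: dict[int, Optional[Fragment]] = {}
    processed: list[Fragment] = []  # kept sorted by decreasing score
    for g in order:
        best: Optional[Fragment] = None
        for f in processed:
            if precedes(f, g):
                best = f
                break
        scores[g.id] = eff[g.id] + (scores[best.id] if best else 0)
        back[g.id] = best
        # insert keeping decreasing score; ties broken as in the DP
        i = 0
        while i < len(processed) and not _better_predecessor(
            processed[i], g, scores, ref
        ):
            i += 1
        processed.insert(i, g)

    end: Optional[Fragment] = None
    for f in order:
        if _better_predecessor(end, f, scores, ref):
            end = f
    out: list[Fragment] = []
    cur = end
    while cur is not None:
        out.append(cur)
        cur = back[cur.id]
    out.reverse()
    return Chain(fragments=tuple(out), score=sum(f.weight for f in out))


def select_subset_chain(
    partials: TSequence[Fragment],
    m: int,
    use_heuristic_above: int = 2000,
) -> Chain:
    """Chain partial fragments via the k-subset construction.

    For each k in ``{floor(m/2)+1, ..., m}`` the k sequences with the most
    fragment-covered bases are selected (ties: lower sequence index) and
    only fragments occurring in all of them are chained.  The chain
    covering the most bases wins; on ties the larger k (more sequences
    anchored) is kept.
    """
    if not partials:
        return Chain(fragments=(), score=0)
    cov = [0] * m
    for f in partials:
        for k in range(m):
            if f.occurs_in(k):
                cov[k] += f.base_length
    ranked = sorted(range(m), key=lambda k: (-cov[k], k))

    best: Chain = Chain(fragments=(), score=0)
    for k in range(m // 2 + 1, m + 1):
        selected = set(ranked[:k])
        subset = [f for f in partials if all(f.occurs_in(s) for s in selected)]
        if not subset:
            continue
        chain = (
            chain_dp(subset)
            if len(subset) <= use_heuristic_above
            else chain_heuristic(subset)
        )
        if chain.score >= best.score:
            best = chain
    return best


@dataclass(frozen=True)
class Candidate:
    """A candidate occurrence of a chain fragment in one sequence."""

    fragment_index: int  # index into the chain's fragment tuple
    sequence: int
    position: int  # 0-based start in that sequence
    weight: int


def his_augment(chain: Chain, candidates: TSequence[Candidate]) -> Chain:
    """Fill absent fragment occurrences by a heaviest-increasing-subsequence
    selection, independently per sequence.

    The fragment order of the chain is fixed; within each sequence a
    maximum-weight subset of candidates is chosen whose positions increase
    with fragment order and which do not overlap each other or existing
    anchored positions.  Candidates for fragments already anchored in that
    sequence are discarded.
    """
    if not chain.fragments or not candidates:
        return chain
    frags = list(chain.fragments)
    nf = len(frags)
    m = len(frags[0].mum.positions)

    per_seq: dict[int, list[Candidate]] = {}
    for c in candidates:
        if not 0 <= c.fragment_index < nf or not 0 <= c.sequence < m:
            raise ValueError("candidate indices out of range")
        if frags[c.fragment_index].occurs_in(c.sequence):
            continue  # conflicts with an existing anchored position
        per_seq.setdefault(c.sequence, []).append(c)

    for s, cands in per_seq.items():
        fixed = [
            (i, frags[i].mum.positions[s]) for i in range(nf) if frags[i].occurs_in(s)
        ]

        def fits_fixed(c: Candidate) -> bool:
            for i, p in fixed:
                if i < c.fragment_index and p + frags[i].length > c.position:
                    return False
                if i > c.fragment_index and c.position + frags[c.fragment_index].length > p:
                    return False
            return True

        cands = sorted(
            (c for c in cands if fits_fixed(c) and c.position >= 0),
            key=lambda c: (c.fragment_index, c.position, -c.weight),
        )
        if not cands:
            continue
        nc = len(cands)
        dp = [0] * nc
        back: list[int] = [-1] * nc
        for j in range(nc):
            cj = cands[j]
            dp[j] = cj.weight
            for i in range(j):
                ci = cands[i]
                if ci.fragment_index >= cj.fragment_index:
                    continue
                if ci.position + frags[ci.fragment_index].length > cj.position:
                    continue
                if dp[i] + cj.weight > dp[j]:
                    dp[j] = dp[i] + cj.weight
                    back[j] = i
        j = max(range(nc), key=lambda i: (dp[i], -cands[i].position, -i))
        chosen: list[Candidate] = []
        while j != -1:
            chosen.append(cands[j])
            j = back[j]
        for c in chosen:
            frags[c.fragment_index] = replace(
                frags[c.fragment_index],
                mum=frags[c.fragment_index].mum.with_position(s, c.position),
            )

    return Chain(fragments=tuple(frags), score=chain.score)
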