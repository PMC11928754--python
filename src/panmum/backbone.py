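"""Backbone construction: lift parse-level anchors to bases and extend them.

The parse-level chain fixes, per sequence, intervals of phrases that are
base-identical across all sequences.  Each chain fragment is lifted to the
base level through the parse coordinate maps and then extended base-by-base
simultaneously in all sequences.  A single mismatching column (most likely
a SNP) is crossed and extension continues if at least ``min_match`` bases
match exactly beyond it; otherwise extension stops before the mismatch.
Only substitution columns are crossed -- every sequence advances exactly
one base -- so indels terminate extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence as TSequence

from .chaining import Chain, Fragment, chain_dp, chain_heuristic
from .esa import build_gsa
from .multimum import find_multimums
from .pfp import Parse, PfpParams, base_weight, parse_collection

__all__ = ["Anchor", "BackboneStats", "lift_to_base", "extend_anchor", "build_backbone"]

log = logging.getLogger(__name__)


@dataclass
class Anchor:
    """Per-sequence base intervals (0-based half-open) aligned column-wise.

    All present intervals have equal length.  ``mismatch_columns`` are the
    in-anchor column offsets at which not all sequences carry the same
    residue (SNP candidates crossed during extension).
    """

    intervals: list[Optional[tuple[int, int]]]
    mismatch_columns: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        for iv in self.intervals:
            if iv is not None:
                return iv[1] - iv[0]
        return 0

    def occurs_in(self, k: int) -> bool:
        return self.intervals[k] is not None

    @property
    def present(self) -> list[int]:
        return [k for k, iv in enumerate(self.intervals) if iv is not None]


@dataclass
class BackboneStats:
    """Phase counters reported by :func:`build_backbone`."""

    phrase_count: int = 0
    multimum_count: int = 0
    anchor_count: int = 0
    extension_count: int = 0  # mismatching columns crossed (SNP candidates)
    covered_bases_chain: int = 0  # before extension
    covered_bases_extended: int = 0


def lift_to_base(chain: Chain, parses: TSequence[Parse]) -> list[Anchor]:
    """Replace each meta-symbol span with its phrases' base interval."""
    anchors: list[Anchor] = []
    for frag in chain.fragments:
        intervals: list[Optional[tuple[int, int]]] = []
        length: Optional[int] = None
        for k, p in enumerate(frag.mum.positions):
            if p is None:
                intervals.append(None)
                continue
            starts = parses[k].phrase_starts
            lo, hi = starts[p], starts[p + frag.length]
            intervals.append((lo, hi))
            if length is None:
                length = hi - lo
            elif hi - lo != length:
                raise ValueError("parse-level anchor expands to unequal base lengths")
        anchors.append(Anchor(intervals=intervals))
    return anchors


def extend_anchor(
    seqs: TSequence[str],
    anchor: Anchor,
    min_match: int = 10,
    left_bounds: TSequence[int] | None = None,
    right_bounds: TSequence[int] | None = None,
) -> Anchor:
    """Extend an exact-match anchor across isolated mismatching columns.

    Both directions are handled the same way (left first): advance all
    present sequences in lockstep while their next residues agree; at a
    disagreeing column, cross it and keep going only if at least
    ``min_match`` residues then agree in every sequence before the next
    disagreement or a bound.  Bounds (per sequence, absolute positions)
    cap the extension at sequence ends or neighbouring anchors.
    """
    ks = anchor.present
    if not ks:
        return anchor
    starts = {k: anchor.intervals[k][0] for k in ks}
    ends = {k: anchor.intervals[k][1] for k in ks}
    lb = {k: (left_bounds[k] if left_bounds is not None else 0) for k in ks}
    rb = {k: (right_bounds[k] if right_bounds is not None else len(seqs[k])) for k in ks}

    def step_ok(off: int, left: bool) -> Optional[bool]:
        """None if a bound blocks the step; else whether residues agree."""
        chars = []
        for k in ks:
            pos = starts[k] - off if left else ends[k] + off - 1
            if left and pos < lb[k]:
                return None
            if not left and pos >= rb[k]:
                return None
            chars.append(seqs[k][pos])
        return all(c == chars[0] for c in chars[1:])

    def extend(left: bool) -> tuple[int, list[int]]:
        committed = 0
        mismatches: list[int] = []
        off = 1
        while True:
            ok = step_ok(off, left)
            if ok is None:
                break
            if ok:
                committed = off
                off += 1
                continue
            # probe across the mismatch: need >= min_match exact matches
            run = 0
            probe = off + 1
            while True:
                nxt = step_ok(probe, left)
                if nxt is None or nxt is False:
                    break
                run += 1
                probe += 1
            if run >= min_match:
                mismatches.append(off)
                committed = off + run
                off = probe
            else:
                break
        return committed, mismatches

    ext_l, mis_l = extend(left=True)
    for k in ks:
        starts[k] -= ext_l
    ext_r, mis_r = extend(left=False)
    for k in ks:
        ends[k] += ext_r

    orig_len = anchor.length
    cols = sorted(
        [ext_l - d for d in mis_l]
        + [c + ext_l for c in anchor.mismatch_columns]
        + [ext_l + orig_len + d - 1 for d in mis_r]
    )
    intervals: list[Optional[tuple[int, int]]] = list(anchor.intervals)
    for k in ks:
        intervals[k] = (starts[k], ends[k])
    return Anchor(intervals=intervals, mismatch_columns=cols)


def build_backbone(
    seqs: TSequence[str],
    pfp_params: PfpParams | None = None,
    min_match: int = 10,
    dp_max_fragments: int = 2000,
    min_weight: int = 1,
) -> tuple[list[Anchor], BackboneStats]:
    """Phases 2a-2d: parse, find parse-level multiMUMs, chain, lift, extend.

    Returns the extended anchors in chain order together with phase
    counters.  ``min_weight`` filters fragments expanding to fewer bases
    before chaining.  With no multiMUM at all, the backbone is empty and
    gap completion sees one all-spanning gap.
    """
    stats = BackboneStats()
    pfp_params = pfp_params or PfpParams()
    dictionary, parses = parse_collection(seqs, pfp_params)
    stats.phrase_count = len(dictionary)
    log.info("pfp: %d distinct phrases over %d sequences", len(dictionary), len(seqs))

    gsa = build_gsa([p.symbols for p in parses])
    mums = find_multimums(gsa)
    stats.multimum_count = len(mums)
    log.info("multimum: %d parse-level multiMUMs", len(mums))

    frags = []
    for i, mum in enumerate(mums):
        # weight: bases obtained by expanding the meta-symbols
        k0 = next(k for k, p in enumerate(mum.positions) if p is not None)
        w = base_weight(parses[k0], mum.positions[k0], mum.positions[k0] + mum.length)
        if w >= min_weight:
            frags.append(Fragment(mum=mum, weight=w, base_length=w, id=i))

    chain = (
        chain_dp(frags) if len(frags) <= dp_max_fragments else chain_heuristic(frags)
    )
    stats.anchor_count = len(chain)
    log.info("chaining: %d anchors, score %d", len(chain), chain.score)

    anchors = lift_to_base(chain, parses)
    stats.covered_bases_chain = sum(a.length * len(a.present) for a in anchors)

    extended: list[Anchor] = []
    m = len(seqs)
    for i, anchor in enumerate(anchors):
        lbs = [0] * m
        rbs = [len(s) for s in seqs]
        if extended:
            prev = extended[-1]
            for k in prev.present:
                lbs[k] = prev.intervals[k][1]
        if i + 1 < len(anchors):
            nxt = anchors[i + 1]
            for k in nxt.present:
                rbs[k] = nxt.intervals[k][0]
        ext = extend_anchor(seqs, anchor, min_match=min_match, left_bounds=lbs, right_bounds=rbs)
        stats.extension_count += len(ext.mismatch_columns)
        extended.append(ext)

    stats.covered_bases_extended = sum(a.length * len(a.present) for a in extended)
    log.info(
        "extension: %d mismatch columns crossed; %d -> %d covered bases",
        stats.extension_count,
        stats.covered_bases_chain,
        stats.covered_bases_extended,
    )
    return extended, stats
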