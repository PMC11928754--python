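"""Recursive completion of the alignment between backbone anchors.

A *gap* is the per-sequence region between two consecutive anchors.  Small
gaps go straight to the small-gap aligner.  Large gaps are split further:

1. find partial multiMUMs inside the gap (on the parse level for very
   large gaps, with a smaller modulus; on the base level otherwise, or
   when a parse-level attempt found nothing);
2. chain them with the k-subset heuristic (every anchor must occur in more
   than half of the gap's non-empty sequences, which makes the chained
   anchors totally orderable);
3. try to map each chained anchor into the sequences it is absent from and
   accept confident, length-preserving hits via the heaviest-increasing-
   subsequence selection;
4. split the gap at the anchors and recurse on the sub-gaps.

A sequence that shares no anchor with the rest while long anchors span all
other sequences is declared unalignable for this gap: its residues are
re-inserted verbatim (an ``unaligned`` block) after the gap's blocks and
the recursion continues without it.  Recursion depth is capped; at the cap
the remaining gap is delegated to the small-gap aligner.
"""

from __future__ import annotations

import functools
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence as TSequence

import edlib

from .alignment import GAP, AlignmentBlock
from .chaining import Candidate, Chain, Fragment, his_augment, precedes, select_subset_chain
from .config import PipelineConfig
from .esa import build_gsa
from .multimum import MultiMUM, find_partial_multimums
from .pfp import PfpParams, parse_collection
from .smallgap import align_small

__all__ = [
    "Gap",
    "MapperMatch",
    "BuiltinMapper",
    "ExternalMapper",
    "read_paf",
    "order_check",
    "map_fragment",
    "fill_gap",
]

log = logging.getLogger(__name__)


@dataclass
class Gap:
    """Texts of one inter-anchor region, one slice per sequence.

    Slices may be empty.  ``residual_anchors`` are fragments (in slice
    coordinates) inherited from a higher recursion level that lower-level
    chains must stay consistent with.
    """

    slices: list[str]
    depth: int = 0
    residual_anchors: list[Fragment] = field(default_factory=list)


@dataclass(frozen=True)
class MapperMatch:
    """One placement of a query fragment inside a target gap region."""

    query_id: str
    target_id: str
    target_start: int
    target_end: int
    quality: int

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError("mapping quality must be non-negative")


class BuiltinMapper:
    """Exact-seed + infix-verification mapper.

    Seeds of length >= 21 sampled from the query are located exactly in
    the target; each candidate placement is verified with a semi-global
    (infix) unit-cost alignment.  The quality score is calibrated so that
    a unique near-exact placement scores far above 30 while ambiguous or
    weak placements score below it.
    """

    def __init__(self, seed_length: int = 21, max_seed_hits: int = 50, pad: int = 50):
        self.seed_length = seed_length
        self.max_seed_hits = max_seed_hits
        self.pad = pad

    def _candidate_offsets(self, query: str, target: str) -> list[int]:
        k = self.seed_length
        if len(query) < k:
            return [0] if len(target) <= 200_000 else []
        seed_positions = sorted({0, (len(query) - k) // 2, len(query) - k})
        offsets: set[int] = set()
        for sp in seed_positions:
            seed = query[sp : sp + k]
            start = 0
            hits = 0
            while hits < self.max_seed_hits:
                i = target.find(seed, start)
                if i < 0:
                    break
                offsets.add(i - sp)
                start = i + 1
                hits += 1
        return sorted(offsets)

    def map(self, query: str, target: str) -> list[MapperMatch]:
        if not query or not target:
            return []
        cands: list[tuple[int, int, int]] = []  # (distance, start, end)
        seen: set[int] = set()
        for off in self._candidate_offsets(query, target):
            lo = max(0, off - self.pad)
            hi = min(len(target), off + len(query) + self.pad)
            window = target[lo:hi]
            res = edlib.align(query, window, mode="HW", task="locations")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            ls, le = res["locations"][0]
            start, end = lo + ls, lo + le + 1
            if start in seen:
                continue
            seen.add(start)
            cands.append((int(res["editDistance"]), start, end))
        if not cands:
            return []
        cands.sort()
        best_d = cands[0][0]
        margin = max(1, len(query) // 20)
        ambiguous = len(cands) > 1 and cands[1][0] - best_d <= margin
        out = []
        for rank, (d, s, e) in enumerate(cands):
            if rank == 0 and not ambiguous:
                identity = 1.0 - d / max(1, len(query))
                q = int(60 * max(0.0, 2 * identity - 1.0))
            else:
                q = 3
            out.append(
                MapperMatch(
                    query_id="q", target_id="t", target_start=s, target_end=e, quality=q
                )
            )
        return out


class ExternalMapper:
    """Subprocess hook for an external mapper emitting PAF.

    ``command`` is a template with ``{query}``, ``{target}`` and
    ``{output}`` placeholders (FASTA query/target in, PAF out).
    """

    def __init__(self, command: str, timeout: float = 600.0):
        self.command = command
        self.timeout = timeout

    def map(self, query: str, target: str) -> list[MapperMatch]:
        with tempfile.TemporaryDirectory() as td:
            qf, tf, of = (Path(td) / n for n in ("q.fa", "t.fa", "out.paf"))
            qf.write_text(f">q\n{query}\n", encoding="ascii")
            tf.write_text(f">t\n{target}\n", encoding="ascii")
            cmd = self.command.format(query=qf, target=tf, output=of)
            try:
                subprocess.run(
                    cmd, shell=True, check=True, capture_output=True, timeout=self.timeout
                )
                text = of.read_text(encoding="ascii") if of.exists() else ""
            except Exception as exc:
                log.warning("external mapper failed (%s); no matches used", exc)
                return []
        return read_paf(text.splitlines())


def read_paf(lines) -> list[MapperMatch]:
    """Parse PAF records (columns 1-12; MAPQ is column 12).

    Only forward-strand matches are kept -- reverse hits would be
    inversions, which the colinear model does not represent.
    """
    out = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(f"PAF record has {len(cols)} columns, expected >= 12")
        if cols[4] != "+":
            continue
        out.append(
            MapperMatch(
                query_id=cols[0],
                target_id=cols[5],
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                quality=int(cols[11]),
            )
        )
    return out


def map_fragment(mapper, fragment_text: str, gap_region: str, mapq_min: int = 30) -> list[MapperMatch]:
    """Map a fragment into a gap region, keeping confident hits only."""
    if mapper is None:
        return []
    try:
        matches = mapper.map(fragment_text, gap_region)
    except Exception as exc:
        log.warning("mapper raised (%s); proceeding without extension", exc)
        return []
    return [mm for mm in matches if mm.quality >= mapq_min]


def order_check(frags: TSequence[Fragment]) -> tuple[list[Fragment], list[Fragment]]:
    """Linearly order fragments under <<, excluding violating ones.

    Every surviving pair is <<-comparable; when a pair is incompatible
    (crossing or overlapping) the lighter fragment is excluded and
    reported.
    """
    pool = list(frags)
    excluded: list[Fragment] = []
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                f, g = pool[i], pool[j]
                shares = any(
                    pf is not None and pg is not None
                    for pf, pg in zip(f.positions, g.positions)
                )
                if shares and not precedes(f, g) and not precedes(g, f):
                    drop = f if f.weight <= g.weight else g
                    log.info("order_check: excluding crossing fragment id=%d", drop.id)
                    excluded.append(drop)
                    pool.remove(drop)
                    changed = True
                    break
            if changed:
                break

    def cmp(f: Fragment, g: Fragment) -> int:
        if precedes(f, g):
            return -1
        if precedes(g, f):
            return 1
        return 0

    return sorted(pool, key=functools.cmp_to_key(cmp)), excluded


# ---------------------------------------------------------------------------
# gap anchor search


def _gap_fragments(
    slices: TSequence[str], active: list[int], level: str, config: PipelineConfig
) -> list[Fragment]:
    """Partial multiMUMs of the gap's non-empty slices as base-level fragments."""
    texts = [slices[j] for j in active]
    m_eff = len(texts)
    min_occ = m_eff // 2 + 1
    m = len(slices)
    frags: list[Fragment] = []
    if level == "parse":
        params = PfpParams(window=config.window, modulus=config.gap_modulus)
        _, parses = parse_collection(texts, params)
        gsa = build_gsa([p.symbols for p in parses])
        for mum in find_partial_multimums(gsa, min_occ=min_occ):
            positions: list[Optional[int]] = [None] * m
            base_len = None
            ok = True
            for a, p in enumerate(mum.positions):
                if p is None:
                    continue
                starts = parses[a].phrase_starts
                lo, hi = starts[p], starts[p + mum.length]
                if base_len is None:
                    base_len = hi - lo
                elif hi - lo != base_len:
                    ok = False
                    break
                positions[active[a]] = lo
            if not ok or not base_len:
                continue
            occ = sum(p is not None for p in positions)
            frags.append(
                Fragment(
                    mum=MultiMUM(length=base_len, positions=tuple(positions), level="base"),
                    weight=base_len * occ,
                    base_length=base_len,
                )
            )
    else:
        gsa = build_gsa(texts)
        for mum in find_partial_multimums(gsa, min_occ=min_occ):
            if mum.length < config.min_base_anchor:
                continue
            positions = [None] * m
            for a, p in enumerate(mum.positions):
                if p is not None:
                    positions[active[a]] = p
            occ = sum(p is not None for p in positions)
            frags.append(
                Fragment(
                    mum=MultiMUM(length=mum.length, positions=tuple(positions), level="base"),
                    weight=mum.length * occ,
                    base_length=mum.length,
                )
            )
    return frags


def _compatible_with_residuals(f: Fragment, residuals: TSequence[Fragment]) -> bool:
    for r in residuals:
        shares = any(
            pf is not None and pr is not None for pf, pr in zip(f.positions, r.positions)
        )
        if shares and not precedes(f, r) and not precedes(r, f):
            return False
    return True


def _gap_chain(
    slices: TSequence[str],
    active: list[int],
    level: str,
    config: PipelineConfig,
    residuals: TSequence[Fragment],
) -> Chain:
    frags = _gap_fragments(slices, active, level, config)
    if residuals:
        frags = [f for f in frags if _compatible_with_residuals(f, residuals)]
        frags.extend(replace(r, mandatory=True) for r in residuals)
    if not frags:
        return Chain(fragments=(), score=0)
    chain = select_subset_chain(
        frags, m=len(slices), use_heuristic_above=config.dp_max_fragments
    )
    # re-merge residuals the subset selection may have dropped
    missing = [
        r
        for r in residuals
        if not any(f.mum is r.mum or f.positions == r.positions for f in chain.fragments)
    ]
    if missing:
        merged, _ = order_check(list(chain.fragments) + [replace(r, mandatory=True) for r in missing])
        chain = Chain(fragments=tuple(merged), score=sum(f.weight for f in merged))
    return chain


def _mapper_extend(
    chain: Chain, slices: TSequence[str], active: list[int], config: PipelineConfig
) -> Chain:
    """Step 3: map chained fragments into sequences they are absent from."""
    if not chain.fragments:
        return chain
    mapper = config.external_mapper or BuiltinMapper()
    frags = chain.fragments
    candidates: list[Candidate] = []
    for s in active:
        text = slices[s]
        # bounding present fragments around each absent run in this sequence
        for idx, f in enumerate(frags):
            if f.occurs_in(s):
                continue
            lo = 0
            for i in range(idx - 1, -1, -1):
                if frags[i].occurs_in(s):
                    lo = frags[i].positions[s] + frags[i].length
                    break
            hi = len(text)
            for i in range(idx + 1, len(frags)):
                if frags[i].occurs_in(s):
                    hi = frags[i].positions[s]
                    break
            if hi <= lo:
                continue
            src = next(k for k in range(len(slices)) if f.occurs_in(k))
            query = slices[src][f.positions[src] : f.positions[src] + f.length]
            for mm in map_fragment(mapper, query, text[lo:hi], config.mapq_min):
                if mm.target_end - mm.target_start != f.length:
                    continue  # only length-preserving hits can share columns
                candidates.append(
                    Candidate(
                        fragment_index=idx,
                        sequence=s,
                        position=lo + mm.target_start,
                        weight=f.base_length,
                    )
                )
    if not candidates:
        return chain
    return his_augment(chain, candidates)


# ---------------------------------------------------------------------------
# splitting and recursion


def _anchor_block(slices: TSequence[str], frag: Fragment) -> AlignmentBlock:
    rows = []
    for j in range(len(slices)):
        p = frag.positions[j]
        rows.append(slices[j][p : p + frag.length] if p is not None else GAP * frag.length)
    return AlignmentBlock(rows=rows, kind="anchor")


def _split_slices(slices: TSequence[str], frags: TSequence[Fragment]) -> list[list[str]]:
    """Per-sequence partition of the gap into len(frags)+1 sub-gap slices.

    A sequence in which a fragment is absent contributes its whole region
    between the two neighbouring *present* fragments to the first sub-gap
    after the earlier one.
    """
    m = len(slices)
    k = len(frags)
    subs = [["" for _ in range(m)] for _ in range(k + 1)]
    for j in range(m):
        cur = 0
        prev_present = -1
        for i, f in enumerate(frags):
            if f.positions[j] is None:
                continue
            s = f.positions[j]
            subs[prev_present + 1][j] = slices[j][cur:s]
            cur = s + f.length
            prev_present = i
        subs[prev_present + 1][j] = slices[j][cur:]
    return subs


def _unaligned_block(slices: TSequence[str], j: int) -> AlignmentBlock:
    rows = [slices[j] if r == j else GAP * len(slices[j]) for r in range(len(slices))]
    return AlignmentBlock(rows=rows, kind="unaligned")


def fill_gap(
    gap: Gap, config: PipelineConfig | None = None, _parse_failed: bool = False
) -> list[AlignmentBlock]:
    """Close one gap recursively, returning its alignment blocks in order."""
    config = config or PipelineConfig()
    slices = gap.slices
    m = len(slices)
    lens = [len(s) for s in slices]
    if max(lens, default=0) == 0:
        return []
    active = [j for j in range(m) if lens[j] > 0]

    if len(active) == 1:
        return [_unaligned_block(slices, active[0])]

    if max(lens) <= config.small_gap_threshold:
        return [align_small(slices, external=config.external_aligner)]
    if gap.depth >= config.max_depth:
        log.warning(
            "gap recursion depth cap (%d) reached at size %d; delegating to the "
            "small-gap aligner",
            config.max_depth,
            max(lens),
        )
        return [align_small(slices, external=config.external_aligner)]

    level = (
        "parse"
        if not _parse_failed
        and max(lens) >= config.parse_gap_factor * config.small_gap_threshold
        else "base"
    )
    chain = _gap_chain(slices, active, level, config, gap.residual_anchors)
    if not chain.fragments and level == "parse":
        log.info("gap: parse-level search found nothing; switching to base level")
        level = "base"
        chain = _gap_chain(slices, active, level, config, gap.residual_anchors)

    chain = _mapper_extend(chain, slices, active, config)

    if not chain.fragments:
        log.warning(
            "gap of size %d yielded no anchors at either level; delegating to the "
            "small-gap aligner",
            max(lens),
        )
        return [align_small(slices, external=config.external_aligner)]

    # unalignable-sequence removal
    frags = list(chain.fragments)
    removed: list[int] = []
    for s in active:
        if any(f.occurs_in(s) for f in frags):
            continue
        others = [a for a in active if a != s]
        spanning = any(
            f.base_length >= config.removal_min_anchor
            and all(f.occurs_in(o) for o in others)
            for f in frags
        )
        if spanning:
            removed.append(s)
    if removed:
        log.info("gap: removing unalignable sequences %s", removed)
        reduced = list(slices)
        for s in removed:
            reduced[s] = ""
        inner = fill_gap(
            Gap(slices=reduced, depth=gap.depth, residual_anchors=gap.residual_anchors),
            config,
            _parse_failed,
        )
        return inner + [_unaligned_block(slices, s) for s in removed]

    ordered, _ = order_check(frags)
    if not ordered:
        return [align_small(slices, external=config.external_aligner)]

    sub_slices = _split_slices(slices, ordered)
    blocks: list[AlignmentBlock] = []
    no_progress = all(f.positions == r.positions for f, r in zip(ordered, gap.residual_anchors)) and len(
        ordered
    ) == len(gap.residual_anchors)
    for i, sub in enumerate(sub_slices):
        blocks.extend(
            fill_gap(
                Gap(slices=sub, depth=gap.depth + 1),
                config,
                _parse_failed=no_progress and level == "parse",
            )
        )
        if i < len(ordered):
            blocks.append(_anchor_block(slices, ordered[i]))
    return blocks
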