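"""Alignment containers: blocks and the block-concatenated MSA.

An :class:`AlignmentBlock` is a set of equal-length gapped rows over the m
sequences (rows may be all-gap).  The final :class:`MSA` is the
concatenation of blocks; removing gap symbols from row j yields exactly the
residues of input sequence j that the alignment covers (the projection
property).  Blocks carry a *kind* tag: ``anchor`` and ``gap`` blocks are
aligned material, ``unaligned`` blocks hold residues of sequences that
could not be aligned in a region and were re-inserted verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TSequence

GAP = "-"

__all__ = ["GAP", "AlignmentBlock", "MSA", "merge_blocks", "ProjectionError"]


class ProjectionError(ValueError):
    """Raised when a produced alignment does not reproduce its inputs."""


@dataclass
class AlignmentBlock:
    """Equal-length gapped rows over all m sequences."""

    rows: list[str]
    kind: str = "gap"  # "anchor" | "gap" | "unaligned"

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"block rows have unequal lengths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class MSA:
    """Gapped rows of equal length, partitioned into blocks.

    ``block_boundaries`` are the cumulative column offsets at which blocks
    end (last entry equals ``column_count``); ``block_kinds`` parallels it.
    """

    rows: list[str]
    ids: list[str] = field(default_factory=list)
    block_boundaries: list[int] = field(default_factory=list)
    block_kinds: list[str] = field(default_factory=list)

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def m(self) -> int:
        return len(self.rows)

    def ungapped(self, j: int) -> str:
        return self.rows[j].replace(GAP, "")

    def blocks(self):
        """Iterate (start_col, end_col, kind) per block."""
        prev = 0
        for b, kind in zip(self.block_boundaries, self.block_kinds):
            yield prev, b, kind
            prev = b

    def validate_projection(self, seqs: TSequence[str]) -> None:
        """Check every row reproduces its input sequence exactly."""
        for j, s in enumerate(seqs):
            got = self.ungapped(j)
            if got != s:
                k = next(
                    (i for i, (a, b) in enumerate(zip(got, s)) if a != b),
                    min(len(got), len(s)),
                )
                raise ProjectionError(
                    f"row {j} does not project onto its input sequence "
                    f"(first difference at residue {k}; row has {len(got)} "
                    f"residues, input {len(s)})"
                )


def merge_blocks(blocks: TSequence[AlignmentBlock], ids: TSequence[str] | None = None) -> MSA:
    """Concatenate blocks (dropping zero-width ones) into a global MSA."""
    blocks = [b for b in blocks if b.width > 0]
    if not blocks:
        return MSA(rows=[], ids=list(ids) if ids else [])
    m = len(blocks[0].rows)
    if any(len(b.rows) != m for b in blocks):
        raise ValueError("blocks disagree on the number of sequences")
    rows = ["".join(b.rows[j] for b in blocks) for j in range(m)]
    boundaries: list[int] = []
    kinds: list[str] = []
    off = 0
    for b in blocks:
        off += b.width
        boundaries.append(off)
        kinds.append(b.kind)
    return MSA(
        rows=rows,
        ids=list(ids) if ids is not None else [f"seq{j}" for j in range(m)],
        block_boundaries=boundaries,
        block_kinds=kinds,
    )
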