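"""Sequence and alignment I/O: FASTA in, MAF / gapped FASTA out.

Alignment rows are written per block in MAF with per-row ``s`` lines
(start, size, strand ``+``, srcSize); rows of size 0 are emitted rather
than dropped so every block has exactly m rows and row/sequence
correspondence stays trivial.  Both emitted dialects round-trip: reading
an alignment written by this module reproduces the MSA bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence as TSequence

from Bio import SeqIO

from .alignment import GAP, MSA

__all__ = [
    "Sequence",
    "FastaError",
    "read_fasta",
    "write_alignment",
    "read_maf",
    "read_gapped_fasta",
    "write_fasta",
]


class FastaError(ValueError):
    """Malformed FASTA input, reported with the offending line number."""


@dataclass(frozen=True)
class Sequence:
    """One input sequence: unique id plus uppercase residues.

    ``source_offsets`` optionally records contig boundary positions when
    the residues are a concatenation of separator-joined contigs.
    """

    id: str
    residues: str
    source_offsets: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


def _validate_fasta_lines(path: Path) -> None:
    """Light structural validation so errors carry a line number
    (Bio.SeqIO is silent about several malformed shapes)."""
    open_header: Optional[int] = None
    has_residues = False
    with open(path, encoding="ascii", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if open_header is not None and not has_residues:
                    raise FastaError(
                        f"{path}:{open_header}: record has no residues"
                    )
                open_header = lineno
                has_residues = False
            else:
                if open_header is None:
                    raise FastaError(
                        f"{path}:{lineno}: expected a '>' header before residues"
                    )
                has_residues = True
    if open_header is not None and not has_residues:
        raise FastaError(f"{path}:{open_header}: record has no residues")


def read_fasta(path) -> list[Sequence]:
    """Read a FASTA file into :class:`Sequence` records (order preserved).

    Residues are uppercased; Windows line endings are handled; an empty
    file yields an empty list; malformed input raises :class:`FastaError`
    naming the line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(Sequence(id=rec.id, residues=str(rec.seq).upper()))
    return out


def write_fasta(seqs: TSequence[Sequence], path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 80):
                fh.write(s.residues[i : i + 80] + "\n")


def _row_starts(msa: MSA) -> list[list[int]]:
    """Per block and row: number of residues consumed before the block."""
    consumed = [0] * msa.m
    starts: list[list[int]] = []
    for lo, hi, _ in msa.blocks():
        starts.append(list(consumed))
        for j in range(msa.m):
            consumed[j] += hi - lo - msa.rows[j].count(GAP, lo, hi)
    return starts


def write_alignment(msa: MSA, fmt: str, path) -> None:
    """Write the MSA as ``maf`` or gapped ``fasta``."""
    if fmt == "maf":
        _write_maf(msa, path)
    elif fmt == "fasta":
        with open(path, "w", encoding="ascii") as fh:
            for j in range(msa.m):
                fh.write(f">{msa.ids[j]}\n{msa.rows[j]}\n")
    else:
        raise ValueError(f"unknown alignment format {fmt!r} (use 'maf' or 'fasta')")


def _write_maf(msa: MSA, path) -> None:
    src_sizes = [len(msa.ungapped(j)) for j in range(msa.m)]
    boundaries = msa.block_boundaries or ([msa.column_count] if msa.column_count else [])
    kinds = msa.block_kinds or ["gap"] * len(boundaries)
    starts = _row_starts(msa) if msa.block_boundaries else [[0] * msa.m]
    with open(path, "w", encoding="ascii") as fh:
        fh.write("##maf version=1 scoring=none\n")
        prev = 0
        for bi, hi in enumerate(boundaries):
            fh.write(f"a block={bi} kind={kinds[bi]}\n")
            for j in range(msa.m):
                text = msa.rows[j][prev:hi]
                size = len(text) - text.count(GAP)
                fh.write(
                    f"s {msa.ids[j]} {starts[bi][j]} {size} + {src_sizes[j]} {text}\n"
                )
            fh.write("\n")
            prev = hi


def read_maf(path) -> MSA:
    """Read a MAF file written by :func:`write_alignment` back into an MSA."""
    ids: list[str] = []
    kinds: list[str] = []
    pieces: dict[str, list[str]] = {}
    block_widths: list[int] = []
    with open(path, encoding="ascii") as fh:
        cur_width = 0
        in_block = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("a"):
                in_block = True
                cur_width = 0
                kind = "gap"
                for tokn in line.split()[1:]:
                    if tokn.startswith("kind="):
                        kind = tokn[5:]
                kinds.append(kind)
            elif line.startswith("s "):
                _, sid, _start, _size, _strand, _src, text = line.split()
                if sid not in pieces:
                    pieces[sid] = []
                    ids.append(sid)
                pieces[sid].append(text)
                cur_width = len(text)
            elif not line.strip() and in_block:
                block_widths.append(cur_width)
                in_block = False
        if in_block:
            block_widths.append(cur_width)
    rows = ["".join(pieces[sid]) for sid in ids]
    boundaries = []
    off = 0
    for w in block_widths:
        off += w
        boundaries.append(off)
    return MSA(rows=rows, ids=ids, block_boundaries=boundaries, block_kinds=kinds)


def read_gapped_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, gapped row) pairs from an aligned FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq)
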