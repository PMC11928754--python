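"""Center-star progressive alignment for small gaps.

Slices between two anchors are aligned with a classic center-star scheme
under unit edit costs (match 0, mismatch 1, indel 1): the star is the slice
minimizing the total pairwise edit distance (computed exactly for up to 8
non-empty slices, estimated on a sample otherwise), every other slice is
aligned to the star pairwise-optimally, and the pairwise alignments are
merged through the star's gap pattern.  The induced pairwise cost of the
result is within a factor 2 of the optimal sum-of-pairs cost.

An external multiple aligner can be hooked in as a subprocess (FASTA in,
gapped FASTA out); its output is validated against the projection property
and the built-in center-star is the fallback.
"""

from __future__ import annotations

import logging
import re
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence as TSequence

import edlib
import numpy as np

from .alignment import GAP, AlignmentBlock

__all__ = ["pairwise_edit_align", "align_small", "ExternalAligner"]

log = logging.getLogger(__name__)

# above this cell count the quadratic DP hands the path computation to
# edlib's banded aligner (identical cost model)
_DP_CELL_LIMIT = 250_000


def _nw_align(a: str, b: str) -> tuple[str, str, int]:
    """Unit-cost global alignment by dynamic programming with traceback."""
    n, k = len(a), len(b)
    dp = np.empty((n + 1, k + 1), dtype=np.int32)
    dp[0] = np.arange(k + 1)
    dp[1:, 0] = np.arange(1, n + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = dp[i]
        prev = dp[i - 1]
        for j in range(1, k + 1):
            row[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,
                row[j - 1] + 1,
            )
    ga, gb = [], []
    i, j = n, k
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            ga.append(a[i - 1])
            gb.append(GAP)
            i -= 1
        else:
            ga.append(GAP)
            gb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ga)), "".join(reversed(gb)), int(dp[n, k])


def _edlib_align(a: str, b: str) -> tuple[str, str, int]:
    """Same cost model via edlib's banded aligner (used for large slices)."""
    res = edlib.align(a, b, mode="NW", task="path")
    ga, gb = [], []
    i = j = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        num = int(num)
        if op in "=XM":
            ga.append(a[i : i + num])
            gb.append(b[j : j + num])
            i += num
            j += num
        elif op == "D":  # deletion in target: consumes b
            ga.append(GAP * num)
            gb.append(b[j : j + num])
            j += num
        else:  # insertion: consumes a
            ga.append(a[i : i + num])
            gb.append(GAP * num)
            i += num
    return "".join(ga), "".join(gb), int(res["editDistance"])


def pairwise_edit_align(a: str, b: str) -> tuple[str, str, int]:
    """Optimal unit-cost pairwise alignment; cost is the Levenshtein distance."""
    if not a and not b:
        return "", "", 0
    if not a:
        return GAP * len(b), b, len(b)
    if not b:
        return a, GAP * len(a), len(a)
    if (len(a) + 1) * (len(b) + 1) > _DP_CELL_LIMIT:
        return _edlib_align(a, b)
    return _nw_align(a, b)


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return len(a) + len(b)
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def _pick_star(slices: TSequence[str], nonempty: list[int], rng_seed: int = 0) -> int:
    if len(nonempty) == 1:
        return nonempty[0]
    if len(nonempty) <= 8:
        others = nonempty
    else:
        rng = np.random.default_rng(rng_seed)
        others = sorted(rng.choice(nonempty, size=8, replace=False).tolist())
    best, best_cost = nonempty[0], None
    for c in nonempty:
        cost = sum(_edit_distance(slices[c], slices[o]) for o in others if o != c)
        if best_cost is None or cost < best_cost:
            best, best_cost = c, cost
    return best


def _merge_into_star(master: list[str], star_gapped: str, other_gapped: str) -> list[str]:
    """Merge a pairwise (star, other) alignment into the master alignment.

    ``master[0]`` is the gapped star row; gaps present in one alignment but
    not the other are inserted into all affected rows.
    """
    nrows = len(master)
    merged: list[list[str]] = [[] for _ in range(nrows + 1)]
    i = j = 0  # i over master columns, j over pairwise columns
    mstar = master[0]
    while i < len(mstar) or j < len(star_gapped):
        mc = mstar[i] if i < len(mstar) else None
        pc = star_gapped[j] if j < len(star_gapped) else None
        if mc == GAP:  # gap introduced by an earlier merge: new row pads
            for r in range(nrows):
                merged[r].append(master[r][i])
            merged[-1].append(GAP)
            i += 1
        elif pc == GAP:  # new pairwise gap in the star: master rows pad
            for r in range(nrows):
                merged[r].append(GAP)
            merged[-1].append(other_gapped[j])
            j += 1
        else:  # both carry the same real star residue
            for r in range(nrows):
                merged[r].append(master[r][i])
            merged[-1].append(other_gapped[j])
            i += 1
            j += 1
    return ["".join(row) for row in merged]


def align_small(slices: TSequence[str], external: "ExternalAligner | None" = None) -> AlignmentBlock:
    """Align gap slices into one block (center-star; optional external tool)."""
    m = len(slices)
    nonempty = [j for j in range(m) if slices[j]]
    if not nonempty:
        return AlignmentBlock(rows=[""] * m, kind="gap")

    if external is not None:
        block = external.try_align(slices)
        if block is not None:
            return block

    if len(nonempty) == 1:
        j = nonempty[0]
        rows = [slices[j] if k == j else GAP * len(slices[j]) for k in range(m)]
        return AlignmentBlock(rows=rows, kind="gap")

    star = _pick_star(slices, nonempty)
    master = [slices[star]]  # row order: star first, then others as merged
    order = [star]
    for j in nonempty:
        if j == star:
            continue
        gs, go, _ = pairwise_edit_align(slices[star], slices[j])
        master = _merge_into_star(master, gs, go)
        order.append(j)

    width = len(master[0])
    rows = [GAP * width] * m
    for r, j in enumerate(order):
        rows[j] = master[r]
    return AlignmentBlock(rows=rows, kind="gap")


class ExternalAligner:
    """Subprocess hook for an external MSA tool (FASTA in, gapped FASTA out).

    ``command`` is a template with ``{input}`` and ``{output}``
    placeholders.  Output failing the projection check is rejected and the
    built-in aligner takes over.
    """

    def __init__(self, command: str, timeout: float = 600.0):
        self.command = command
        self.timeout = timeout

    def try_align(self, slices: TSequence[str]) -> AlignmentBlock | None:
        from .seqio import read_gapped_fasta  # local import to avoid a cycle

        nonempty = [j for j in range(len(slices)) if slices[j]]
        with tempfile.TemporaryDirectory() as td:
            inp = Path(td) / "slices.fa"
            out = Path(td) / "aligned.fa"
            inp.write_text(
                "".join(f">s{j}\n{slices[j]}\n" for j in nonempty), encoding="ascii"
            )
            cmd = self.command.format(input=inp, output=out)
            try:
                subprocess.run(
                    cmd, shell=True, check=True, capture_output=True, timeout=self.timeout
                )
                rows_by_id = dict(read_gapped_fasta(out))
            except Exception as exc:  # crash or malformed output -> fallback
                log.warning("external aligner failed (%s); falling back", exc)
                return None
        try:
            width = len(next(iter(rows_by_id.values())))
            rows = []
            for j in range(len(slices)):
                if j in set(nonempty):
                    row = rows_by_id[f"s{j}"]
                    if row.replace(GAP, "") != slices[j]:
                        raise ValueError("projection mismatch")
                    rows.append(row)
                else:
                    rows.append(GAP * width)
            return AlignmentBlock(rows=rows, kind="gap")
        except Exception as exc:
            log.warning("external aligner output rejected (%s); falling back", exc)
            return None
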