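"""Alignment-quality metrics: percent coverage, percent identity, SP-value.

* coverage: bases inside aligned blocks (anchors and aligned gaps, not
  verbatim-reinserted material) relative to all input bases;
* identity: columns without gaps in which all residues are identical,
  relative to the number of columns, optionally omitting an excluded
  column interval from numerator and denominator (e.g. a centromere-like
  region that has no meaningful alignment);
* SP-value: sum of pairwise distances over all unordered row pairs divided
  by the number of sequences (lower is better).  Two modes: ``induced``
  scores the gapped rows as aligned (gap-vs-residue and mismatch cost 1,
  gap-vs-gap 0); ``exact`` recomputes the true Levenshtein distance of the
  ungapped rows, which lower-bounds the induced score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as TSequence

import edlib

from .alignment import GAP, MSA
from .backbone import Anchor

__all__ = ["MetricsReport", "coverage_percent", "identity_percent", "sp_value", "metrics_report"]


@dataclass
class MetricsReport:
    coverage_percent: float
    identity_percent: Optional[float]
    sp_value: float
    excluded_region: Optional[tuple[int, int]] = None

    def to_tsv(self) -> str:
        ident = "NA" if self.identity_percent is None else f"{self.identity_percent:.2f}"
        return (
            "metric\tvalue\n"
            f"Coverage in percent\t{self.coverage_percent:.2f}\n"
            f"Identity in percent\t{ident}\n"
            f"SP-value\t{self.sp_value:.6g}\n"
        )


def _covered_bases_msa(msa: MSA) -> int:
    total = 0
    for lo, hi, kind in msa.blocks():
        if kind == "unaligned":
            continue
        for row in msa.rows:
            total += (hi - lo) - row.count(GAP, lo, hi)
    return total


def coverage_percent(anchors_or_msa, seqs: TSequence[str]) -> float:
    """Percentage of all input bases contained in aligned material.

    Accepts either a list of :class:`Anchor` (backbone-stage coverage) or
    a final :class:`MSA` (verbatim-reinserted blocks do not count).
    """
    total = sum(len(s) for s in seqs)
    if total == 0:
        return 0.0
    if isinstance(anchors_or_msa, MSA):
        covered = _covered_bases_msa(anchors_or_msa)
    else:
        covered = sum(
            iv[1] - iv[0]
            for a in anchors_or_msa
            for iv in a.intervals
            if iv is not None
        )
    return 100.0 * covered / total


def identity_percent(
    msa: MSA, excluded_region: Optional[tuple[int, int]] = None
) -> Optional[float]:
    """Percentage of gap-free, single-residue columns; None if no columns."""
    lo_x, hi_x = excluded_region if excluded_region is not None else (0, 0)
    n_cols = 0
    n_ident = 0
    rows = msa.rows
    for c in range(msa.column_count):
        if lo_x <= c < hi_x:
            continue
        n_cols += 1
        first = rows[0][c]
        if first == GAP:
            continue
        if all(r[c] == first for r in rows):
            n_ident += 1
    if n_cols == 0:
        return None
    return 100.0 * n_ident / n_cols


def _induced_pair_distance(a: str, b: str) -> int:
    return sum(
        1 for x, y in zip(a, b) if not (x == GAP and y == GAP) and x != y
    )


def sp_value(rows: TSequence[str], mode: str = "induced", scale: float = 1.0) -> float:
    """Sum of pairwise distances over unordered pairs divided by the number
    of sequences, times ``scale`` (use 1e5 for a display scale of 1e-5)."""
    m = len(rows)
    if m < 2:
        raise ValueError("SP-value needs at least 2 sequences")
    total = 0
    for i in range(m):
        for j in range(i + 1, m):
            if mode == "induced":
                total += _induced_pair_distance(rows[i], rows[j])
            elif mode == "exact":
                a, b = rows[i].replace(GAP, ""), rows[j].replace(GAP, "")
                if not a or not b:
                    total += len(a) + len(b)
                else:
                    total += int(
                        edlib.align(a, b, mode="NW", task="distance")["editDistance"]
                    )
            else:
                raise ValueError(f"unknown SP mode {mode!r}")
    return scale * total / m


def metrics_report(
    msa: MSA,
    seqs: TSequence[str],
    excluded_region: Optional[tuple[int, int]] = None,
    sp_mode: str = "induced",
) -> MetricsReport:
    return MetricsReport(
        coverage_percent=coverage_percent(msa, seqs),
        identity_percent=identity_percent(msa, excluded_region),
        sp_value=sp_value(msa.rows, mode=sp_mode),
        excluded_region=excluded_region,
    )
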