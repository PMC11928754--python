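"""Synthetic pangenome generation for tests and demonstrations.

Each simulated individual derives independently from one i.i.d.-uniform
ACGT ancestor by per-base substitutions (SNPs), short indels with
geometric lengths, optional deletion of leading/trailing/internal segments
(emulating the missing data of fragmented, contig-based assemblies), and
optional large inversions (a documented failure mode of colinear
alignment, not something the aligner is expected to recover).  Every
variant is recorded in a truth table; re-applying the recorded variants to
the ancestor reproduces each sequence exactly.

The generator models free mutation only: no recombination, no shared
ancestry structure between individuals, no repeat families and no mutation
rate heterogeneity.  Tests passing on these fixtures demonstrate the
mechanics of the aligner under controlled divergence, not performance on
real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import Sequence

__all__ = ["FixtureParams", "Variant", "generate", "apply_variants", "toy_instance"]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Variant:
    """One recorded difference from the ancestor.

    ``position`` is the 0-based ancestor coordinate; ``kind`` is one of
    ``snp`` (``alt`` replaces one base), ``ins`` (``alt`` inserted before
    the position), ``del`` (``length`` bases removed), ``inv``
    (``length`` bases reverse-complemented), ``missing`` (``length`` bases
    removed to emulate assembly gaps).
    """

    kind: str
    position: int
    length: int = 0
    alt: str = ""


@dataclass(frozen=True)
class FixtureParams:
    """Simulation parameters: rates are per ancestor base."""

    ancestor_length: int = 50_000
    m: int = 5
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    indel_length_p: float = 0.3  # geometric success prob.; mean 1/p bases
    missing_fraction: float = 0.0
    inversion_count: int = 0
    inversion_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate, self.missing_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _derive(
    ancestor: str, rng: np.random.Generator, params: FixtureParams
) -> tuple[str, list[Variant]]:
    variants: list[Variant] = []
    n = len(ancestor)

    # inversions first (non-overlapping, interior)
    inverted_spans: list[tuple[int, int]] = []
    for _ in range(params.inversion_count):
        for _attempt in range(20):
            lo = int(rng.integers(0, max(1, n - params.inversion_length)))
            hi = lo + params.inversion_length
            if all(hi <= a or lo >= b for a, b in inverted_spans):
                inverted_spans.append((lo, hi))
                variants.append(Variant("inv", lo, params.inversion_length))
                break

    # per-base SNPs and indels
    snp_hits = np.flatnonzero(rng.random(n) < params.snp_rate)
    indel_hits = set(np.flatnonzero(rng.random(n) < params.indel_rate).tolist())
    alt_choice = rng.integers(0, 3, size=snp_hits.size)
    for pos, c in zip(snp_hits.tolist(), alt_choice.tolist()):
        ref = ancestor[pos]
        alt = _BASES.replace(ref, "")[c]
        variants.append(Variant("snp", pos, 1, alt))
    for pos in sorted(indel_hits):
        length = int(rng.geometric(params.indel_length_p))
        if rng.random() < 0.5:
            variants.append(Variant("ins", pos, length, _random_dna(rng, length)))
        else:
            variants.append(Variant("del", pos, min(length, n - pos)))

    # missing segments: half the missing mass at the ends, half internal
    if params.missing_fraction > 0:
        miss_total = int(round(params.missing_fraction * n))
        lead = int(rng.integers(0, miss_total // 2 + 1))
        trail = int(rng.integers(0, (miss_total - lead) // 2 + 1))
        internal = miss_total - lead - trail
        if lead:
            variants.append(Variant("missing", 0, lead))
        if trail:
            variants.append(Variant("missing", n - trail, trail))
        if internal:
            lo = int(rng.integers(lead, max(lead + 1, n - trail - internal)))
            variants.append(Variant("missing", lo, internal))

    seq = apply_variants(ancestor, variants)
    return seq, variants


def apply_variants(ancestor: str, variants: list[Variant]) -> str:
    """Reproduce a derived sequence from the ancestor and its truth record."""
    n = len(ancestor)
    # removal mask and substitution layer first, then insertions/inversions
    keep = np.ones(n, dtype=bool)
    chars = list(ancestor)
    inserts: dict[int, str] = {}
    for v in variants:
        if v.kind == "snp":
            chars[v.position] = v.alt
        elif v.kind in ("del", "missing"):
            keep[v.position : v.position + v.length] = False
        elif v.kind == "ins":
            inserts[v.position] = inserts.get(v.position, "") + v.alt
        elif v.kind == "inv":
            seg = "".join(chars[v.position : v.position + v.length])
            chars[v.position : v.position + v.length] = list(
                seg.translate(_COMP)[::-1]
            )
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    out: list[str] = []
    for i in range(n):
        if i in inserts:
            out.append(inserts[i])
        if keep[i]:
            out.append(chars[i])
    if n in inserts:
        out.append(inserts[n])
    return "".join(out)


def generate(
    params: FixtureParams | None = None,
) -> tuple[str, list[Sequence], dict[str, list[Variant]]]:
    """Simulate a pangenome: returns (ancestor, sequences, truth record)."""
    params = params or FixtureParams()
    rng = np.random.default_rng(params.seed)
    ancestor = _random_dna(rng, params.ancestor_length)
    seqs: list[Sequence] = []
    truth: dict[str, list[Variant]] = {}
    for j in range(params.m):
        residues, variants = _derive(ancestor, rng, params)
        sid = f"ind{j}"
        seqs.append(Sequence(id=sid, residues=residues))
        truth[sid] = variants
    return ancestor, seqs, truth


def toy_instance() -> list[str]:
    """The worked toy instance over the 4-symbol alphabet A,B,C,D.

    Three parse-like symbol sequences whose enhanced GSA has exactly one
    qualifying width-3 lcp-interval, yielding the single multiMUM "BC" of
    length 2 at (1-based) starts 2, 1, 2.
    """
    return ["ABCA", "BCAC", "ABCD"]
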