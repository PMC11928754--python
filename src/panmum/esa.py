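"""Enhanced generalized suffix array (GSA) over m sentinel-terminated texts.

Each document ``S_j`` is conceptually terminated by its own sentinel ``#_j``
with ``#_1 < #_2 < ... < #_m`` smaller than every regular symbol.  The
implementation concatenates the documents with per-document separator ranks
ordered by document index; because every sentinel occurs exactly once,
suffix comparisons never run past a document boundary and the concatenated
construction realizes exactly the m-sentinel semantics, including the
tie-break that equal suffixes are ordered by increasing document index.

The structure carries, per suffix-array row: the within-document start
position (``sa``), the document index (``da``), the longest common prefix
with the previous row (``lcp``, with ``lcp[0] = -1`` and a virtual ``-1``
past the end) and the preceding symbol (``bwt``; the document's own
sentinel when the suffix starts at position 0).

Works uniformly for base-level texts (strings) and parse-level symbol
sequences (tuples/lists of ints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterator, Sequence as TSequence

import numpy as np

__all__ = ["EnhancedGSA", "LcpInterval", "build_gsa", "enumerate_lcp_intervals"]


@dataclass(frozen=True)
class LcpInterval:
    """Maximal interval of suffix-array rows sharing a prefix of length ``ell``.

    Bounds are inclusive row indices (0-based) with ``lb < rb``.
    """

    ell: int
    lb: int
    rb: int

    @property
    def width(self) -> int:
        return self.rb - self.lb + 1


@dataclass
class EnhancedGSA:
    """SA + document array + LCP array + BWT over ``m`` documents."""

    sa: np.ndarray  # within-document 0-based suffix start positions
    da: np.ndarray  # 0-based document indices
    lcp: np.ndarray  # lcp[0] == -1; lcp[i] = |lcp(suffix at i-1, suffix at i)|
    bwt: np.ndarray  # integer tokens; 1..m are sentinels, > m regular symbols
    n: int  # total rows: m + sum of document lengths
    m: int  # number of documents
    docs: list[tuple[Hashable, ...]]  # original documents (symbol tuples)

    def bwt_is_sentinel(self, i: int) -> bool:
        return int(self.bwt[i]) <= self.m

    def suffix_prefix(self, i: int, length: int) -> tuple[Hashable, ...]:
        """The first ``length`` symbols of the suffix at row ``i``."""
        d, p = int(self.da[i]), int(self.sa[i])
        return self.docs[d][p : p + length]


def _suffix_array_int(arr: np.ndarray) -> np.ndarray:
    """Suffix array of an integer array by prefix doubling (O(n log^2 n))."""
    n = arr.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    order = np.argsort(arr, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    sv = arr[order]
    rank[order] = np.cumsum(np.concatenate(([0], (sv[1:] != sv[:-1]).astype(np.int64))))
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        idx = np.lexsort((key2, rank))
        changed = (rank[idx[1:]] != rank[idx[:-1]]) | (key2[idx[1:]] != key2[idx[:-1]])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[idx] = np.cumsum(np.concatenate(([0], changed.astype(np.int64))))
        rank = new_rank
        if rank[idx[-1]] == n - 1:
            return idx.astype(np.int64)
        k *= 2


def _lcp_kasai(arr: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array (lcp[i] between rows i-1 and i) by Kasai's algorithm."""
    n = arr.size
    lcp = np.zeros(n, dtype=np.int64)
    if n == 0:
        return lcp
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    a = arr
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and a[i + h] == a[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    lcp[0] = -1
    return lcp


def build_gsa(seqs: TSequence) -> EnhancedGSA:
    """Build the enhanced GSA of ``m`` non-empty symbol sequences.

    ``seqs`` may be strings (base level) or sequences of ints (parse
    level); symbols must be mutually comparable within one call.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    docs = [tuple(s) for s in seqs]
    if any(len(d) == 0 for d in docs):
        raise ValueError("sequences must be non-empty")
    m = len(docs)

    alphabet = sorted({sym for d in docs for sym in d})
    tok = {sym: m + 1 + r for r, sym in enumerate(alphabet)}

    # concatenation: doc_0 #_1 doc_1 #_2 ... doc_{m-1} #_m
    total = sum(len(d) for d in docs) + m
    concat = np.empty(total, dtype=np.int64)
    doc_of = np.empty(total, dtype=np.int64)
    pos_in_doc = np.empty(total, dtype=np.int64)
    off = 0
    for j, d in enumerate(docs):
        for k, sym in enumerate(d):
            concat[off + k] = tok[sym]
        concat[off + len(d)] = j + 1  # sentinel #_{j+1}
        doc_of[off : off + len(d) + 1] = j
        pos_in_doc[off : off + len(d) + 1] = np.arange(len(d) + 1)
        off += len(d) + 1

    sa_abs = _suffix_array_int(concat)
    lcp = _lcp_kasai(concat, sa_abs)

    da = doc_of[sa_abs]
    sa = pos_in_doc[sa_abs]
    bwt = np.where(sa == 0, da + 1, concat[np.maximum(sa_abs - 1, 0)])

    return EnhancedGSA(sa=sa, da=da, lcp=lcp, bwt=bwt, n=total, m=m, docs=docs)


def enumerate_lcp_intervals(
    gsa: EnhancedGSA, min_ell: int = 1
) -> Iterator[LcpInterval]:
    """Enumerate every lcp-interval exactly once (stack algorithm, O(n)).

    The root interval (ell = 0, spanning all rows) is reported only when
    ``min_ell == 0``.  At most ``n - 1`` intervals exist.
    """
    n = gsa.n
    lcp = gsa.lcp
    stack: list[list[int]] = [[0, 0]]  # (ell, lb)
    for i in range(1, n + 1):
        cur = int(lcp[i]) if i < n else -1  # virtual lcp[n] = -1
        lb = i - 1
        while cur < stack[-1][0]:
            ell, slb = stack.pop()
            if ell >= min_ell and i - 1 > slb:
                yield LcpInterval(ell=ell, lb=slb, rb=i - 1)
            lb = slb
            if not stack:
                break
        if not stack or cur > stack[-1][0]:
            stack.append([cur, lb])
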