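"""Independent brute-force oracles used to verify the implementation.

Everything here works directly from definitions (sort all suffixes, try
all substrings, enumerate all chains/subsets) and shares no code with the
package beyond trivial data types.
"""

from __future__ import annotations

from itertools import product


def _mapped_suffix(docs, j, p):
    """Suffix of document j starting at p, as comparable tokens ending in
    the document's own sentinel (#_1 < ... < #_m < all symbols)."""
    return tuple(("sym", c) for c in docs[j][p:]) + (("sent", j),)


def token_key(tok):
    kind, v = tok
    return (0, v) if kind == "sent" else (1, v)


def naive_gsa(docs):
    """Sort every suffix of every document; return (sa, da, lcp, bwt).

    ``bwt`` entries are ('sent', doc) or ('sym', symbol) tokens; ``lcp``
    uses -1 at index 0.
    """
    entries = []
    for j, d in enumerate(docs):
        for p in range(len(d) + 1):
            key = tuple(token_key(t) for t in _mapped_suffix(docs, j, p))
            entries.append((key, j, p))
    entries.sort()
    sa = [p for _, _, p in entries]
    da = [j for _, j, _ in entries]
    lcp = [-1]
    for (ka, _, _), (kb, _, _) in zip(entries, entries[1:]):
        h = 0
        while h < len(ka) and h < len(kb) and ka[h] == kb[h]:
            h += 1
        lcp.append(h)
    bwt = []
    for _, j, p in entries:
        bwt.append(("sent", j) if p == 0 else ("sym", docs[j][p - 1]))
    return sa, da, lcp, bwt


def naive_lcp_intervals(lcp):
    """Every (ell, lb, rb) satisfying the lcp-interval definition, ell >= 1."""
    n = len(lcp)
    out = set()
    for lb in range(n):
        for rb in range(lb + 1, n):
            inner = lcp[lb + 1 : rb + 1]
            ell = min(inner)
            if ell < 1:
                continue
            if lcp[lb] >= ell:
                continue
            if rb + 1 < n and lcp[rb + 1] >= ell:
                continue
            out.add((ell, lb, rb))
    return out


def _occurrences(doc, w):
    return [p for p in range(len(doc) - len(w) + 1) if tuple(doc[p : p + len(w)]) == tuple(w)]


def brute_partial_multimums(docs, min_occ):
    """All (length, positions-with-None) tuples satisfying the partial
    multiMUM definition with the all-occurrences-accounted semantics:
    the substring occurs exactly once in each covered sequence, nowhere
    else, in at least min_occ sequences, and is left- and right-maximal
    over the covered set (position 0 / sequence end act as per-document
    sentinels)."""
    m = len(docs)
    out = set()
    for src in docs:
        for i in range(len(src)):
            for j in range(i + 1, len(src) + 1):
                w = src[i:j]
                occs = [_occurrences(d, w) for d in docs]
                if any(len(o) > 1 for o in occs):
                    continue
                covered = [k for k in range(m) if len(occs[k]) == 1]
                if len(covered) < min_occ:
                    continue
                pos = tuple(occs[k][0] if len(occs[k]) == 1 else None for k in range(m))
                left = {
                    ("sent", k) if pos[k] == 0 else ("sym", docs[k][pos[k] - 1])
                    for k in covered
                }
                if len(left) == 1:
                    continue
                right = {
                    ("sent", k)
                    if pos[k] + len(w) == len(docs[k])
                    else ("sym", docs[k][pos[k] + len(w)])
                    for k in covered
                }
                if len(right) == 1:
                    continue
                out.add((len(w), pos))
    return out


def brute_multimums(docs):
    return brute_partial_multimums(docs, min_occ=len(docs))


def frag_precedes(f, g):
    """(length, positions, weight) fragments; << on common sequences."""
    common = False
    for pf, pg in zip(f[1], g[1]):
        if pf is None or pg is None:
            continue
        common = True
        if pf + f[0] > pg:
            return False
    return common


def brute_best_chain_score(frags, ref=0):
    """Optimal chain score by exhaustive subset enumeration (k <= ~15).

    Fragments are (length, positions, weight) with all positions present;
    << is transitive there, so a subset is a chain iff consecutive
    elements (sorted by the first position) precede each other.
    """
    k = len(frags)
    best = 0
    for mask in range(1 << k):
        sel = [frags[i] for i in range(k) if mask >> i & 1]
        sel.sort(key=lambda f: f[1][ref])
        if all(frag_precedes(a, b) for a, b in zip(sel, sel[1:])):
            best = max(best, sum(f[2] for f in sel))
    return best


def brute_his_best(candidates, frag_lengths, fixed):
    """Max total weight of a feasible candidate subset for one sequence.

    ``candidates``: (fragment_index, position, weight); ``fixed``: list of
    (fragment_index, position) already anchored in this sequence.  A
    subset is feasible if fragment indices are distinct and positions
    strictly increase without overlap along the fragment order, also
    against the fixed anchors.
    """
    n = len(candidates)
    best = 0
    for mask in range(1 << n):
        sel = [candidates[i] for i in range(n) if mask >> i & 1]
        items = sel + [(i, p, 0) for i, p in fixed]
        idxs = [i for i, _, _ in items]
        if len(set(idxs)) != len(idxs):
            continue
        items.sort()
        ok = True
        for (i1, p1, _), (i2, p2, _) in zip(items, items[1:]):
            if p1 + frag_lengths[i1] > p2:
                ok = False
                break
        if ok:
            best = max(best, sum(w for _, _, w in sel))
    return best


def dp_levenshtein(a, b):
    """Classical dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def all_strings(alphabet, max_len):
    """Every string over ``alphabet`` of length 1..max_len."""
    for L in range(1, max_len + 1):
        for tup in product(alphabet, repeat=L):
            yield "".join(tup)


def all_partitions(s, max_parts):
    """Every split of ``s`` into 1..max_parts non-empty contiguous parts."""
    n = len(s)
    if n == 0:
        return
    def rec(start, parts_left):
        if start == n:
            yield []
            return
        if parts_left == 0:
            return
        for end in range(start + 1, n + 1):
            for rest in rec(end, parts_left - 1):
                yield [s[start:end]] + rest
    yield from rec(0, max_parts)
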