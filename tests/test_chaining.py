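"""Fragment chaining: exact DP vs exhaustive enumeration, heuristics, HIS."""

import numpy as np
import pytest

from panmum import (
    Candidate,
    Chain,
    Fragment,
    MultiMUM,
    chain_dp,
    chain_heuristic,
    his_augment,
    precedes,
    select_subset_chain,
)

from oracles import brute_best_chain_score, brute_his_best


def frag(length, positions, weight=None, fid=0):
    return Fragment(
        mum=MultiMUM(length=length, positions=tuple(positions)),
        weight=weight if weight is not None else length,
        base_length=length,
        id=fid,
    )


def random_fragments(rng, k, m, span=60):
    out = []
    for i in range(k):
        length = int(rng.integers(1, 6))
        pos = tuple(int(x) for x in rng.integers(0, span, size=m))
        out.append(frag(length, pos, weight=int(rng.integers(1, 10)), fid=i))
    return out


def as_tuples(frags):
    return [(f.length, f.positions, f.weight) for f in frags]


def assert_valid_chain(chain: Chain):
    for a, b in zip(chain.fragments, chain.fragments[1:]):
        assert precedes(a, b)


class TestPrecedes:
    def test_irreflexive(self):
        f = frag(3, (0, 0))
        assert not precedes(f, f)

    def test_disjoint_same_order(self):
        assert precedes(frag(2, (0, 5)), frag(2, (3, 8)))

    def test_crossing_pair_neither_direction(self):
        f, g = frag(2, (0, 10)), frag(2, (5, 2))
        assert not precedes(f, g) and not precedes(g, f)

    def test_touching_is_allowed_overlap_is_not(self):
        f = frag(3, (0, 0))
        assert precedes(f, frag(1, (3, 3)))  # ends at 2, next starts at 3
        assert not precedes(f, frag(1, (2, 3)))

    def test_partials_compared_on_common_sequences(self):
        f = frag(2, (0, 0, None))
        g = frag(2, (5, None, 0))
        assert precedes(f, g)  # only sequence 0 is common
        assert not precedes(frag(2, (None, 0, 1)), frag(2, (3, None, None)))


class TestChainDP:
    def test_single_fragment(self):
        c = chain_dp([frag(4, (0, 0))])
        assert len(c) == 1 and c.score == 4

    def test_empty(self):
        assert chain_dp([]).score == 0

    def test_excludes_overlapping_and_noncolinear(self):
        # mirror of the schematic exclusion cases: crossing and overlapping
        # fragments cannot join the colinear chain
        i = frag(3, (0, 0), weight=3, fid=0)
        ii = frag(3, (4, 4), weight=3, fid=1)
        iii = frag(3, (8, 8), weight=3, fid=2)
        crossing = frag(3, (12, 0), weight=9, fid=3)
        overlapping = frag(3, (5, 5), weight=1, fid=4)
        frags = [i, ii, iii, crossing, overlapping]
        c = chain_dp(frags)
        assert c.score == brute_best_chain_score(as_tuples(frags))
        assert {f.id for f in c.fragments} == {0, 1, 2}

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(60):
            k = int(rng.integers(1, 11))
            m = int(rng.integers(1, 4))
            frags = random_fragments(rng, k, m)
            c = chain_dp(frags)
            assert_valid_chain(c)
            assert c.score == brute_best_chain_score(as_tuples(frags))

    def test_monotonicity_adding_a_fragment(self, rng):
        for _ in range(30):
            frags = random_fragments(rng, 8, 2)
            base = chain_dp(frags[:-1]).score
            assert chain_dp(frags).score >= base


class TestChainHeuristic:
    def test_always_valid(self, rng):
        for _ in range(60):
            frags = random_fragments(rng, int(rng.integers(1, 12)), 2)
            assert_valid_chain(chain_heuristic(frags))

    def test_equals_dp_when_all_colinear(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 10))
            frags = [frag(2, (5 * i, 5 * i), weight=int(rng.integers(1, 9)), fid=i) for i in range(k)]
            assert chain_heuristic(frags).score == chain_dp(frags).score

    def test_near_colinear_instances_rarely_suboptimal(self, rng):
        mismatches = 0
        trials = 150
        for _ in range(trials):
            k = 12
            frags = [frag(3, (4 * i, 4 * i), weight=int(rng.integers(2, 9)), fid=i) for i in range(k)]
            # one disruptive crossing fragment (<=10% of the instance)
            frags.append(frag(3, (50, 0), weight=1, fid=k))
            h, d = chain_heuristic(frags), chain_dp(frags)
            assert_valid_chain(h)
            if h.score != d.score:
                mismatches += 1
        assert mismatches / trials <= 0.01


class TestSubsetChain:
    def test_reduces_to_full_chain_when_everything_full(self, rng):
        frags = [frag(2, (4 * i, 4 * i, 4 * i), fid=i) for i in range(5)]
        c = select_subset_chain(frags, m=3)
        assert c.score == chain_dp(frags).score

    def test_dropping_a_poor_sequence_wins(self):
        # sequence 2 lacks all long fragments; the k=2 chain covers more bases
        long1 = frag(10, (0, 0, None), weight=20, fid=0)
        long2 = frag(10, (20, 20, None), weight=20, fid=1)
        short = frag(2, (40, 40, 0), weight=6, fid=2)
        c = select_subset_chain([long1, long2, short], m=3)
        ids = {f.id for f in c.fragments}
        assert {0, 1} <= ids

    def test_matches_exhaustive_subset_search(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 5))
            k = int(rng.integers(1, 7))
            frags = []
            for i in range(k):
                length = int(rng.integers(1, 5))
                occ = [bool(rng.random() < 0.8) for _ in range(m)]
                if sum(occ) <= m // 2:
                    for j in range(m // 2 + 1 - sum(occ)):
                        occ[j] = True
                pos = tuple(
                    int(rng.integers(0, 40)) if o else None for o in occ
                )
                n_occ = sum(p is not None for p in pos)
                frags.append(frag(length, pos, weight=length * n_occ, fid=i))
            got = select_subset_chain(frags, m=m)
            # the construction fixes, per k, the k sequences with the most
            # covered bases (ties to the lower index); chains within each
            # such subset are enumerated exhaustively
            cov = [0] * m
            for f in frags:
                for s in range(m):
                    if f.positions[s] is not None:
                        cov[s] += f.base_length
            ranked = sorted(range(m), key=lambda s: (-cov[s], s))
            best = 0
            for size in range(m // 2 + 1, m + 1):
                subset = sorted(ranked[:size])
                cand = [
                    f for f in frags if all(f.positions[s] is not None for s in subset)
                ]
                if cand:
                    best = max(
                        best, brute_best_chain_score(as_tuples(cand), ref=subset[0])
                    )
            assert got.score == best
            # and never exceeds the exhaustive all-subsets optimum
            import itertools

            ceiling = 0
            for size in range(m // 2 + 1, m + 1):
                for subset in itertools.combinations(range(m), size):
                    cand = [
                        f for f in frags if all(f.positions[s] is not None for s in subset)
                    ]
                    if cand:
                        ceiling = max(
                            ceiling,
                            brute_best_chain_score(as_tuples(cand), ref=subset[0]),
                        )
            assert got.score <= ceiling


class TestHisAugment:
    def chain_of(self, *frags):
        return Chain(fragments=tuple(frags), score=sum(f.weight for f in frags))

    def test_no_candidates_is_identity(self):
        c = self.chain_of(frag(2, (0, 0, None)))
        assert his_augment(c, []) == c

    def test_crossing_candidates_keep_the_heavier(self):
        c = self.chain_of(
            frag(2, (0, 0, None), fid=0), frag(2, (5, 5, None), fid=1)
        )
        cands = [
            Candidate(fragment_index=0, sequence=2, position=10, weight=2),
            Candidate(fragment_index=1, sequence=2, position=0, weight=5),
        ]
        out = his_augment(c, cands)
        assert out.fragments[0].positions[2] is None
        assert out.fragments[1].positions[2] == 0

    def test_candidate_conflicting_with_existing_anchor_discarded(self):
        c = self.chain_of(frag(2, (0, 0, 7)))
        out = his_augment(
            c, [Candidate(fragment_index=0, sequence=2, position=1, weight=9)]
        )
        assert out.fragments[0].positions[2] == 7

    def test_matches_exponential_oracle(self, rng):
        for _ in range(40):
            nf = int(rng.integers(2, 6))
            frags = []
            fixed = []
            for i in range(nf):
                present = bool(rng.random() < 0.4)
                pos = 10 * i if present else None
                frags.append(frag(3, (10 * i, pos), fid=i))
                if present:
                    fixed.append((i, 10 * i))
            c = self.chain_of(*frags)
            nc = int(rng.integers(0, 9))
            pairs = set()
            while len(pairs) < nc:
                pairs.add((int(rng.integers(0, nf)), int(rng.integers(0, 50))))
            cands = [
                Candidate(
                    fragment_index=fi,
                    sequence=1,
                    position=p,
                    weight=int(rng.integers(1, 10)),
                )
                for fi, p in sorted(pairs)
            ]
            cands = [c2 for c2 in cands if frags[c2.fragment_index].positions[1] is None]
            out = his_augment(c, cands)
            added = sum(
                c2.weight
                for c2 in cands
                if out.fragments[c2.fragment_index].positions[1] == c2.position
            )
            oracle = brute_his_best(
                [(c2.fragment_index, c2.position, c2.weight) for c2 in cands],
                {i: frags[i].length for i in range(nf)},
                fixed,
            )
            assert added == oracle
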