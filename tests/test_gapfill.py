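"""Gap completion: mapper, PAF, ordering, splitting, removal, recursion."""

import numpy as np
import pytest

from panmum import (
    BuiltinMapper,
    Fragment,
    Gap,
    MapperMatch,
    MultiMUM,
    PipelineConfig,
    fill_gap,
    map_fragment,
    merge_blocks,
    order_check,
    read_paf,
)

from conftest import random_dna


def frag(length, positions, weight=None, fid=0):
    return Fragment(
        mum=MultiMUM(length=length, positions=tuple(positions)),
        weight=weight if weight is not None else length,
        base_length=length,
        id=fid,
    )


def check_projection(blocks, slices):
    msa = merge_blocks(blocks, ids=[f"s{j}" for j in range(len(slices))])
    for j, s in enumerate(slices):
        assert msa.ungapped(j) == s
    return msa


class TestBuiltinMapper:
    def test_exact_unique_hit_max_quality(self, rng):
        target = random_dna(rng, 400)
        query = target[100:180]
        (best, *rest) = BuiltinMapper().map(query, target)
        assert (best.target_start, best.target_end) == (100, 180)
        assert best.quality == 60

    def test_absent_fragment_no_confident_match(self, rng):
        query = random_dna(rng, 60)
        target = random_dna(rng, 400)
        hits = map_fragment(BuiltinMapper(), query, target, mapq_min=30)
        # nothing similar was planted; any residual hit must be weak
        assert hits == []

    def test_duplicated_hit_is_ambiguous(self, rng):
        core = random_dna(rng, 60)
        target = core + random_dna(rng, 50) + core
        hits = BuiltinMapper().map(core, target)
        assert all(h.quality < 30 for h in hits)

    def test_planted_with_2pct_substitutions_recovered(self, rng):
        target = random_dna(rng, 2000)
        query = list(target[700:1000])
        for p in rng.choice(len(query), size=6, replace=False):
            query[p] = "ACGT"[int(rng.integers(0, 4))]
        query = "".join(query)
        hits = map_fragment(BuiltinMapper(), query, target, mapq_min=30)
        assert hits and abs(hits[0].target_start - 700) <= 6


class TestPaf:
    def test_parse_and_filter(self):
        lines = [
            "q\t100\t0\t100\t+\tt\t500\t40\t140\t95\t100\t60",
            "q\t100\t0\t100\t-\tt\t500\t40\t140\t95\t100\t60",  # reverse: dropped
            "q\t100\t0\t100\t+\tt\t500\t200\t300\t60\t100\t3",
        ]
        matches = read_paf(lines)
        assert len(matches) == 2
        assert matches[0].target_start == 40 and matches[0].quality == 60
        assert [m.quality for m in matches] == [60, 3]

    def test_malformed_record(self):
        with pytest.raises(ValueError):
            read_paf(["q\t1\t2"])

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            MapperMatch("q", "t", 0, 5, -1)


class TestOrderCheck:
    def test_five_fragment_configuration_linearly_ordered(self):
        # five partial fragments, each absent somewhere, but >m/2 presence
        # forces a unique linear order I << II << III << IV << V
        m = 3
        frags = [
            frag(2, (0, 0, None), fid=1),
            frag(2, (5, 5, 5), fid=2),
            frag(2, (None, 10, 10), fid=3),
            frag(2, (10, 15, None), fid=4),
            frag(2, (20, 20, 20), fid=5),
        ]
        shuffled = [frags[3], frags[0], frags[4], frags[2], frags[1]]
        ordered, excluded = order_check(shuffled)
        assert excluded == []
        assert [f.id for f in ordered] == [1, 2, 3, 4, 5]

    def test_single_anchor(self):
        f = frag(2, (0, 0))
        assert order_check([f]) == ([f], [])

    def test_crossing_pair_excluded(self):
        a = frag(2, (0, 10), weight=5, fid=1)
        b = frag(2, (10, 0), weight=2, fid=2)
        ordered, excluded = order_check([a, b])
        assert [f.id for f in ordered] == [1]
        assert [f.id for f in excluded] == [2]


class TestFillGap:
    def cfg(self, **kw):
        defaults = dict(small_gap_threshold=50, min_base_anchor=12, max_depth=6)
        defaults.update(kw)
        return PipelineConfig(**defaults)

    def test_empty_gap(self):
        assert fill_gap(Gap(slices=["", "", ""]), self.cfg()) == []

    def test_small_gap_delegates_to_center_star(self, rng):
        slices = [random_dna(rng, 30) for _ in range(3)]
        blocks = fill_gap(Gap(slices=slices), self.cfg())
        assert len(blocks) == 1 and blocks[0].kind == "gap"
        check_projection(blocks, slices)

    def test_planted_anchor_splits_large_gap(self, rng):
        core = random_dna(rng, 80)
        slices = [
            random_dna(rng, 60) + core + random_dna(rng, 60) for _ in range(3)
        ]
        blocks = fill_gap(Gap(slices=slices), self.cfg())
        kinds = [b.kind for b in blocks]
        assert "anchor" in kinds
        msa = check_projection(blocks, slices)
        # the planted core is recovered as an identical aligned region
        assert core in msa.rows[0].replace("-", "")

    def test_single_nonempty_slice_is_unaligned(self, rng):
        slices = ["", random_dna(rng, 200), ""]
        blocks = fill_gap(Gap(slices=slices), self.cfg())
        assert [b.kind for b in blocks] == ["unaligned"]
        check_projection(blocks, slices)

    def test_unalignable_sequence_removed_and_reinserted(self, rng):
        shared = random_dna(rng, 600)
        slices = [
            random_dna(rng, 30) + shared + random_dna(rng, 30),
            random_dna(rng, 25) + shared + random_dna(rng, 35),
            random_dna(rng, 650),  # unrelated
        ]
        cfg = self.cfg(removal_min_anchor=300, small_gap_threshold=40)
        blocks = fill_gap(Gap(slices=slices), cfg)
        kinds = [b.kind for b in blocks]
        assert kinds[-1] == "unaligned"
        assert blocks[-1].rows[2].replace("-", "") == slices[2]
        check_projection(blocks, slices)

    def test_depth_cap_delegates(self, rng):
        slices = [random_dna(rng, 120) for _ in range(2)]
        blocks = fill_gap(Gap(slices=slices, depth=99), self.cfg())
        assert len(blocks) == 1
        check_projection(blocks, slices)

    def test_recursion_projection_on_divergent_copies(self, rng):
        base = random_dna(rng, 800)
        slices = []
        for _ in range(4):
            s = list(base)
            for p in rng.integers(0, len(base), size=20):
                s[int(p)] = "ACGT"[int(rng.integers(0, 4))]
            slices.append("".join(s))
        blocks = fill_gap(Gap(slices=slices), self.cfg(small_gap_threshold=60))
        check_projection(blocks, slices)

    def test_disjoint_gaps_fill_independently(self, rng):
        # the blocks of one gap do not depend on when (or whether) another
        # gap is processed: repeated and reordered runs agree block-wise
        g1 = [random_dna(rng, 70) for _ in range(2)]
        g2 = [random_dna(rng, 70) for _ in range(2)]
        cfg = self.cfg()
        first_1 = [b.rows for b in fill_gap(Gap(slices=g1), cfg)]
        first_2 = [b.rows for b in fill_gap(Gap(slices=g2), cfg)]
        again_2 = [b.rows for b in fill_gap(Gap(slices=g2), cfg)]
        again_1 = [b.rows for b in fill_gap(Gap(slices=g1), cfg)]
        assert first_1 == again_1 and first_2 == again_2

    def test_residual_anchor_constrains_chain(self, rng):
        # a residual anchor in the middle must appear in the output blocks
        left = random_dna(rng, 100)
        mid = random_dna(rng, 40)
        right = random_dna(rng, 100)
        slices = [left + mid + right, left + mid + right]
        residual = frag(len(mid), (len(left), len(left)), fid=7)
        blocks = fill_gap(
            Gap(slices=slices, residual_anchors=[residual]),
            self.cfg(small_gap_threshold=30),
        )
        msa = check_projection(blocks, slices)
        anchor_rows = ["".join(b.rows[0]) for b in blocks if b.kind == "anchor"]
        assert any(mid in r for r in anchor_rows)


class TestExternalMapper:
    def test_stub_paf_command(self):
        from panmum import ExternalMapper

        cmd = (
            "printf 'q\\t50\\t0\\t50\\t+\\tt\\t200\\t30\\t80\\t48\\t50\\t55\\n' > {output}"
        )
        matches = ExternalMapper(cmd).map("A" * 50, "C" * 200)
        assert len(matches) == 1
        assert (matches[0].target_start, matches[0].quality) == (30, 55)

    def test_failing_command_yields_no_matches(self):
        from panmum import ExternalMapper

        assert ExternalMapper("false").map("ACGT", "ACGTACGT") == []
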