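"""BAC expansion, extension, overlap resolution and gene association."""

import numpy as np
import pytest

from cnapath import (
    BacClone,
    Gene,
    GenomicInterval,
    SegmentCall,
    assign_genes_to_bacs,
    associate_gene_bac,
    expand_bacs,
    extend_bacs,
    genes_in_altered_segments,
    resolve_bac_overlaps,
)

from _oracles import brute_force_overlay


def _random_disjoint_bacs(rng, n=8, chrom="chr1"):
    bacs = []
    pos = int(rng.integers(0, 100_000))
    for i in range(n):
        span = int(rng.integers(5_000, 200_000))
        bacs.append(
            BacClone(
                f"R{i}",
                GenomicInterval(chrom, pos, pos + span),
                left_anchored=bool(rng.integers(0, 2)),
                right_anchored=bool(rng.integers(0, 2)),
            )
        )
        pos += span + int(rng.integers(1_000, 400_000))
    return bacs


class TestExpand:
    @pytest.mark.parametrize(
        "raw, left, right, expected",
        [
            # mapped span >= 100 kb: unchanged
            ((100_000, 220_000), False, False, (100_000, 220_000)),
            # unanchored: symmetric growth to 165 kb about the midpoint
            ((100_000, 105_000), False, False, (20_000, 185_000)),
            # single anchor: growth only away from the anchored end
            ((100_000, 105_000), True, False, (100_000, 265_000)),
            ((200_000, 205_000), False, True, (40_000, 205_000)),
            # both ends anchored: never expanded
            ((100_000, 105_000), True, True, (100_000, 105_000)),
        ],
    )
    def test_isolated_bac_rules(self, raw, left, right, expected):
        b = BacClone("b", GenomicInterval("chr1", *raw), left_anchored=left,
                     right_anchored=right)
        expand_bacs([b])
        assert (b.expanded.start, b.expanded.end) == expected

    def test_expansion_contains_raw_and_anchors_immobile(self, rng):
        for trial in range(5):
            bacs = _random_disjoint_bacs(np.random.default_rng(100 + trial))
            expand_bacs(bacs)
            for b in bacs:
                assert b.expanded.start <= b.raw.start
                assert b.expanded.end >= b.raw.end
                if b.left_anchored:
                    assert b.expanded.start == b.raw.start
                if b.right_anchored:
                    assert b.expanded.end == b.raw.end

    def test_no_new_overlaps_after_expansion(self, rng):
        for trial in range(5):
            bacs = _random_disjoint_bacs(np.random.default_rng(200 + trial))
            expand_bacs(bacs)
            ordered = sorted(bacs, key=lambda b: b.expanded.start)
            for a, b in zip(ordered, ordered[1:]):
                assert a.expanded.end <= b.expanded.start

    def test_neighbours_split_intervening_space(self):
        # two unanchored stubs 100 kb apart both want 165 kb: the gap is
        # assigned roughly equally and they do not collide
        a = BacClone("a", GenomicInterval("chr1", 500_000, 505_000))
        b = BacClone("b", GenomicInterval("chr1", 605_000, 610_000))
        expand_bacs([a, b])
        assert a.expanded.end <= b.expanded.start
        boundary_gap_share = a.expanded.end - 505_000
        assert abs(boundary_gap_share - (605_000 - 505_000) / 2) <= 2_000
        # blocked side compensated on the free side
        assert a.expanded.length > 100_000

    def test_leftmost_bac_clamped_at_zero(self):
        b = BacClone("b", GenomicInterval("chr1", 10_000, 15_000))
        expand_bacs([b])
        assert b.expanded.start == 0
        assert b.expanded.end == 165_000  # compensatory growth rightward


class TestExtend:
    def test_gap_split_at_midpoint(self):
        a = BacClone("a", GenomicInterval("chr1", 0, 200_000),
                     left_anchored=True, right_anchored=True)
        b = BacClone("b", GenomicInterval("chr1", 300_000, 450_000),
                     left_anchored=True, right_anchored=True)
        expand_bacs([a, b])
        extend_bacs([a, b])
        assert (a.extended.start, a.extended.end) == (0, 250_000)
        assert (b.extended.start, b.extended.end) == (250_000, 450_000)

    def test_odd_gap_extra_base_to_left(self):
        a = BacClone("a", GenomicInterval("chr1", 0, 100_001),
                     left_anchored=True, right_anchored=True)
        b = BacClone("b", GenomicInterval("chr1", 200_002, 300_000),
                     left_anchored=True, right_anchored=True)
        expand_bacs([a, b])
        extend_bacs([a, b])
        assert a.extended.end == 150_002  # gap 100001 -> left gets 50001
        assert b.extended.start == 150_002

    def test_single_bac_spans_covered_range(self):
        b = BacClone("b", GenomicInterval("chr1", 400_000, 565_000))
        expand_bacs([b])
        extend_bacs([b])
        assert (b.extended.start, b.extended.end) == (400_000, 565_000)

    def test_zero_gap_leaves_expanded(self):
        a = BacClone("a", GenomicInterval("chr1", 0, 200_000),
                     left_anchored=True, right_anchored=True)
        b = BacClone("b", GenomicInterval("chr1", 200_000, 400_000),
                     left_anchored=True, right_anchored=True)
        expand_bacs([a, b])
        extend_bacs([a, b])
        assert a.extended == a.expanded
        assert b.extended == b.expanded

    def test_tiling_is_contiguous_and_disjoint(self, rng):
        for trial in range(5):
            bacs = _random_disjoint_bacs(np.random.default_rng(300 + trial))
            expand_bacs(bacs)
            extend_bacs(bacs)
            ordered = sorted(bacs, key=lambda b: b.extended.start)
            for a, b in zip(ordered, ordered[1:]):
                assert a.extended.end == b.extended.start
            covered_min = min(b.raw.start for b in bacs)
            covered_max = max(b.raw.end for b in bacs)
            assert ordered[0].extended.start <= covered_min
            assert ordered[-1].extended.end >= covered_max

    def test_empty_chromosome(self):
        assert extend_bacs([]) == []


class TestOverlapResolution:
    def test_contained_bac_is_duplicate_and_adopts_final_coords(self):
        a = BacClone("A", GenomicInterval("chr1", 0, 200_000))
        b = BacClone("B", GenomicInterval("chr1", 50_000, 120_000))
        resolve_bac_overlaps([a, b])
        assert b.duplicate_of == "A"
        expand_bacs([a, b])
        extend_bacs([a, b])
        assert b.extended == a.extended
        assert b.expanded == a.expanded

    def test_partial_overlap_freezes_shared_ends(self):
        a = BacClone("A", GenomicInterval("chr1", 0, 100_000))
        b = BacClone("B", GenomicInterval("chr1", 80_000, 150_000))
        resolve_bac_overlaps([a, b])
        assert a.right_frozen and b.left_frozen
        assert not a.left_frozen and not b.right_frozen
        expand_bacs([a, b])
        # frozen ends immobile; expansion only on A-left / B-right
        assert a.expanded.end == 100_000
        assert b.expanded.start == 80_000
        assert a.expanded.start == 0  # clamped
        assert b.expanded.end > 150_000

    def test_disjoint_bacs_untouched(self, toy_bacs):
        resolve_bac_overlaps(toy_bacs)
        assert all(b.duplicate_of is None for b in toy_bacs)
        assert not any(b.left_frozen or b.right_frozen for b in toy_bacs)


class TestAssociation:
    def test_full_containment_accepted(self):
        g = Gene("g", GenomicInterval("chr1", 10_000, 20_000))
        assert associate_gene_bac(g, GenomicInterval("chr1", 0, 100_000))

    def test_short_bac_vs_broad_gene_rejected(self):
        g = Gene("g", GenomicInterval("chr1", 0, 300_000))
        bac = GenomicInterval("chr1", 100_000, 190_000)  # 90 kb < 100 kb
        assert not associate_gene_bac(g, bac, mode="expanded")

    def test_extended_mode_needs_half_the_gene(self):
        g = Gene("g", GenomicInterval("chr1", 0, 100_000))
        bac = GenomicInterval("chr1", 60_000, 200_000)  # 40% overlap
        assert not associate_gene_bac(g, bac, mode="extended")
        assert associate_gene_bac(g, bac, mode="expanded")

    def test_other_chromosome_and_zero_length_rejected(self):
        g = Gene("g", GenomicInterval("chr2", 0, 10_000))
        assert not associate_gene_bac(g, GenomicInterval("chr1", 0, 100_000))
        g0 = Gene("g0", GenomicInterval("chr1", 5_000, 5_000))
        assert not associate_gene_bac(g0, GenomicInterval("chr1", 0, 100_000))

    def test_extended_assignment_is_exclusive(self, toy_bacs, toy_genes):
        resolve_bac_overlaps(toy_bacs)
        expand_bacs(toy_bacs)
        extend_bacs(toy_bacs)
        mapping = assign_genes_to_bacs(toy_genes, toy_bacs, mode="extended")
        assert set(mapping) == {g.gene_id for g in toy_genes}
        assert all(len(v) == 1 for v in mapping.values())


class TestSegmentOverlay:
    def test_direct_overlay_simple(self):
        genes = [Gene(f"g{i}", GenomicInterval("chr1", i * 10_000, i * 10_000 + 5_000))
                 for i in range(9)]
        segs = [SegmentCall("s1", GenomicInterval("chr1", 0, 25_000), 1)]
        mat = genes_in_altered_segments(segs, genes)
        assert mat["s1"].tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0]

    def test_tied_conflict_becomes_zero(self):
        genes = [Gene("g", GenomicInterval("chr1", 0, 10_000))]
        segs = [
            SegmentCall("s1", GenomicInterval("chr1", 0, 5_000), 1),
            SegmentCall("s1", GenomicInterval("chr1", 5_000, 10_000), -1),
        ]
        mat = genes_in_altered_segments(segs, genes)
        assert mat.loc["g", "s1"] == 0

    def test_larger_overlap_wins_conflict(self):
        genes = [Gene("g", GenomicInterval("chr1", 0, 10_000))]
        segs = [
            SegmentCall("s1", GenomicInterval("chr1", 0, 7_000), 1),
            SegmentCall("s1", GenomicInterval("chr1", 7_000, 10_000), -1),
        ]
        mat = genes_in_altered_segments(segs, genes)
        assert mat.loc["g", "s1"] == 1

    def test_bac_mediated_call_follows_bac_interval(self, toy_bacs, toy_genes):
        resolve_bac_overlaps(toy_bacs)
        expand_bacs(toy_bacs)
        extend_bacs(toy_bacs)
        mapping = assign_genes_to_bacs(toy_genes, toy_bacs, mode="extended")
        # a deletion covering g3's BAC but not g3's own right edge still
        # deletes g3, because calls are BAC-mediated
        bac = next(b for b in toy_bacs if b.bac_id == mapping["g3"][0])
        segs = [SegmentCall("s1", GenomicInterval("chr1", bac.extended.start,
                                                  bac.extended.start + 1_000), -1)]
        mat = genes_in_altered_segments(
            segs, toy_genes, gene_bac_map=mapping, bacs=toy_bacs, mode="extended"
        )
        assert mat.loc["g3", "s1"] == -1

    def test_matches_brute_force_overlay(self, rng):
        # toy genome, direct mode, against the per-base oracle
        local = np.random.default_rng(42)
        genes = []
        pos = 0
        for i in range(12):
            span = int(local.integers(50, 400))
            genes.append(Gene(f"g{i}", GenomicInterval("chr1", pos, pos + span)))
            pos += span + int(local.integers(0, 200))
        segs = []
        for sample in ("s1", "s2", "s3"):
            for _ in range(4):
                start = int(local.integers(0, pos))
                end = start + int(local.integers(50, 800))
                segs.append(SegmentCall(sample, GenomicInterval("chr1", start, end),
                                        int(local.choice([-1, 1]))))
        mat = genes_in_altered_segments(segs, genes)
        oracle = brute_force_overlay(
            [(s.sample_id, s.interval.chrom, s.interval.start, s.interval.end, s.state)
             for s in segs],
            [(g.gene_id, g.interval.chrom, g.interval.start, g.interval.end)
             for g in genes],
        )
        for g in genes:
            for sample in ("s1", "s2", "s3"):
                assert mat.loc[g.gene_id, sample] == oracle[(g.gene_id, sample)]

    def test_sample_without_segments_absent_or_zero(self):
        genes = [Gene("g", GenomicInterval("chr1", 0, 1_000))]
        segs = [SegmentCall("s1", GenomicInterval("chr1", 0, 500), 1)]
        mat = genes_in_altered_segments(segs, genes)
        assert list(mat.columns) == ["s1"]
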