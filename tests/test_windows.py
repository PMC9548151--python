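"""Codon mapping and window construction, checked against brute force."""

import numpy as np
import pytest

from conftest import DictSource, make_allele
from flankrnn.windows import (
    CodingContext,
    ExonBoundaryError,
    FrameshiftError,
    IndelVariant,
    OutsideCdsError,
    WindowError,
    average_locus_annotations,
    build_indel_window,
    build_snv_window,
    locate_codon,
)

# ---------------------------------------------------------------------------
# independent brute-force reference
# ---------------------------------------------------------------------------

def bf_coding_positions(ctx):
    pos = []
    for a, b in ctx.cds_segments:
        pos.extend(range(a, b + 1))
    return pos[::-1] if ctx.strand == "-" else pos


def bf_locate(pos, ctx):
    order = bf_coding_positions(ctx)
    i = order.index(pos)
    return i // 3 + 1, i % 3


def bf_mean_profile(source, ctx, pos, F):
    al = source.missense_alleles(ctx.transcript_id, ctx.chrom, pos)
    if not al:
        return None
    vals = np.stack([np.where(a.missing_mask, np.nan, a.features) for a in al])
    return np.nanmean(vals, axis=0)


def bf_snv_window(target, source, ctx):
    """Enumerate the +-1-codon window and assemble the 11xF matrix directly."""
    order = bf_coding_positions(ctx)
    i = order.index(target.pos)
    c = i // 3
    F = len(target.features)
    in_window = [j for j in range(len(order)) if c - 1 <= j // 3 <= c + 1]
    left = [bf_mean_profile(source, ctx, order[j], F) for j in in_window if j < i]
    right = [bf_mean_profile(source, ctx, order[j], F) for j in in_window if j > i]
    tgt = np.where(target.missing_mask, np.nan, target.features)
    pad = np.zeros(F)
    rows = (
        [pad] * (5 - len(left))
        + [pad if v is None else v for v in left]
        + [tgt]
        + [pad if v is None else v for v in right]
        + [pad] * (5 - len(right))
    )
    return np.stack(rows)


# ---------------------------------------------------------------------------
# locate_codon
# ---------------------------------------------------------------------------

class TestLocateCodon:
    def test_single_segment_first_base(self):
        ctx = CodingContext("T", "chr1", "+", ((101, 109),))
        assert locate_codon(101, ctx) == (1, 0)

    def test_single_segment_arithmetic(self):
        ctx = CodingContext("T", "chr1", "+", ((101, 109),))
        assert locate_codon(105, ctx) == (2, 1)

    def test_split_codon_across_exons(self):
        ctx = CodingContext("T", "chr1", "+", ((101, 104), (201, 205)))
        # enumeration: 101,102,103,104,201,202,... -> 202 is the 6th CDS base
        assert locate_codon(202, ctx) == (2, 2)
        # full agreement with brute-force enumeration
        for pos in list(range(101, 105)) + list(range(201, 206)):
            assert locate_codon(pos, ctx) == bf_locate(pos, ctx)

    def test_minus_strand_counts_in_coding_orientation(self):
        ctx = CodingContext("T", "chr1", "-", ((101, 109),))
        assert locate_codon(109, ctx) == (1, 0)  # highest position is first base
        assert locate_codon(101, ctx) == (3, 2)
        for pos in range(101, 110):
            assert locate_codon(pos, ctx) == bf_locate(pos, ctx)

    def test_position_outside_cds_rejected(self):
        ctx = CodingContext("T", "chr1", "+", ((101, 104), (201, 205)))
        for pos in (100, 150, 206):  # upstream, intron, downstream
            with pytest.raises(OutsideCdsError):
                locate_codon(pos, ctx)

    def test_cds_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError):
            CodingContext("T", "chr1", "+", ((101, 110),))


# ---------------------------------------------------------------------------
# locus averaging
# ---------------------------------------------------------------------------

class TestAverageLocus:
    def test_single_allele_is_identity(self):
        a = make_allele(105, "C", features=[0.2, 0.4, 0.1, 0.0])
        p = average_locus_annotations([a])
        np.testing.assert_array_equal(p.features, a.features)
        assert p.n_alleles_averaged == 1

    def test_two_alleles_arithmetic_mean(self):
        a = make_allele(105, "C", features=[0.2, 0.0, 0.0, 0.0])
        b = make_allele(105, "G", features=[0.4, 1.0, 0.0, 0.0])
        p = average_locus_annotations([a, b])
        assert p.features[0] == pytest.approx(0.3)
        assert p.n_alleles_averaged == 2

    def test_missing_entries_excluded_from_the_mean(self):
        a = make_allele(105, "C", features=[1.0, 2.0, 0, 0])
        b = make_allele(105, "G", features=[3.0, np.nan, 0, 0],
                        missing=[False, True, False, False])
        c = make_allele(105, "T", features=[5.0, 4.0, 0, 0])
        p = average_locus_annotations([a, b, c])
        assert p.features[0] == pytest.approx(3.0)
        assert p.features[1] == pytest.approx(3.0)  # mean of the two present

    def test_empty_list_rejected(self):
        with pytest.raises(WindowError):
            average_locus_annotations([])

    def test_mixed_positions_rejected(self):
        with pytest.raises(WindowError):
            average_locus_annotations([make_allele(105, "C"), make_allele(106, "C")])


# ---------------------------------------------------------------------------
# SNV windows
# ---------------------------------------------------------------------------

def full_source(positions, tx="TOY"):
    """One missense allele per position, features encode the position."""
    return DictSource(
        [make_allele(p, "C", features=[float(p), 1.0, 2.0, 0.5], tx=tx)
         for p in positions]
    )


class TestSnvWindow:
    def test_codon_offset_zero_pad_layout(self, toy_transcript):
        src = full_source(range(101, 116))
        target = make_allele(107, "G", features=[9.0, 9.0, 9.0, 0.9])
        w = build_snv_window(target, src, toy_transcript)
        assert w.length == 11 and w.target_index == 5
        # 3 real left loci (codon 2) preceded by 2 pads; 5 real right loci
        assert list(w.pad_mask) == [True, True, False, False, False, False,
                                    False, False, False, False, False]
        assert [l.pos for l in w.loci[2:5]] == [104, 105, 106]
        assert [l.pos for l in w.loci[6:]] == [108, 109, 110, 111, 112]
        np.testing.assert_array_equal(w.loci[5].features, target.features)

    @pytest.mark.parametrize("pos,n_left_real,n_right_real", [
        (107, 3, 5),  # offset 0
        (108, 4, 4),  # offset 1
        (109, 5, 3),  # offset 2
        (101, 0, 5),  # first codon, first base: upstream entirely padding
        (115, 5, 0),  # last codon, last base
    ])
    def test_real_context_counts_by_offset_and_boundary(
        self, toy_transcript, pos, n_left_real, n_right_real
    ):
        src = full_source(range(101, 116))
        target = make_allele(pos, "G")
        w = build_snv_window(target, src, toy_transcript)
        assert w.length == 11
        pads = w.pad_mask
        assert (~pads[:5]).sum() == n_left_real
        assert (~pads[6:]).sum() == n_right_real
        assert not pads[5]

    def test_loci_without_missense_alleles_become_padding(self, toy_transcript):
        src = DictSource([make_allele(105, "C", features=[1, 1, 1, 1]),
                          make_allele(106, "C", consequence="synonymous")])
        target = make_allele(107, "G")
        w = build_snv_window(target, src, toy_transcript)
        # only position 105 contributes context; 106 (synonymous-only) pads
        real = [l.pos for l in w.loci if not l.is_padding and l.pos != 107]
        assert real == [105]

    def test_synonymous_target_rejected(self, toy_transcript, toy_source):
        with pytest.raises(WindowError):
            build_snv_window(
                make_allele(107, "G", consequence="synonymous"),
                toy_source, toy_transcript,
            )

    def test_matches_brute_force_for_every_position(self, toy_transcript, toy_source):
        """Oracle equivalence over all 15 CDS positions of the toy transcript."""
        for pos in range(101, 116):
            target = make_allele(pos, "T", features=[7.0, -1.0, 0.5, 0.1])
            w = build_snv_window(target, toy_source, toy_transcript)
            expected = bf_snv_window(target, toy_source, toy_transcript)
            np.testing.assert_array_equal(w.X, expected)

    def test_adding_synonymous_alleles_never_changes_a_window(
        self, toy_transcript, toy_alleles
    ):
        base = DictSource(toy_alleles)
        extra = list(toy_alleles) + [
            make_allele(p, "X", consequence="synonymous", features=[99, 99, 99, 99])
            for p in range(101, 116)
        ]
        augmented = DictSource(extra)
        for pos in (101, 105, 108, 113):
            target = make_allele(pos, "T")
            w1 = build_snv_window(target, base, toy_transcript)
            w2 = build_snv_window(target, augmented, toy_transcript)
            np.testing.assert_array_equal(w1.X, w2.X)

    def test_context_features_within_contributing_allele_bounds(self, toy_transcript):
        rng = np.random.default_rng(8)
        alleles = []
        for pos in range(101, 116):
            for alt in ("C", "G", "T")[: rng.integers(1, 4)]:
                alleles.append(make_allele(pos, alt, features=rng.normal(size=4)))
        src = DictSource(alleles)
        target = make_allele(108, "A")
        w = build_snv_window(target, src, toy_transcript)
        for l in w.loci:
            if l.is_padding or l.pos == 108:
                continue
            contrib = np.stack(
                [a.features for a in src.missense_alleles("TOY", "chr1", l.pos)]
            )
            assert np.all(l.features >= contrib.min(axis=0) - 1e-12)
            assert np.all(l.features <= contrib.max(axis=0) + 1e-12)

    def test_minus_strand_window_runs_in_coding_orientation(self):
        ctx = CodingContext("M", "chr2", "-", ((201, 215),))
        alleles = [
            make_allele(p, "C", features=[float(p), 0, 0, 0], tx="M")
            for p in range(201, 216)
        ]
        for a in alleles:
            a.chrom = "chr2"
        src = DictSource(alleles)
        target = make_allele(208, "G", tx="M")
        target.chrom = "chr2"
        w = build_snv_window(target, src, ctx)
        real_pos = [l.pos for l in w.loci if not l.is_padding]
        assert real_pos == sorted(real_pos, reverse=True)  # descending genomic


# ---------------------------------------------------------------------------
# indel windows
# ---------------------------------------------------------------------------

class TestIndelWindow:
    def setup_method(self):
        # 60-codon plus-strand transcript with a missense allele everywhere
        self.ctx = CodingContext("BIG", "chr3", "+", ((1001, 1180),))
        alleles = [
            make_allele(p, "C", features=[float(p), 1.0, 0.0, 0.0], tx="BIG")
            for p in range(1001, 1181)
        ]
        for a in alleles:
            a.chrom = "chr3"
        self.src = DictSource(alleles)

    def test_codon_aligned_3bp_deletion_layout(self):
        # delete codon 4 exactly: positions 1010..1012 (anchor 1009)
        var = IndelVariant("chr3", 1009, "A" + "NNN", "A")
        w = build_indel_window(var, self.src, self.ctx, n_features=4)
        assert w.length == 58
        assert w.target_span == (5, 3)
        # left block: 2 pads + 3 real (codon 3); right block mirrors
        assert list(w.pad_mask[:5]) == [True, True, False, False, False]
        assert [l.pos for l in w.loci[2:5]] == [1007, 1008, 1009]
        assert [l.pos for l in w.loci[5:8]] == [1010, 1011, 1012]
        assert all(w.pad_mask[8:53])  # target block right-padded to 48
        assert list(w.pad_mask[53:]) == [False, False, False, True, True]
        assert [l.pos for l in w.loci[53:56]] == [1013, 1014, 1015]

    def test_48bp_deletion_with_full_flanks_has_no_padding(self):
        # delete codons 6..21 (48 bases, positions 1016..1063), offset-0 start
        var = IndelVariant("chr3", 1015, "A" + "N" * 48, "A")
        w = build_indel_window(var, self.src, self.ctx, n_features=4)
        assert w.length == 58
        assert w.target_span == (5, 48)
        # context is 3 real + 2 pads per side (codon-aligned deletion)
        assert (~w.pad_mask).sum() == 48 + 3 + 3

    def test_mid_codon_deletion_gets_five_context_loci_per_side(self):
        # deletion of 3 bases starting mid-codon: positions 1011..1013
        var = IndelVariant("chr3", 1010, "ANNN", "A")
        w = build_indel_window(var, self.src, self.ctx, n_features=4)
        left_real = [l.pos for l in w.loci[:5] if not l.is_padding]
        right_real = [l.pos for l in w.loci[53:] if not l.is_padding]
        assert left_real == [1007, 1008, 1009, 1010]  # codon 3 + 1 leftover base
        assert right_real == [1014, 1015, 1016, 1017, 1018]

    def test_frameshift_length_rejected(self):
        with pytest.raises(FrameshiftError):
            build_indel_window(
                IndelVariant("chr3", 1009, "ANN", "A"), self.src, self.ctx, 4
            )

    def test_over_48bp_rejected(self):
        var = IndelVariant("chr3", 1009, "A" + "N" * 51, "A")
        with pytest.raises(WindowError):
            build_indel_window(var, self.src, self.ctx, 4)

    def test_insertion_surrogates_average_adjacent_loci(self):
        # 3-base insertion between codons 2 and 3 (after position 1006)
        var = IndelVariant("chr3", 1006, "A", "ANNN")
        w = build_indel_window(var, self.src, self.ctx, n_features=4)
        assert w.target_span == (5, 3)
        expected = (1006.0 + 1007.0) / 2  # mean of the flanking loci profiles
        for l in w.loci[5:8]:
            assert l.features[0] == pytest.approx(expected)

    def test_deletion_spanning_exon_junction_rejected(self):
        ctx = CodingContext("SPL", "chr3", "+", ((1001, 1009), (1101, 1109)))
        var = IndelVariant("chr3", 1007, "A" + "NNN", "A")  # deletes 1008,1009,1101?
        with pytest.raises(ExonBoundaryError):
            build_indel_window(var, self.src, ctx, 4)

    def test_shape_invariant_across_lengths(self):
        """Every non-frameshift deletion length 3..48 yields exactly 58 loci."""
        for k in range(3, 49, 3):
            var = IndelVariant("chr3", 1030, "A" + "N" * k, "A")
            w = build_indel_window(var, self.src, self.ctx, n_features=4)
            assert w.length == 58
            assert w.target_span[1] == k
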