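"""Codon-context window construction for SNVs and non-frameshift indels.

A target variant is mapped to its codon; all missense SNVs within +-1 codon
(at most 9 coding bases) contribute context.  At each context locus the
annotation vectors of all missense alleles are averaged into one per-locus
profile, while the target locus carries the observed allele's own
annotations.  The window is then padded so the target sits at the centre of
an 11-locus matrix (SNVs), or embedded in a 58-locus matrix (indels: up to
48 target loci plus up to 5 context loci per side).  Synonymous and other
non-missense alleles never contribute context.

Padding rows are all-zero vectors, i.e. the feature mean when the
annotation table has been standardized, and are flagged with
``is_padding`` so the model can receive an explicit pad indicator channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

from .features import AlleleAnnotation

SNV_WINDOW_LENGTH = 11
SNV_TARGET_INDEX = 5
SNV_RETRIEVAL_MAX_BP = 9
MAX_CONTEXT_PER_SIDE = 5
INDEL_WINDOW_LENGTH = 58
INDEL_TARGET_BLOCK = 48
MAX_INDEL_LENGTH = 48


class WindowError(ValueError):
    """Base class for window-construction failures."""


class OutsideCdsError(WindowError):
    """Position does not fall in the transcript's coding sequence."""


class FrameshiftError(WindowError):
    """Indel length is not a multiple of 3."""


class ExonBoundaryError(WindowError):
    """Indel spans an exon junction; no windowing rule is defined."""


@dataclass(frozen=True)
class CodingContext:
    """Coding-sequence layout of one transcript.

    ``cds_segments`` are 1-based inclusive genomic intervals in ascending
    genomic order; for minus-strand transcripts coding order runs from the
    last segment backwards.  Total CDS length must be divisible by 3.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        segs = tuple(tuple(map(int, s)) for s in self.cds_segments)
        if not segs:
            raise ValueError("at least one CDS segment required")
        for a, b in segs:
            if b < a:
                raise ValueError(f"invalid segment {a}..{b}")
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError("CDS segments must be disjoint and ascending")
        object.__setattr__(self, "cds_segments", segs)
        if len(self.coding_positions) % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")

    @property
    def coding_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in coding (5'->3' transcript) order."""
        parts = [np.arange(a, b + 1) for a, b in self.cds_segments]
        pos = np.concatenate(parts)
        return pos[::-1].copy() if self.strand == "-" else pos

    @property
    def n_coding_bases(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    @property
    def n_codons(self) -> int:
        return self.n_coding_bases // 3

    def coding_index(self, pos: int) -> int:
        """0-based index of a genomic position in coding order."""
        cp = self.coding_positions
        hits = np.flatnonzero(cp == pos)
        if hits.size == 0:
            raise OutsideCdsError(
                f"position {pos} is not in the CDS of {self.transcript_id}"
            )
        return int(hits[0])

    def genomic_position(self, coding_idx: int) -> int:
        return int(self.coding_positions[coding_idx])


def locate_codon(variant_or_pos, coding_context: CodingContext) -> tuple[int, int]:
    """Map a variant (or raw genomic position) to (codon_index, codon_offset).

    ``codon_index`` is 1-based along the CDS; ``codon_offset`` in {0,1,2} is
    counted in coding orientation, so the mapping is strand-aware.
    """
    pos = getattr(variant_or_pos, "pos", variant_or_pos)
    i = coding_context.coding_index(int(pos))
    return i // 3 + 1, i % 3


@dataclass
class LocusProfile:
    """Per-locus feature profile: one averaged (or direct) annotation row."""

    pos: int
    features: np.ndarray
    n_alleles_averaged: int = 1
    is_padding: bool = False

    @classmethod
    def padding(cls, n_features: int) -> "LocusProfile":
        return cls(
            pos=0,
            features=np.zeros(n_features),
            n_alleles_averaged=0,
            is_padding=True,
        )


def average_locus_annotations(alleles: Sequence[AlleleAnnotation]) -> LocusProfile:
    """Average annotation vectors of all missense alleles at one locus.

    The per-feature mean ignores missing entries; a feature missing in every
    allele stays NaN (callers impute upstream, so this is unusual).
    """
    if not alleles:
        raise WindowError("cannot average an empty allele list; pad instead")
    pos0 = alleles[0].pos
    chrom0 = alleles[0].chrom
    if any(a.pos != pos0 or a.chrom != chrom0 for a in alleles):
        raise WindowError("alleles to average must share (chrom, pos)")
    F = np.stack([a.features for a in alleles])
    M = np.stack([a.missing_mask for a in alleles])
    F = np.where(M, np.nan, F)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(F, axis=0)
    return LocusProfile(pos=pos0, features=mean, n_alleles_averaged=len(alleles))


class AnnotationSource(Protocol):
    """Lookup of missense alleles per (transcript, locus)."""

    def missense_alleles(
        self, transcript_id: str, chrom: str, pos: int
    ) -> list[AlleleAnnotation]:
        ...


@dataclass
class WindowMatrix:
    """Fixed-shape loci x features model input.

    SNV windows have exactly 11 loci with the target at index 5; indel
    windows have exactly 58 loci with ``target_span = (start, length)``.
    """

    loci: list[LocusProfile]
    target_index: int | None = None
    target_span: tuple[int, int] | None = None
    label: int | None = None

    @property
    def length(self) -> int:
        return len(self.loci)

    @property
    def X(self) -> np.ndarray:
        return np.stack([l.features for l in self.loci])

    @property
    def pad_mask(self) -> np.ndarray:
        return np.array([l.is_padding for l in self.loci], dtype=bool)

    def with_label(self, label: int) -> "WindowMatrix":
        return WindowMatrix(self.loci, self.target_index, self.target_span, int(label))


def _context_profile(
    source: AnnotationSource, ctx: CodingContext, pos: int, n_features: int
) -> LocusProfile:
    alleles = source.missense_alleles(ctx.transcript_id, ctx.chrom, pos)
    if not alleles:
        return LocusProfile.padding(n_features)
    return average_locus_annotations(alleles)


def build_snv_window(
    target: AlleleAnnotation,
    source: AnnotationSource,
    coding_context: CodingContext,
) -> WindowMatrix:
    """Assemble the 11 x F window around a missense target SNV.

    The retrieval window is the affected codon plus one codon on each side
    (at most 9 coding bases).  The target locus uses the observed allele's
    own annotations; every other in-window locus is the average over its
    missense alleles, or a padding profile when none exists.  Symmetric
    padding places the target at index 5 with exactly 5 loci per side.
    """
    if target.consequence != "missense":
        raise WindowError("SNV windows are defined for missense targets only")
    nf = target.features.shape[0]
    t = coding_context.coding_index(target.pos)
    codon0 = t // 3  # 0-based affected codon
    lo = max(0, 3 * (codon0 - 1))
    hi = min(coding_context.n_coding_bases, 3 * (codon0 + 2))
    assert hi - lo <= SNV_RETRIEVAL_MAX_BP

    cp = coding_context.coding_positions
    left = [
        _context_profile(source, coding_context, int(cp[i]), nf) for i in range(lo, t)
    ]
    right = [
        _context_profile(source, coding_context, int(cp[i]), nf) for i in range(t + 1, hi)
    ]
    target_profile = LocusProfile(
        pos=target.pos,
        features=np.where(target.missing_mask, np.nan, target.features),
        n_alleles_averaged=1,
    )
    n_pad_left = MAX_CONTEXT_PER_SIDE - len(left)
    n_pad_right = MAX_CONTEXT_PER_SIDE - len(right)
    loci = (
        [LocusProfile.padding(nf) for _ in range(n_pad_left)]
        + left
        + [target_profile]
        + right
        + [LocusProfile.padding(nf) for _ in range(n_pad_right)]
    )
    assert len(loci) == SNV_WINDOW_LENGTH
    return WindowMatrix(loci=loci, target_index=SNV_TARGET_INDEX)


@dataclass(frozen=True)
class IndelVariant:
    """Left-anchored pure insertion or deletion (VCF convention).

    Either ``ref`` or ``alt`` must be a single base shared by both; the
    other carries the inserted/deleted bases.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if min(len(self.ref), len(self.alt)) != 1 or len(self.ref) == len(self.alt):
            raise WindowError(
                "only pure left-anchored insertions/deletions are supported"
            )

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def _codon_context_indices(
    ctx: CodingContext, lo: int, hi: int
) -> tuple[list[int], list[int]]:
    """Coding indices of left/right context for a target occupying [lo, hi].

    Context is the remaining bases of the partially affected codons plus one
    full flanking codon, capped at 5 per side.
    """
    L = ctx.n_coding_bases
    c_first, c_last = lo // 3, hi // 3
    left_start = max(0, 3 * (c_first - 1), lo - MAX_CONTEXT_PER_SIDE)
    right_end = min(L, 3 * (c_last + 2), hi + 1 + MAX_CONTEXT_PER_SIDE)
    return list(range(left_start, lo)), list(range(hi + 1, right_end))


def build_indel_window(
    target: IndelVariant,
    source: AnnotationSource,
    coding_context: CodingContext,
    n_features: int,
) -> WindowMatrix:
    """Assemble the 58 x F window for a non-frameshift indel.

    Deletions: the target loci are the deleted reference positions, each
    carrying its missense-averaged annotations.  Insertions: the target
    region (one locus per inserted base) is filled with a surrogate profile
    averaged from the two reference loci adjacent to the insertion point.
    Context covers the remainder of partially affected codons plus one full
    flanking codon (at most 5 loci per side); the target block is
    left-aligned in a 48-slot region and everything is padded to 58 loci.
    """
    if target.length % 3 != 0:
        raise FrameshiftError(
            f"indel length {target.length} is not a multiple of 3 (frameshift)"
        )
    if target.length > MAX_INDEL_LENGTH:
        raise WindowError(f"indel length {target.length} exceeds {MAX_INDEL_LENGTH}")
    nf = n_features
    cp = coding_context.coding_positions

    if target.is_deletion:
        deleted = [target.pos + 1 + k for k in range(target.length)]
        try:
            idx = sorted(coding_context.coding_index(p) for p in deleted)
        except OutsideCdsError as e:
            raise ExonBoundaryError(
                f"deletion touches non-CDS bases: {e}"
            ) from e
        if idx[-1] - idx[0] != len(idx) - 1:
            raise ExonBoundaryError("deletion spans an exon junction")
        lo, hi = idx[0], idx[-1]
        target_profiles = [
            _context_profile(source, coding_context, int(cp[i]), nf)
            for i in range(lo, hi + 1)
        ]
    else:  # insertion between genomic pos and pos+1
        try:
            i_anchor = coding_context.coding_index(target.pos)
            i_next = coding_context.coding_index(target.pos + 1)
        except OutsideCdsError as e:
            raise ExonBoundaryError(
                f"insertion point touches non-CDS bases: {e}"
            ) from e
        if abs(i_next - i_anchor) != 1:
            raise ExonBoundaryError("insertion point spans an exon junction")
        j = min(i_anchor, i_next)  # left coding neighbour
        neighbours = [
            _context_profile(source, coding_context, int(cp[j]), nf),
            _context_profile(source, coding_context, int(cp[j + 1]), nf),
        ]
        real = [p for p in neighbours if not p.is_padding]
        if real:
            surrogate_vec = np.mean([p.features for p in real], axis=0)
            surrogate = LocusProfile(
                pos=target.pos,
                features=surrogate_vec,
                n_alleles_averaged=sum(p.n_alleles_averaged for p in real),
            )
            target_profiles = [
                LocusProfile(surrogate.pos, surrogate.features.copy(),
                             surrogate.n_alleles_averaged)
                for _ in range(target.length)
            ]
        else:
            target_profiles = [LocusProfile.padding(nf) for _ in range(target.length)]

    if target.is_deletion:
        left_ids, right_ids = _codon_context_indices(coding_context, lo, hi)
    else:
        L = coding_context.n_coding_bases
        c_left = j // 3
        c_right = (j + 1) // 3
        left_start = max(0, 3 * (c_left - 1), j + 1 - MAX_CONTEXT_PER_SIDE)
        right_end = min(L, 3 * (c_right + 2), j + 1 + MAX_CONTEXT_PER_SIDE)
        left_ids = list(range(left_start, j + 1))
        right_ids = list(range(j + 1, right_end))

    left = [_context_profile(source, coding_context, int(cp[i]), nf) for i in left_ids]
    right = [_context_profile(source, coding_context, int(cp[i]), nf) for i in right_ids]

    n_pad_left = MAX_CONTEXT_PER_SIDE - len(left)
    n_pad_target = INDEL_TARGET_BLOCK - len(target_profiles)
    n_pad_right = MAX_CONTEXT_PER_SIDE - len(right)
    loci = (
        [LocusProfile.padding(nf) for _ in range(n_pad_left)]
        + left
        + target_profiles
        + [LocusProfile.padding(nf) for _ in range(n_pad_target)]
        + right
        + [LocusProfile.padding(nf) for _ in range(n_pad_right)]
    )
    assert len(loci) == INDEL_WINDOW_LENGTH
    return WindowMatrix(
        loci=loci,
        target_span=(MAX_CONTEXT_PER_SIDE, len(target_profiles)),
    )
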