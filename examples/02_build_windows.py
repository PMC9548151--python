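"""Map a variant to its codon and assemble its +-1-codon context window.

Shows the 11-locus SNV window (target centred at index 5, padding outside
the retrieval window) and a 58-locus window for an in-frame deletion.
"""

import numpy as np

from flankrnn.features import AlleleAnnotation
from flankrnn.windows import (
    CodingContext,
    IndelVariant,
    build_indel_window,
    build_snv_window,
    locate_codon,
)


class TinySource:
    """One missense allele per locus whose first feature encodes the position."""

    def missense_alleles(self, transcript_id, chrom, pos):
        if not 101 <= pos <= 130:
            return []
        return [AlleleAnnotation(
            chrom=chrom, pos=pos, ref="A", alt="C", transcript_id=transcript_id,
            codon_index=(pos - 101) // 3 + 1, codon_offset=(pos - 101) % 3,
            consequence="missense",
            features=np.array([float(pos), 1.0, 2.0, 0.0]),
            missing_mask=np.zeros(4, dtype=bool),
        )]


ctx = CodingContext("TX1", "chr1", "+", ((101, 130),))  # 10 codons
source = TinySource()

pos = 113
codon, offset = locate_codon(pos, ctx)
print(f"variant chr1:{pos} -> codon {codon}, offset {offset} (0-based within codon)")

target = source.missense_alleles("TX1", "chr1", pos)[0]
w = build_snv_window(target, source, ctx)
print(f"\nSNV window: {w.length} loci, target at index {w.target_index}")
for i, locus in enumerate(w.loci):
    tag = "TARGET" if i == w.target_index else ("pad" if locus.is_padding else "context")
    print(f"  slot {i:2d}: pos={locus.pos or '-':>6} {tag}")

var = IndelVariant("chr1", 109, "ACGT", "A")  # deletes 110..112 (codon 4)
wi = build_indel_window(var, source, ctx, n_features=4)
start, length = wi.target_span
print(
    f"\nindel window: {wi.length} loci; deleted block occupies slots "
    f"{start}..{start + length - 1}; "
    f"{int((~wi.pad_mask).sum())} real loci, the rest padding"
)
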