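import numpy as np
import pandas as pd
import pytest

from flankrnn.features import AlleleAnnotation, FeatureSchema
from flankrnn.simulate import (
    SyntheticConfig,
    generate_annotation_table,
    generate_clinvar_records,
    generate_transcript_layout,
)
from flankrnn.windows import CodingContext


@pytest.fixture(scope="session")
def toy_schema():
    """4-feature schema: small enough to hand-write window expectations."""
    return FeatureSchema(
        names=("fA", "fB", "cA", "afA"),
        categories=("functional", "functional", "conservation", "allele_frequency"),
        orientations=(1, 1, 1, 1),
    )


@pytest.fixture(scope="session")
def toy_transcript():
    """5-codon single-exon plus-strand transcript: CDS 101..115 on chr1."""
    return CodingContext(
        transcript_id="TOY", chrom="chr1", strand="+", cds_segments=((101, 115),)
    )


def make_allele(pos, alt, consequence="missense", features=None, missing=None, tx="TOY"):
    f = np.asarray(features if features is not None else [0.0, 0.0, 0.0, 0.0], float)
    m = np.asarray(missing if missing is not None else [False] * len(f), bool)
    i = pos - 101
    return AlleleAnnotation(
        chrom="chr1", pos=pos, ref="A", alt=alt, transcript_id=tx,
        codon_index=i // 3 + 1, codon_offset=i % 3,
        consequence=consequence, features=f, missing_mask=m,
    )


class DictSource:
    """Minimal annotation source backed by a {pos: [alleles]} dict."""

    def __init__(self, alleles):
        self.by_pos = {}
        for a in alleles:
            self.by_pos.setdefault((a.transcript_id, a.chrom, a.pos), []).append(a)

    def missense_alleles(self, transcript_id, chrom, pos):
        return [
            a
            for a in self.by_pos.get((transcript_id, chrom, pos), [])
            if a.consequence == "missense"
        ]


@pytest.fixture(scope="session")
def toy_alleles():
    """Hand-written allele table over the 5-codon toy transcript.

    Positions 101..115; some loci have multiple missense alleles, some only
    synonymous ones, some none at all.
    """
    rng = np.random.default_rng(42)
    alleles = []
    for pos in range(101, 116):
        n = int(rng.integers(0, 3))
        alts = ["C", "G", "T"][:n]
        for k, alt in enumerate(alts):
            cons = "synonymous" if (pos + k) % 5 == 0 else "missense"
            feats = rng.normal(size=4).round(3)
            alleles.append(make_allele(pos, alt, cons, feats))
    return alleles


@pytest.fixture(scope="session")
def toy_source(toy_alleles):
    return DictSource(toy_alleles)


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic dataset reused across io/pipeline/CLI tests."""
    cfg = SyntheticConfig(n_transcripts=6, codons_per_transcript=30, seed=7)
    layouts = generate_transcript_layout(cfg)
    table, truth = generate_annotation_table(cfg, layouts)
    records, book = generate_clinvar_records(cfg, truth)
    return {
        "config": cfg,
        "layouts": layouts,
        "table": table,
        "truth": truth,
        "records": records,
        "book": book,
    }
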