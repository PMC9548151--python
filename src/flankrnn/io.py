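"""Table and VCF plumbing.

Formats
-------
Annotation table
    Tab-separated, one row per (chrom, pos, ref, alt, transcript), header
    names the schema features; missing values written as ``.`` (dbNSFP
    dialect).  Feature values are stored in each tool's native orientation;
    :class:`AnnotationTable` harmonizes them on load so larger always means
    more damaging.
Coding table
    Tab-separated transcript definitions: transcript_id, chrom, strand,
    comma-separated 1-based inclusive CDS exon intervals (``start-end``).
Clinical records
    Tab-separated ClinVar-style label table: variant key, ``|``-separated
    significance assertions, per-dataset presence flags and max AFs.
Variants
    VCF 4.x via cyvcf2; multi-allelic records are split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curation import POPULATION_DATASETS, ClinicalRecord
from .features import (
    AlleleAnnotation,
    FeatureSchema,
    StandardizerStats,
    apply_standardizer,
    fit_standardizer,
    impute_missing,
)
from .windows import CodingContext, LocusProfile, average_locus_annotations

MISSING_TOKEN = "."
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "transcript_id",
    "codon_index", "codon_offset", "consequence",
]


def write_annotation_table(df: pd.DataFrame, schema: FeatureSchema, path) -> None:
    """Write the dbNSFP-dialect TSV; NaN feature values become ``.``."""
    cols = VARIANT_COLUMNS + list(schema.names)
    out = df[cols].copy()
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_annotation_table(path, schema: FeatureSchema) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], dtype={"chrom": str})
    missing_cols = set(VARIANT_COLUMNS + list(schema.names)) - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {sorted(missing_cols)}")
    return df


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


class AnnotationTable:
    """In-memory per-allele annotation store with locus lookups.

    Holds the raw table plus a working feature matrix (orientation
    harmonized).  ``impute()`` and ``standardize()`` mutate the working
    matrix in place; lookups serve :class:`AlleleAnnotation` views of it.
    """

    def __init__(self, df: pd.DataFrame, schema: FeatureSchema):
        self.df = df.reset_index(drop=True)
        self.schema = schema
        raw = self.df[list(schema.names)].to_numpy(dtype=float)
        self.missing_mask = ~np.isfinite(raw)
        self.features = schema.harmonize(np.nan_to_num(raw, nan=np.nan))
        self.features[self.missing_mask] = np.nan
        self._imputed = not self.missing_mask.any()
        self._cache: dict[str, dict[int, list[int]]] = {}
        self._key_index: dict[tuple, int] | None = None

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path, schema: FeatureSchema) -> "AnnotationTable":
        return cls(read_annotation_table(path, schema), schema)

    def write_tsv(self, path) -> None:
        write_annotation_table(self.df, self.schema, path)

    def with_schema(self, schema: FeatureSchema) -> "AnnotationTable":
        """Project onto a (sub-)schema, e.g. the AF-free 24-feature one."""
        return AnnotationTable(self.df, schema)

    # -- preprocessing -----------------------------------------------------
    def impute(self, **kwargs) -> None:
        if self.missing_mask.any():
            work = self.features.copy()
            work[self.missing_mask] = 0.0
            self.features = impute_missing(
                work, self.missing_mask, feature_names=self.schema.names, **kwargs
            )
        self._imputed = True
        self._cache.clear()

    def fit_standardizer(self, row_indices=None) -> StandardizerStats:
        if not self._imputed:
            raise ValueError("impute before standardizing")
        rows = self.features if row_indices is None else self.features[row_indices]
        return fit_standardizer(rows)

    def standardize(self, stats: StandardizerStats) -> None:
        if not self._imputed:
            raise ValueError("impute before standardizing")
        self.features = apply_standardizer(self.features, stats)
        self._cache.clear()

    # -- lookups -----------------------------------------------------------
    def find_rows(self, chrom: str, pos: int, ref: str, alt: str) -> list[int]:
        """Row indices of one (chrom, pos, ref, alt) allele, one per transcript."""
        if self._key_index is None:
            idx: dict[tuple, list[int]] = {}
            for i, r in enumerate(
                self.df[["chrom", "pos", "ref", "alt"]].itertuples(index=False)
            ):
                idx.setdefault((str(r[0]), int(r[1]), r[2], r[3]), []).append(i)
            self._key_index = idx
        return self._key_index.get((str(chrom), int(pos), ref, alt), [])

    def allele_at_row(self, i: int) -> AlleleAnnotation:
        return self._row_allele(i)

    def _row_allele(self, i: int) -> AlleleAnnotation:
        r = self.df.iloc[i]
        mask = (
            np.zeros(self.features.shape[1], dtype=bool)
            if self._imputed
            else self.missing_mask[i]
        )
        return AlleleAnnotation(
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            ref=str(r["ref"]),
            alt=str(r["alt"]),
            transcript_id=str(r["transcript_id"]),
            codon_index=int(r["codon_index"]),
            codon_offset=int(r["codon_offset"]),
            consequence=str(r["consequence"]),
            features=np.where(mask, np.nan, self.features[i]),
            missing_mask=mask,
        )

    def _transcript_cache(self, transcript_id: str) -> dict[int, list[int]]:
        if transcript_id not in self._cache:
            sub = self.df.index[
                (self.df["transcript_id"] == transcript_id)
                & (self.df["consequence"] == "missense")
            ]
            by_pos: dict[int, list[int]] = {}
            for i in sub:
                by_pos.setdefault(int(self.df.at[i, "pos"]), []).append(int(i))
            self._cache[transcript_id] = by_pos
        return self._cache[transcript_id]

    def missense_alleles(
        self, transcript_id: str, chrom: str, pos: int
    ) -> list[AlleleAnnotation]:
        rows = self._transcript_cache(transcript_id).get(int(pos), [])
        return [self._row_allele(i) for i in rows if self.df.at[i, "chrom"] == chrom]

    def lookup(
        self, chrom: str, pos: int, ref: str, alt: str, transcript_id: str | None = None
    ) -> list[AlleleAnnotation]:
        """All rows (one per transcript unless restricted) for one allele."""
        rows = self.find_rows(chrom, pos, ref, alt)
        out = [self._row_allele(i) for i in rows]
        if transcript_id is not None:
            out = [a for a in out if a.transcript_id == transcript_id]
        return out


# -- coding table -----------------------------------------------------------

def write_coding_table(layouts: Iterable[CodingContext], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstrand\tcds_segments\n")
        for t in layouts:
            segs = ",".join(f"{a}-{b}" for a, b in t.cds_segments)
            fh.write(f"{t.transcript_id}\t{t.chrom}\t{t.strand}\t{segs}\n")


def read_coding_table(path) -> list[CodingContext]:
    out = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for r in df.itertuples(index=False):
        segs = tuple(
            tuple(int(x) for x in part.split("-")) for part in r.cds_segments.split(",")
        )
        out.append(
            CodingContext(
                transcript_id=r.transcript_id,
                chrom=r.chrom,
                strand=r.strand,
                cds_segments=segs,
            )
        )
    return out


# -- clinical records --------------------------------------------------------

def write_clinical_records(records: Iterable[ClinicalRecord], path) -> None:
    cols = (
        ["variant_key", "chrom", "pos", "assertions"]
        + [f"present_{d}" for d in POPULATION_DATASETS]
        + [f"max_af_{d}" for d in POPULATION_DATASETS]
        + ["indel_length", "is_frameshift"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.variant_key,
                r.chrom,
                str(r.pos),
                "|".join(sorted(r.assertions)),
            ]
            row += [str(int(r.presence.get(d, False))) for d in POPULATION_DATASETS]
            row += [repr(float(r.max_af.get(d, 0.0))) for d in POPULATION_DATASETS]
            row.append(MISSING_TOKEN if r.indel_length is None else str(r.indel_length))
            row.append(
                MISSING_TOKEN if r.is_frameshift is None else str(int(r.is_frameshift))
            )
            fh.write("\t".join(row) + "\n")


def read_clinical_records(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], dtype={"chrom": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ClinicalRecord(
                variant_key=r.variant_key,
                chrom=str(r.chrom),
                pos=int(r.pos),
                assertions=frozenset(str(r.assertions).split("|")),
                presence={
                    d: bool(getattr(r, f"present_{d}")) for d in POPULATION_DATASETS
                },
                max_af={d: float(getattr(r, f"max_af_{d}")) for d in POPULATION_DATASETS},
                indel_length=None if pd.isna(r.indel_length) else int(r.indel_length),
                is_frameshift=None if pd.isna(r.is_frameshift) else bool(r.is_frameshift),
            )
        )
    return out


# -- scored output ------------------------------------------------------------

def config_digest(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_scores(
    rows: Sequence[dict], path, *, tool_version: str, digest: str, seed: int
) -> None:
    """Scored output table with a reproducibility header."""
    with open(path, "w") as fh:
        fh.write(f"##tool_version={tool_version}\n")
        fh.write(f"##config_digest={digest}\n")
        fh.write(f"##seed={seed}\n")
        cols = ["variant_key", "transcript_id", "score", "class", "model"]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write(
                f"{r['variant_key']}\t{r['transcript_id']}\t{r['score']:.6f}\t"
                f"{r['class']}\t{r['model']}\n"
            )


def write_unscorable(rows: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\treason\n")
        for r in rows:
            fh.write(f"{r['variant_key']}\t{r['reason']}\n")


# -- VCF ----------------------------------------------------------------------

def read_vcf_variants(path) -> list[tuple[str, int, str, str]]:
    """(chrom, pos, ref, alt) tuples with multi-allelic records split."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.append((rec.CHROM, int(rec.POS), rec.REF, alt))
    return out
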