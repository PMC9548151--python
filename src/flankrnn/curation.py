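"""Training/test-set curation: clinical labels, presence filters, matching, splits.

Labels come from ClinVar-style significance assertions.  A variant is a
true positive (TP) when all its assertions are pathogenic or likely
pathogenic, a true negative (TN) when all are benign or likely benign.
Records whose assertions mix the benign side, the pathogenic side and/or
VUS are conflicting and removed.

Training SNVs additionally pass a population-presence filter: a variant is
kept only if it is absent from at least one of gnomAD / ExAC / 1000GP
(removing "easy" common benign variants) while still present in at least
one of them (preserving allele-frequency information).  Indels are
restricted to non-frameshift events of length >1 and <=48 bp.

Test sets use location-matched negatives: for each pathogenic variant one
candidate negative is sampled uniformly within 10 kb on the same
chromosome, without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

PATHOGENIC_SIDE = frozenset({"pathogenic", "likely_pathogenic"})
BENIGN_SIDE = frozenset({"benign", "likely_benign"})
VALID_ASSERTIONS = PATHOGENIC_SIDE | BENIGN_SIDE | {"vus"}

POPULATION_DATASETS = ("1000GP", "ExAC", "gnomAD")

#: outcomes of clinical-label resolution
TP, TN, CONFLICTING, VUS_ONLY = "TP", "TN", "conflicting", "vus_only"

DEFAULT_RARE_AF = 0.01
MATCH_WINDOW_BP = 10_000
TRAIN_FRACTION = 0.70


@dataclass
class ClinicalRecord:
    """Clinical-significance record for one variant.

    ``presence`` flags record whether the variant is observed (has any AF
    record) in each population dataset; ``max_af`` carries the maximum
    subpopulation AF per dataset (0 for absent).  Indel records also carry
    length and frameshift status.
    """

    variant_key: str
    assertions: frozenset[str]
    presence: dict[str, bool] = field(default_factory=dict)
    max_af: dict[str, float] = field(default_factory=dict)
    chrom: str = ""
    pos: int = 0
    indel_length: int | None = None
    is_frameshift: bool | None = None

    def __post_init__(self) -> None:
        self.assertions = frozenset(self.assertions)
        if not self.assertions:
            raise ValueError("a clinical record needs at least one assertion")
        bad = self.assertions - VALID_ASSERTIONS
        if bad:
            raise ValueError(f"unknown assertions: {sorted(bad)}")

    @property
    def overall_max_af(self) -> float:
        return max(self.max_af.values(), default=0.0)


def resolve_clinical_label(record: ClinicalRecord) -> str:
    """Resolve an assertion set to TP / TN / conflicting / vus_only.

    Conflicts are any mix across {benign side, pathogenic side, VUS}:
    benign-side with VUS, pathogenic-side with VUS, or benign-side with
    pathogenic-side.
    """
    a = record.assertions
    has_path = bool(a & PATHOGENIC_SIDE)
    has_benign = bool(a & BENIGN_SIDE)
    has_vus = "vus" in a
    if sum((has_path, has_benign, has_vus)) > 1:
        return CONFLICTING
    if has_path:
        return TP
    if has_benign:
        return TN
    return VUS_ONLY


def passes_presence_filter(record: ClinicalRecord) -> bool:
    """Absent from >=1 of the three population datasets AND present in >=1."""
    present = [bool(record.presence.get(d, False)) for d in POPULATION_DATASETS]
    return (not all(present)) and any(present)


@dataclass
class LabeledRecord:
    record: ClinicalRecord
    label: int  # 1 = pathogenic
    provenance: str


def filter_training_snvs(records: Iterable[ClinicalRecord]) -> list[LabeledRecord]:
    """Apply the SNV training filters: presence filter, then label resolution.

    Only consistently pathogenic (label 1) or benign (label 0) records
    survive; conflicting and VUS-only records are dropped.
    """
    out: list[LabeledRecord] = []
    for rec in records:
        if not passes_presence_filter(rec):
            continue
        outcome = resolve_clinical_label(rec)
        if outcome == TP:
            out.append(LabeledRecord(rec, 1, "snv_train"))
        elif outcome == TN:
            out.append(LabeledRecord(rec, 0, "snv_train"))
    return out


def filter_training_indels(records: Iterable[ClinicalRecord]) -> list[LabeledRecord]:
    """Keep non-frameshift indels with 1 < length <= 48, labelled as for SNVs."""
    out: list[LabeledRecord] = []
    for rec in records:
        if rec.is_frameshift or rec.indel_length is None:
            continue
        if not (1 < rec.indel_length <= 48):
            continue
        outcome = resolve_clinical_label(rec)
        if outcome == TP:
            out.append(LabeledRecord(rec, 1, "indel_train"))
        elif outcome == TN:
            out.append(LabeledRecord(rec, 0, "indel_train"))
    return out


def is_rare(record: ClinicalRecord, threshold: float = DEFAULT_RARE_AF) -> bool:
    """Rare means maximum population AF below the threshold (default 0.01)."""
    return record.overall_max_af < threshold


@dataclass
class MatchResult:
    pairs: list[tuple[ClinicalRecord, ClinicalRecord]]
    unmatched: list[ClinicalRecord]

    @property
    def negatives(self) -> list[ClinicalRecord]:
        return [neg for _, neg in self.pairs]


def match_negatives_by_location(
    positives: Sequence[ClinicalRecord],
    candidate_negatives: Sequence[ClinicalRecord],
    window_bp: int = MATCH_WINDOW_BP,
    seed: int = 0,
) -> MatchResult:
    """Sample one location-matched negative per positive, without replacement.

    Eligible candidates lie on the same chromosome within ``window_bp`` of
    the positive.  Positives are processed in a deterministic order and each
    draws uniformly among its remaining eligible candidates; positives with
    none left are reported unmatched.  Candidates that are also positives
    (same variant key) are never eligible.
    """
    rng = np.random.default_rng(seed)
    pos_keys = {p.variant_key for p in positives}
    available = [c for c in candidate_negatives if c.variant_key not in pos_keys]
    taken = np.zeros(len(available), dtype=bool)
    chroms = np.array([c.chrom for c in available])
    positions = np.array([c.pos for c in available], dtype=np.int64)

    pairs: list[tuple[ClinicalRecord, ClinicalRecord]] = []
    unmatched: list[ClinicalRecord] = []
    for p in sorted(positives, key=lambda r: (r.chrom, r.pos, r.variant_key)):
        eligible = np.flatnonzero(
            (~taken)
            & (chroms == p.chrom)
            & (np.abs(positions - p.pos) <= window_bp)
        )
        if eligible.size == 0:
            unmatched.append(p)
            continue
        pick = int(rng.choice(eligible))
        taken[pick] = True
        pairs.append((p, available[pick]))
    return MatchResult(pairs=pairs, unmatched=unmatched)


def split_train_val(
    examples: Sequence,
    labels: Sequence[int],
    train_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Stratified disjoint split; returns (train_indices, val_indices).

    ``|train| = round(train_fraction * n)`` overall, with each label class
    split as close to the fraction as rounding allows.
    """
    n = len(examples)
    if n != len(labels):
        raise ValueError("examples and labels must align")
    if n < 10:
        raise ValueError("need at least 10 examples to split")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    n_train_total = int(round(train_fraction * n))
    train_idx: list[int] = []
    classes = sorted(np.unique(y).tolist())
    remaining = n_train_total
    for k, cls in enumerate(classes):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        if k == len(classes) - 1:
            n_cls = remaining
        else:
            n_cls = int(round(train_fraction * idx.size))
            n_cls = min(n_cls, remaining)
        train_idx.extend(idx[:n_cls].tolist())
        remaining -= n_cls
    train_set = set(train_idx)
    val_idx = [i for i in range(n) if i not in train_set]
    return sorted(train_idx), sorted(val_idx)
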