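"""End-to-end orchestration: curation -> windows -> preprocessing -> training
-> evaluation, plus VCF annotation with trained models.

Pipeline order follows the method: impute missing scores first, fit the
standardizer on training-split target rows only, standardize the whole
annotation table with those statistics, then assemble windows (padding rows
are zero, i.e. the training feature mean, in standardized space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .curation import (
    LabeledRecord,
    filter_training_snvs,
    is_rare,
    split_train_val,
)
from .features import FeatureSchema, StandardizerStats
from .io import (
    AnnotationTable,
    config_digest,
    read_vcf_variants,
    variant_key,
    write_scores,
    write_unscorable,
)
from .metrics import EvalResult, ScoreSet, evaluate
from .model import (
    AblationVariant,
    ModelConfig,
    TrainedModel,
    TrainingHistory,
    build_feed_forward_model,
    build_indel_model,
    build_snv_model,
    encode_windows,
    train,
)
from .nn import HEAD_FINAL_LOCUS
from .windows import (
    CodingContext,
    ExonBoundaryError,
    FrameshiftError,
    IndelVariant,
    MAX_INDEL_LENGTH,
    WindowError,
    build_indel_window,
    build_snv_window,
)


@dataclass
class SnvDataset:
    """Model-ready SNV training bundle (windows already standardized)."""

    X_train: np.ndarray  # (n, 11, F+1)
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    target_train: np.ndarray  # (n, F) target-locus vectors for the ablation
    target_val: np.ndarray
    schema: FeatureSchema
    stats: StandardizerStats
    keys_val: list[str]

    @property
    def n_features(self) -> int:
        return len(self.schema)


class EmptyDatasetError(RuntimeError):
    pass


def prepare_snv_dataset(
    table: AnnotationTable,
    layouts: Sequence[CodingContext],
    records,
    *,
    seed: int = 0,
    max_examples: int | None = None,
    variant: AblationVariant | None = None,
    train_fraction: float = 0.70,
) -> SnvDataset:
    """Curate records, preprocess the table, and build labeled SNV windows."""
    if variant is not None and variant.schema is not table.schema:
        table = table.with_schema(variant.schema)
    schema = table.schema
    layout_by_id = {t.transcript_id: t for t in layouts}

    labeled = filter_training_snvs(records)
    if variant is not None and variant.restrict_rare:
        labeled = [l for l in labeled if is_rare(l.record, variant.rare_threshold)]
    if not labeled:
        raise EmptyDatasetError("no records survived the training filters")

    examples: list[tuple[int, int, str]] = []  # (table row, label, key)
    for l in labeled:
        chrom, pos, ref, alt = l.record.variant_key.split(":")
        for i in table.find_rows(chrom, int(pos), ref, alt):
            row = table.df.iloc[i]
            if row["consequence"] != "missense":
                continue
            if row["transcript_id"] not in layout_by_id:
                continue
            examples.append((i, l.label, l.record.variant_key))
    if not examples:
        raise EmptyDatasetError("no curated variant maps to a missense table row")

    rng = np.random.default_rng(seed)
    if max_examples is not None and len(examples) > max_examples:
        sel = rng.choice(len(examples), size=max_examples, replace=False)
        examples = [examples[int(j)] for j in np.sort(sel)]

    labels = [e[1] for e in examples]
    train_idx, val_idx = split_train_val(
        examples, labels, train_fraction=train_fraction, seed=seed
    )

    table.impute()
    train_rows = [examples[j][0] for j in train_idx]
    stats = table.fit_standardizer(row_indices=train_rows)
    table.standardize(stats)

    def build(split_idx):
        windows, ys, keys, t_rows = [], [], [], []
        for j in split_idx:
            i, y, key = examples[j]
            target = table.allele_at_row(i)
            layout = layout_by_id[target.transcript_id]
            windows.append(build_snv_window(target, table, layout))
            ys.append(y)
            keys.append(key)
            t_rows.append(i)
        X = encode_windows(windows)
        return X, np.array(ys), keys, table.features[t_rows]

    X_train, y_train, _, target_train = build(train_idx)
    X_val, y_val, keys_val, target_val = build(val_idx)
    return SnvDataset(
        X_train=X_train, y_train=y_train, X_val=X_val, y_val=y_val,
        target_train=target_train, target_val=target_val,
        schema=schema, stats=stats, keys_val=keys_val,
    )


@dataclass
class PipelineResult:
    model: TrainedModel
    eval_result: EvalResult
    val_scores: ScoreSet
    n_train: int
    n_val: int

    @property
    def auc(self) -> float:
        return self.eval_result.auc


def train_snv_classifier(
    dataset: SnvDataset,
    config: ModelConfig | None = None,
    *,
    feed_forward: bool = False,
) -> PipelineResult:
    """Train the recurrent SNV model (or its target-only dense ablation)."""
    config = config or ModelConfig()
    F = dataset.n_features
    if feed_forward:
        net = build_feed_forward_model(config, n_features=F)
        Xtr, Xva = dataset.target_train, dataset.target_val
        kind = "feed_forward"
    else:
        net = build_snv_model(config, n_features=F)
        Xtr, Xva = dataset.X_train, dataset.X_val
        kind = "snv"
    history = train(net, Xtr, dataset.y_train, Xva, dataset.y_val, config)
    model = TrainedModel(
        net=net, schema=dataset.schema, stats=dataset.stats,
        config=config, history=history, kind=kind,
    )
    scores = model.net.predict(Xva)
    score_set = ScoreSet(scores=scores, labels=dataset.y_val, source=kind)
    return PipelineResult(
        model=model,
        eval_result=evaluate(score_set),
        val_scores=score_set,
        n_train=len(dataset.y_train),
        n_val=len(dataset.y_val),
    )


def evaluate_af_masked(model: TrainedModel, dataset: SnvDataset) -> EvalResult:
    """Held-out performance with AF features masked to the absent-variant value."""
    X = dataset.X_val if model.kind == "snv" else dataset.target_val
    scores = model.predict(X, mask_af=True)
    return evaluate(ScoreSet(scores=scores, labels=dataset.y_val, source="af_masked"))


# ---------------------------------------------------------------------------
# Indel pipeline
# ---------------------------------------------------------------------------

@dataclass
class IndelDataset:
    X_train: np.ndarray  # (n, 58, F+1)
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    schema: FeatureSchema
    stats: StandardizerStats


def prepare_indel_dataset(
    table: AnnotationTable,
    layouts: Sequence[CodingContext],
    indels: Sequence[tuple[IndelVariant, str, int]],
    *,
    seed: int = 0,
    train_fraction: float = 0.70,
) -> IndelDataset:
    """Build labeled 58-locus windows for non-frameshift indels."""
    layout_by_id = {t.transcript_id: t for t in layouts}
    labels = [y for _, _, y in indels]
    train_idx, val_idx = split_train_val(
        indels, labels, train_fraction=train_fraction, seed=seed
    )
    table.impute()
    missense_rows = np.flatnonzero((table.df["consequence"] == "missense").to_numpy())
    stats = table.fit_standardizer(row_indices=missense_rows)
    table.standardize(stats)
    F = len(table.schema)

    def build(split_idx):
        ws, ys = [], []
        for j in split_idx:
            var, tx_id, y = indels[j]
            w = build_indel_window(var, table, layout_by_id[tx_id], n_features=F)
            ws.append(w)
            ys.append(y)
        return encode_windows(ws), np.array(ys)

    X_train, y_train = build(train_idx)
    X_val, y_val = build(val_idx)
    return IndelDataset(X_train, y_train, X_val, y_val, table.schema, stats)


def train_indel_classifier(
    dataset: IndelDataset, config: ModelConfig | None = None
) -> PipelineResult:
    config = config or ModelConfig(head_mode=HEAD_FINAL_LOCUS)
    net = build_indel_model(config, n_features=len(dataset.schema))
    history = train(
        net, dataset.X_train, dataset.y_train, dataset.X_val, dataset.y_val, config
    )
    model = TrainedModel(
        net=net, schema=dataset.schema, stats=dataset.stats,
        config=config, history=history, kind="indel",
    )
    scores = net.predict(dataset.X_val)
    score_set = ScoreSet(scores=scores, labels=dataset.y_val, source="indel")
    return PipelineResult(
        model=model,
        eval_result=evaluate(score_set),
        val_scores=score_set,
        n_train=len(dataset.y_train),
        n_val=len(dataset.y_val),
    )


# ---------------------------------------------------------------------------
# VCF annotation
# ---------------------------------------------------------------------------

REASON_NOT_CODING = "not_in_any_transcript"
REASON_NOT_MISSENSE = "not_missense_or_unannotated"
REASON_FRAMESHIFT = "frameshift"
REASON_TOO_LONG = "too_long"
REASON_EXON_BOUNDARY = "exon_boundary"
REASON_WINDOW = "window_error"


def annotate_vcf(
    vcf_path,
    raw_table: AnnotationTable,
    layouts: Sequence[CodingContext],
    snv_model: TrainedModel,
    indel_model: TrainedModel | None,
    out_prefix: str,
    *,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Score every scorable variant of a VCF, per transcript.

    SNVs route to the SNV model (missense annotation required), pure indels
    with in-frame length to the indel model; everything else lands in the
    unscorable report with a reason code.  SNV and indel outputs are written
    to separate files.
    """
    layout_by_id = {t.transcript_id: t for t in layouts}
    variants = read_vcf_variants(vcf_path)

    snv_table = raw_table.with_schema(snv_model.schema)
    snv_table.impute()
    snv_table.standardize(snv_model.stats)
    if indel_model is not None:
        indel_table = raw_table.with_schema(indel_model.schema)
        indel_table.impute()
        indel_table.standardize(indel_model.stats)

    snv_rows, indel_rows, unscorable = [], [], []
    for chrom, pos, ref, alt in variants:
        key = variant_key(chrom, pos, ref, alt)
        if len(ref) == 1 and len(alt) == 1:
            rows = [
                i
                for i in snv_table.find_rows(chrom, pos, ref, alt)
                if snv_table.df.at[i, "consequence"] == "missense"
                and snv_table.df.at[i, "transcript_id"] in layout_by_id
            ]
            if not rows:
                unscorable.append({"variant_key": key, "reason": REASON_NOT_MISSENSE})
                continue
            for i in rows:
                target = snv_table.allele_at_row(i)
                w = build_snv_window(
                    target, snv_table, layout_by_id[target.transcript_id]
                )
                score = float(snv_model.predict([w])[0])
                snv_rows.append(
                    {
                        "variant_key": key,
                        "transcript_id": target.transcript_id,
                        "score": score,
                        "class": "pathogenic" if score > threshold else "benign",
                        "model": "snv",
                    }
                )
        else:
            try:
                var = IndelVariant(chrom=chrom, pos=pos, ref=ref, alt=alt)
            except WindowError:
                unscorable.append({"variant_key": key, "reason": REASON_WINDOW})
                continue
            if var.length % 3 != 0:
                unscorable.append({"variant_key": key, "reason": REASON_FRAMESHIFT})
                continue
            if var.length > MAX_INDEL_LENGTH:
                unscorable.append({"variant_key": key, "reason": REASON_TOO_LONG})
                continue
            if indel_model is None:
                unscorable.append({"variant_key": key, "reason": "no_indel_model"})
                continue
            hits = [
                t for t in layouts
                if t.chrom == chrom
                and any(a <= pos <= b for a, b in t.cds_segments)
            ]
            if not hits:
                unscorable.append({"variant_key": key, "reason": REASON_NOT_CODING})
                continue
            scored_any = False
            for t in hits:
                try:
                    w = build_indel_window(
                        var, indel_table, t, n_features=len(indel_model.schema)
                    )
                except ExonBoundaryError:
                    unscorable.append(
                        {"variant_key": key, "reason": REASON_EXON_BOUNDARY}
                    )
                    continue
                except WindowError:
                    unscorable.append({"variant_key": key, "reason": REASON_WINDOW})
                    continue
                score = float(indel_model.predict([w])[0])
                indel_rows.append(
                    {
                        "variant_key": key,
                        "transcript_id": t.transcript_id,
                        "score": score,
                        "class": "pathogenic" if score > threshold else "benign",
                        "model": "indel",
                    }
                )
                scored_any = True
    digest = config_digest(f"{threshold}:{seed}:{len(layouts)}")
    write_scores(
        snv_rows, f"{out_prefix}.snv.tsv",
        tool_version=__version__, digest=digest, seed=seed,
    )
    write_scores(
        indel_rows, f"{out_prefix}.indel.tsv",
        tool_version=__version__, digest=digest, seed=seed,
    )
    write_unscorable(unscorable, f"{out_prefix}.unscorable.tsv")
    return {
        "n_snv_scored": len(snv_rows),
        "n_indel_scored": len(indel_rows),
        "n_unscorable": len(unscorable),
        "snv_rows": snv_rows,
        "indel_rows": indel_rows,
        "unscorable": unscorable,
    }
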