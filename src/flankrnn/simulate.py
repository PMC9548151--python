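"""Synthetic annotation data with controllable, recoverable signal structure.

Emulates the statistical shape of a dbNSFP-like per-allele annotation table
so the whole pipeline (curation -> windows -> training -> evaluation) is
testable without any external download:

* per-locus multi-allele structure (1-3 alternative alleles, a configurable
  synonymous fraction),
* 24 functional/conservation scores driven by shared low-rank latents, so
  designated feature pairs correlate in the 0.4-1 range seen among real
  component scores,
* heavy-zero allele-frequency features (a point mass at 0 for unobserved
  variants, Beta-distributed max-subpopulation AF otherwise), with benign
  variants stochastically more often observed,
* missing values at a configurable rate, and
* ClinVar-like assertion sets with controlled rates of conflicts and VUS.

Label/signal geometry: each codon ``c`` of each transcript carries a latent
pathogenicity field value ``r_c`` (iid standard normal).  All missense
alleles in codon ``c`` are pathogenic iff ``r_c`` exceeds the
``1 - p_pathogenic`` quantile.  An allele's *features* are shifted by
``effect_size_target`` times its own label plus ``effect_size_context``
times the field value of the codon *preceding* its own
(``r_{c-1}``).  Hence the downstream flanking codon of a target at codon
``c`` carries ``r_c`` — the target's label signal — in its features, while
the target's own features carry only ``r_{c-1}``, which is independent of
the label.  Setting ``effect_size_target = 0`` therefore plants label
signal exclusively in the context, the configuration used to demonstrate
that the recurrent model exploits flanking information a target-only
feed-forward net cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .curation import ClinicalRecord
from .features import ALLELE_FREQUENCY, FeatureSchema
from .io import AnnotationTable, variant_key
from .windows import CodingContext, IndelVariant

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_transcripts: int = 50
    codons_per_transcript: int = 100
    multi_exon_fraction: float = 0.4
    minus_strand_fraction: float = 0.5
    allele_count_probs: tuple[float, ...] = (0.5, 0.3, 0.2)  # P(1..3 alts)
    fraction_synonymous: float = 0.25
    fraction_other: float = 0.05
    p_pathogenic: float = 0.35
    effect_size_target: float = 0.8
    effect_size_context: float = 0.5
    block_correlation_range: tuple[float, float] = (0.45, 0.85)
    cross_block_coupling: float = 0.6
    af_p_observed_benign: float = 0.7
    af_p_observed_pathogenic: float = 0.35
    af_p_dataset_given_observed: float = 0.75
    af_beta_benign: tuple[float, float] = (0.5, 20.0)
    af_beta_pathogenic: tuple[float, float] = (0.3, 50.0)
    missingness_rate: float = 0.05
    conflict_rate: float = 0.05
    vus_only_rate: float = 0.05
    likely_rate: float = 0.4
    second_assertion_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.multi_exon_fraction, self.minus_strand_fraction,
            self.fraction_synonymous, self.fraction_other, self.p_pathogenic,
            self.af_p_observed_benign, self.af_p_observed_pathogenic,
            self.af_p_dataset_given_observed, self.missingness_rate,
            self.conflict_rate, self.vus_only_rate, self.likely_rate,
            self.second_assertion_rate,
        ] + list(self.allele_count_probs)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if abs(sum(self.allele_count_probs) - 1) > 1e-9:
            raise ValueError("allele_count_probs must sum to 1")
        if self.codons_per_transcript < 3:
            raise ValueError("need at least 3 codons per transcript")

    @classmethod
    def context_signal(cls, **overrides) -> "SyntheticConfig":
        """Label signal planted exclusively in the flanking codons.

        The target's own features and the AF features are uninformative, so
        a target-only feed-forward model has nothing to learn from while the
        recurrent model can read the context.
        """
        base = cls(
            n_transcripts=75,
            effect_size_target=0.0,
            effect_size_context=2.0,
            af_p_observed_pathogenic=0.55,
            af_p_observed_benign=0.55,
            af_beta_pathogenic=(0.5, 20.0),
        )
        return replace(base, **overrides)

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """No label signal anywhere (feature/AF distributions label-free)."""
        base = cls(
            effect_size_target=0.0,
            effect_size_context=0.0,
            af_p_observed_pathogenic=0.55,
            af_p_observed_benign=0.55,
            af_beta_pathogenic=(0.5, 20.0),
        )
        return replace(base, **overrides)


@dataclass
class SyntheticTruth:
    """Generator bookkeeping: latent labels and planted effects per variant."""

    variants: pd.DataFrame  # one row per generated allele
    codon_field: dict[str, np.ndarray]  # transcript -> r_c values
    clinical_outcomes: pd.DataFrame | None = None  # expected curation outcomes


def generate_transcript_layout(config: SyntheticConfig) -> list[CodingContext]:
    """Transcript layouts: single- and multi-exon, both strands.

    CDS lengths are always multiples of 3.  Transcripts are spread over
    chromosomes with generous spacing so windows never collide.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layouts = []
    L = config.codons_per_transcript * 3
    for k in range(config.n_transcripts):
        chrom = f"chr{k % 22 + 1}"
        start = 10_000 + 1_000_000 * (k // 22)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if rng.random() < config.multi_exon_fraction and L >= 9:
            n_exons = int(rng.integers(2, 4))
            cuts = np.sort(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
            lengths = np.diff(np.concatenate([[0], cuts, [L]]))
            segs = []
            g = start
            for ln in lengths:
                segs.append((g, g + int(ln) - 1))
                g += int(ln) + int(rng.integers(50, 500))  # intron
            segments = tuple(segs)
        else:
            segments = ((start, start + L - 1),)
        layouts.append(
            CodingContext(
                transcript_id=f"TX{k:04d}",
                chrom=chrom,
                strand=strand,
                cds_segments=segments,
            )
        )
    return layouts


def _alt_bases(rng: np.random.Generator, ref: str, n: int) -> list[str]:
    pool = [b for b in "ACGT" if b != ref]
    return list(rng.choice(pool, size=n, replace=False))


def generate_annotation_table(
    config: SyntheticConfig,
    layouts: Sequence[CodingContext],
    schema: FeatureSchema | None = None,
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Per-allele annotation table plus recoverable ground truth."""
    config.validate()
    schema = schema or FeatureSchema.synthetic()
    rng = np.random.default_rng(config.seed + 1)

    rows = []
    codon_field: dict[str, np.ndarray] = {}
    for tx in layouts:
        n_codons = tx.n_codons
        r = rng.standard_normal(n_codons)
        codon_field[tx.transcript_id] = r
        cp = tx.coding_positions
        ref_bases = rng.choice(BASES, size=len(cp))
        n_alts = rng.choice(
            np.arange(1, len(config.allele_count_probs) + 1),
            size=len(cp),
            p=config.allele_count_probs,
        )
        for i, pos in enumerate(cp):
            codon = i // 3
            alts = _alt_bases(rng, ref_bases[i], int(n_alts[i]))
            for alt in alts:
                u = rng.random()
                if u < config.fraction_synonymous:
                    consequence = "synonymous"
                elif u < config.fraction_synonymous + config.fraction_other:
                    consequence = "other"
                else:
                    consequence = "missense"
                rows.append(
                    (
                        tx.chrom, int(pos), ref_bases[i], alt, tx.transcript_id,
                        codon + 1, i % 3, consequence, codon,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "transcript_id",
            "codon_index", "codon_offset", "consequence", "_codon0",
        ],
    )
    n = len(df)

    # latent labels: all missense alleles of codon c share 1{r_c > q}
    threshold = norm.ppf(1 - config.p_pathogenic)
    r_own = np.empty(n)
    r_prev = np.empty(n)
    for tx in layouts:
        m = (df["transcript_id"] == tx.transcript_id).to_numpy()
        c = df.loc[m, "_codon0"].to_numpy()
        r = codon_field[tx.transcript_id]
        r_own[m] = r[c]
        r_prev[m] = np.where(c > 0, r[np.maximum(c - 1, 0)], 0.0)
    labels = (r_own > threshold).astype(int)
    is_missense = (df["consequence"] == "missense").to_numpy()

    # feature blocks: shared latents per allele, shifted by planted effects
    g = config.effect_size_target * labels + config.effect_size_context * r_prev
    z_func = g + rng.standard_normal(n)
    z_cons = config.cross_block_coupling * g + rng.standard_normal(n)
    lo, hi = config.block_correlation_range
    rho_func = np.linspace(lo, hi, 16)
    rho_cons = np.linspace(lo, hi, 8)
    F_func = (
        np.sqrt(rho_func) * z_func[:, None]
        + np.sqrt(1 - rho_func) * rng.standard_normal((n, 16))
    )
    F_cons = (
        np.sqrt(rho_cons) * z_cons[:, None]
        + np.sqrt(1 - rho_cons) * rng.standard_normal((n, 8))
    )

    # allele-frequency features: zero-inflated Beta, benign more observed
    p_obs = np.where(
        labels == 1, config.af_p_observed_pathogenic, config.af_p_observed_benign
    )
    observed = rng.random(n) < p_obs
    a_b, b_b = config.af_beta_benign
    a_p, b_p = config.af_beta_pathogenic
    base_af = np.where(
        labels == 1, rng.beta(a_p, b_p, size=n), rng.beta(a_b, b_b, size=n)
    )
    # datasets: 1000GP, ExAC, gnomAD exomes, gnomAD genomes
    present4 = rng.random((n, 4)) < config.af_p_dataset_given_observed
    none = ~present4.any(axis=1)
    if none.any():  # an observed variant is present in at least one dataset
        force = rng.integers(0, 4, size=int(none.sum()))
        present4[np.flatnonzero(none), force] = True
    present4 &= observed[:, None]
    jitter = rng.lognormal(mean=0.0, sigma=0.3, size=(n, 4))
    F_af = np.clip(base_af[:, None] * jitter, 0.0, 1.0) * present4

    F_all = np.concatenate([F_func, F_cons, F_af], axis=1)

    # missingness on the 24 score features only (AF absent means 0, not NaN)
    miss = rng.random((n, 24)) < config.missingness_rate
    F_all[:, :24][miss] = np.nan

    # write features in raw tool orientation; the table harmonizes on load
    raw = F_all * np.array(schema.orientations, dtype=float)
    raw[:, schema.af_indices] = F_all[:, schema.af_indices]  # AF never flipped
    for j, name in enumerate(schema.names):
        df[name] = raw[:, j]

    truth_df = pd.DataFrame(
        {
            "variant_key": [
                variant_key(c, p, r_, a)
                for c, p, r_, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
            ],
            "transcript_id": df["transcript_id"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "codon0": df["_codon0"],
            "consequence": df["consequence"],
            "label": labels,
            "is_missense": is_missense,
            "observed": observed,
            "present_1000GP": present4[:, 0],
            "present_ExAC": present4[:, 1],
            "present_gnomAD_exomes": present4[:, 2],
            "present_gnomAD_genomes": present4[:, 3],
            "af_1000GP": F_af[:, 0],
            "af_ExAC": F_af[:, 1],
            "af_gnomAD_exomes": F_af[:, 2],
            "af_gnomAD_genomes": F_af[:, 3],
            "r_own": r_own,
        }
    )
    df = df.drop(columns=["_codon0"])
    table = AnnotationTable(df, schema)
    return table, SyntheticTruth(variants=truth_df, codon_field=codon_field)


CONFLICT_SCENARIOS = ("benign_vus", "pathogenic_vus", "benign_pathogenic")


def generate_clinvar_records(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """ClinVar-like records for every missense variant in the truth table.

    Returns the records plus a bookkeeping frame with the expected
    label-resolution outcome per record, so filter outputs can be checked
    against exact counts.
    """
    rng = np.random.default_rng(config.seed + 2)
    t = truth.variants
    sub = t[t["is_missense"]].drop_duplicates("variant_key")
    records: list[ClinicalRecord] = []
    outcomes = []
    for r in sub.itertuples(index=False):
        y = int(r.label)
        side = (
            ["pathogenic", "likely_pathogenic"] if y else ["benign", "likely_benign"]
        )
        primary = side[1] if rng.random() < config.likely_rate else side[0]
        assertions = {primary}
        if rng.random() < config.second_assertion_rate:
            assertions.add(side[1 - side.index(primary)])
        u = rng.random()
        if u < config.conflict_rate:
            scenario = CONFLICT_SCENARIOS[int(rng.integers(0, 3))]
            if scenario == "benign_vus":
                assertions = {"benign", "vus"}
            elif scenario == "pathogenic_vus":
                assertions = {"pathogenic", "vus"}
            else:
                assertions = {"benign", "pathogenic"}
            expected = "conflicting"
        elif u < config.conflict_rate + config.vus_only_rate:
            assertions = {"vus"}
            scenario = ""
            expected = "vus_only"
        else:
            scenario = ""
            expected = "TP" if y else "TN"
        presence = {
            "1000GP": bool(r.present_1000GP),
            "ExAC": bool(r.present_ExAC),
            "gnomAD": bool(r.present_gnomAD_exomes or r.present_gnomAD_genomes),
        }
        max_af = {
            "1000GP": float(r.af_1000GP),
            "ExAC": float(r.af_ExAC),
            "gnomAD": float(max(r.af_gnomAD_exomes, r.af_gnomAD_genomes)),
        }
        records.append(
            ClinicalRecord(
                variant_key=r.variant_key,
                assertions=frozenset(assertions),
                presence=presence,
                max_af=max_af,
                chrom=str(r.chrom),
                pos=int(r.pos),
            )
        )
        outcomes.append((r.variant_key, expected, scenario, y))
    book = pd.DataFrame(
        outcomes, columns=["variant_key", "expected_outcome", "conflict_scenario", "label"]
    )
    return records, book


def generate_indel_variants(
    config: SyntheticConfig,
    layouts: Sequence[CodingContext],
    truth: SyntheticTruth,
    n_variants: int = 200,
    max_codons: int = 4,
) -> list[tuple[IndelVariant, str, int]]:
    """Codon-aligned non-frameshift deletions with labels from the codon field.

    A deletion removing codons [c, c+k) is pathogenic iff the mean latent
    field over those codons exceeds the pathogenicity quantile.  Only
    deletions fully inside one exon are emitted.
    """
    rng = np.random.default_rng(config.seed + 3)
    threshold = norm.ppf(1 - config.p_pathogenic)
    out: list[tuple[IndelVariant, str, int]] = []
    plus_layouts = [t for t in layouts if t.strand == "+"]
    attempts = 0
    while len(out) < n_variants and attempts < n_variants * 50:
        attempts += 1
        tx = plus_layouts[int(rng.integers(0, len(plus_layouts)))]
        k = int(rng.integers(1, max_codons + 1))
        c = int(rng.integers(1, tx.n_codons - k))  # keep a left flank codon
        cp = tx.coding_positions
        idx = np.arange(3 * c, 3 * (c + k))
        pos = cp[idx]
        if not np.all(np.diff(pos) == 1):  # spans an exon junction
            continue
        anchor = int(pos[0]) - 1
        if anchor not in cp:  # anchor must sit in the CDS for windowing context
            continue
        deleted = "".join(rng.choice(BASES, size=3 * k))
        anchor_base = str(rng.choice(BASES))
        var = IndelVariant(
            chrom=tx.chrom, pos=anchor, ref=anchor_base + deleted, alt=anchor_base
        )
        r = truth.codon_field[tx.transcript_id][c : c + k]
        label = int(r.mean() > threshold)
        out.append((var, tx.transcript_id, label))
    return out
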