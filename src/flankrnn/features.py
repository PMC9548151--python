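"""Annotation feature schema, allele-frequency derivation, imputation, standardization.

Every variant (target or context) is described by an ordered vector of 28
annotation features: 16 functional prediction scores, 8 conservation scores
and 4 allele-frequency (AF) features, one per population dataset (1000
Genomes, ExAC, gnomAD exomes, gnomAD genomes).  The schema is
configuration-driven so synthetic feature sets can stand in for the real
tool scores, but the category counts (16/8/4) and the ordering contract are
fixed.

AF features are the *maximum* allele frequency across the subpopulations of
a dataset; a variant with no record in a dataset has AF 0, not missing.
Missing tool scores are imputed with an iterative low-rank (probabilistic
PCA style) completion before all 28 features are standardized to zero mean
and unit variance using statistics estimated on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

FUNCTIONAL = "functional"
CONSERVATION = "conservation"
ALLELE_FREQUENCY = "allele_frequency"

CATEGORY_COUNTS = {FUNCTIONAL: 16, CONSERVATION: 8, ALLELE_FREQUENCY: 4}

#: Default feature names: the 16 functional scores, 8 conservation scores and
#: 4 max-subpopulation AF features consumed by the classifier.  Orientation
#: is +1 when larger raw values mean more damaging.
DEFAULT_FEATURES: list[tuple[str, str, int]] = [
    ("SIFT", FUNCTIONAL, -1),  # SIFT scores benign-high; flipped on load
    ("Polyphen2_HDIV", FUNCTIONAL, 1),
    ("Polyphen2_HVAR", FUNCTIONAL, 1),
    ("MutationAssessor", FUNCTIONAL, 1),
    ("PROVEAN", FUNCTIONAL, -1),
    ("VEST4", FUNCTIONAL, 1),
    ("M-CAP", FUNCTIONAL, 1),
    ("REVEL", FUNCTIONAL, 1),
    ("MutPred", FUNCTIONAL, 1),
    ("MVP", FUNCTIONAL, 1),
    ("PrimateAI", FUNCTIONAL, 1),
    ("DEOGEN2", FUNCTIONAL, 1),
    ("CADD", FUNCTIONAL, 1),
    ("fathmm-XF", FUNCTIONAL, 1),
    ("Eigen", FUNCTIONAL, 1),
    ("GenoCanyon", FUNCTIONAL, 1),
    ("GERP", CONSERVATION, 1),
    ("phyloP100way_vertebrate", CONSERVATION, 1),
    ("phyloP30way_mammalian", CONSERVATION, 1),
    ("phyloP17way_primate", CONSERVATION, 1),
    ("phastCons100way_vertebrate", CONSERVATION, 1),
    ("phastCons30way_mammalian", CONSERVATION, 1),
    ("phastCons17way_primate", CONSERVATION, 1),
    ("SiPhy", CONSERVATION, 1),
    ("AF_1000GP", ALLELE_FREQUENCY, 1),
    ("AF_ExAC", ALLELE_FREQUENCY, 1),
    ("AF_gnomAD_exomes", ALLELE_FREQUENCY, 1),
    ("AF_gnomAD_genomes", ALLELE_FREQUENCY, 1),
]


class SchemaError(ValueError):
    """Raised when a feature schema violates its structural invariants."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 28-feature annotation schema.

    Parameters
    ----------
    names
        Ordered feature identifiers.
    categories
        Category per feature, aligned with ``names``; each is one of
        ``functional``, ``conservation``, ``allele_frequency``.
    orientations
        +1 if larger raw values mean more damaging, -1 if the raw tool
        scores benign-high (flipped by :meth:`harmonize`).
    """

    names: tuple[str, ...]
    categories: tuple[str, ...]
    orientations: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.orientations:
            object.__setattr__(self, "orientations", tuple([1] * len(self.names)))
        if not (len(self.names) == len(self.categories) == len(self.orientations)):
            raise SchemaError("names, categories and orientations must align")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("duplicate feature names")
        counts = {c: self.categories.count(c) for c in CATEGORY_COUNTS}
        if counts != CATEGORY_COUNTS and len(self.names) == 28:
            raise SchemaError(
                f"expected 16 functional + 8 conservation + 4 allele_frequency, got {counts}"
            )
        bad = set(self.categories) - set(CATEGORY_COUNTS)
        if bad:
            raise SchemaError(f"unknown categories: {sorted(bad)}")
        if any(o not in (-1, 1) for o in self.orientations):
            raise SchemaError("orientations must be +1 or -1")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices_of(self, category: str) -> np.ndarray:
        """Column indices of one category, in schema order."""
        return np.array([i for i, c in enumerate(self.categories) if c == category])

    @property
    def af_indices(self) -> np.ndarray:
        return self.indices_of(ALLELE_FREQUENCY)

    def harmonize(self, features: np.ndarray) -> np.ndarray:
        """Flip benign-high columns so larger always means more damaging."""
        flip = np.array(self.orientations, dtype=float)
        return np.asarray(features, dtype=float) * flip

    def drop_allele_frequency(self) -> "FeatureSchema":
        """24-feature schema used by the AF-free ablation."""
        keep = [i for i, c in enumerate(self.categories) if c != ALLELE_FREQUENCY]
        return FeatureSchema(
            names=tuple(self.names[i] for i in keep),
            categories=tuple(self.categories[i] for i in keep),
            orientations=tuple(self.orientations[i] for i in keep),
        )

    # -- config round-trip ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": n, "category": c, "orientation": o}
                for n, c, o in zip(self.names, self.categories, self.orientations)
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        feats = d["features"]
        return cls(
            names=tuple(f["name"] for f in feats),
            categories=tuple(f["category"] for f in feats),
            orientations=tuple(int(f.get("orientation", 1)) for f in feats),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FeatureSchema":
        return cls(
            names=tuple(n for n, _, _ in DEFAULT_FEATURES),
            categories=tuple(c for _, c, _ in DEFAULT_FEATURES),
            orientations=tuple(o for _, _, o in DEFAULT_FEATURES),
        )

    @classmethod
    def synthetic(cls) -> "FeatureSchema":
        """Generic feature names for simulated annotation tables."""
        names = (
            [f"func_{i:02d}" for i in range(16)]
            + [f"cons_{i}" for i in range(8)]
            + ["AF_1000GP", "AF_ExAC", "AF_gnomAD_exomes", "AF_gnomAD_genomes"]
        )
        cats = [FUNCTIONAL] * 16 + [CONSERVATION] * 8 + [ALLELE_FREQUENCY] * 4
        # a couple of benign-high columns so orientation handling is exercised
        orient = [1] * 28
        orient[0] = -1
        orient[4] = -1
        return cls(tuple(names), tuple(cats), tuple(orient))


@dataclass
class AlleleAnnotation:
    """One candidate allele at one coding locus.

    ``features`` is aligned with a :class:`FeatureSchema`; entries where
    ``missing_mask`` is True are ignored (NaN by convention).
    """

    chrom: str
    pos: int  # 1-based genomic position
    ref: str
    alt: str
    transcript_id: str
    codon_index: int  # 1-based codon number in the CDS
    codon_offset: int  # position within codon, 0..2 in coding orientation
    consequence: str  # missense | synonymous | other
    features: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.features.shape != self.missing_mask.shape:
            raise ValueError("features and missing_mask must have the same shape")
        present = ~self.missing_mask
        if not np.all(np.isfinite(self.features[present])):
            raise ValueError("non-missing features must be finite")
        if self.codon_offset not in (0, 1, 2):
            raise ValueError("codon_offset must be in {0,1,2}")


def max_subpopulation_af(af_records: Mapping[str, float] | None) -> float:
    """Maximum allele frequency across the subpopulations of one dataset.

    A variant absent from the dataset (no record / empty mapping) has
    frequency 0: unobserved means AF = 0, not missing.
    """
    if not af_records:
        return 0.0
    values = np.asarray(list(af_records.values()), dtype=float)
    if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
        raise ValueError(f"allele frequencies must lie in [0,1], got {af_records}")
    return float(values.max())


class ImputationError(ValueError):
    pass


def _complete_fixed_rank(
    X0: np.ndarray,
    mask: np.ndarray,
    col_mean: np.ndarray,
    rank: int,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool]:
    """Alternate truncated-SVD reconstruction with observed-entry re-imposition."""
    X = X0.copy()
    X[mask] = np.take(col_mean, np.nonzero(mask)[1])
    prev = X[mask].copy()
    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X - mu, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank] + mu
        X[mask] = recon[mask]
        scale = max(1.0, float(np.max(np.abs(prev))))
        if np.max(np.abs(X[mask] - prev)) / scale < tol:
            converged = True
            break
        prev = X[mask].copy()
    return X, converged


def impute_missing(
    features: np.ndarray,
    missing_mask: np.ndarray,
    *,
    max_rank: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Fill missing entries by iterative low-rank (probabilistic-PCA style)
    completion with automatic rank determination.

    Missing cells are initialised at the column mean, then refined by
    alternating a rank-``r`` SVD reconstruction of the column-centred matrix
    with re-imposition of the observed entries.  The rank is determined
    automatically: a small fraction of *observed* entries is held out, the
    completion is run at every candidate rank (1 .. ``max_rank``, capped by
    the matrix size), and the rank reconstructing the held-out entries best
    is refit on all observed data.  Deterministic for a fixed ``seed``
    (which only controls the held-out entry choice).

    Parameters
    ----------
    features : (n, p) array
        Raw feature matrix; entries under ``missing_mask`` are ignored.
    missing_mask : (n, p) bool array
        True where the value is missing.

    Returns
    -------
    (n, p) array with observed entries untouched and missing ones filled.

    Raises
    ------
    ImputationError
        If any column is entirely missing (named in the message).
    """
    X = np.array(features, dtype=float)
    mask = np.asarray(missing_mask, dtype=bool)
    if X.shape != mask.shape or X.ndim != 2:
        raise ImputationError("features and missing_mask must be matching 2-D arrays")
    n, p = X.shape
    fully_missing = mask.all(axis=0)
    if fully_missing.any():
        cols = np.flatnonzero(fully_missing)
        names = (
            [feature_names[c] for c in cols] if feature_names is not None else list(cols)
        )
        raise ImputationError(f"columns entirely missing: {names}")
    if not mask.any():
        return X

    col_mean = np.array([X[~mask[:, j], j].mean() for j in range(p)])
    rank_cap = max(1, int(min(max_rank, n - 1, p - 1)))

    # hold out ~10% of observed entries (never emptying a column) to pick rank;
    # on large tables the rank is selected on a row subsample for speed
    rng = np.random.default_rng(seed)
    n_select = 4000
    if n > n_select:
        rows = np.sort(rng.choice(n, size=n_select, replace=False))
        sub_ok = ~mask[rows].all(axis=0)
        if sub_ok.all():
            X_sel, mask_sel = X[rows], mask[rows]
        else:
            X_sel, mask_sel = X, mask
    else:
        X_sel, mask_sel = X, mask
    obs = np.argwhere(~mask_sel)
    rng.shuffle(obs)
    n_holdout = max(1, int(0.1 * len(obs)))
    col_obs_left = (~mask_sel).sum(axis=0).astype(int)
    holdout: list[tuple[int, int]] = []
    for i, j in obs[: 4 * n_holdout]:
        if len(holdout) >= n_holdout:
            break
        if col_obs_left[j] > 2:
            holdout.append((int(i), int(j)))
            col_obs_left[j] -= 1
    if holdout:
        hmask = mask_sel.copy()
        hi = tuple(np.array(holdout).T)
        hmask[hi] = True
        truth = X_sel[hi]
        hcol_mean = np.array([X_sel[~hmask[:, j], j].mean() for j in range(p)])
        best_rank, best_err = 1, np.inf
        for r in range(1, rank_cap + 1):
            Xr, _ = _complete_fixed_rank(
                X_sel, hmask, hcol_mean, r, max(tol, 1e-4), min(max_iter, 30)
            )
            err = float(np.sqrt(np.mean((Xr[hi] - truth) ** 2)))
            if err < best_err - 1e-12:
                best_err, best_rank = err, r
    else:
        best_rank = rank_cap

    out, converged = _complete_fixed_rank(X, mask, col_mean, best_rank, tol, max_iter)
    if not converged:
        warnings.warn(
            "low-rank imputation did not converge; falling back to column means",
            RuntimeWarning,
            stacklevel=2,
        )
        out = X.copy()
        out[mask] = np.take(col_mean, np.nonzero(mask)[1])
    return out


@dataclass(frozen=True)
class StandardizerStats:
    """Per-feature location/scale estimated on training data.

    The population (divide-by-n) standard deviation convention is used.
    """

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if np.any(self.std <= 0):
            raise ValueError("standard deviation must be > 0 for every feature")


def fit_standardizer(features: np.ndarray) -> StandardizerStats:
    """Estimate per-column mean and population standard deviation.

    Raises
    ------
    ValueError
        On a zero-variance (degenerate) column.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("standardizer requires a complete (imputed) matrix")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population convention
    if np.any(std <= 0):
        bad = np.flatnonzero(std <= 0)
        raise ValueError(f"zero-variance feature columns: {bad.tolist()}")
    return StandardizerStats(mean=mean, std=std)


def apply_standardizer(features: np.ndarray, stats: StandardizerStats) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    return (X - stats.mean) / stats.std
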