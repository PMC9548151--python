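"""Meta-classifier construction, training, prediction and hyperparameter search.

Two architectures share one recurrent core: the SNV model reads an 11 x 28
window, passes it through stacked bidirectional GRU layers and keeps only
the learned state at the target locus (index 5) before the dense stack and
the single sigmoid output; the indel model reads a 58 x 28 window and keeps
only the final-step states of the two directions.  A padding-indicator
channel is appended to the feature axis, so internally the nets consume
F + 1 channels.

Training minimises binary cross-entropy with Adam and keeps the parameter
snapshot with the smallest validation log loss.  Hyperparameters are chosen
by Bayesian optimisation (Gaussian-process surrogate with expected
improvement), with a plain random-search fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .features import (
    FeatureSchema,
    StandardizerStats,
    apply_standardizer,
)
from .nn import HEAD_FINAL_LOCUS, HEAD_TARGET_CROP
from .windows import (
    INDEL_WINDOW_LENGTH,
    SNV_TARGET_INDEX,
    SNV_WINDOW_LENGTH,
    WindowMatrix,
)

ABLATION_KINDS = ("rare_only", "af_free", "feed_forward")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one classifier."""

    gru_units: tuple[int, ...] = (32,)
    dense_units: tuple[int, ...] = (32,)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0
    head_mode: str = HEAD_TARGET_CROP

    def validate(self) -> None:
        if self.head_mode not in (HEAD_TARGET_CROP, HEAD_FINAL_LOCUS):
            raise ValueError(f"invalid head_mode {self.head_mode!r}")
        if not self.gru_units or any(u < 1 for u in self.gru_units):
            raise ValueError("gru_units must be positive")
        if any(u < 1 for u in self.dense_units):
            raise ValueError("dense_units must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def build_snv_model(config: ModelConfig, n_features: int = 28) -> nn.SequenceClassifier:
    """Untrained SNV net: 11 x (F+1) -> bi-GRU stack -> target-locus state -> dense -> sigmoid."""
    config.validate()
    if config.head_mode != HEAD_TARGET_CROP:
        raise ValueError("SNV models require head_mode='target_locus_crop'")
    return nn.SequenceClassifier(
        seq_len=SNV_WINDOW_LENGTH,
        n_features=n_features + 1,  # + padding indicator channel
        gru_units=list(config.gru_units),
        dense_units=list(config.dense_units),
        head_mode=HEAD_TARGET_CROP,
        target_index=SNV_TARGET_INDEX,
        dropout=config.dropout,
        seed=config.seed,
    )


def build_indel_model(config: ModelConfig, n_features: int = 28) -> nn.SequenceClassifier:
    """Untrained indel net: 58 x (F+1) -> bi-GRU stack -> final-step states -> dense -> sigmoid."""
    config.validate()
    if config.head_mode != HEAD_FINAL_LOCUS:
        raise ValueError("indel models require head_mode='final_locus'")
    return nn.SequenceClassifier(
        seq_len=INDEL_WINDOW_LENGTH,
        n_features=n_features + 1,
        gru_units=list(config.gru_units),
        dense_units=list(config.dense_units),
        head_mode=HEAD_FINAL_LOCUS,
        dropout=config.dropout,
        seed=config.seed,
    )


def build_feed_forward_model(
    config: ModelConfig, n_features: int = 28
) -> nn.FeedForwardClassifier:
    """Dense-only ablation consuming the target-locus feature vector alone."""
    config.validate()
    return nn.FeedForwardClassifier(
        n_features=n_features,
        dense_units=list(config.dense_units),
        dropout=config.dropout,
        seed=config.seed,
    )


def encode_windows(windows: Sequence[WindowMatrix]) -> np.ndarray:
    """Stack windows into (n, L, F+1) with the pad-indicator channel appended."""
    Xs = []
    for w in windows:
        X = w.X
        pad = w.pad_mask.astype(float)[:, None]
        Xs.append(np.concatenate([X, pad], axis=1))
    return np.stack(Xs)


def _as_net_input(net, X: np.ndarray) -> np.ndarray:
    """Accept (n, L, F) or (n, L, F+1); append an all-real pad channel if absent."""
    X = np.asarray(X, dtype=float)
    if isinstance(net, nn.FeedForwardClassifier):
        return X
    if X.ndim == 2:
        X = X[None]
    if X.shape[2] == net.n_features - 1:
        pad = np.zeros(X.shape[:2] + (1,))
        X = np.concatenate([X, pad], axis=2)
    return X


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else float("nan")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\n")
            for e, tl, vl in zip(self.epochs, self.train_loss, self.val_loss):
                fh.write(f"{e}\t{tl:.6f}\t{vl:.6f}\n")


def train(
    net,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig,
) -> TrainingHistory:
    """Fit with Adam on mean BCE; restore the min-validation-loss snapshot.

    Deterministic given ``config.seed`` (initialisation is done by the
    builder; this seeds batching and dropout).
    """
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    X_train = _as_net_input(net, X_train)
    X_val = _as_net_input(net, X_val)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(lr=config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_state = net.get_state()
    stall = 0
    n = X_train.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = net.loss_and_grads(X_train[sel], y_train[sel], rng=rng)
            opt.step(net.parameters(), grads)
            batch_losses.append(loss)
        val_loss = nn.bce_loss(net.predict(X_val), y_val)
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(float(val_loss))
        if val_loss < best_loss - 1e-7:
            best_loss = val_loss
            best_state = net.get_state()
            history.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    net.set_state(best_state)
    return history


@dataclass
class TrainedModel:
    """Network parameters bound to their feature schema and standardizer.

    Prediction refuses schema-width mismatches rather than re-aligning.
    """

    net: object
    schema: FeatureSchema
    stats: StandardizerStats
    config: ModelConfig
    history: TrainingHistory
    kind: str  # snv | indel | feed_forward

    def _expected_width(self) -> int:
        return len(self.schema)

    def predict(self, X, mask_af: bool = False) -> np.ndarray:
        """Scores in (0,1), one per window; inputs must be standardized.

        ``mask_af=True`` replaces the allele-frequency columns with the
        standardized value of AF = 0 (the absent-variant value) at
        prediction time, without retraining.
        """
        if isinstance(X, WindowMatrix):
            X = [X]
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], WindowMatrix):
            X = encode_windows(X)
        X = np.asarray(X, dtype=float)
        feat_axis = X.shape[-1]
        F = self._expected_width()
        if feat_axis not in (F, F + 1):
            raise ValueError(
                f"schema mismatch: model expects {F} features, input has {feat_axis}"
            )
        if mask_af:
            X = mask_af_columns(X, self.schema, self.stats)
        return self.net.predict(_as_net_input(self.net, X))

    def classify(self, X, threshold: float = 0.5, **kw) -> np.ndarray:
        """1 (pathogenic) when score > threshold, else 0 (benign)."""
        return (self.predict(X, **kw) > threshold).astype(int)

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        blob = {
            "format_version": 1,
            "kind": self.kind,
            "config": asdict(self.config),
            "schema": self.schema.to_dict(),
            "stats": {"mean": self.stats.mean.tolist(), "std": self.stats.std.tolist()},
            "history": {
                "epochs": self.history.epochs,
                "train_loss": self.history.train_loss,
                "val_loss": self.history.val_loss,
                "best_epoch": self.history.best_epoch,
            },
            "params": {k: v.tolist() for k, v in self.net.get_state().items()},
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            blob = json.load(fh)
        cfg_d = blob["config"]
        cfg_d["gru_units"] = tuple(cfg_d["gru_units"])
        cfg_d["dense_units"] = tuple(cfg_d["dense_units"])
        config = ModelConfig(**cfg_d)
        schema = FeatureSchema.from_dict(blob["schema"])
        stats = StandardizerStats(
            mean=np.array(blob["stats"]["mean"]), std=np.array(blob["stats"]["std"])
        )
        kind = blob["kind"]
        if kind == "snv":
            net = build_snv_model(config, n_features=len(schema))
        elif kind == "indel":
            net = build_indel_model(config, n_features=len(schema))
        elif kind == "feed_forward":
            net = build_feed_forward_model(config, n_features=len(schema))
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        net.set_state({k: np.array(v) for k, v in blob["params"].items()})
        h = blob["history"]
        history = TrainingHistory(
            epochs=h["epochs"],
            train_loss=h["train_loss"],
            val_loss=h["val_loss"],
            best_epoch=h["best_epoch"],
        )
        return cls(net=net, schema=schema, stats=stats, config=config,
                   history=history, kind=kind)


def mask_af_columns(
    X: np.ndarray, schema: FeatureSchema, stats: StandardizerStats
) -> np.ndarray:
    """Set AF feature columns to the standardized absent-variant value (AF=0)."""
    X = np.array(X, dtype=float, copy=True)
    idx = schema.af_indices
    if idx.size == 0:
        return X
    masked_value = (0.0 - stats.mean[idx]) / stats.std[idx]
    X[..., idx] = masked_value
    return X


@dataclass(frozen=True)
class AblationVariant:
    """Recipe for one sensitivity-analysis variant.

    ``rare_only`` restricts training data to max AF < ``rare_threshold``;
    ``af_free`` drops the 4 AF columns from the schema (24 features);
    ``feed_forward`` replaces the recurrent net with a dense stack over the
    target-locus vector alone.
    """

    kind: str
    schema: FeatureSchema
    restrict_rare: bool = False
    feed_forward: bool = False
    rare_threshold: float = 0.01


def build_ablation_variant(kind: str, schema: FeatureSchema) -> AblationVariant:
    if kind not in ABLATION_KINDS:
        raise ValueError(f"unknown ablation kind {kind!r}; expected {ABLATION_KINDS}")
    if kind == "rare_only":
        return AblationVariant(kind=kind, schema=schema, restrict_rare=True)
    if kind == "af_free":
        return AblationVariant(kind=kind, schema=schema.drop_allele_frequency())
    return AblationVariant(kind=kind, schema=schema, feed_forward=True)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Ranges/choices searched over; the trial budget lives at the call site."""

    gru_units: tuple[int, ...] = (16, 32, 64, 128)
    n_gru_layers: tuple[int, ...] = (1, 2)
    dense_units: tuple[int, ...] = (16, 32, 64)
    dropout: tuple[float, float] = (0.0, 0.5)
    learning_rate: tuple[float, float] = (1e-4, 1e-2)  # log-uniform
    batch_size: tuple[int, ...] = (32, 64, 128)

    def validate(self) -> None:
        if not (self.gru_units and self.n_gru_layers and self.dense_units
                and self.batch_size):
            raise ValueError("search space must be nonempty")


@dataclass
class Trial:
    config: ModelConfig
    val_loss: float


def _sample_config(
    space: SearchSpace, rng: np.random.Generator, base: ModelConfig
) -> ModelConfig:
    u = int(rng.choice(space.gru_units))
    nl = int(rng.choice(space.n_gru_layers))
    du = int(rng.choice(space.dense_units))
    dr = float(rng.uniform(*space.dropout))
    lo, hi = np.log10(space.learning_rate[0]), np.log10(space.learning_rate[1])
    lr = float(10 ** rng.uniform(lo, hi))
    bs = int(rng.choice(space.batch_size))
    return replace(
        base,
        gru_units=(u,) * nl,
        dense_units=(du,),
        dropout=dr,
        learning_rate=lr,
        batch_size=bs,
    )


def _encode(config: ModelConfig, space: SearchSpace) -> np.ndarray:
    return np.array(
        [
            space.gru_units.index(config.gru_units[0]),
            len(config.gru_units),
            space.dense_units.index(config.dense_units[0]),
            config.dropout,
            np.log10(config.learning_rate),
            space.batch_size.index(config.batch_size),
        ],
        dtype=float,
    )


def hyperparameter_search(
    space: SearchSpace,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    *,
    n_trials: int,
    base_config: ModelConfig,
    build=build_snv_model,
    n_features: int = 28,
    seed: int = 0,
    method: str = "gp",
) -> tuple[ModelConfig, list[Trial]]:
    """Pick the config with the smallest validation log loss.

    ``method='gp'`` fits a Gaussian-process surrogate to completed trials
    and proposes the candidate with maximal expected improvement among a
    random candidate pool; the first third of the budget (minimum 3 trials)
    is random exploration.  ``method='random'`` is the fallback: pure random
    sampling.  Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("trial budget must be >= 1")
    if method not in ("gp", "random"):
        raise ValueError("method must be 'gp' or 'random'")
    space.validate()
    rng = np.random.default_rng(seed)
    X_tr, y_tr = train_data
    X_va, y_va = val_data
    trials: list[Trial] = []

    def run_trial(config: ModelConfig) -> float:
        net = build(config, n_features=n_features)
        hist = train(net, X_tr, y_tr, X_va, y_va, config)
        return hist.best_val_loss

    n_init = min(n_trials, max(3, n_trials // 3))
    for _ in range(n_init):
        cfg = _sample_config(space, rng, base_config)
        trials.append(Trial(cfg, run_trial(cfg)))

    if method == "gp" and n_trials > n_init:
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern
        from scipy.stats import norm

        for _ in range(n_trials - n_init):
            Xobs = np.stack([_encode(t.config, space) for t in trials])
            yobs = np.array([t.val_loss for t in trials])
            finite = np.isfinite(yobs)
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-4,
                random_state=int(rng.integers(2**31)),
            )
            gp.fit(Xobs[finite], yobs[finite])
            candidates = [_sample_config(space, rng, base_config) for _ in range(64)]
            Xc = np.stack([_encode(c, space) for c in candidates])
            mu, sd = gp.predict(Xc, return_std=True)
            best = yobs[finite].min()
            sd = np.maximum(sd, 1e-9)
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            cfg = candidates[int(np.argmax(ei))]
            trials.append(Trial(cfg, run_trial(cfg)))
    else:
        for _ in range(n_trials - n_init):
            cfg = _sample_config(space, rng, base_config)
            trials.append(Trial(cfg, run_trial(cfg)))

    best_trial = min(trials, key=lambda t: t.val_loss)
    return best_trial.config, trials


def write_trial_log(trials: Iterable[Trial], path) -> None:
    with open(path, "w") as fh:
        fh.write("trial\tgru_units\tdense_units\tdropout\tlearning_rate\t"
                 "batch_size\tval_loss\n")
        for i, t in enumerate(trials):
            c = t.config
            fh.write(
                f"{i}\t{','.join(map(str, c.gru_units))}\t"
                f"{','.join(map(str, c.dense_units))}\t{c.dropout:.4f}\t"
                f"{c.learning_rate:.6g}\t{c.batch_size}\t{t.val_loss:.6f}\n"
            )
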