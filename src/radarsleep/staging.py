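"""LSTM sleep staging: estimator, label mapping, training workflows.

:class:`LSTMSleepStager` is a scikit-learn-style sequence classifier mapping
per-epoch feature sequences (whole nights) to sleep stages.  It supports the
three workflows of the transfer-learning protocol: training from random
initialization, continuing optimization from pretrained weights at a reduced
learning rate (:meth:`LSTMSleepStager.fine_tune`), and prediction.  Feature
normalization statistics always travel with the model.

Sequences are passed hmmlearn-style: a 2-d feature matrix of concatenated
nights plus a ``lengths`` vector, or a list of per-night matrices.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rnn import Adam, SequenceNet
from .config import StagingModelConfig
from .features import FEATURE_COLUMNS
from .hypnogram import (  # noqa: F401  (re-exported label API)
    AASM5_TO_MERGED3,
    Hypnogram,
    LabelScheme,
    SCHEME_AASM5,
    SCHEME_MERGED3,
    get_scheme,
    map_labels,
)

try:  # sklearn is a soft structural dependency: the estimator works without it
    from sklearn.base import BaseEstimator, ClassifierMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

    class ClassifierMixin:  # type: ignore[no-redef]
        pass

__all__ = [
    "LSTMSleepStager",
    "PredictionSeries",
    "map_labels",
    "prepare_sequences",
    "train",
    "fine_tune",
    "predict",
]


# ---------------------------------------------------------------------------
# data preparation


def _as_sequences(X, lengths: Sequence[int] | None) -> list[np.ndarray]:
    if isinstance(X, (list, tuple)):
        return [np.asarray(x, dtype=float) for x in X]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d (n_epochs, n_features) or a list of such arrays")
    if lengths is None:
        return [X]
    lengths = np.asarray(lengths, dtype=int)
    if lengths.sum() != len(X):
        raise ValueError("lengths must sum to the number of rows in X")
    out, pos = [], 0
    for L in lengths:
        out.append(X[pos:pos + L])
        pos += L
    return out


def _split_like(y, seqs: list[np.ndarray]) -> list[np.ndarray]:
    y = np.asarray(y, dtype=object).ravel()
    out, pos = [], 0
    for s in seqs:
        out.append(y[pos:pos + len(s)])
        pos += len(s)
    if pos != len(y):
        raise ValueError("y length does not match X")
    return out


def _fill_invalid(X: np.ndarray) -> np.ndarray:
    """Forward-fill NaN feature values within a night, then back-fill, then
    zero — invalid epochs stay in the sequence but carry imputed values."""
    df = pd.DataFrame(X)
    return df.ffill().bfill().fillna(0.0).to_numpy(dtype=float)


#: heavy-tailed, non-negative features that are log-compressed at model input
LOG_COMPRESSED_FEATURES = ("ACT", "VLF", "LF", "HF", "LFHF", "TotalPower", "RRV_LF")


def prepare_sequences(tables: list[pd.DataFrame], scheme: str | LabelScheme = "aasm5",
                      feature_columns: list[str] | None = None,
                      log_power: bool = True,
                      ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Turn epoch feature tables into (X, y) sequence lists for the stager.

    Stage labels are mapped into the requested scheme; invalid-epoch feature
    values are imputed by per-night forward fill (the epochs keep their
    labels and stay in the sequence).  Power-like features span orders of
    magnitude (detection glitches inflate spectral power by factors of
    10^4), so by default they enter the model as ``log1p`` — without this,
    z-normalization is dominated by the outliers.
    """
    scheme = get_scheme(scheme)
    cols = feature_columns or FEATURE_COLUMNS
    Xs, ys = [], []
    for t in tables:
        missing = [c for c in cols if c not in t.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        X = t[cols].to_numpy(dtype=float).copy()
        if log_power:
            for j, c in enumerate(cols):
                if c in LOG_COMPRESSED_FEATURES:
                    X[:, j] = np.log1p(np.maximum(X[:, j], 0.0))
        Xs.append(_fill_invalid(X))
        labels = t["stage"].to_numpy(dtype=object)
        if scheme.name == "merged3":
            labels = np.array([AASM5_TO_MERGED3.get(l, l) for l in labels], dtype=object)
        ys.append(labels)
    return Xs, ys


def _pad_stack(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length sequences into a (T, B, D) array plus lengths."""
    lengths = np.array([len(s) for s in seqs], dtype=int)
    T = int(lengths.max())
    D = seqs[0].shape[1]
    out = np.zeros((T, len(seqs), D))
    for b, s in enumerate(seqs):
        out[: len(s), b] = s
    return out, lengths


# ---------------------------------------------------------------------------
# prediction container


class PredictionSeries:
    """Per-epoch predicted stages plus per-class scores for one input table."""

    def __init__(self, stages: np.ndarray, scores: np.ndarray, classes: tuple[str, ...]):
        self.stages = np.asarray(stages, dtype=object)
        self.scores = np.asarray(scores, dtype=float)
        self.classes = tuple(classes)
        if self.scores.shape != (len(self.stages), len(self.classes)):
            raise ValueError("scores shape must be (n_epochs, n_classes)")
        if np.any(self.scores < 0) or not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("scores must be non-negative and sum to 1 per epoch")

    def __len__(self) -> int:
        return len(self.stages)

    def to_hypnogram(self) -> Hypnogram:
        scheme = SCHEME_AASM5 if set(self.classes) == set(SCHEME_AASM5.classes) else SCHEME_MERGED3
        return Hypnogram(self.stages, scheme)


# ---------------------------------------------------------------------------
# the estimator


class LSTMSleepStager(BaseEstimator, ClassifierMixin):
    """Whole-night LSTM sequence classifier for sleep staging.

    Parameters mirror :class:`~radarsleep.config.StagingModelConfig`.  After
    ``fit`` the estimator exposes ``classes_``, the feature normalization
    statistics ``norm_mean_`` / ``norm_std_`` (computed on the training
    nights and always applied at prediction time), the trained network
    ``net_`` and a per-epoch training log ``history_``.

    Batching is by whole nights: each optimization step consumes a seeded
    random minibatch of ``batch_size`` night sequences (all nights when the
    cohort is smaller), so training is deterministic for a fixed seed.
    Early stopping monitors loss on a held-out validation subset of nights
    (the last ``val_fraction`` of the training nights) and restores the best
    parameters.
    """

    def __init__(self, hidden_size: int = 64, n_layers: int = 2,
                 bidirectional: bool = False, dropout: float = 0.25,
                 learning_rate: float = 0.01, fine_tune_lr_factor: float = 0.1,
                 max_epochs: int = 120, patience: int = 12,
                 val_fraction: float = 0.2, class_weight: str = "balanced",
                 grad_clip: float = 5.0, scheme: str = "aasm5",
                 batch_size: int | None = 16, random_state: int = 0):
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.fine_tune_lr_factor = fine_tune_lr_factor
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.grad_clip = grad_clip
        self.scheme = scheme
        self.batch_size = batch_size
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _config(self) -> StagingModelConfig:
        cfg = StagingModelConfig(
            hidden_size=self.hidden_size, n_layers=self.n_layers,
            bidirectional=self.bidirectional, dropout=self.dropout,
            learning_rate=self.learning_rate,
            fine_tune_lr_factor=self.fine_tune_lr_factor,
            max_epochs=self.max_epochs, patience=self.patience,
            val_fraction=self.val_fraction, class_weight=self.class_weight,
            grad_clip=self.grad_clip, scheme=self.scheme, seed=self.random_state,
        )
        cfg.validate()
        return cfg

    def _encode_labels(self, ys: list[np.ndarray]) -> list[np.ndarray]:
        lut = {c: i for i, c in enumerate(self.classes_)}
        out = []
        for y in ys:
            bad = set(y) - set(lut)
            if bad:
                raise ValueError(f"labels {sorted(bad)} not in scheme {self.scheme}")
            out.append(np.array([lut[v] for v in y], dtype=int))
        return out

    def _class_weights(self, ys: list[np.ndarray]) -> np.ndarray:
        counts = np.zeros(len(self.classes_))
        for y in ys:
            for i in range(len(self.classes_)):
                counts[i] += np.sum(y == i)
        if self.class_weight == "none":
            w = np.ones_like(counts)
        else:
            w = np.zeros_like(counts)
            present = counts > 0
            w[present] = counts[present].sum() / (present.sum() * counts[present])
            # cap inverse-frequency weights: in a small cohort a rare stage
            # (N1 at a few %) otherwise dominates the loss and the model
            # collapses onto it
            w = np.minimum(w, 5.0)
        if np.any(counts == 0):
            absent = [self.classes_[i] for i in np.flatnonzero(counts == 0)]
            warnings.warn(f"classes absent from training labels get zero weight: {absent}",
                          stacklevel=3)
        return w

    def _normalize(self, seqs: list[np.ndarray]) -> list[np.ndarray]:
        return [(s - self.norm_mean_) / self.norm_std_ for s in seqs]

    def _fit_normalization(self, seqs: list[np.ndarray]) -> None:
        """Robust location/scale per feature: median and IQR/1.349 (the
        Gaussian-equivalent SD).  Detection glitches give interval and power
        features heavy tails; moment-based statistics would let a handful of
        corrupted epochs set the scale and crush the physiological contrast."""
        stacked = np.concatenate(seqs, axis=0)
        self.norm_mean_ = np.nanmedian(stacked, axis=0)
        q75, q25 = np.nanpercentile(stacked, [75, 25], axis=0)
        scale = (q75 - q25) / 1.349
        sd = np.nanstd(stacked, axis=0)
        scale = np.where(scale > 1e-12, scale, sd)
        self.norm_std_ = np.where(scale > 1e-12, scale, 1.0)

    def _optimize(self, train_seqs, train_ys, val_seqs, val_ys, lr: float,
                  max_epochs: int, seed: int) -> pd.DataFrame:
        cw = self._class_weights(train_ys)
        Xtr, len_tr = _pad_stack(self._normalize(train_seqs))
        ytr, _ = _pad_stack([y[:, None] for y in train_ys])
        ytr = ytr[:, :, 0].astype(int)
        if val_seqs:
            Xva, len_va = _pad_stack(self._normalize(val_seqs))
            yva, _ = _pad_stack([y[:, None] for y in val_ys])
            yva = yva[:, :, 0].astype(int)
        rng = np.random.default_rng(seed)
        opt = Adam(self.net_.params(), lr=lr, grad_clip=self.grad_clip)
        best_loss = np.inf
        best_state = self.net_.get_state()
        since_best = 0
        rows = []
        n_seq = Xtr.shape[1]
        bs = n_seq if self.batch_size is None else min(self.batch_size, n_seq)
        for step in range(max_epochs):
            order = rng.permutation(n_seq)
            losses = []
            for i in range(0, n_seq, bs):
                cols = order[i:i + bs]
                loss, grads = self.net_.loss_and_grads(
                    Xtr[:, cols], ytr[:, cols], len_tr[cols], cw, rng)
                opt.step(grads)
                losses.append(loss)
            if val_seqs:
                monitor = self.net_.loss(Xva, yva, len_va, cw)
            else:
                monitor = self.net_.loss(Xtr, ytr, len_tr, cw)
            rows.append({"step": step, "train_loss": float(np.mean(losses)),
                         "val_loss": monitor})
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_state = self.net_.get_state()
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.net_.set_state(best_state)
        self.best_val_loss_ = float(best_loss)
        return pd.DataFrame(rows)

    def _train_val_split(self, seqs, ys):
        n = len(seqs)
        n_val = int(round(self.val_fraction * n))
        n_val = min(max(n_val, 1 if self.val_fraction > 0 and n >= 2 else 0), n - 1)
        if n_val == 0:
            return seqs, ys, [], []
        return seqs[:-n_val], ys[:-n_val], seqs[-n_val:], ys[-n_val:]

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, lengths: Sequence[int] | None = None) -> "LSTMSleepStager":
        """Train from random initialization on whole-night sequences."""
        self._config()
        seqs = _as_sequences(X, lengths)
        ys = _split_like(y, seqs)
        if len(seqs) < 2:
            raise ValueError("training requires at least 2 nights")
        self.classes_ = get_scheme(self.scheme).classes
        self.n_features_in_ = seqs[0].shape[1]
        ys_enc = self._encode_labels(ys)
        tr_s, tr_y, va_s, va_y = self._train_val_split(seqs, ys_enc)
        self._fit_normalization(tr_s)
        self.net_ = SequenceNet(self.n_features_in_, len(self.classes_),
                                hidden=self.hidden_size, n_layers=self.n_layers,
                                bidirectional=self.bidirectional, dropout=self.dropout,
                                seed=self.random_state)
        self.history_ = self._optimize(tr_s, tr_y, va_s, va_y,
                                       lr=self.learning_rate,
                                       max_epochs=self.max_epochs,
                                       seed=self.random_state + 1)
        return self

    def fine_tune(self, X, y, lengths: Sequence[int] | None = None,
                  recompute_normalization: bool = True,
                  random_state: int | None = None) -> "LSTMSleepStager":
        """Continue optimizing all weights on a new domain.

        Uses a fresh optimizer at ``learning_rate * fine_tune_lr_factor``
        and, by default, recomputes the feature normalization statistics on
        the target training nights (the radar features live on different
        scales than the reference features).  With ``max_epochs == 0`` this
        is the identity: the model, including its normalization, is
        untouched.
        """
        self._check_fitted()
        if self.max_epochs == 0:
            return self
        seqs = _as_sequences(X, lengths)
        ys = _split_like(y, seqs)
        if seqs[0].shape[1] != self.n_features_in_:
            raise ValueError("feature schema of the target tables does not match the model")
        ys_enc = self._encode_labels(ys)
        tr_s, tr_y, va_s, va_y = self._train_val_split(seqs, ys_enc)
        if recompute_normalization:
            self._fit_normalization(tr_s)
        seed = self.random_state if random_state is None else random_state
        log = self._optimize(tr_s, tr_y, va_s, va_y,
                             lr=self.learning_rate * self.fine_tune_lr_factor,
                             max_epochs=self.max_epochs, seed=seed + 7)
        log["phase"] = "fine_tune"
        self.history_ = pd.concat([self.history_, log], ignore_index=True)
        return self

    def predict_proba(self, X, lengths: Sequence[int] | None = None) -> np.ndarray:
        self._check_fitted()
        seqs = _as_sequences(X, lengths)
        out = []
        for s in seqs:
            if s.shape[1] != self.n_features_in_:
                raise ValueError("feature count mismatch")
            xn = self._normalize([_fill_invalid(s)])[0]
            probs = self.net_.predict_proba(xn[:, None, :], np.array([len(s)]))
            out.append(probs[:, 0, :])
        return np.concatenate(out, axis=0)

    def predict(self, X, lengths: Sequence[int] | None = None) -> np.ndarray:
        probs = self.predict_proba(X, lengths)
        return np.asarray(self.classes_, dtype=object)[np.argmax(probs, axis=1)]

    def predict_series(self, table: pd.DataFrame) -> PredictionSeries:
        """Predict one night's feature table into a :class:`PredictionSeries`."""
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        Xs, _ = prepare_sequences([table.assign(stage="W")], scheme="aasm5")
        probs = self.predict_proba(Xs[0])
        stages = np.asarray(self.classes_, dtype=object)[np.argmax(probs, axis=1)]
        return PredictionSeries(stages, probs, self.classes_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + config + normalization."""
        self._check_fitted()
        meta = {
            "format_version": 1,
            "params": self.get_params(),
            "classes": list(self.classes_),
            "n_features_in": int(self.n_features_in_),
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.net_.params())}
        buf = _io.BytesIO()
        np.savez(buf, norm_mean=self.norm_mean_, norm_std=self.norm_std_,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "LSTMSleepStager":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(**meta["params"])
            model.classes_ = tuple(meta["classes"])
            model.n_features_in_ = meta["n_features_in"]
            model.norm_mean_ = data["norm_mean"]
            model.norm_std_ = data["norm_std"]
            model.net_ = SequenceNet(model.n_features_in_, len(model.classes_),
                                     hidden=model.hidden_size, n_layers=model.n_layers,
                                     bidirectional=model.bidirectional,
                                     dropout=model.dropout, seed=model.random_state)
            state = [data[f"p{i}"] for i in range(len(model.net_.params()))]
            model.net_.set_state(state)
            model.history_ = pd.DataFrame()
        return model


# ---------------------------------------------------------------------------
# module-level workflow wrappers


def _stager_from_config(config: StagingModelConfig, seed: int) -> LSTMSleepStager:
    config.validate()
    return LSTMSleepStager(
        hidden_size=config.hidden_size, n_layers=config.n_layers,
        bidirectional=config.bidirectional, dropout=config.dropout,
        learning_rate=config.learning_rate,
        fine_tune_lr_factor=config.fine_tune_lr_factor,
        max_epochs=config.max_epochs, patience=config.patience,
        val_fraction=config.val_fraction, class_weight=config.class_weight,
        grad_clip=config.grad_clip, scheme=config.scheme, random_state=seed,
    )


def train(tables: list[pd.DataFrame], config: StagingModelConfig | None = None,
          seed: int = 0) -> LSTMSleepStager:
    """Train a stager from scratch on a list of night feature tables."""
    config = config or StagingModelConfig()
    model = _stager_from_config(config, seed)
    Xs, ys = prepare_sequences(tables, scheme=config.scheme)
    return model.fit(Xs, np.concatenate(ys))


def fine_tune(model: LSTMSleepStager, tables: list[pd.DataFrame],
              random_state: int | None = None,
              recompute_normalization: bool = True) -> LSTMSleepStager:
    """Fine-tune a pretrained stager on target-domain feature tables."""
    Xs, ys = prepare_sequences(tables, scheme=model.scheme)
    return model.fine_tune(Xs, np.concatenate(ys), random_state=random_state,
                           recompute_normalization=recompute_normalization)


def predict(model: LSTMSleepStager, table: pd.DataFrame) -> PredictionSeries:
    """Predict one night's table; wrapper over :meth:`LSTMSleepStager.predict_series`."""
    return model.predict_series(table)
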