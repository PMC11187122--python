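"""Optimisation protocols: DCAE pretraining and patient-specific fits.

Two regimes are implemented with the same machinery:

* ``train_dcae`` — unsupervised reconstruction (MSE) of standardized
  source-corpus windows, 80/20 random holdout, Adam(3e-4), batches of
  2048, up to 2000 epochs with patience 200.

* ``train_predictor`` — supervised interictal/preictal classification,
  binary cross-entropy over *balanced* batches of 64 (32 per class; the
  minority class is oversampled with replacement, one epoch being one
  pass over the majority class), Adam(3e-4), up to 500 epochs with
  patience 50.  In ``standard`` mode the whole network trains from
  scratch; in ``transfer`` mode the encoder comes from a DCAE bundle and
  stays frozen.  Fits are repeated ``n_repeats`` times with distinct
  seeds and metrics are averaged downstream.

Early stopping monitors validation loss and restores the best-epoch
weights.  The paper-scale epoch counts are the defaults; reduced-scale
protocols for desk experiments are built with :func:`scaled`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .annotate import INTERICTAL, PREICTAL
from .models import (
    DCAE,
    DCAEConfig,
    Predictor,
    PredictorConfig,
    WeightBundle,
    build_dcae,
    build_predictor,
    transfer_encoder,
)

__all__ = [
    "TrainProtocol",
    "FitResult",
    "dcae_protocol",
    "predictor_protocol",
    "scaled",
    "train_dcae",
    "train_predictor",
    "train_predictor_repeats",
]


@dataclass
class TrainProtocol:
    mode: str  # {"dcae", "standard", "transfer"}
    batch_size: int
    max_epochs: int
    patience: int
    lr: float = 3e-4
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def dcae_protocol(**overrides) -> TrainProtocol:
    base = dict(mode="dcae", batch_size=2048, max_epochs=2000, patience=200)
    base.update(overrides)
    return TrainProtocol(**base)


def predictor_protocol(mode: str = "standard", **overrides) -> TrainProtocol:
    base = dict(mode=mode, batch_size=64, max_epochs=500, patience=50)
    base.update(overrides)
    return TrainProtocol(**base)


def scaled(proto: TrainProtocol, max_epochs: int, patience: int | None = None, **overrides) -> TrainProtocol:
    """Reduced-scale copy of a protocol (desk experiments, tests)."""
    patience = patience if patience is not None else max(1, max_epochs // 2)
    return dataclasses.replace(
        proto, max_epochs=max_epochs, patience=patience, **overrides
    )


@dataclass
class FitResult:
    weights: WeightBundle  #: full model state at the best validation epoch
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0
    mode: str = ""


class _EarlyStopper:
    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.best_state: dict[str, np.ndarray] | None = None
        self.stale = 0

    def update(self, epoch: int, val_loss: float, model: nn.Layer) -> bool:
        """Record the epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.best_state = model.state_dict()
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def _eval_mse(model: DCAE, X: np.ndarray, batch: int) -> float:
    model.set_training(False)
    total, count = 0.0, 0
    for i in range(0, len(X), batch):
        xb = X[i : i + batch]
        out = model(nn.Tensor(xb))
        total += float(np.mean((out.data - xb) ** 2)) * len(xb)
        count += len(xb)
    return total / count


def train_dcae(
    X: np.ndarray,
    proto: TrainProtocol,
    cfg: DCAEConfig | None = None,
    holdout: float = 0.2,
) -> tuple[DCAE, FitResult]:
    """Fit the autoencoder on standardized windows ``X`` (n, channels, len).

    The 80/20 train/validation split is random across windows.  Returns
    the model (restored to its best validation epoch) and the fit record;
    the transferable encoder is extracted with
    :func:`~ictalert.models.encoder_bundle`.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    cfg = cfg or DCAEConfig(n_channels=X.shape[1], input_len=X.shape[2])
    rng = np.random.default_rng(proto.seed)
    model = build_dcae(cfg, seed=proto.seed)
    for drop in model.sublayers():
        if isinstance(drop, nn.SpatialDropout1D):
            drop.rng = np.random.default_rng(rng.integers(2**31))

    perm = rng.permutation(len(X))
    n_val = max(1, int(round(holdout * len(X))))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("training set too small for the requested holdout")
    Xtr, Xva = X[train_idx], X[val_idx]

    opt = nn.Adam([p for p in model.params()], lr=proto.lr)
    stopper = _EarlyStopper(proto.patience)
    result = FitResult(weights=None, seed=proto.seed, mode="dcae")  # type: ignore[arg-type]
    batch = min(proto.batch_size, len(Xtr))
    for epoch in range(proto.max_epochs):
        model.set_training(True)
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for i in range(0, len(order), batch):
            xb = Xtr[order[i : i + batch]].astype(np.float32)
            opt.zero_grad()
            loss = nn.mse_loss(model(nn.Tensor(xb)), xb)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(xb)
        result.train_loss.append(epoch_loss / len(order))
        val_loss = _eval_mse(model, Xva, batch)
        result.val_loss.append(val_loss)
        result.stopped_epoch = epoch + 1
        if stopper.update(epoch, val_loss, model):
            break
    if stopper.best_state is not None:
        model.load_state_dict(stopper.best_state)
    result.best_epoch = stopper.best_epoch + 1
    result.weights = WeightBundle(
        tensors=model.state_dict(),
        config_hash=cfg.encoder_hash(),
        provenance={"stage": "dcae", "seed": proto.seed},
    )
    return model, result


def _encode_batched(model: Predictor, X: np.ndarray, batch: int = 256) -> np.ndarray:
    """Deterministic eval-mode encoder features for a frozen encoder.

    Caching these once turns every subsequent epoch into BiLSTM+head work
    only, which is what makes long transfer fits cheap.
    """
    model.encoder.set_training(False)
    out = []
    for i in range(0, len(X), batch):
        out.append(model.encoder(nn.Tensor(X[i : i + batch].astype(np.float32))).data)
    return np.concatenate(out, axis=0)


def _eval_ce(forward, X: np.ndarray, y: np.ndarray, batch: int) -> float:
    total = 0.0
    for i in range(0, len(X), batch):
        logits = forward(nn.Tensor(X[i : i + batch].astype(np.float32)))
        total += float(nn.softmax_cross_entropy(logits, y[i : i + batch]).data) * len(
            X[i : i + batch]
        )
    return total / len(X)


def _balanced_batches(
    y: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index batches with equal class counts; one epoch = one pass over the
    majority class, the minority oversampled with replacement."""
    half = batch_size // 2
    idx0 = np.flatnonzero(y == INTERICTAL)
    idx1 = np.flatnonzero(y == PREICTAL)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present in the training selection")
    major, minor = (idx0, idx1) if len(idx0) >= len(idx1) else (idx1, idx0)
    major = rng.permutation(major)
    batches = []
    for i in range(0, len(major) - half + 1, half):
        maj = major[i : i + half]
        mino = rng.choice(minor, size=half, replace=True)
        batches.append(np.concatenate([maj, mino]))
    if not batches:  # fewer majority samples than half a batch
        mino = rng.choice(minor, size=half, replace=True)
        batches = [np.concatenate([major, mino])]
    return batches


def train_predictor(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    proto: TrainProtocol,
    pcfg: PredictorConfig | None = None,
    dcae_bundle: WeightBundle | None = None,
) -> tuple[Predictor, FitResult]:
    """One patient-specific fit in ``standard`` or ``transfer`` mode.

    ``transfer`` mode requires a DCAE encoder bundle; its weights are
    copied in and frozen, so only the BiLSTM and classifier train.
    Inputs must already be standardized with the mode's statistics
    (patient training set for standard, source corpus for transfer).
    """
    if proto.mode not in ("standard", "transfer"):
        raise ValueError(f"unknown predictor mode {proto.mode!r}")
    if proto.mode == "transfer" and dcae_bundle is None:
        raise ValueError("transfer mode requires a DCAE weight bundle")
    classes = np.unique(y_train)
    if not {INTERICTAL, PREICTAL} <= set(classes.tolist()):
        raise ValueError("training selection must contain both classes")
    pcfg = pcfg or PredictorConfig(
        encoder=DCAEConfig(n_channels=X_train.shape[1], input_len=X_train.shape[2])
    )
    rng = np.random.default_rng(proto.seed)
    model = build_predictor(pcfg, seed=proto.seed)
    for drop in model.sublayers():
        if isinstance(drop, nn.SpatialDropout1D):
            drop.rng = np.random.default_rng(rng.integers(2**31))
    if proto.mode == "transfer":
        transfer_encoder(dcae_bundle, model, freeze=True)
        # frozen encoder => features are constant: encode once, then every
        # epoch trains only the BiLSTM and classifier on cached features
        Xtr_feat = _encode_batched(model, X_train)
        Xva_feat = _encode_batched(model, X_val)
        head_forward = lambda x: model.head(model.bilstm(x))  # noqa: E731
        train_inputs, val_inputs, forward = Xtr_feat, Xva_feat, head_forward
    else:
        train_inputs, val_inputs, forward = X_train, X_val, model.forward

    opt = nn.Adam([p for p in model.params() if p.trainable], lr=proto.lr)
    stopper = _EarlyStopper(proto.patience)
    result = FitResult(weights=None, seed=proto.seed, mode=proto.mode)  # type: ignore[arg-type]
    for epoch in range(proto.max_epochs):
        model.set_training(True)
        epoch_loss, n_seen = 0.0, 0
        for batch_idx in _balanced_batches(y_train, proto.batch_size, rng):
            xb = train_inputs[batch_idx].astype(np.float32)
            yb = y_train[batch_idx]
            opt.zero_grad()
            loss = nn.softmax_cross_entropy(forward(nn.Tensor(xb)), yb)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch_idx)
            n_seen += len(batch_idx)
        result.train_loss.append(epoch_loss / n_seen)
        model.set_training(False)
        val_loss = _eval_ce(forward, val_inputs, y_val, proto.batch_size)
        result.val_loss.append(val_loss)
        result.stopped_epoch = epoch + 1
        if stopper.update(epoch, val_loss, model):
            break
    if stopper.best_state is not None:
        model.load_state_dict(stopper.best_state)
    result.best_epoch = stopper.best_epoch + 1
    result.weights = WeightBundle(
        tensors=model.state_dict(),
        config_hash=pcfg.encoder.encoder_hash(),
        provenance={"stage": proto.mode, "seed": proto.seed},
    )
    return model, result


def train_predictor_repeats(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    proto: TrainProtocol,
    pcfg: PredictorConfig | None = None,
    dcae_bundle: WeightBundle | None = None,
) -> list[tuple[Predictor, FitResult]]:
    """``proto.n_repeats`` independent fits with distinct recorded seeds."""
    out = []
    for r in range(proto.n_repeats):
        proto_r = dataclasses.replace(proto, seed=int((proto.seed + 9973 * (r + 1)) % 2**31))
        out.append(
            train_predictor(
                X_train, y_train, X_val, y_val, proto_r, pcfg=pcfg, dcae_bundle=dcae_bundle
            )
        )
    return out
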