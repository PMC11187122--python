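"""Model architectures and weight-transfer mechanics.

Two networks share one encoder architecture:

* the **DCAE** (deep convolutional autoencoder) — six strided Conv1D
  layers (each followed by batch normalisation, a swish activation and
  spatial dropout) that compress a standardized 10-s window, and a
  decoder of three upsampling + three Conv1D layers that restores the
  original shape.  Trained unsupervised (reconstruction MSE) on the
  source corpus.

* the **predictor** — the same encoder, then a bidirectional LSTM over
  the encoder's temporal feature-map sequence, then one dense layer with
  a 2-way softmax (interictal vs preictal).  In transfer mode the encoder
  is initialised from a trained DCAE and frozen: it then acts as a fixed
  feature extractor (inference-mode batch norm, no dropout) and receives
  no gradient.

Transferred weights travel as a :class:`WeightBundle`, a flat name->array
mapping tagged with a hash of the encoder architecture so that loading
into a mismatched configuration fails loudly rather than silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from math import prod
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "DCAEConfig",
    "PredictorConfig",
    "WeightBundle",
    "DCAE",
    "Predictor",
    "build_dcae",
    "build_predictor",
    "transfer_encoder",
    "encoder_bundle",
]


@dataclass(frozen=True)
class DCAEConfig:
    """Autoencoder architecture.

    Defaults give a x64 temporal compression of a 2560-sample window
    (six stride-2 convolutions) restored by three x4 upsampling steps.
    """

    n_channels: int = 19
    input_len: int = 2560
    enc_filters: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    kernel: int = 5
    strides: tuple[int, ...] = (2, 2, 2, 2, 2, 2)
    dec_filters: tuple[int, ...] = (64, 32)  # third decoder conv maps back to n_channels
    upsample_factors: tuple[int, ...] = (4, 4, 4)
    spatial_dropout: float = 0.2

    def __post_init__(self):
        if len(self.enc_filters) != len(self.strides):
            raise ValueError("one stride per encoder layer required")
        if prod(self.strides) != prod(self.upsample_factors):
            raise ValueError(
                "product of encoder strides must equal product of decoder upsample "
                f"factors ({prod(self.strides)} != {prod(self.upsample_factors)})"
            )
        if len(self.dec_filters) + 1 != len(self.upsample_factors):
            raise ValueError("decoder needs one conv per upsampling layer")
        if self.input_len % prod(self.strides) != 0:
            raise ValueError("input_len must be divisible by the total stride")

    @property
    def latent_channels(self) -> int:
        return self.enc_filters[-1]

    @property
    def latent_len(self) -> int:
        return self.input_len // prod(self.strides)

    def encoder_hash(self) -> str:
        payload = {
            "n_channels": self.n_channels,
            "input_len": self.input_len,
            "enc_filters": self.enc_filters,
            "kernel": self.kernel,
            "strides": self.strides,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PredictorConfig:
    encoder: DCAEConfig = field(default_factory=DCAEConfig)
    bilstm_units: int = 64
    encoder_frozen: bool = False


@dataclass
class WeightBundle:
    """Named parameter tensors plus architecture hash and provenance."""

    tensors: dict[str, np.ndarray]
    config_hash: str
    provenance: dict = field(default_factory=dict)

    MAGIC = b"ICTW1\n"

    def save(self, path: str | Path) -> Path:
        """Byte-stable single-file serialisation (header JSON + raw arrays)."""
        path = Path(path)
        names = sorted(self.tensors)
        header = {
            "config_hash": self.config_hash,
            "provenance": self.provenance,
            "arrays": [
                {
                    "name": n,
                    "dtype": str(self.tensors[n].dtype),
                    "shape": list(self.tensors[n].shape),
                }
                for n in names
            ],
        }
        blob = json.dumps(header, sort_keys=True).encode() + b"\n"
        with open(path, "wb") as fh:
            fh.write(self.MAGIC)
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            for n in names:
                fh.write(np.ascontiguousarray(self.tensors[n]).tobytes())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "WeightBundle":
        with open(path, "rb") as fh:
            if fh.read(len(cls.MAGIC)) != cls.MAGIC:
                raise ValueError(f"{path} is not a weight bundle")
            n = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(n))
            tensors = {}
            for meta in header["arrays"]:
                dtype = np.dtype(meta["dtype"])
                count = int(np.prod(meta["shape"])) if meta["shape"] else 1
                arr = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype)
                tensors[meta["name"]] = arr.reshape(meta["shape"]).copy()
        return cls(
            tensors=tensors,
            config_hash=header["config_hash"],
            provenance=header["provenance"],
        )


def _build_encoder(cfg: DCAEConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch = cfg.n_channels
    for i, (out_ch, stride) in enumerate(zip(cfg.enc_filters, cfg.strides)):
        layers.append(nn.Conv1D(in_ch, out_ch, cfg.kernel, stride, name=f"enc{i}.conv", rng=rng))
        layers.append(nn.BatchNorm1D(out_ch, name=f"enc{i}.bn"))
        layers.append(nn.Swish())
        layers.append(nn.SpatialDropout1D(cfg.spatial_dropout, rng=rng))
        in_ch = out_ch
    return nn.Sequential(layers)


class DCAE(nn.Layer):
    def __init__(self, cfg: DCAEConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = _build_encoder(cfg, rng)
        dec: list[nn.Layer] = []
        in_ch = cfg.latent_channels
        out_channels = list(cfg.dec_filters) + [cfg.n_channels]
        for i, (out_ch, factor) in enumerate(zip(out_channels, cfg.upsample_factors)):
            dec.append(nn.UpSample1D(factor))
            dec.append(nn.Conv1D(in_ch, out_ch, cfg.kernel, 1, name=f"dec{i}.conv", rng=rng))
            last = i == len(out_channels) - 1
            if not last:  # final reconstruction layer is linear (standardized target)
                dec.append(nn.BatchNorm1D(out_ch, name=f"dec{i}.bn"))
                dec.append(nn.Swish())
                dec.append(nn.SpatialDropout1D(cfg.spatial_dropout, rng=rng))
            in_ch = out_ch
        self.decoder = nn.Sequential(dec)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.decoder(self.encoder(x))


class Predictor(nn.Layer):
    """Encoder + BiLSTM + softmax classifier for single 10-s windows.

    The BiLSTM runs over the encoder's temporal feature-map steps within
    one window (40 steps under the default x64 compression), so each
    window is classified independently — the firing-power stage is what
    integrates evidence across windows.
    """

    def __init__(self, cfg: PredictorConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = _build_encoder(cfg.encoder, rng)
        self.bilstm = nn.BiLSTM(cfg.encoder.latent_channels, cfg.bilstm_units, rng=rng)
        self.head = nn.Dense(2 * cfg.bilstm_units, 2, name="classifier", rng=rng)
        if cfg.encoder_frozen:
            self._freeze_encoder()

    def _freeze_encoder(self) -> None:
        self.encoder.set_trainable(False)
        self.encoder.set_training(False)  # fixed feature extractor
        self.cfg.encoder_frozen = True

    def set_training(self, mode: bool) -> None:
        super().set_training(mode)
        if self.cfg.encoder_frozen:
            self.encoder.set_training(False)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.head(self.bilstm(self.encoder(x)))

    def predict_proba(self, windows: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities [(interictal, preictal)] for an array of windows."""
        was_training = self.training
        self.set_training(False)
        out = []
        for i in range(0, len(windows), batch_size):
            logits = self.forward(nn.Tensor(windows[i : i + batch_size].astype(np.float32)))
            out.append(nn.softmax(logits.data, axis=1))
        self.set_training(was_training)
        return (
            np.concatenate(out, axis=0) if out else np.empty((0, 2), dtype=np.float32)
        )


def build_dcae(cfg: DCAEConfig, seed: int = 0) -> DCAE:
    return DCAE(cfg, seed=seed)


def build_predictor(cfg: PredictorConfig, seed: int = 0) -> Predictor:
    return Predictor(cfg, seed=seed)


def encoder_bundle(dcae: DCAE, provenance: dict | None = None) -> WeightBundle:
    """Extract the encoder half of a DCAE as a transferable bundle."""
    state = dcae.encoder.state_dict()
    return WeightBundle(
        tensors=state,
        config_hash=dcae.cfg.encoder_hash(),
        provenance=provenance or {},
    )


def transfer_encoder(bundle: WeightBundle, predictor: Predictor, freeze: bool = True) -> Predictor:
    """Copy DCAE encoder weights into a predictor, optionally freezing them.

    Rejects on architecture-hash mismatch and on any tensor shape
    mismatch (listing the offending tensor names); never partially loads.
    """
    expected = predictor.cfg.encoder.encoder_hash()
    if bundle.config_hash != expected:
        raise ValueError(
            f"encoder architecture mismatch: bundle {bundle.config_hash} vs "
            f"predictor {expected}"
        )
    own = predictor.encoder.state_dict()
    bad = [
        name
        for name in own
        if name not in bundle.tensors or bundle.tensors[name].shape != own[name].shape
    ]
    if bad:
        raise ValueError(f"tensor mismatch for: {sorted(bad)}")
    predictor.encoder.load_state_dict({k: bundle.tensors[k] for k in own})
    if freeze:
        predictor._freeze_encoder()
    else:
        predictor.encoder.set_trainable(True)
        predictor.cfg.encoder_frozen = False
    predictor.transfer_provenance = dict(bundle.provenance)
    return predictor
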