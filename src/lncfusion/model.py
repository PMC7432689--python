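"""Multimodal classifier: two dense submodels (OFH, k-mer), one
convolutional submodel (one-hot), descriptor fusion, two-step training.

Training follows the two-step schedule: (1) each submodel is pretrained
independently on its modality with binary cross-entropy; (2) the last
hidden-layer activations (descriptors) are concatenated into a dense
fusion network whose parameters are learned with the submodels frozen,
after which the whole stack is fine-tuned end-to-end at a reduced
learning rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import (FickettLookup, HexamerTable, build_hexamer_table,
                       default_fickett_lookup, feature_table, one_hot_batch)
from .nn import (Adam, BatchNorm, Conv1D, Dense, Dropout, Flatten, MaxPool1D,
                 ReLU, Sequential, bce_with_logits, sigmoid)
from .sequence_io import LabeledDataset, Transcript

logger = logging.getLogger(__name__)

MODALITIES = ("ofh", "kmer", "onehot")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters (CPU-sized defaults)."""

    ofh_hidden: tuple[int, ...] = (64, 32)
    kmer_hidden: tuple[int, ...] = (128, 64)
    cnn_filters: int = 32
    cnn_kernel: int = 10
    cnn_pool: int = 5
    cnn_blocks: int = 2
    cnn_dense: tuple[int, ...] = (64,)
    fusion_hidden: tuple[int, ...] = (64,)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    finetune_lr: float = 1e-4
    batch_size: int = 128
    pretrain_epochs: int = 20
    fusion_epochs: int = 10
    finetune_epochs: int = 10
    seed: int = 0
    maxlen: int = 3000
    k: int = 6
    score_step: int = 1
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self) -> None:
        for widths in (self.ofh_hidden, self.kmer_hidden, self.cnn_dense,
                       self.fusion_hidden):
            if any(w < 1 for w in widths):
                raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0,1)")
        if self.learning_rate <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if min(self.pretrain_epochs, self.fusion_epochs, self.finetune_epochs) < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1 or self.maxlen < 1:
            raise ValueError("batch_size and maxlen must be >= 1")
        bad = set(self.modalities) - set(MODALITIES)
        if bad or not self.modalities:
            raise ValueError(f"modalities must be a non-empty subset of {MODALITIES}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for key in ("ofh_hidden", "kmer_hidden", "cnn_dense", "fusion_hidden",
                    "modalities"):
            d[key] = tuple(d[key])
        return cls(**d)


def fast_config(**overrides) -> ModelConfig:
    """A small configuration for tests and desk-scale benchmarks."""
    base = dict(ofh_hidden=(32, 16), kmer_hidden=(64, 32), cnn_filters=16,
                cnn_kernel=10, cnn_pool=5, cnn_blocks=2, cnn_dense=(32,),
                fusion_hidden=(32,), dropout=0.1, batch_size=64,
                pretrain_epochs=12, fusion_epochs=8, finetune_epochs=4,
                maxlen=500)
    base.update(overrides)
    return ModelConfig(**base)


class FeatureEncoder:
    """Binds the feature tables and normalization fitted on training data.

    Predictions are undefined without the training-time hexamer table and
    OFH standardization, so the encoder travels with the model archive.
    """

    def __init__(self, hexamer_table: HexamerTable,
                 lookup: FickettLookup | None = None,
                 ofh_mean: np.ndarray | None = None,
                 ofh_std: np.ndarray | None = None,
                 k: int = 6, maxlen: int = 3000, score_step: int = 1) -> None:
        self.hexamer_table = hexamer_table
        self.lookup = lookup if lookup is not None else default_fickett_lookup()
        self.ofh_mean = ofh_mean if ofh_mean is not None else np.zeros(4)
        self.ofh_std = ofh_std if ofh_std is not None else np.ones(4)
        self.k = k
        self.maxlen = maxlen
        self.score_step = score_step

    @classmethod
    def fit(cls, data: LabeledDataset, config: ModelConfig,
            pseudocount: float = 1.0) -> "FeatureEncoder":
        """Build the hexamer table from the dataset's coding class and the
        OFH standardization from all training transcripts."""
        lnc, pc = data.class_split()
        if not lnc or not pc:
            raise ValueError("training data must contain both classes")
        table = build_hexamer_table(coding=pc, noncoding=lnc,
                                    pseudocount=pseudocount)
        enc = cls(table, k=config.k, maxlen=config.maxlen,
                  score_step=config.score_step)
        ofh, _ = feature_table(data.transcripts, enc.lookup, table,
                               k=1, score_step=config.score_step)
        enc.ofh_mean = ofh.mean(axis=0)
        enc.ofh_std = np.where(ofh.std(axis=0) > 1e-12, ofh.std(axis=0), 1.0)
        return enc

    def encode(self, transcripts: Sequence[Transcript],
               modalities: Sequence[str]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if "ofh" in modalities or "kmer" in modalities:
            ofh, km = feature_table(transcripts, self.lookup, self.hexamer_table,
                                    k=self.k, score_step=self.score_step)
            if "ofh" in modalities:
                out["ofh"] = (ofh - self.ofh_mean) / self.ofh_std
            if "kmer" in modalities:
                out["kmer"] = km
        if "onehot" in modalities:
            out["onehot"] = one_hot_batch(transcripts, self.maxlen)
        return out


class Submodel:
    """A modality network: feature stack (descriptor output) + sigmoid head."""

    def __init__(self, modality: str, features: Sequential, head: Dense,
                 descriptor_width: int) -> None:
        self.modality = modality
        self.features = features
        self.head = head
        self.descriptor_width = descriptor_width
        self.full = Sequential([features, head])

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.full.forward(x, training=training)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(x, training=False)).reshape(-1)

    def descriptor(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.features.forward(x, training=training)


def _dense_stack(n_in: int, widths: Sequence[int], dropout: float,
                 rng: np.random.Generator) -> Sequential:
    layers = []
    prev = n_in
    for w in widths:
        layers.append(Dense(prev, w, rng))
        layers.append(ReLU())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        prev = w
    return Sequential(layers)


def cnn_output_length(maxlen: int, config: ModelConfig) -> int:
    length = maxlen
    for _ in range(config.cnn_blocks):
        length = length - config.cnn_kernel + 1
        length //= config.cnn_pool
        if length < 1:
            raise ValueError(
                f"maxlen={maxlen} too short for {config.cnn_blocks} conv blocks")
    return length


def build_submodel(modality: str, config: ModelConfig,
                   rng: np.random.Generator | None = None) -> Submodel:
    """Construct an untrained submodel with seeded initialization."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if modality == "ofh":
        stack = _dense_stack(4, config.ofh_hidden, config.dropout, rng)
        width = config.ofh_hidden[-1]
    elif modality == "kmer":
        stack = _dense_stack(4 ** config.k, config.kmer_hidden, config.dropout, rng)
        width = config.kmer_hidden[-1]
    elif modality == "onehot":
        layers: list = []
        c_in = 4
        for _ in range(config.cnn_blocks):
            layers += [Conv1D(c_in, config.cnn_filters, config.cnn_kernel, rng),
                       BatchNorm(config.cnn_filters), ReLU(),
                       MaxPool1D(config.cnn_pool)]
            c_in = config.cnn_filters
        flat = config.cnn_filters * cnn_output_length(config.maxlen, config)
        layers.append(Flatten())
        dense = _dense_stack(flat, config.cnn_dense, config.dropout, rng)
        stack = Sequential(layers + dense.layers)
        width = config.cnn_dense[-1]
    else:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    head = Dense(width, 1, rng)
    return Submodel(modality, stack, head, width)


def _train_epochs(net: Sequential, X: np.ndarray | list[np.ndarray],
                  y: np.ndarray, epochs: int, lr: float, batch_size: int,
                  rng: np.random.Generator,
                  forward_backward=None) -> list[float]:
    """Generic mini-batch Adam loop; returns per-epoch mean loss."""
    n = len(y)
    opt = Adam(net, lr=lr)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            if forward_backward is not None:
                loss = forward_backward(idx)
            else:
                z = net.forward(X[idx], training=True)
                loss, dz = bce_with_logits(z, y[idx])
                net.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def pretrain_submodels(data: LabeledDataset, config: ModelConfig,
                       encoder: FeatureEncoder | None = None,
                       ) -> tuple[dict[str, Submodel], FeatureEncoder]:
    """Step one: train each modality submodel independently."""
    y = data.labels.astype(np.float64)
    if len(np.unique(data.labels)) < 2:
        raise ValueError("training data must contain both classes")
    if encoder is None:
        encoder = FeatureEncoder.fit(data, config)
    X = encoder.encode(data.transcripts, config.modalities)
    submodels: dict[str, Submodel] = {}
    for i, modality in enumerate(config.modalities):
        rng = np.random.default_rng(config.seed + 1000 * i)
        sub = build_submodel(modality, config, rng)
        history = _train_epochs(sub.full, X[modality], y, config.pretrain_epochs,
                                config.learning_rate, config.batch_size, rng)
        for epoch, loss in enumerate(history, 1):
            logger.info("pretrain[%s] epoch %d loss %.5f", modality, epoch, loss)
        sub.history = history  # type: ignore[attr-defined]
        submodels[modality] = sub
    return submodels, encoder


@dataclass
class Prediction:
    id: str
    p_lnc: float
    label: int
    threshold: float = 0.5
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok" and not (0.0 <= self.p_lnc <= 1.0):
            raise ValueError(f"p_lnc outside [0,1]: {self.p_lnc}")


class TrainedModel:
    """A fused multimodal classifier plus the feature state it was trained
    with (hexamer table, Fickett lookup, OFH standardization)."""

    def __init__(self, config: ModelConfig, encoder: FeatureEncoder,
                 submodels: dict[str, Submodel], fusion: Sequential,
                 head: Dense) -> None:
        self.config = config
        self.encoder = encoder
        self.submodels = submodels
        self.fusion = fusion
        self.head = head
        self.architecture = "+".join(config.modalities)

    # -- inference ---------------------------------------------------------

    def _forward(self, X: dict[str, np.ndarray], training: bool = False,
                 submodel_training: bool = False) -> np.ndarray:
        desc = [self.submodels[m].descriptor(X[m], training=submodel_training)
                for m in self.config.modalities]
        fused = self.fusion.forward(np.concatenate(desc, axis=1),
                                    training=training)
        return self.head.forward(fused, training=training)

    def predict_proba(self, transcripts: Sequence[Transcript]) -> np.ndarray:
        X = self.encoder.encode(transcripts, self.config.modalities)
        return sigmoid(self._forward(X)).reshape(-1)

    def predict(self, transcripts: Sequence[Transcript],
                threshold: float = 0.5) -> list[Prediction]:
        ok = [t for t in transcripts if len(t) >= 6]
        proba = iter(self.predict_proba(ok)) if ok else iter(())
        preds = []
        for t in transcripts:
            if len(t) >= 6:
                p = float(next(proba))
                preds.append(Prediction(t.id, p, int(p >= threshold), threshold))
            else:
                preds.append(Prediction(t.id, float("nan"), -1, threshold,
                                        status="too_short"))
        return preds

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {
            "hexamer_f_coding": self.encoder.hexamer_table.f_coding,
            "hexamer_f_noncoding": self.encoder.hexamer_table.f_noncoding,
            "ofh_mean": self.encoder.ofh_mean,
            "ofh_std": self.encoder.ofh_std,
        }
        for m, sub in self.submodels.items():
            for name, arr in sub.full.state_arrays().items():
                arrays[f"sub_{m}/{name}"] = arr
        for name, arr in self.fusion.state_arrays().items():
            arrays[f"fusion/{name}"] = arr
        for key, arr in self.head.params.items():
            arrays[f"head/{key}"] = arr
        np.savez_compressed(path, config=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            config = ModelConfig.from_json(bytes(data["config"]).decode())
            table = HexamerTable(data["hexamer_f_coding"],
                                 data["hexamer_f_noncoding"])
            encoder = FeatureEncoder(table, ofh_mean=data["ofh_mean"],
                                     ofh_std=data["ofh_std"], k=config.k,
                                     maxlen=config.maxlen,
                                     score_step=config.score_step)
            rng = np.random.default_rng(config.seed)
            submodels = {m: build_submodel(m, config, rng)
                         for m in config.modalities}
            fusion, head = _build_fusion(submodels, config, rng)
            for m, sub in submodels.items():
                state = {name: data[f"sub_{m}/{name}"]
                         for name in sub.full.state_arrays()}
                sub.full.load_state_arrays(state)
            fusion.load_state_arrays(
                {name: data[f"fusion/{name}"] for name in fusion.state_arrays()})
            for key in head.params:
                head.params[key] = np.array(data[f"head/{key}"])
        return cls(config, encoder, submodels, fusion, head)


def _build_fusion(submodels: dict[str, Submodel], config: ModelConfig,
                  rng: np.random.Generator) -> tuple[Sequential, Dense]:
    width = sum(submodels[m].descriptor_width for m in config.modalities)
    fusion = _dense_stack(width, config.fusion_hidden, config.dropout, rng)
    head = Dense(config.fusion_hidden[-1], 1, rng)
    return fusion, head


def fuse_and_finetune(submodels: dict[str, Submodel], data: LabeledDataset,
                      config: ModelConfig,
                      encoder: FeatureEncoder) -> TrainedModel:
    """Step two: train the fusion network on frozen descriptors, then
    fine-tune everything end-to-end at the reduced learning rate."""
    missing = set(config.modalities) - set(submodels)
    if missing:
        raise ValueError(f"missing pretrained submodels for {sorted(missing)}")
    for m in config.modalities:
        expected = {"ofh": config.ofh_hidden[-1], "kmer": config.kmer_hidden[-1],
                    "onehot": config.cnn_dense[-1]}[m]
        if submodels[m].descriptor_width != expected:
            raise ValueError(
                f"descriptor width mismatch for {m}: model "
                f"{submodels[m].descriptor_width} vs config {expected}")

    rng = np.random.default_rng(config.seed + 777)
    fusion, head = _build_fusion(submodels, config, rng)
    y = data.labels.astype(np.float64)
    X = encoder.encode(data.transcripts, config.modalities)
    model = TrainedModel(config, encoder, submodels, fusion, head)

    feature_stacks = [submodels[m].features for m in config.modalities]
    widths = [submodels[m].descriptor_width for m in config.modalities]

    def make_step(finetune: bool):
        def step(idx: np.ndarray) -> float:
            desc = [stack.forward(X[m][idx], training=finetune)
                    for m, stack in zip(config.modalities, feature_stacks)]
            fused = fusion.forward(np.concatenate(desc, axis=1), training=True)
            z = head.forward(fused, training=True)
            loss, dz = bce_with_logits(z, y[idx])
            dcat = fusion.backward(head.backward(dz))
            if finetune:
                lo = 0
                for w, stack in zip(widths, feature_stacks):
                    stack.backward(dcat[:, lo:lo + w])
                    lo += w
            return loss
        return step

    # phase 1: fusion parameters only, submodels frozen (inference mode)
    for stack in feature_stacks:
        stack.set_trainable(False)
    phase1_net = Sequential([fusion, head])
    hist1 = _train_epochs(phase1_net, None, y, config.fusion_epochs,
                          config.learning_rate, config.batch_size, rng,
                          forward_backward=make_step(finetune=False))
    for epoch, loss in enumerate(hist1, 1):
        logger.info("fusion epoch %d loss %.5f", epoch, loss)

    # phase 2: unfreeze and fine-tune end-to-end
    for stack in feature_stacks:
        stack.set_trainable(True)
    whole_net = Sequential(feature_stacks + [fusion, head])
    hist2 = _train_epochs(whole_net, None, y, config.finetune_epochs,
                          config.finetune_lr, config.batch_size, rng,
                          forward_backward=make_step(finetune=True))
    for epoch, loss in enumerate(hist2, 1):
        logger.info("finetune epoch %d loss %.5f", epoch, loss)

    model.history = {"fusion": hist1, "finetune": hist2}  # type: ignore[attr-defined]
    return model


def train_model(data: LabeledDataset, config: ModelConfig) -> TrainedModel:
    """Full two-step schedule: pretrain the submodels, then fuse/fine-tune."""
    submodels, encoder = pretrain_submodels(data, config)
    return fuse_and_finetune(submodels, data, config, encoder)


def decision_fusion_vote(submodels: dict[str, Submodel],
                         encoder: FeatureEncoder,
                         transcripts: Sequence[Transcript],
                         threshold: float = 0.5) -> list[Prediction]:
    """Majority vote of the three submodels' thresholded labels; the
    reported probability is the mean of the three probabilities."""
    if set(submodels) != set(MODALITIES):
        raise ValueError(f"voting requires all three submodels {MODALITIES}")
    X = encoder.encode(transcripts, MODALITIES)
    probas = np.stack([submodels[m].predict_proba(X[m]) for m in MODALITIES])
    votes = (probas >= threshold).sum(axis=0)
    mean_p = probas.mean(axis=0)
    return [Prediction(t.id, float(p), int(v >= 2), threshold)
            for t, p, v in zip(transcripts, mean_p, votes)]
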