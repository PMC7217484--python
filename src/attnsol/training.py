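"""Training loop: binary cross-entropy + Adam on the attention model.

The optimization recipe follows the reference setup: Adam, initial
learning rate 0.01 held constant, L2 regularization 1e-6, 50 epochs,
batch size 1001.  Binary cross-entropy on the sigmoid output is the
canonical loss for a binary label and a probability-like score.
Training is deterministic given the model seed (initialization) and the
training seed (per-epoch shuffling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .model import ModelConfig, ModelParams, _forward_batch, build_model
from .sequence_io import DEFAULT_VOCABULARY, ProteinRecord, Vocabulary, encode_batch

__all__ = ["TrainConfig", "train", "evaluate_epoch"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 1001
    epochs: int = 50
    l2: float = 1e-6
    seed: int = 0
    loss: str = "bce"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be nonnegative")
        if self.loss != "bce":
            raise ValueError(f"unsupported loss {self.loss!r}")


def _check_labelled(records: list[ProteinRecord]) -> np.ndarray:
    labels = []
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabelled")
        labels.append(rec.label)
    y = np.asarray(labels, dtype=np.float64)
    if len(records) == 0:
        raise ValueError("no records")
    if y.min() == y.max():
        raise ValueError("training data contains a single class; need both labels")
    return y


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # softplus(logit) - y*logit is the numerically stable BCE
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def _backward_batch(
    params: ModelParams, caches: dict, dlogits: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss wrt every weight, given d(loss)/d(logit)."""
    cfg = params.config
    mask = caches["mask"]
    tokens = caches["tokens"]
    a, p, sP = caches["a"], caches["p"], caches["sP"]
    grads = {k: np.zeros_like(v) for k, v in params.weights.items()}

    dhs = []
    for subnet in ("P", "A"):
        if subnet == "P":
            dp = dlogits[:, None] * a
            ds = dp * np.where(sP > 0, 1.0, cfg.leaky_slope) * mask
        else:
            da = dlogits[:, None] * p
            # softmax backward; a is zero at padding so ds vanishes there
            ds = a * (da - (da * a).sum(axis=1, keepdims=True))

        h_top = caches[f"{subnet}.h_top"]
        B, T, D = h_top.shape
        ds_flat = ds.reshape(B * T)
        grads[f"{subnet}.linear.w"] = ds_flat @ h_top.reshape(B * T, D)
        grads[f"{subnet}.linear.b"] = np.asarray(ds_flat.sum())
        dhs.append(ds[:, :, None] * params.weights[f"{subnet}.linear.w"])

    for layer in range(cfg.num_layers - 1, -1, -1):
        dhs, per_rec = _nn.bigru_layer_backward(dhs, caches[f"l{layer}"])
        names = [
            f"{subnet}.l{layer}.{direction}"
            for subnet in ("P", "A")
            for direction in ("fwd", "bwd")
        ]
        for name, g in zip(names, per_rec):
            for k, v in g.items():
                grads[f"{name}.{k}"] = v
    dEmb_in = dhs[0] + dhs[1]

    E = params.weights["embedding"].shape[1]
    np.add.at(
        grads["embedding"],
        tokens.reshape(-1),
        (dEmb_in * mask[:, :, None]).reshape(-1, E),
    )
    return grads


def train(
    records: list[ProteinRecord],
    mconfig: ModelConfig | None = None,
    tconfig: TrainConfig | None = None,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
) -> tuple[ModelParams, list[float]]:
    """Train from scratch on labelled records; returns (params, per-epoch mean loss)."""
    mconfig = mconfig or ModelConfig()
    tconfig = tconfig or TrainConfig()
    y_all = _check_labelled(records)
    params = build_model(mconfig)
    # optimization runs in single precision (ample for SGD noise levels);
    # the returned parameters are float64 so inference identities hold tightly
    params.weights = {k: v.astype(np.float32) for k, v in params.weights.items()}
    opt = _nn.Adam(params.weights, lr=tconfig.learning_rate, weight_decay=tconfig.l2)
    rng = np.random.default_rng(tconfig.seed)
    n = len(records)

    history: list[float] = []
    order = np.arange(n)
    for _epoch in range(tconfig.epochs):
        epoch_loss = 0.0
        # fresh batch composition every epoch: stale, repeating minibatches
        # reduce gradient diversity and stall convergence
        rng.shuffle(order)
        for start in range(0, n, tconfig.batch_size):
            idx = order[start : start + tconfig.batch_size]
            batch = encode_batch([records[i] for i in idx], vocab)
            y = y_all[idx][batch.permutation]
            caches = _forward_batch(params, batch, want_cache=True)
            logits = caches["logits"]
            loss = _bce_from_logits(logits, y)
            dlogits = ((caches["scores"] - y) / idx.size).astype(caches["scores"].dtype)
            grads = _backward_batch(params, caches, dlogits)
            opt.step(params.weights, grads)
            epoch_loss += loss * idx.size
        history.append(epoch_loss / n)
    params.weights = {k: v.astype(np.float64) for k, v in params.weights.items()}
    return params, history


def evaluate_epoch(
    params: ModelParams,
    records: list[ProteinRecord],
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    batch_size: int = 256,
) -> float:
    """Mean per-sequence binary cross-entropy; no parameter update."""
    y_all = _check_labelled_loose(records)
    total = 0.0
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        batch = encode_batch(chunk, vocab)
        y = y_all[start : start + batch_size][batch.permutation]
        caches = _forward_batch(params, batch, want_cache=False)
        total += _bce_from_logits(caches["logits"], y) * len(chunk)
    return total / len(records)


def _check_labelled_loose(records: list[ProteinRecord]) -> np.ndarray:
    """Like _check_labelled but permits a single class (evaluation only)."""
    labels = []
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabelled")
        labels.append(rec.label)
    if not labels:
        raise ValueError("no records")
    return np.asarray(labels, dtype=np.float64)
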