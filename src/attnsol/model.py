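"""The attention-based solubility architecture.

Two subnetworks share a trainable residue embedding.  The predictor
subnetwork P assigns each residue a real-valued solubility contribution
p_i (LeakyReLU output); the attention subnetwork A assigns nonnegative
weights a_i that sum to one over the real residues (sequence-wide
SoftMax).  The sequence score is

    score = sigmoid( sum_i a_i * p_i )

so the elementwise products a_i * p_i form a per-residue *solubility
profile*: positive entries push the protein towards the soluble class,
negative entries towards the insoluble one.

Each subnetwork is a 2-layer bidirectional GRU with 20 hidden units per
direction; at every position the 40-dim concatenation of the two
directions is mapped to a scalar by an affine layer.  With the shared
21x20 embedding (20 amino acids + one PAD/unknown row) the default
architecture has exactly 25,462 trainable scalars.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .sequence_io import DEFAULT_VOCABULARY, EncodedBatch, ProteinRecord, Vocabulary, encode_batch

__all__ = [
    "ModelConfig",
    "ModelParams",
    "SolubilityOutput",
    "build_model",
    "count_parameters",
    "forward",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_SUBNETS = ("P", "A")
_DIRS = ("fwd", "bwd")
_GRU_KEYS = ("W_ih", "W_hh", "b_ih", "b_hh")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; the defaults are the reference architecture."""

    vocab_size: int = 21
    embed_dim: int = 20
    hidden_dim: int = 20
    num_layers: int = 2
    bidirectional: bool = True
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vocab_size", "embed_dim", "hidden_dim", "num_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ModelParams:
    """Trainable weights: shared embedding + two recurrent subnetworks.

    ``weights`` maps flat names (e.g. ``"P.l0.fwd.W_ih"``) to numpy arrays;
    the dict is the unit the optimizer and the serializer operate on.
    """

    def __init__(self, config: ModelConfig, weights: dict[str, np.ndarray]):
        self.config = config
        self.weights = weights

    def subnet_layer(self, subnet: str, layer: int, direction: str) -> dict[str, np.ndarray]:
        prefix = f"{subnet}.l{layer}.{direction}."
        return {k: self.weights[prefix + k] for k in _GRU_KEYS}

    def copy(self) -> "ModelParams":
        return ModelParams(self.config, {k: v.copy() for k, v in self.weights.items()})


@dataclass
class SolubilityOutput:
    """Per-sequence model output.

    score is in (0,1); attention sums to 1 over the sequence; profile[i]
    = attention[i] * prediction[i] and score = sigmoid(sum(profile)).
    """

    id: str
    score: float
    attention: np.ndarray
    prediction: np.ndarray

    @property
    def profile(self) -> np.ndarray:
        return self.attention * self.prediction


def build_model(config: ModelConfig | None = None) -> ModelParams:
    """Initialize all trainable weights from the config seed.

    Recurrent layers use Glorot-uniform input kernels, orthogonal
    recurrent kernels and zero biases; the affine heads are Glorot with
    zero bias; the shared embedding (including the trainable
    PAD/unknown row) is Uniform(-0.05, 0.05).  These are the standard
    recurrent-network defaults, which keep gate pre-activations in the
    unsaturated regime at the 0.01 learning rate used for training.
    """
    config = config or ModelConfig()
    if not config.bidirectional:
        raise ValueError("only the bidirectional architecture is supported")
    rng = np.random.default_rng(config.seed)
    w: dict[str, np.ndarray] = {
        "embedding": rng.uniform(-0.05, 0.05, size=(config.vocab_size, config.embed_dim))
    }
    ndir = 2
    for subnet in _SUBNETS:
        for layer in range(config.num_layers):
            in_dim = config.embed_dim if layer == 0 else ndir * config.hidden_dim
            for direction in _DIRS:
                gp = _nn.init_gru_params(rng, in_dim, config.hidden_dim)
                for k, v in gp.items():
                    w[f"{subnet}.l{layer}.{direction}.{k}"] = v
        w[f"{subnet}.linear.w"] = _nn.glorot_uniform(rng, (1, ndir * config.hidden_dim))[0]
        w[f"{subnet}.linear.b"] = np.zeros(())
    return ModelParams(config, w)


def count_parameters(params: ModelParams) -> int:
    """Exact number of trainable scalars."""
    return int(sum(v.size for v in params.weights.values()))


def _masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax over unmasked positions only; zeros elsewhere."""
    neg = np.where(mask > 0, logits, -np.inf)
    m = neg.max(axis=1, keepdims=True)
    e = np.exp(neg - m)
    e = np.where(mask > 0, e, 0.0)
    return e / e.sum(axis=1, keepdims=True)


def _forward_batch(params: ModelParams, batch: EncodedBatch, want_cache: bool = False):
    """Shared forward over a sorted batch; returns per-row arrays (batch order).

    Returns dict with scores (B,), attention (B,T), prediction (B,T),
    logits (B,), and — when ``want_cache`` — everything backprop needs.
    """
    cfg = params.config
    if batch.token_matrix.max() >= cfg.vocab_size:
        raise ValueError("token index out of vocabulary")
    X = params.weights["embedding"][batch.token_matrix]  # (B, T, E)
    mask = batch.mask.astype(X.dtype, copy=False)
    lengths = batch.lengths
    caches: dict = {"tokens": batch.token_matrix, "mask": mask, "lengths": lengths}

    # both subnetworks advance together: one fused call per layer
    hs = [X, X]  # P, A
    for layer in range(cfg.num_layers):
        pdicts = [
            params.subnet_layer(subnet, layer, direction)
            for subnet in _SUBNETS
            for direction in _DIRS
        ]
        hs, c = _nn.bigru_layer_forward(hs, lengths, mask, pdicts, want_cache)
        caches[f"l{layer}"] = c

    scalars = {}
    for subnet, h in zip(_SUBNETS, hs):
        w_lin = params.weights[f"{subnet}.linear.w"]
        s = h @ w_lin + params.weights[f"{subnet}.linear.b"]  # (B, T)
        caches[f"{subnet}.h_top"] = h if want_cache else None
        scalars[subnet] = s

    sP = scalars["P"]
    p = np.where(sP > 0, sP, cfg.leaky_slope * sP) * mask
    a = _masked_softmax(scalars["A"], mask)
    logits = (a * p).sum(axis=1)
    scores = _nn.sigmoid(logits)
    caches.update({"sP": sP, "p": p, "a": a, "logits": logits, "scores": scores})
    return caches


def forward(params: ModelParams, batch: EncodedBatch) -> list[SolubilityOutput]:
    """Score an encoded batch; outputs restored to the batch's input order."""
    res = _forward_batch(params, batch, want_cache=False)
    outputs: list[SolubilityOutput | None] = [None] * batch.batch_size
    for row in range(batch.batch_size):
        n = int(batch.lengths[row])
        outputs[batch.permutation[row]] = SolubilityOutput(
            id=batch.ids[row],
            score=float(res["scores"][row]),
            attention=res["a"][row, :n].copy(),
            prediction=res["p"][row, :n].copy(),
        )
    return outputs  # type: ignore[return-value]


def predict(
    params: ModelParams,
    records: list[ProteinRecord],
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    batch_size: int = 256,
) -> list[SolubilityOutput]:
    """Batched convenience wrapper over :func:`forward` (input order preserved).

    Results are independent of the batch partitioning.
    """
    outputs: list[SolubilityOutput] = []
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        outputs.extend(forward(params, encode_batch(chunk, vocab)))
    return outputs


def save_checkpoint(
    params: ModelParams, path: str | Path, vocab: Vocabulary = DEFAULT_VOCABULARY
) -> None:
    """Serialize config + weights + vocabulary to one ``.npz`` file."""
    meta = json.dumps({"config": asdict(params.config), "vocab": vocab.tokens})
    np.savez(path, __meta__=np.array(meta), **params.weights)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, Vocabulary]:
    with np.load(path) as data:
        meta = json.loads(str(data["__meta__"]))
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    return ModelParams(ModelConfig(**meta["config"]), weights), Vocabulary(meta["vocab"])
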