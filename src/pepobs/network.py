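"""Dense feed-forward rank-regression network.

The predictor is a fully connected network of five hidden layers with 128
rectifier (ReLU) units each and a single linear output, trained with plain
stochastic gradient descent (learning rate 0.001, minibatch size 3, 10
epochs) on the squared error between predicted observability and the
protein-normalized peptide intensity. Overfitting is damped by dropout at
probability 0.2 on hidden-unit outputs, applied at training time only with
inverted scaling (activations divided by 1-p), so prediction needs no
rescaling.

The implementation is plain numpy with explicit backpropagation — the
network is small enough that this is both fast and fully reproducible from
a single integer seed (weight initialization, per-epoch shuffling and
dropout masks all derive from it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .digestion import PeptideRecord, proteotypic_peptides
from .features import FeatureRegistry, Standardizer
from .proteins import ProteinRecord

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The defaults are the reference configuration: 5 dense hidden layers of
    128 ReLU nodes, dropout 0.2, SGD at learning rate 0.001, minibatch 3,
    10 epochs.
    """

    hidden_layers: int = 5
    nodes_per_layer: int = 128
    dropout_p: float = 0.2
    learning_rate: float = 0.001
    minibatch_size: int = 3
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.nodes_per_layer < 1:
            raise ValueError("need at least one hidden layer and one node")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedModel:
    """Layer weights/biases plus everything needed to reuse them.

    ``weights[l]`` has shape (fan_in, fan_out); hidden activations are
    rectifiers, the output unit is linear. The registry and standardizer
    pin the feature space the weights live in.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: ModelConfig
    registry: FeatureRegistry
    standardizer: Optional[Standardizer] = None
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


def build_network(config: ModelConfig, n_features: int,
                  registry: Optional[FeatureRegistry] = None) -> TrainedModel:
    """Initialize a network with Glorot-uniform weights, seeded.

    Weights are drawn uniformly from ±sqrt(6 / (fan_in + fan_out)); biases
    start at zero. The same seed yields bit-identical initial weights.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    sizes = ([n_features]
             + [config.nodes_per_layer] * config.hidden_layers
             + [1])
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedModel(
        weights=weights,
        biases=biases,
        config=config,
        registry=registry if registry is not None else FeatureRegistry(),
    )


def _forward(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    a = X
    last = len(model.weights) - 1
    for l, (W, b) in enumerate(zip(model.weights, model.biases)):
        a = a @ W + b
        if l < last:
            a = np.maximum(a, 0.0)
    return a[:, 0]


def train(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[ModelConfig] = None,
) -> TrainedModel:
    """Train in place with SGD on the mean squared error; returns the model.

    ``X`` must already be standardized with the model's stored parameters.
    Examples are reshuffled every epoch with the run seed; the last short
    minibatch is used as-is. The loss trace records the mean minibatch loss
    per epoch. A non-finite loss aborts with a diagnostic.
    """
    cfg = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of examples")
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {X.shape[1]}")

    rng = np.random.default_rng([cfg.seed, 0x5eed])
    n = X.shape[0]
    bs = cfg.minibatch_size
    lr = cfg.learning_rate
    p = cfg.dropout_p
    keep = 1.0 - p
    W, B = model.weights, model.biases
    n_layers = len(W)
    model.loss_trace = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = X[idx], y[idx]
            m = xb.shape[0]

            # forward, caching pre-dropout inputs per layer
            acts = [xb]
            masks = []
            a = xb
            for l in range(n_layers - 1):
                z = a @ W[l] + B[l]
                h = np.maximum(z, 0.0)
                if p > 0.0:
                    mask = rng.random(h.shape) < keep
                    h = h * mask / keep
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
                a = h
            out = (a @ W[-1] + B[-1])[:, 0]
            resid = out - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // bs}: "
                    f"{loss!r}; try a smaller learning rate")
            epoch_losses.append(loss)

            # backward
            delta = (2.0 / m) * resid[:, None]          # dL/d(out)
            grad_w = acts[-1].T @ delta
            grad_b = delta.sum(axis=0)
            delta = delta @ W[-1].T
            W[-1] -= lr * grad_w
            B[-1] -= lr * grad_b
            for l in range(n_layers - 2, -1, -1):
                h = acts[l + 1]
                if masks[l] is not None:
                    delta = delta * masks[l] / keep
                delta = delta * (h > 0.0)
                grad_w = acts[l].T @ delta
                grad_b = delta.sum(axis=0)
                if l > 0:
                    delta = delta @ W[l].T
                W[l] -= lr * grad_w
                B[l] -= lr * grad_b
        model.loss_trace.append(float(np.mean(epoch_losses)))
    return model


def predict(model: TrainedModel, X: np.ndarray,
            registry_version: Optional[str] = None) -> np.ndarray:
    """Deterministic forward pass (dropout disabled); one score per row.

    When ``registry_version`` is given it must match the registry the model
    was trained with.
    """
    if registry_version is not None and registry_version != model.registry.version:
        raise ValueError(
            f"feature registry mismatch: model has "
            f"{model.registry.version!r}, vectors have {registry_version!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {X.shape[1]}")
    return _forward(model, X)


@dataclass
class RankedPeptide:
    peptide: PeptideRecord
    raw_score: float
    normalized_score: float


@dataclass
class RankResult:
    """Ranked proteotypic peptides of one protein, top score 1.0.

    ``normalized`` is False when the maximum raw score was not positive, in
    which case raw scores are emitted unscaled and the flag tells the
    consumer that max-normalization was skipped.
    """

    protein_id: str
    entries: list[RankedPeptide]
    normalized: bool = True


def rank_protein(
    model: TrainedModel,
    protein: ProteinRecord,
    database: Sequence[ProteinRecord],
    min_length: int = 6,
    max_length: int = 30,
    parent_map: Optional[dict] = None,
) -> RankResult:
    """Digest, filter to proteotypic candidates, score, and rank one protein.

    Scores are divided by the maximum score so the top peptide reads 1.0;
    ties are broken lexicographically by peptide sequence. Callers ranking
    many proteins should precompute ``tryptic_parent_map(database)`` once.
    """
    candidates = proteotypic_peptides(protein, database,
                                      min_length=min_length,
                                      max_length=max_length,
                                      parent_map=parent_map)
    if not candidates:
        return RankResult(protein_id=protein.id, entries=[], normalized=False)
    X = np.array([model.registry.featurize(p, protein) for p in candidates])
    if model.standardizer is not None:
        X = model.standardizer.apply(X)
    scores = predict(model, X)
    top = float(scores.max())
    normalized = top > 0
    order = sorted(range(len(candidates)),
                   key=lambda i: (-scores[i], candidates[i].sequence))
    entries = [
        RankedPeptide(
            peptide=candidates[i],
            raw_score=float(scores[i]),
            normalized_score=float(scores[i] / top) if normalized
            else float(scores[i]),
        )
        for i in order
    ]
    return RankResult(protein_id=protein.id, entries=entries,
                      normalized=normalized)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Write the model as one JSON document; float64 values round-trip exactly."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(model.config),
        "registry": model.registry.to_dict(),
        "standardizer": (model.standardizer.to_dict()
                         if model.standardizer else None),
        "loss_trace": model.loss_trace,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: Union[str, Path]) -> TrainedModel:
    """Load a model saved by :func:`save_model`; round trip is bit-exact."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a pepobs model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload['format_version']!r}")
    model = TrainedModel(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        config=ModelConfig(**payload["config"]),
        registry=FeatureRegistry.from_dict(payload["registry"]),
        standardizer=(Standardizer.from_dict(payload["standardizer"])
                      if payload.get("standardizer") else None),
        loss_trace=list(payload.get("loss_trace", [])),
    )
    return model
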