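"""Feature importance from first-hidden-layer activation potentials.

After training, the contribution of each input feature can be read off the
first hidden layer. For feature i of (standardized) example k and neuron j
the activation potential is

    a_ijk = w_ji * x_ik + b_j

its magnitude averaged over M examples is

    p_ij = (1/M) Σ_k |a_ijk|

the relative contribution of feature i at neuron j normalizes by the
neuron's total average potential

    c_ij = p_ij / Σ_{i=1..N} p_ij

and summing the rectified contributions over all H first-layer neurons
gives the net positive contribution of the feature

    c_i+ = Σ_{j=1..H} max(0, c_ij).

The default ("averaged") mode uses the example-averaged magnitude p_ij in
the numerator, which makes c_ij example-free. A "strict" mode instead forms
per-example contributions c_ijk = a_ijk / Σ_i p_ij and averages them over
examples, with the rectifier applied either before or after that average
(``rectify="before_mean"`` / ``"after_mean"``). Both reduce to the same
numbers on a single-example set with non-negative potentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .network import TrainedModel

_CHUNK = 256


@dataclass
class FeatureImportance:
    feature: str
    index: int
    c_plus: float


@dataclass
class ImportanceReport:
    """Net positive contribution per feature, with intermediates.

    ``entries`` are sorted descending by c_i+ for presentation; ``index``
    retains each feature's original registry position. ``p`` is the (N, H)
    matrix of average activation-potential magnitudes.
    """

    entries: list[FeatureImportance]
    p: np.ndarray
    n_examples: int
    n_neurons: int
    n_features: int
    mode: str
    degenerate: bool = False

    def c_plus_by_index(self) -> np.ndarray:
        out = np.empty(self.n_features)
        for e in self.entries:
            out[e.index] = e.c_plus
        return out

    def top(self, n: int) -> list[FeatureImportance]:
        return self.entries[:n]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": range(1, len(self.entries) + 1),
                "feature_name": [e.feature for e in self.entries],
                "c_i_plus": [e.c_plus for e in self.entries],
                "mode": self.mode,
            }
        )


def activation_potential(model: TrainedModel, X: np.ndarray,
                         example: int, feature: int, neuron: int) -> float:
    """a_ijk = w_ji x_ik + b_j for one (example, feature, neuron) triple."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W, b = model.weights[0], model.biases[0]
    if not (0 <= example < X.shape[0]):
        raise IndexError(f"example index {example} out of range")
    if not (0 <= feature < W.shape[0]):
        raise IndexError(f"feature index {feature} out of range")
    if not (0 <= neuron < W.shape[1]):
        raise IndexError(f"neuron index {neuron} out of range")
    return float(W[feature, neuron] * X[example, feature] + b[neuron])


def average_potentials(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """p_ij = mean_k |w_ji x_ik + b_j| as an (N, H) matrix.

    Computed in chunks of examples so the (M, N, H) tensor is never
    materialized.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("need at least one example")
    W, b = model.weights[0], model.biases[0]
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"model expects {W.shape[0]} features, got {X.shape[1]}")
    total = np.zeros_like(W)
    for start in range(0, X.shape[0], _CHUNK):
        chunk = X[start:start + _CHUNK]
        a = chunk[:, :, None] * W[None, :, :] + b[None, None, :]
        total += np.abs(a).sum(axis=0)
    return total / X.shape[0]


def feature_importance(
    model: TrainedModel,
    X: np.ndarray,
    mode: Literal["averaged", "strict"] = "averaged",
    rectify: Literal["before_mean", "after_mean"] = "before_mean",
    feature_names: Sequence[str] | None = None,
) -> ImportanceReport:
    """Net positive contribution c_i+ of every input feature.

    ``X`` must be standardized with the model's stored parameters (the same
    space the first-layer weights were learned in); by convention the
    training examples are used, but any example set may be supplied.
    """
    if mode not in ("averaged", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W, b = model.weights[0], model.biases[0]
    N, H = W.shape
    M = X.shape[0]
    names = (list(feature_names) if feature_names is not None
             else model.registry.names)
    if len(names) != N:
        raise ValueError(f"{len(names)} feature names for {N} features")

    p = average_potentials(model, X)
    denom = p.sum(axis=0)  # per neuron j: Σ_i p_ij
    degenerate = bool(np.all(denom == 0.0))
    if degenerate:
        warnings.warn("all activation potentials are zero; "
                      "importance report is all zeros")
        c_plus = np.zeros(N)
    else:
        safe = np.where(denom == 0.0, 1.0, denom)
        if mode == "averaged":
            c = p / safe[None, :]
            c_plus = np.maximum(c, 0.0).sum(axis=1)
        else:
            acc = np.zeros((N, H))
            for start in range(0, M, _CHUNK):
                chunk = X[start:start + _CHUNK]
                a = chunk[:, :, None] * W[None, :, :] + b[None, None, :]
                cijk = a / safe[None, None, :]
                if rectify == "before_mean":
                    acc += np.maximum(cijk, 0.0).sum(axis=0)
                else:
                    acc += cijk.sum(axis=0)
            mean_c = acc / M
            if rectify == "after_mean":
                mean_c = np.maximum(mean_c, 0.0)
            c_plus = mean_c.sum(axis=1)
        c_plus = np.where(denom[None, :].sum() == 0.0, 0.0, c_plus)

    order = sorted(range(N), key=lambda i: (-c_plus[i], names[i]))
    entries = [
        FeatureImportance(feature=names[i], index=i, c_plus=float(c_plus[i]))
        for i in order
    ]
    label = mode if mode == "averaged" else f"strict:{rectify}"
    return ImportanceReport(
        entries=entries, p=p, n_examples=M, n_neurons=H, n_features=N,
        mode=label, degenerate=degenerate,
    )
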