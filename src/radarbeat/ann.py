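"""Shallow feed-forward network: forward pass, Jacobian, serialization.

Each neuron computes an affine combination of its inputs followed by an
activation -- hyperbolic tangent (default), log-sigmoid or linear in
the hidden layers, and always a log-sigmoid on the single output
neuron, so the network emits a per-sample probability in (0, 1).

The model is deliberately tiny and explicit: a list of (weights, bias,
activation) layers with a flat-parameter view used by the
Levenberg-Marquardt trainer, plus exact decimal-text serialization.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["Layer", "AnnModel", "build_model", "parse_topology"]

_ACTIVATIONS = ("tanh", "logsig", "linear")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "logsig":
        # numerically safe logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if name == "linear":
        return z
    raise ValueError(f"unknown activation '{name}'")


def _act_prime_from_value(name: str, a: np.ndarray) -> np.ndarray:
    """Activation derivative expressed through the activation value."""
    if name == "tanh":
        return 1.0 - a * a
    if name == "logsig":
        return a * (1.0 - a)
    if name == "linear":
        return np.ones_like(a)
    raise ValueError(f"unknown activation '{name}'")


@dataclass
class Layer:
    w: np.ndarray          # (n_out, n_in)
    b: np.ndarray          # (n_out,)
    activation: str

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.w.ndim != 2 or self.b.shape[0] != self.w.shape[0]:
            raise ValueError("layer weight/bias shapes do not chain")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation '{self.activation}'")


@dataclass
class AnnModel:
    layers: List[Layer]
    topology_name: str = ""

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.w.shape[1] != prev.w.shape[0]:
                raise ValueError("adjacent layer dimensions do not chain")
        if self.layers:
            out = self.layers[-1]
            if out.w.shape[0] != 1:
                raise ValueError("final layer must have exactly 1 unit")
            if out.activation != "logsig":
                raise ValueError("output activation is fixed to sigmoid")

    # -- dimensions ---------------------------------------------------------

    @property
    def n_inputs(self) -> int:
        return int(self.layers[0].w.shape[1])

    @property
    def n_params(self) -> int:
        return sum(l.w.size + l.b.size for l in self.layers)

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Batch forward pass; returns probabilities of shape (M,)."""
        a = np.atleast_2d(np.asarray(X, dtype=float))
        if a.shape[1] != self.n_inputs:
            raise ValueError(
                f"input length {a.shape[1]} != model input {self.n_inputs}")
        for layer in self.layers:
            a = _act(layer.activation, a @ layer.w.T + layer.b)
        return a[:, 0]

    def forward_trace(self, X: np.ndarray) -> List[np.ndarray]:
        """Activations per layer (input first), for the Jacobian."""
        a = np.atleast_2d(np.asarray(X, dtype=float))
        acts = [a]
        for layer in self.layers:
            a = _act(layer.activation, a @ layer.w.T + layer.b)
            acts.append(a)
        return acts

    def jacobian(self, X: np.ndarray,
                 dtype=np.float64) -> Tuple[np.ndarray, np.ndarray]:
        """d(output)/d(params) for every row of ``X``.

        Returns ``(J, a)`` with ``J`` of shape (M, n_params), columns in
        flat-parameter order (layer by layer, weights row-major then
        biases), and ``a`` the output probabilities.
        """
        acts = self.forward_trace(X)
        m = acts[0].shape[0]
        deltas = [None] * len(self.layers)
        delta = _act_prime_from_value(self.layers[-1].activation, acts[-1])
        deltas[-1] = delta
        for li in range(len(self.layers) - 1, 0, -1):
            delta = (deltas[li] @ self.layers[li].w) * \
                _act_prime_from_value(self.layers[li - 1].activation, acts[li])
            deltas[li - 1] = delta
        J = np.empty((m, self.n_params), dtype=dtype)
        col = 0
        for li, layer in enumerate(self.layers):
            nw = layer.w.size
            block = deltas[li][:, :, None] * acts[li][:, None, :]
            J[:, col:col + nw] = block.reshape(m, nw)
            col += nw
            nb = layer.b.size
            J[:, col:col + nb] = deltas[li]
            col += nb
        return J, acts[-1][:, 0]

    # -- flat parameter view -------------------------------------------------

    def get_flat(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([l.w.ravel(), l.b]) for l in self.layers])

    def set_flat(self, p: np.ndarray) -> None:
        p = np.asarray(p, dtype=float)
        if p.size != self.n_params:
            raise ValueError("flat parameter vector has wrong length")
        off = 0
        for layer in self.layers:
            nw = layer.w.size
            layer.w = p[off:off + nw].reshape(layer.w.shape).copy()
            off += nw
            nb = layer.b.size
            layer.b = p[off:off + nb].copy()
            off += nb

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "radarbeat-ann",
            "version": 1,
            "topology_name": self.topology_name,
            "layers": [
                {
                    "activation": l.activation,
                    # 17 significant decimal digits round-trip float64 exactly
                    "w": [[float(f"{v:.17g}") for v in row] for row in l.w],
                    "b": [float(f"{v:.17g}") for v in l.b],
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        if d.get("format") != "radarbeat-ann":
            raise ValueError("not a radarbeat ANN model file")
        layers = [Layer(np.asarray(ld["w"], dtype=float),
                        np.asarray(ld["b"], dtype=float),
                        ld["activation"]) for ld in d["layers"]]
        return cls(layers, d.get("topology_name", ""))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "AnnModel":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))


def parse_topology(label: str) -> Tuple[str, List[int]]:
    """Parse a topology label like ``"FF 20 1"`` or ``"NARX 10 1"``.

    Returns ``(kind, hidden_sizes)``.  The trailing ``1`` names the
    single output neuron; all preceding numbers are hidden-layer sizes
    (``"FF 20 2 1"`` has hidden layers of 20 and 2 units).
    """
    tokens = label.replace("_", " ").split()
    if not tokens:
        raise ValueError("empty topology label")
    kind = tokens[0].upper()
    if kind not in ("FF", "NARX"):
        raise ValueError(f"unknown topology kind '{tokens[0]}'")
    try:
        sizes = [int(t) for t in tokens[1:]]
    except ValueError as exc:
        raise ValueError(f"bad topology label '{label}'") from exc
    if not sizes:
        raise ValueError(f"topology label '{label}' names no layers")
    if sizes[-1] == 1 and len(sizes) > 1:
        hidden = sizes[:-1]
    else:
        hidden = sizes
    if any(h < 1 for h in hidden):
        raise ValueError("layer sizes must be positive")
    return kind, hidden


def build_model(topology: str, n_inputs: int,
                hidden_activation: str = "tanh", seed: int = 0) -> AnnModel:
    """Initialize a network for a topology label.

    Weights are symmetric-uniform with scale ``1/sqrt(fan_in)`` per
    layer; biases start at zero.  Fully determined by ``seed``.
    """
    _, hidden = parse_topology(topology)
    rng = np.random.default_rng(seed)
    sizes = [n_inputs] + hidden + [1]
    layers = []
    for li, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = 1.0 / np.sqrt(n_in)
        w = rng.uniform(-scale, scale, size=(n_out, n_in))
        b = np.zeros(n_out)
        act = "logsig" if li == len(sizes) - 2 else hidden_activation
        layers.append(Layer(w, b, act))
    return AnnModel(layers, topology_name=topology)
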