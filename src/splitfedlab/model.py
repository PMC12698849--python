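"""Two-part ("split") CNN: specification, construction, forwards, parameter views.

The full classifier is a single layer stack cut at ``cut_index``: the client
part runs layers ``[0, cut)`` and emits the cut-layer activations ("smashed
data"); the server part runs layers ``[cut, end)`` and emits class scores.
Composing the two parts is mathematically identical to running the un-split
stack, which is the central correctness oracle of the package.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .nn import (Conv2d, Flatten, Layer, Linear, MaxPool2d, ReLU, Sequential,
                 cross_entropy)

# layer spec grammar: ("conv", out_channels, kernel, padding) | ("relu",)
# | ("maxpool", size) | ("flatten",) | ("dense", out_features)
LayerSpecT = tuple


@dataclass
class SplitModelSpec:
    """Architecture plus split point.

    ``layers`` uses a compact tuple grammar (see module source); the last
    layer must be a dense layer of width ``n_classes`` and the cut must fall
    strictly inside the stack.
    """

    layers: list[LayerSpecT]
    cut_index: int
    n_classes: int = 4
    image_size: int = 32
    in_channels: int = 1

    def validate(self) -> None:
        if not (1 <= self.cut_index < len(self.layers)):
            raise ValueError(
                f"cut_index must lie in [1, {len(self.layers) - 1}], got {self.cut_index}")
        last = self.layers[-1]
        if last[0] != "dense" or last[1] != self.n_classes:
            raise ValueError("last layer must be ('dense', n_classes)")
        self._infer_shapes()  # raises on inconsistent shapes

    def _infer_shapes(self) -> list[tuple]:
        """Shape after each layer; raises on inconsistency."""
        shape: tuple = (self.in_channels, self.image_size, self.image_size)
        shapes = []
        for spec in self.layers:
            kind = spec[0]
            if kind == "conv":
                if len(shape) != 3:
                    raise ValueError("conv after flatten is invalid")
                _, k, p = spec[1], spec[2], spec[3]
                h = shape[1] + 2 * p - spec[2] + 1
                w = shape[2] + 2 * p - spec[2] + 1
                if h < 1 or w < 1:
                    raise ValueError("conv kernel larger than input")
                shape = (spec[1], h, w)
            elif kind == "maxpool":
                if len(shape) != 3:
                    raise ValueError("maxpool after flatten is invalid")
                s = spec[1]
                if shape[1] % s or shape[2] % s:
                    raise ValueError("pool size does not divide spatial dims")
                shape = (shape[0], shape[1] // s, shape[2] // s)
            elif kind == "flatten":
                shape = (int(np.prod(shape)),)
            elif kind == "dense":
                if len(shape) != 1:
                    raise ValueError("dense requires a flattened input")
                shape = (spec[1],)
            elif kind == "relu":
                pass
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
            shapes.append(shape)
        return shapes

    def smashed_shape(self) -> tuple:
        """Per-sample shape of the cut-layer activations."""
        return self._infer_shapes()[self.cut_index - 1]

    def to_dict(self) -> dict:
        return {"layers": [list(t) for t in self.layers],
                "cut_index": self.cut_index, "n_classes": self.n_classes,
                "image_size": self.image_size, "in_channels": self.in_channels}

    @classmethod
    def from_dict(cls, d: dict) -> "SplitModelSpec":
        return cls(layers=[tuple(t) for t in d["layers"]],
                   cut_index=int(d["cut_index"]), n_classes=int(d["n_classes"]),
                   image_size=int(d["image_size"]),
                   in_channels=int(d["in_channels"]))


def default_spec(n_classes: int = 4, image_size: int = 32) -> SplitModelSpec:
    """Default architecture: two conv/pool blocks on the client side, the
    classification head on the server side, cut after the second pool so the
    smashed data is a spatial activation map."""
    return SplitModelSpec(
        layers=[("conv", 8, 3, 1), ("relu",), ("maxpool", 2),
                ("conv", 16, 3, 1), ("relu",), ("maxpool", 2),
                ("flatten",), ("dense", 64), ("relu",), ("dense", n_classes)],
        cut_index=6, n_classes=n_classes, image_size=image_size)


def _build_layer(spec: LayerSpecT, shape: tuple) -> tuple[Layer, tuple]:
    kind = spec[0]
    if kind == "conv":
        layer = Conv2d(shape[0], spec[1], kernel_size=spec[2], padding=spec[3])
        h = shape[1] + 2 * spec[3] - spec[2] + 1
        return layer, (spec[1], h, h)
    if kind == "relu":
        return ReLU(), shape
    if kind == "maxpool":
        return MaxPool2d(spec[1]), (shape[0], shape[1] // spec[1], shape[2] // spec[1])
    if kind == "flatten":
        return Flatten(), (int(np.prod(shape)),)
    if kind == "dense":
        return Linear(shape[0], spec[1]), (spec[1],)
    raise ValueError(f"unknown layer kind {kind!r}")


@dataclass
class ParameterVector:
    """Named snapshot of one model part's parameters with a flat view.

    Flat ordering is fixed and documented: layer order, then weights before
    biases within a layer. ``flatten``/``unflatten`` are exact inverses.
    """

    names: list[str]
    arrays: list[np.ndarray]
    role: str = "client_part"

    def copy(self) -> "ParameterVector":
        return ParameterVector(list(self.names), [a.copy() for a in self.arrays],
                               self.role)

    @property
    def n_params(self) -> int:
        return int(sum(a.size for a in self.arrays))

    def flatten(self) -> np.ndarray:
        if not self.arrays:
            return np.zeros(0)
        return np.concatenate([a.ravel() for a in self.arrays])

    def unflatten(self, flat: np.ndarray) -> "ParameterVector":
        if flat.size != self.n_params:
            raise ValueError(f"flat length {flat.size} != {self.n_params}")
        out, pos = [], 0
        for a in self.arrays:
            out.append(np.asarray(flat[pos:pos + a.size]).reshape(a.shape).copy())
            pos += a.size
        return ParameterVector(list(self.names), out, self.role)

    @classmethod
    def from_model(cls, part: Sequential, role: str = "client_part") -> "ParameterVector":
        names, arrays = zip(*part.named_params()) if part.named_params() else ((), ())
        return cls(list(names), [a.copy() for a in arrays], role)

    def apply_to(self, part: Sequential) -> None:
        """Write values back into a model part, in place (preserves optimizer
        state bound to the arrays)."""
        targets = part.named_params()
        if [n for n, _ in targets] != self.names:
            raise ValueError("parameter names do not match the target model part")
        for (_, dst), src in zip(targets, self.arrays, strict=True):
            if dst.shape != src.shape:
                raise ValueError("parameter shape mismatch")
            dst[...] = src


@dataclass
class SmashedBatch:
    """Cut-layer activations for one batch, with provenance metadata."""

    activations: np.ndarray
    client_id: int = 0
    sample_indices: np.ndarray | None = None
    labels: np.ndarray | None = None  # transmitted alongside in the default wiring


@dataclass
class SplitModel:
    """Client and server parts of one split network."""

    spec: SplitModelSpec
    client: Sequential
    server: Sequential

    def monolithic(self) -> Sequential:
        """The un-split stack, sharing parameter arrays with both parts."""
        return Sequential(self.client.layers + self.server.layers)

    def copy(self) -> "SplitModel":
        m = build_split_model(self.spec, seed=0)
        ParameterVector.from_model(self.client).apply_to(m.client)
        ParameterVector.from_model(self.server).apply_to(m.server)
        return m


def build_split_model(spec: SplitModelSpec, seed: int = 0) -> SplitModel:
    """Instantiate both parts with deterministic-given-seed initialization."""
    spec.validate()
    rng = np.random.default_rng(seed)
    shape: tuple = (spec.in_channels, spec.image_size, spec.image_size)
    layers: list[Layer] = []
    for lspec in spec.layers:
        layer, shape = _build_layer(lspec, shape)
        if hasattr(layer, "init_params"):
            layer.init_params(rng)
        layers.append(layer)
    return SplitModel(spec=spec, client=Sequential(layers[:spec.cut_index]),
                      server=Sequential(layers[spec.cut_index:]))


def client_forward(model: SplitModel, images: np.ndarray, client_id: int = 0,
                   sample_indices: np.ndarray | None = None,
                   labels: np.ndarray | None = None) -> SmashedBatch:
    """Forward a preprocessed image batch through the client part.

    ``images`` is (n, H, W) in [-1, 1]; the returned activations keep the
    differentiable caches needed for a later backward pass.
    """
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None, :, :]
    acts = model.client.forward(x)
    return SmashedBatch(activations=acts, client_id=client_id,
                        sample_indices=sample_indices, labels=labels)


def server_forward(model: SplitModel, smashed: SmashedBatch) -> np.ndarray:
    """Forward smashed activations through the server part; returns class
    scores (pre-softmax), one row per sample."""
    return model.server.forward(smashed.activations)


def loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of class scores against integer labels."""
    value, _ = cross_entropy(scores, np.asarray(labels))
    return value


def predict(model: SplitModel, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class predictions for preprocessed images."""
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None, :, :]
    out = []
    for i in range(0, len(x), batch_size):
        scores = model.server.forward(model.client.forward(x[i:i + batch_size]))
        out.append(scores.argmax(axis=1))
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def save_checkpoint(model: SplitModel, path: str) -> None:
    """Serialize spec (JSON) + named parameter arrays (npz) into a directory."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "spec.json"), "w") as fh:
        json.dump(model.spec.to_dict(), fh, indent=2)
    arrays = {}
    for prefix, part in (("client", model.client), ("server", model.server)):
        for name, arr in part.named_params():
            arrays[f"{prefix}/{name}"] = arr
    np.savez(os.path.join(path, "params.npz"), **arrays)


def load_checkpoint(path: str) -> SplitModel:
    with open(os.path.join(path, "spec.json")) as fh:
        spec = SplitModelSpec.from_dict(json.load(fh))
    model = build_split_model(spec, seed=0)
    with np.load(os.path.join(path, "params.npz")) as npz:
        for prefix, part in (("client", model.client), ("server", model.server)):
            for name, arr in part.named_params():
                arr[...] = npz[f"{prefix}/{name}"]
    return model
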