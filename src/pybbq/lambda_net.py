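"""Convolutional lambda predictor.

A five-layer 1D convolutional network maps the K x 37 feature matrix of a
chain to K pairs (sin lambda, cos lambda); the angle is recovered with the
quadrant-aware arctangent, which is invariant to any positive rescaling of
the pair, so the network output needs no normalisation.  Training minimises
a masked mean-squared error on the two channels — the standard remedy for
the periodicity of a dihedral target.

The reference architecture uses 1024 kernels of sizes 11, 9, 5 and 3
followed by a two-channel 1x1 layer; narrower variants (same depth, fewer
kernels) are available for CPU-scale experiments.  The implementation is
self-contained numpy: same-length zero-padded convolutions, ReLU hidden
activations, a linear output layer and Adam with early stopping on a
validation split.

Output position i carries the lambda of the plate between Ca_{i-1} and
Ca_i, following the residue-to-plate convention of the reconstruction
module; position 0 is masked (no preceding plate).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plate_geometry import BackboneStructure, LambdaSeries, lambda_from_backbone, wrap_angle
from .structure_io import CaTrace
from .trace_features import FEATURE_COLUMNS, FeatureMatrix, build_feature_matrix

REFERENCE_LAYERS = ((1024, 11), (1024, 9), (1024, 5), (1024, 3), (2, 1))


class ConfigurationError(ValueError):
    """Invalid network or training configuration."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: (n_kernels, kernel_size) per layer."""

    layers: tuple = REFERENCE_LAYERS
    activation: str = "relu"
    n_features: int = len(FEATURE_COLUMNS)

    def __post_init__(self):
        if len(self.layers) != 5:
            raise ConfigurationError("the network has exactly five layers")
        if tuple(self.layers[-1]) != (2, 1):
            raise ConfigurationError("final layer must be two kernels of size 1")
        if self.activation != "relu":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")

    @classmethod
    def scaled(cls, width: int) -> "NetworkSpec":
        """Same depth and kernel sizes as the reference, narrower layers."""
        sizes = [k for _, k in REFERENCE_LAYERS[:-1]]
        return cls(layers=tuple([(width, s) for s in sizes] + [(2, 1)]))


@dataclass
class TrainingConfig:
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 100
    validation_fraction: float = 0.1
    patience: int = 20          # early-stopping patience, epochs
    shuffle: bool = True


# ---------------------------------------------------------------------------
# Conv1D network with hand-rolled backprop
# ---------------------------------------------------------------------------

class _Conv1D:
    """Same-length zero-padded 1D convolution over a (K, C_in) signal."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.ksize = ksize
        self.c_in = c_in
        self.c_out = c_out
        scale = np.sqrt(2.0 / (ksize * c_in))       # He initialisation
        self.w = rng.normal(0.0, scale, size=(ksize * c_in, c_out))
        self.b = np.zeros(c_out)
        self._x_pad = None

    @property
    def pad(self) -> tuple[int, int]:
        left = (self.ksize - 1) // 2
        return left, self.ksize - 1 - left

    def _windows(self, x_pad: np.ndarray, kk: int) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(x_pad, self.ksize, axis=0)
        # win: (K, C_in, ksize) -> (K, ksize * C_in) matching w's layout
        return win.transpose(0, 2, 1).reshape(kk, self.ksize * self.c_in)

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        kk = x.shape[0]
        left, right = self.pad
        x_pad = np.pad(x, ((left, right), (0, 0)))
        if keep:
            self._x_pad = x_pad
        return self._windows(x_pad, kk) @ self.w + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        kk = grad_out.shape[0]
        left, right = self.pad
        cols = self._windows(self._x_pad, kk)
        self.gw = cols.T @ grad_out
        self.gb = grad_out.sum(axis=0)
        gcols = grad_out @ self.w.T                 # (K, ksize * C_in)
        gcols = gcols.reshape(kk, self.ksize, self.c_in)
        gx_pad = np.zeros_like(self._x_pad)
        for t in range(self.ksize):
            gx_pad[t:t + kk] += gcols[:, t, :]
        self._x_pad = None
        return gx_pad[left:left + kk] if right == 0 else gx_pad[left:-right]

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


class Network:
    """Sequential Conv1D stack mapping (K, n_features) -> (K, 2)."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list[_Conv1D] = []
        c_in = spec.n_features
        for c_out, ksize in spec.layers:
            self.layers.append(_Conv1D(c_in, c_out, ksize, rng))
            c_in = c_out

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.spec.n_features:
            raise ConfigurationError(
                f"input must be K x {self.spec.n_features}, got {x.shape}")
        self._relu_masks = []
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, keep=keep)
            if i < last:                            # hidden layers: ReLU
                mask = h > 0
                if keep:
                    self._relu_masks.append(mask)
                h = h * mask
        return h

    def backward(self, grad_out: np.ndarray) -> None:
        g = grad_out
        last = len(self.layers) - 1
        for i in range(last, -1, -1):
            if i < last:
                g = g * self._relu_masks[i]
            g = self.layers[i].backward(g)

    def weight_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.w, layer.b])
        return out

    def set_weights(self, arrays) -> None:
        arrays = list(arrays)
        for i, layer in enumerate(self.layers):
            layer.w = arrays[2 * i].copy()
            layer.b = arrays[2 * i + 1].copy()


class _Adam:
    def __init__(self, network: Network, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = network
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(a) for a in network.weight_arrays()]
        self.v = [np.zeros_like(a) for a in network.weight_arrays()]

    def step(self) -> None:
        self.t += 1
        grads = []
        for layer in self.net.layers:
            grads.extend([layer.gw, layer.gb])
        arrays = self.net.weight_arrays()
        for arr, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> Network:
    """Deterministically initialised, untrained lambda-prediction network."""
    return Network(spec or NetworkSpec(), seed)


# ---------------------------------------------------------------------------
# Targets and training
# ---------------------------------------------------------------------------

def angles_from_sincos(pairs: np.ndarray) -> LambdaSeries:
    """Quadrant-aware recovery of lambda from (sin, cos) estimate pairs.

    Invariant to positive rescaling of each pair; positions where both
    components are (numerically) zero are flagged undefined.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected a K x 2 array of (sin, cos) pairs")
    if not np.all(np.isfinite(pairs)):
        raise ValueError("non-finite (sin, cos) estimate")
    norms = np.hypot(pairs[:, 0], pairs[:, 1])
    defined = norms > 1e-12
    values = np.zeros(len(pairs))
    values[defined] = wrap_angle(np.arctan2(pairs[defined, 0], pairs[defined, 1]))
    return LambdaSeries(values, defined)


def _as_backbone(obj) -> BackboneStructure:
    if isinstance(obj, BackboneStructure):
        return obj
    if hasattr(obj, "backbone"):                    # SyntheticChain
        return obj.backbone
    if hasattr(obj, "atoms"):                       # ProteinChain
        from .structure_io import backbone_from_chain
        return backbone_from_chain(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a backbone")


def make_training_pairs(structures) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Turn full-atom chains into (features, sin/cos targets, mask) triples.

    Targets at output position i are (sin, cos) of the lambda of the plate
    between Ca_{i-1} and Ca_i, measured from the experimental backbone;
    position 0 and plates with undefined lambda are masked out.
    """
    dataset = []
    for obj in structures:
        bb = _as_backbone(obj)
        trace = CaTrace(bb.chain_id, list(bb.residue_names), bb.ca)
        features = build_feature_matrix(trace).values
        lams = lambda_from_backbone(bb)
        kk = bb.n_residues
        targets = np.zeros((kk, 2))
        mask = np.zeros(kk, dtype=bool)
        mask[1:] = lams.defined_mask
        targets[1:, 0] = np.sin(lams.values)
        targets[1:, 1] = np.cos(lams.values)
        targets[~mask] = 0.0
        if mask.any():
            dataset.append((features, targets, mask))
    return dataset


@dataclass
class TrainedModel:
    """A trained network plus its provenance."""

    network: Network
    config: TrainingConfig
    history: list[dict] = field(default_factory=list)
    dataset_fingerprint: str = ""

    @property
    def spec(self) -> NetworkSpec:
        return self.network.spec

    def save(self, path) -> None:
        meta = {
            "layers": [list(l) for l in self.spec.layers],
            "activation": self.spec.activation,
            "n_features": self.spec.n_features,
            "feature_layout": _feature_layout_hash(),
            "dataset_fingerprint": self.dataset_fingerprint,
            "seed": self.config.seed,
        }
        arrays = {f"arr_{i}": a for i, a in
                  enumerate(self.network.weight_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no checkpoint at {path}")
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["feature_layout"] != _feature_layout_hash():
                raise ConfigurationError(
                    "checkpoint was trained with a different feature layout")
            spec = NetworkSpec(layers=tuple(tuple(l) for l in meta["layers"]),
                               activation=meta["activation"],
                               n_features=meta["n_features"])
            net = Network(spec, seed=0)
            n = len(net.weight_arrays())
            net.set_weights([data[f"arr_{i}"] for i in range(n)])
        model = cls(net, TrainingConfig(seed=meta.get("seed", 0)))
        model.dataset_fingerprint = meta.get("dataset_fingerprint", "")
        return model


def _feature_layout_hash() -> str:
    return hashlib.sha256("|".join(FEATURE_COLUMNS).encode()).hexdigest()[:16]


def _masked_loss_and_grad(pred, targets, mask):
    diff = (pred - targets) * mask[:, None]
    n = 2 * max(int(mask.sum()), 1)
    return float((diff ** 2).sum() / n), 2.0 * diff / n


def train(network: Network, dataset, config: TrainingConfig | None = None) -> TrainedModel:
    """Fit the network with Adam on masked sin/cos MSE.

    One chain per optimisation step (variable K needs no batching tricks);
    a fixed fraction of chains is held out for validation and the weights
    with the best validation loss are returned.  Fully deterministic under
    a fixed config seed.
    """
    config = config or TrainingConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * len(dataset)))
    order = rng.permutation(len(dataset))
    val_idx = set(order[:n_val].tolist())
    train_set = [dataset[i] for i in order if i not in val_idx]
    val_set = [dataset[i] for i in order if i in val_idx]
    if not train_set:
        raise ValueError("no chains left for training after the split")

    fingerprint = hashlib.sha256()
    for feats, targets, mask in dataset:
        fingerprint.update(np.ascontiguousarray(feats).tobytes())
    model = TrainedModel(network, config,
                         dataset_fingerprint=fingerprint.hexdigest()[:16])

    opt = _Adam(network, config.learning_rate)
    best_val = np.inf
    best_weights = [a.copy() for a in network.weight_arrays()]
    stale = 0
    for epoch in range(config.epochs):
        if config.shuffle:
            idx = rng.permutation(len(train_set))
        else:
            idx = np.arange(len(train_set))
        total = 0.0
        for i in idx:
            feats, targets, mask = train_set[i]
            pred = network.forward(feats, keep=True)
            loss, grad = _masked_loss_and_grad(pred, targets, mask)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            network.backward(grad)
            opt.step()
            total += loss
        train_loss = total / len(train_set)
        if val_set:
            val_loss = float(np.mean([
                _masked_loss_and_grad(network.forward(f), t, m)[0]
                for f, t, m in val_set]))
        else:
            val_loss = train_loss
        model.history.append({"epoch": epoch, "train_loss": train_loss,
                              "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [a.copy() for a in network.weight_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    network.set_weights(best_weights)
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_sincos(model: TrainedModel | Network, features) -> np.ndarray:
    net = model.network if isinstance(model, TrainedModel) else model
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    return net.forward(values)


def predict_lambda(model: TrainedModel | Network, features) -> LambdaSeries:
    """Per-residue lambda estimates for a feature matrix.

    Position i carries the plate between Ca_{i-1} and Ca_i; position 0 has
    no plate and is masked undefined.
    """
    series = angles_from_sincos(predict_sincos(model, features))
    series.defined_mask[0] = False
    return series


def predict_plate_lambdas(model: TrainedModel | Network, trace: CaTrace) -> LambdaSeries:
    """Plate-indexed lambda series (length K-1) ready for reconstruction."""
    per_residue = predict_lambda(model, build_feature_matrix(trace))
    return LambdaSeries(per_residue.values[1:], per_residue.defined_mask[1:])
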