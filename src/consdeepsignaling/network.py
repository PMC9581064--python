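"""The pathway-constrained network and its comparator architectures.

The main model predicts the dose-response AUC of a (drug, cell line) pair
from a length K*n input vector (K features per gene: expression, copy
number, is_target flag).  Its first two layers are sparsity-constrained
linear maps::

    G = (C_XG o W_XG)^T X        # gene tier, one node per gene
    P = (C_GP o W_GP)^T G        # pathway tier, one node per pathway

where ``o`` is the element-wise product with a fixed binary mask, so a
weight exists only where the mask allows a connection.  The pathway tier
feeds a densely connected head (ReLU layers of 256/128/32 units by
default) ending in a single linear output.  Training minimizes mean
squared error.

Everything here — layers, backprop, masking — is plain numpy.  The masks
are enforced structurally: the effective weight is ``mask * W`` on every
forward pass and the weight gradient is multiplied by the mask on every
backward pass, so masked-out positions hold exactly 0.0 forever and
receive exactly-zero gradients (not merely small ones).

Three comparator architectures from the same evaluation protocol are
provided: a plain dense DNN, Path-DNN (expression + drug-target features
through the gene->pathway mask), and PASNet (expression only through the
mask, one dropout-regularized hidden layer, L2 penalties).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .masks import MaskMatrix, build_gene_feature_mask, build_gene_pathway_mask

__all__ = [
    "ModelConfig",
    "ModelState",
    "Parameter",
    "Linear",
    "Activation",
    "Dropout",
    "Sequential",
    "init_model",
    "build_dnn_baseline",
    "build_pathdnn_baseline",
    "build_pasnet_baseline",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

MODEL_KINDS = ("consdeepsignaling", "dnn", "pathdnn", "pasnet")


@dataclass
class ModelConfig:
    """Architecture configuration.

    Parameters
    ----------
    K, n, s
        Features per gene, number of genes, number of pathways.
    head_sizes
        Widths of the dense ReLU layers between the pathway tier and the
        linear output (the "DBN head").
    gene_pathway_activation
        Activation applied at the gene and pathway tiers; the masked-tier
        equations carry no nonlinearity, so the default is ``"linear"``.
    use_bias_masked_layers
        Whether the masked tiers carry bias terms (off by default, again
        matching the bias-free tier equations).
    seed
        Seed for weight initialization (and dropout streams).
    """

    K: int
    n: int
    s: int
    head_sizes: tuple[int, ...] = (256, 128, 32)
    gene_pathway_activation: str = "linear"
    use_bias_masked_layers: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.head_sizes = tuple(int(h) for h in self.head_sizes)
        if self.K < 1 or self.n < 1 or self.s < 1:
            raise ValueError(f"K, n, s must be positive, got {self.K}, {self.n}, {self.s}")
        if not self.head_sizes or any(h < 1 for h in self.head_sizes):
            raise ValueError(f"head_sizes must be non-empty positive, got {self.head_sizes}")
        if self.gene_pathway_activation not in ("linear", "relu"):
            raise ValueError(f"gene_pathway_activation must be linear|relu, got "
                             f"{self.gene_pathway_activation!r}")


class Parameter:
    """A trainable array, its gradient buffer and optional structural mask."""

    __slots__ = ("name", "value", "grad", "mask", "l2")

    def __init__(self, name: str, value: np.ndarray,
                 mask: np.ndarray | None = None, l2: float = 0.0) -> None:
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.mask = None if mask is None else np.asarray(mask, dtype=float)
        self.l2 = float(l2)
        if self.mask is not None:
            if self.mask.shape != self.value.shape:
                raise ValueError(f"{name}: mask shape {self.mask.shape} != value shape "
                                 f"{self.value.shape}")
            self.value *= self.mask  # masked positions start (and stay) at 0

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    """x @ (mask o W) + b, with exact gradient masking on the backward pass."""

    def __init__(self, W: Parameter, b: Parameter | None = None) -> None:
        self.W = W
        self.b = b
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def effective_weight(self) -> np.ndarray:
        if self.W.mask is None:
            return self.W.value
        return self.W.mask * self.W.value

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.effective_weight
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gW = self._x.T @ grad
        if self.W.mask is not None:
            gW = gW * self.W.mask
        self.W.grad += gW
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.effective_weight.T


class Activation(Layer):
    def __init__(self, kind: str, alpha: float = 0.3) -> None:
        if kind not in ("linear", "relu", "leaky_relu"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self.alpha = alpha
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        if self.kind == "linear":
            return x
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return grad
        if self.kind == "relu":
            return grad * (self._x > 0)
        return grad * np.where(self._x > 0, 1.0, self.alpha)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode, seeded stream in train mode."""

    def __init__(self, rate: float, seed: int) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._mask: np.ndarray | None = None

    def reset(self) -> None:
        self.rng = np.random.default_rng(self.seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _dense_stack(rng: np.random.Generator, sizes: Sequence[int], *,
                 prefix: str, activation: str = "relu", alpha: float = 0.3,
                 dropout: Sequence[float] | None = None,
                 dropout_seed: int = 0, l2: float = 0.0,
                 final_linear: bool = True) -> list[Layer]:
    """Dense layers sizes[0] -> sizes[1] -> ... with the given activation
    after every layer except (optionally) a final linear output."""
    layers: list[Layer] = []
    for i in range(len(sizes) - 1):
        fan_in, fan_out = sizes[i], sizes[i + 1]
        W = Parameter(f"{prefix}_W{i}", _glorot(rng, fan_in, fan_out, (fan_in, fan_out)),
                      l2=l2)
        b = Parameter(f"{prefix}_b{i}", np.zeros(fan_out), l2=l2)
        layers.append(Linear(W, b))
        last = i == len(sizes) - 2
        if last and final_linear:
            continue
        layers.append(Activation(activation, alpha=alpha))
        if dropout is not None and dropout[i] > 0:
            layers.append(Dropout(dropout[i], seed=dropout_seed + i))
    return layers


@dataclass
class ModelState:
    """A built model: masked tiers (if any), dense head, and bookkeeping.

    ``tiers`` maps the model's input features to the pathway activations
    ``P`` (for the main model it contains both masked layers; for Path-DNN
    and PASNet the single masked layer; for the plain DNN it is ``None``).
    ``feature_indices`` selects this model's input columns from the full
    gene-major K-features-per-gene design matrix.
    """

    kind: str
    config: ModelConfig
    tiers: Sequential | None
    head: Sequential
    feature_indices: np.ndarray
    masks: dict[str, MaskMatrix] = field(default_factory=dict)
    gene_order: list[str] = field(default_factory=list)
    pathway_order: list[str] = field(default_factory=list)

    def params(self) -> list[Parameter]:
        out = [] if self.tiers is None else self.tiers.params()
        return out + self.head.params()

    def reset_dropout(self) -> None:
        for seq in (self.tiers, self.head):
            if seq is None:
                continue
            for layer in seq.layers:
                if isinstance(layer, Dropout):
                    layer.reset()

    def _select(self, X: np.ndarray) -> np.ndarray:
        return X[..., self.feature_indices]

    def forward_batch(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Predictions for a (batch, K*n) design-matrix slice; returns (batch,)."""
        h = self._select(np.atleast_2d(X))
        if self.tiers is not None:
            h = self.tiers.forward(h, train=train)
        out = self.head.forward(h, train=train)
        return out[:, 0]

    def backward_batch(self, grad_out: np.ndarray) -> None:
        """Backprop d(loss)/d(prediction) through the whole model."""
        grad = np.asarray(grad_out, dtype=float)[:, None]
        grad = self.head.backward(grad)
        if self.tiers is not None:
            self.tiers.backward(grad)

    def predict(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            out[start:start + batch_size] = self.forward_batch(X[start:start + batch_size])
        return out

    def forward(self, x: np.ndarray) -> float:
        """Prediction for one sample vector."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError(f"expected a 1-D sample vector, got shape {x.shape}")
        expected = self.config.K * self.config.n
        if x.shape[0] != expected:
            raise ValueError(f"sample vector length {x.shape[0]} != K*n = {expected}")
        return float(self.forward_batch(x[None, :])[0])

    def pathway_activations(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        if self.tiers is None:
            raise ValueError(f"model kind {self.kind!r} has no pathway tier")
        return self.tiers.forward(self._select(np.atleast_2d(X)), train=train)


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def init_model(config: ModelConfig,
               gene_feature_mask: MaskMatrix,
               gene_pathway_mask: MaskMatrix) -> ModelState:
    """Build the pathway-constrained model from its two masks.

    Weights are drawn from a seeded Glorot-uniform initializer; masked-out
    positions are exactly 0 from the start.  Identical seeds give
    bitwise-identical parameter sets.
    """
    Kn, n, s = config.K * config.n, config.n, config.s
    if gene_feature_mask.shape != (Kn, n):
        raise ValueError(f"gene-feature mask shape {gene_feature_mask.shape} != ({Kn}, {n})")
    if gene_pathway_mask.shape != (n, s):
        raise ValueError(f"gene-pathway mask shape {gene_pathway_mask.shape} != ({n}, {s})")
    rng = np.random.default_rng(config.seed)
    act = config.gene_pathway_activation
    W_xg = Parameter("W_XG", _glorot(rng, Kn, n, (Kn, n)), mask=gene_feature_mask.values)
    W_gp = Parameter("W_GP", _glorot(rng, n, s, (n, s)), mask=gene_pathway_mask.values)
    tier_layers: list[Layer] = [Linear(W_xg, _tier_bias("b_XG", n, config)),
                                Activation(act),
                                Linear(W_gp, _tier_bias("b_GP", s, config)),
                                Activation(act)]
    head_layers = _dense_stack(rng, [s, *config.head_sizes, 1], prefix="head",
                               activation="relu", dropout_seed=config.seed + 1000)
    return ModelState(
        kind="consdeepsignaling",
        config=config,
        tiers=Sequential(tier_layers),
        head=Sequential(head_layers),
        feature_indices=np.arange(Kn),
        masks={"gene_feature": gene_feature_mask, "gene_pathway": gene_pathway_mask},
        gene_order=list(gene_pathway_mask.rows),
        pathway_order=list(gene_pathway_mask.cols),
    )


def _tier_bias(name: str, size: int, config: ModelConfig) -> Parameter | None:
    return Parameter(name, np.zeros(size)) if config.use_bias_masked_layers else None


def build_dnn_baseline(config: ModelConfig) -> ModelState:
    """Plain dense comparator on the same K*n input.

    Two 256-unit LeakyReLU (alpha=0.3) layers with dropout 0.1, then
    256/128/32 ReLU layers and a linear output.
    """
    rng = np.random.default_rng(config.seed)
    Kn = config.K * config.n
    layers = _dense_stack(rng, [Kn, 256, 256], prefix="dnn_lrelu",
                          activation="leaky_relu", alpha=0.3,
                          dropout=[0.1, 0.1], dropout_seed=config.seed + 1000,
                          final_linear=False)
    layers += _dense_stack(rng, [256, 256, 128, 32, 1], prefix="dnn_head",
                           activation="relu")
    return ModelState(kind="dnn", config=config, tiers=None,
                      head=Sequential(layers), feature_indices=np.arange(Kn))


def build_pathdnn_baseline(config: ModelConfig,
                           gene_pathway_mask: MaskMatrix) -> ModelState:
    """Path-DNN comparator: expression + is_target features per gene, one
    masked gene-feature -> pathway layer, then 512/32 ReLU and a linear
    output.  CNV is not used."""
    if gene_pathway_mask.shape != (config.n, config.s):
        raise ValueError(f"gene-pathway mask shape {gene_pathway_mask.shape} != "
                         f"({config.n}, {config.s})")
    rng = np.random.default_rng(config.seed)
    n, s = config.n, config.s
    # expression (offset 0) and is_target (offset K-1) columns, gene-major
    feature_indices = np.sort(np.concatenate([
        np.arange(n) * config.K, np.arange(n) * config.K + (config.K - 1)]))
    # each gene contributes 2 mask rows with identical pathway connectivity
    expanded = np.repeat(gene_pathway_mask.values, 2, axis=0)
    W = Parameter("pathdnn_W", _glorot(rng, 2 * n, s, (2 * n, s)), mask=expanded)
    tiers = Sequential([Linear(W), Activation("linear")])
    head = Sequential(_dense_stack(rng, [s, 512, 32, 1], prefix="pathdnn_head",
                                   activation="relu"))
    return ModelState(kind="pathdnn", config=config, tiers=tiers, head=head,
                      feature_indices=feature_indices,
                      masks={"gene_pathway": gene_pathway_mask},
                      gene_order=list(gene_pathway_mask.rows),
                      pathway_order=list(gene_pathway_mask.cols))


def build_pasnet_baseline(config: ModelConfig,
                          gene_pathway_mask: MaskMatrix,
                          hidden_size: int = 100) -> ModelState:
    """PASNet comparator: expression only through the gene -> pathway mask,
    one ReLU hidden layer with dropout 0.1, linear output; L2 penalty 0.01
    on the hidden and output layers."""
    if gene_pathway_mask.shape != (config.n, config.s):
        raise ValueError(f"gene-pathway mask shape {gene_pathway_mask.shape} != "
                         f"({config.n}, {config.s})")
    rng = np.random.default_rng(config.seed)
    n, s = config.n, config.s
    feature_indices = np.arange(n) * config.K  # expression columns only
    W = Parameter("pasnet_W", _glorot(rng, n, s, (n, s)), mask=gene_pathway_mask.values)
    tiers = Sequential([Linear(W), Activation("linear")])
    head_layers = _dense_stack(rng, [s, hidden_size], prefix="pasnet_hidden",
                               activation="relu", l2=0.01, final_linear=False)
    head_layers.append(Dropout(0.1, seed=config.seed + 1000))
    head_layers += _dense_stack(rng, [hidden_size, 1], prefix="pasnet_out", l2=0.01)
    return ModelState(kind="pasnet", config=config, tiers=tiers,
                      head=Sequential(head_layers), feature_indices=feature_indices,
                      masks={"gene_pathway": gene_pathway_mask},
                      gene_order=list(gene_pathway_mask.rows),
                      pathway_order=list(gene_pathway_mask.cols))


def build_model(kind: str, config: ModelConfig,
                gene_feature_mask: MaskMatrix | None = None,
                gene_pathway_mask: MaskMatrix | None = None) -> ModelState:
    """Dispatch on model kind; builds missing masks from the config shape."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    if kind == "dnn":
        return build_dnn_baseline(config)
    if gene_pathway_mask is None:
        raise ValueError(f"model kind {kind!r} requires a gene-pathway mask")
    if kind == "pathdnn":
        return build_pathdnn_baseline(config, gene_pathway_mask)
    if kind == "pasnet":
        return build_pasnet_baseline(config, gene_pathway_mask)
    if gene_feature_mask is None:
        gene_feature_mask = build_gene_feature_mask(config.K, config.n,
                                                    gene_order=gene_pathway_mask.rows)
    return init_model(config, gene_feature_mask, gene_pathway_mask)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: ModelState, path: str | Path) -> None:
    """Write one archive holding config, orderings, sparse masks and weights.

    Reloading gives bitwise-identical predictions.
    """
    meta = {
        "kind": model.kind,
        "config": asdict(model.config),
        "gene_order": model.gene_order,
        "pathway_order": model.pathway_order,
        "masks": {
            name: {"rows": m.rows, "cols": m.cols,
                   "triplets": [[int(i), int(j)] for i, j in zip(*np.nonzero(m.values))]}
            for name, m in model.masks.items()
        },
        "param_names": [p.name for p in model.params()],
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for p in model.params():
            buf = io.BytesIO()
            np.save(buf, p.value, allow_pickle=False)
            zf.writestr(f"params/{p.name}.npy", buf.getvalue())


def load_checkpoint(path: str | Path) -> ModelState:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        cfg = meta["config"]
        cfg["head_sizes"] = tuple(cfg["head_sizes"])
        config = ModelConfig(**cfg)
        masks = {}
        for name, m in meta["masks"].items():
            values = np.zeros((len(m["rows"]), len(m["cols"])))
            for i, j in m["triplets"]:
                values[i, j] = 1.0
            masks[name] = MaskMatrix(m["rows"], m["cols"], values)
        model = build_model(meta["kind"], config,
                            gene_feature_mask=masks.get("gene_feature"),
                            gene_pathway_mask=masks.get("gene_pathway"))
        by_name = {p.name: p for p in model.params()}
        if set(by_name) != set(meta["param_names"]):
            raise ValueError("checkpoint parameter names do not match rebuilt model")
        for name in meta["param_names"]:
            buf = io.BytesIO(zf.read(f"params/{name}.npy"))
            value = np.load(buf, allow_pickle=False)
            if value.shape != by_name[name].value.shape:
                raise ValueError(f"checkpoint parameter {name} has shape {value.shape}")
            by_name[name].value = value
            by_name[name].grad = np.zeros_like(value)
    return model
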