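"""SmoothGrad pathway-importance attribution.

The pathway tier is the model's interpretable bottleneck: the gradient of
the prediction with respect to the s pathway activations says how much
each signaling pathway drives the predicted drug response at a given
input.  SmoothGrad de-noises this saliency by averaging the gradient over
many Gaussian-perturbed copies of the input.  Per-sample importance
vectors over all test folds are pooled into per-pathway score
distributions (box/violin-ready summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import ModelState

__all__ = [
    "SmoothGradConfig",
    "ImportanceMatrix",
    "pathway_gradient",
    "smoothgrad_importance",
    "importance_matrix",
    "pool_importance",
    "input_ranges",
]


@dataclass
class SmoothGradConfig:
    """SmoothGrad hyperparameters.

    ``noise_scale`` is a fraction of the per-dimension input range (the
    range is computed on the training split only, to avoid test-set
    leakage).  ``perturb`` chooses where noise is injected: at the input
    layer (default) or directly at the pathway activations.
    """

    n_noisy: int = 50
    noise_scale: float = 0.10
    seed: int = 0
    perturb: str = "input"

    def __post_init__(self) -> None:
        if self.n_noisy < 1:
            raise ValueError("n_noisy must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.perturb not in ("input", "pathway"):
            raise ValueError(f"perturb must be input|pathway, got {self.perturb!r}")


@dataclass
class ImportanceMatrix:
    """samples x pathways attribution scores with sample provenance."""

    pathway_order: list[str]
    values: np.ndarray
    provenance: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.pathway_order):
            raise ValueError(f"importance width {self.values.shape[1]} != "
                             f"{len(self.pathway_order)} pathways")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite importance scores")
        if self.provenance and len(self.provenance) != self.values.shape[0]:
            raise ValueError("provenance length does not match sample count")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.pathway_order)
        if self.provenance:
            frame.insert(0, "drug", [p[0] for p in self.provenance])
            frame.insert(1, "cell_line", [p[1] for p in self.provenance])
            frame.insert(2, "fold", [p[2] for p in self.provenance])
        return frame


def _head_gradient(model: ModelState, p_batch: np.ndarray) -> np.ndarray:
    """d(prediction)/d(pathway activations), one row per sample."""
    out = model.head.forward(p_batch, train=False)
    return model.head.backward(np.ones_like(out))


def pathway_gradient(model: ModelState, x: np.ndarray) -> np.ndarray:
    """Gradient of the prediction w.r.t. the s pathway activations at x."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    p = model.pathway_activations(np.atleast_2d(x))
    grad = _head_gradient(model, p)
    return grad[0] if single else grad


def input_ranges(X_train: np.ndarray) -> np.ndarray:
    """Per-dimension input range (max - min) over the training split."""
    X_train = np.atleast_2d(X_train)
    return X_train.max(axis=0) - X_train.min(axis=0)


def smoothgrad_importance(model: ModelState,
                          x: np.ndarray,
                          cfg: SmoothGradConfig,
                          ranges: np.ndarray | None = None) -> np.ndarray:
    """Mean pathway gradient over ``n_noisy`` noise-perturbed copies of x.

    Noise is i.i.d. Gaussian with per-dimension standard deviation
    ``noise_scale * range_d``.  With ``noise_scale=0`` and ``n_noisy=1``
    this equals the plain pathway gradient exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("smoothgrad_importance takes one sample vector")
    rng = np.random.default_rng(cfg.seed)
    if cfg.perturb == "input":
        if ranges is None:
            ranges = np.zeros_like(x) if cfg.noise_scale == 0 else None
        if ranges is None:
            raise ValueError("input-layer perturbation needs per-dimension ranges")
        sd = cfg.noise_scale * np.asarray(ranges, dtype=float)
        noisy = x[None, :] + rng.standard_normal((cfg.n_noisy, x.size)) * sd
        p = model.pathway_activations(noisy)
    else:
        p0 = model.pathway_activations(x[None, :])
        p_ranges = np.zeros(p0.shape[1]) if ranges is None else np.asarray(ranges)
        sd = cfg.noise_scale * p_ranges
        p = p0 + rng.standard_normal((cfg.n_noisy, p0.shape[1])) * sd
    return _head_gradient(model, p).mean(axis=0)


def importance_matrix(model: ModelState,
                      X: np.ndarray,
                      cfg: SmoothGradConfig,
                      ranges: np.ndarray | None = None,
                      provenance: Sequence[tuple[str, str, int]] | None = None
                      ) -> ImportanceMatrix:
    """SmoothGrad importance for every row of X (one seed stream per sample)."""
    X = np.atleast_2d(X)
    rows = [smoothgrad_importance(
        model, X[i],
        SmoothGradConfig(cfg.n_noisy, cfg.noise_scale, cfg.seed + i, cfg.perturb),
        ranges=ranges)
        for i in range(X.shape[0])]
    return ImportanceMatrix(list(model.pathway_order), np.vstack(rows),
                            list(provenance) if provenance else [])


def pool_importance(per_sample: ImportanceMatrix,
                    absolute: bool = False) -> pd.DataFrame:
    """Per-pathway distribution summary pooled over all samples.

    Returns a tidy table with min, quartiles, max, mean and mean absolute
    score per pathway.  Signed scores are summarized by default
    (importance distributions span negative and positive ranges);
    ``absolute=True`` pools |score| instead.
    """
    values = np.abs(per_sample.values) if absolute else per_sample.values
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    return pd.DataFrame({
        "pathway": per_sample.pathway_order,
        "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
        "mean": values.mean(axis=0),
        "mean_abs": np.abs(per_sample.values).mean(axis=0),
    })
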