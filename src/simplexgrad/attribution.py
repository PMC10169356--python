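"""Gradient-based attribution methods.

All four methods consume the predictor contract (``input_gradient``) and
return raw (L, A) maps with no post-processing, so the simplex correction
can be studied as a separate step.  Defaults follow common practice for
genomic sequence models: 20 interpolation points for integrated gradients,
25 noise samples at sigma 0.1 for SmoothGrad, 10 shuffled references for
expected gradients.

On a linear scorer f(x) = sum(w * x) every method collapses to a closed
form (the module's universal oracle): saliency and SmoothGrad give w,
integrated gradients gives w * x, expected gradients gives
w * (x - mean reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttributionConfig:
    """Method hyperparameters; ``seed`` drives SmoothGrad noise and reference shuffles."""

    method: str = "saliency"
    ig_steps: int = 20
    ig_quadrature: str = "left"  # {"left", "trapezoid"}
    sg_samples: int = 25
    sg_sigma: float = 0.1
    eg_references: int = 10
    output: str = "logit"  # {"logit", "prob"}
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ig_steps, self.sg_samples, self.eg_references) < 1:
            raise ValueError("step/sample/reference counts must be >= 1")
        if self.sg_sigma <= 0:
            raise ValueError("sg_sigma must be positive")
        if self.method not in ("saliency", "integrated_gradients", "smoothgrad", "expected_gradients"):
            raise ValueError(f"unknown attribution method {self.method!r}")


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ValueError(f"expected (L, A) or (N, L, A) input, got shape {x.shape}")


def saliency(model, x, config: AttributionConfig | None = None) -> np.ndarray:
    """Raw input gradient of the model output."""
    config = config or AttributionConfig()
    xb, single = _as_batch(x)
    g = model.input_gradient(xb, output=config.output)
    return g[0] if single else g


def integrated_gradients(
    model, x, config: AttributionConfig | None = None, baseline: np.ndarray | None = None
) -> np.ndarray:
    """Path integral of gradients from a baseline (default all-zeros) to x.

    Approximated by a Riemann sum over ``ig_steps`` interpolation points and
    scaled elementwise by (x - baseline); the completeness residual
    |sum(attr) - (f(x) - f(baseline))| shrinks as steps grow.
    """
    config = config or AttributionConfig()
    xb, single = _as_batch(x)
    base = np.zeros_like(xb) if baseline is None else np.broadcast_to(
        np.asarray(baseline, dtype=float), xb.shape
    )
    m = config.ig_steps
    if config.ig_quadrature == "trapezoid":
        alphas = np.linspace(0.0, 1.0, m + 1)
        weights = np.full(m + 1, 1.0 / m)
        weights[[0, -1]] = 0.5 / m
    elif config.ig_quadrature == "left":
        alphas = np.arange(m) / m
        weights = np.full(m, 1.0 / m)
    else:
        raise ValueError(f"unknown quadrature {config.ig_quadrature!r}")
    total = np.zeros_like(xb)
    for a, w in zip(alphas, weights):
        total += w * model.input_gradient(base + a * (xb - base), output=config.output)
    attr = total * (xb - base)
    return attr[0] if single else attr


def smoothgrad(model, x, config: AttributionConfig | None = None) -> np.ndarray:
    """Mean saliency over Gaussian-perturbed copies of the input.

    Noise (zero-centered, sd ``sg_sigma``) is added to every entry of the
    one-hot matrix — deliberately off-simplex, with no renormalization.
    """
    config = config or AttributionConfig()
    xb, single = _as_batch(x)
    rng = np.random.default_rng(config.seed)
    total = np.zeros_like(xb)
    for _ in range(config.sg_samples):
        noisy = xb + rng.normal(0.0, config.sg_sigma, size=xb.shape)
        total += model.input_gradient(noisy, output=config.output)
    g = total / config.sg_samples
    return g[0] if single else g


def _shuffle_positions(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute positions independently per sequence; preserves composition."""
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = x[i, rng.permutation(x.shape[1]), :]
    return out


def expected_gradients(model, x, config: AttributionConfig | None = None) -> np.ndarray:
    """Integrated gradients averaged over shuffled-sequence references.

    Each reference is a positionwise (mononucleotide) shuffle of the query,
    so it has the same nucleotide composition; ``ig_steps`` interpolation
    points are used per reference.
    """
    config = config or AttributionConfig()
    xb, single = _as_batch(x)
    rng = np.random.default_rng(config.seed)
    total = np.zeros_like(xb)
    for _ in range(config.eg_references):
        ref = _shuffle_positions(xb, rng)
        total += integrated_gradients(model, xb, config, baseline=ref)
    attr = total / config.eg_references
    return attr[0] if single else attr


_METHODS = {
    "saliency": saliency,
    "integrated_gradients": integrated_gradients,
    "smoothgrad": smoothgrad,
    "expected_gradients": expected_gradients,
}


def attribute(model, x, config: AttributionConfig) -> np.ndarray:
    """Dispatch on ``config.method``."""
    return _METHODS[config.method](model, x, config)
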