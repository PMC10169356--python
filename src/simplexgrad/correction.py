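"""Projection of attribution maps onto the categorical data simplex.

One-hot sequences satisfy a per-position sum-to-one constraint, so the data
support is (a translate of) the zero-sum hyperplane {v : sum(v) = 0} in each
position's A-dimensional category space.  The component of an input gradient
along the simplex normal n = (1/sqrt(A))(1, ..., 1) is unconstrained by data
and treated as noise.  The correction removes it:

    G_corrected[l, a] = G[l, a] - mean_a G[l, a]

which is exactly the orthogonal projection of each gradient row onto the
zero-sum hyperplane.  This module also quantifies the discarded component:
its magnitude, the signed angle between each gradient row and the simplex
plane, exceedance fractions over angle thresholds, and a differentiable
penalty usable as a training regularizer.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AngleProfile, AttributionMap


def _validate_scores(x) -> np.ndarray:
    """Return scores as a float ndarray with categories on the last axis."""
    if isinstance(x, AttributionMap):
        return x.scores
    arr = np.asarray(x, dtype=float)
    if arr.ndim < 1 or arr.shape[-1] < 2:
        raise ValueError(f"expected an array with A >= 2 categories on the last axis, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("attribution scores contain non-finite entries")
    return arr


def _like(template, scores: np.ndarray):
    if isinstance(template, AttributionMap):
        return replace(template, scores=scores)
    return scores


def correct_attribution(attr):
    """Remove the off-simplex component of an attribution map.

    Subtracts, at every position, the mean score across the A categories.
    Accepts an :class:`AttributionMap` or any array whose last axis indexes
    categories (so batched (N, L, A) stacks work unchanged).  The input is
    not mutated; every output row sums to zero.
    """
    scores = _validate_scores(attr)
    corrected = scores - scores.mean(axis=-1, keepdims=True)
    return _like(attr, corrected)


def orthogonal_magnitude(attr) -> np.ndarray:
    """Per-position magnitude of the gradient component along the simplex normal.

    ||G_perp||_l = |sum_a G[l, a]| / sqrt(A), i.e. |G . n| with
    n = (1/sqrt(A))(1, ..., 1).  Non-negative by construction.
    """
    scores = _validate_scores(attr)
    a = scores.shape[-1]
    return np.abs(scores.sum(axis=-1)) / np.sqrt(a)


def signed_normal_component(attr) -> np.ndarray:
    """Signed projection G . n on the simplex normal (carries the angle sign)."""
    scores = _validate_scores(attr)
    a = scores.shape[-1]
    return scores.sum(axis=-1) / np.sqrt(a)


def gradient_angles(attr) -> AngleProfile:
    """Signed angle between each gradient row and the simplex plane.

    sin(alpha_l) = (G_l . n) / ||G_l||, reported in degrees in [-90, 90].
    Rows with zero norm have no direction; they are flagged invalid rather
    than assigned 0 degrees, so downstream exceedance fractions are not
    deflated by dead positions.
    """
    scores = _validate_scores(attr)
    if scores.ndim != 2:
        raise ValueError("gradient_angles expects a single (L, A) map")
    norms = np.linalg.norm(scores, axis=-1)
    valid = norms > 0
    comp = signed_normal_component(scores)
    sin_a = np.zeros_like(norms)
    np.divide(comp, norms, out=sin_a, where=valid)
    sin_a = np.clip(sin_a, -1.0, 1.0)
    angles = np.degrees(np.arcsin(sin_a))
    angles[~valid] = np.nan
    return AngleProfile(angles=angles, valid_mask=valid)


def angle_exceedance(profile: AngleProfile, thresholds: Iterable[float]) -> dict[float, float]:
    """Fraction of valid positions with |angle| above each threshold (degrees).

    Thresholds must lie in the open interval (0, 90).  Raises ``ValueError``
    if the profile has no valid positions (the fractions would be 0/0).
    """
    thresholds = [float(t) for t in thresholds]
    for t in thresholds:
        if not 0 < t < 90:
            raise ValueError(f"thresholds must lie in (0, 90) degrees, got {t}")
    if profile.n_valid == 0:
        raise ValueError("angle profile has no valid positions; exceedance undefined")
    mags = np.abs(profile.angles[profile.valid_mask])
    return {t: float(np.mean(mags > t)) for t in thresholds}


def off_simplex_penalty(attr, reduction: str = "mean") -> float:
    """Scalar penalty on the off-simplex gradient component.

    With the default ``reduction="mean"`` this is the mean over positions of
    the squared orthogonal magnitude, (1/L) sum_l (sum_a G[l,a])^2 / A.  It is
    zero iff every row has zero mean, and it is a differentiable (quadratic)
    function of the scores, so it can serve as a training-time regularizer
    that steers the learned function to align with the simplex.  ``"sum"``
    and ``"max"`` reductions are available.
    """
    scores = _validate_scores(attr)
    sq = orthogonal_magnitude(scores) ** 2
    if reduction == "mean":
        return float(sq.mean())
    if reduction == "sum":
        return float(sq.sum())
    if reduction == "max":
        return float(sq.max())
    raise ValueError(f"unknown reduction {reduction!r}; use 'mean', 'sum' or 'max'")


class GradientCorrector(BaseEstimator, TransformerMixin):
    """Transformer that projects attribution maps onto the data simplex.

    Stateless: :meth:`fit` only records the category count for validation.
    ``transform`` accepts a single (L, A) map, a batch (N, L, A), or a list
    of :class:`AttributionMap`; the off-simplex component is removed per
    position.  The operation is idempotent, linear, and norm-contracting per
    row.

    Examples
    --------
    >>> import numpy as np
    >>> GradientCorrector().fit_transform(np.array([[0.5, 0.1, -0.2, 0.2]]))
    array([[ 0.35, -0.05, -0.35,  0.05]])
    """

    def fit(self, X, y=None):
        first = X[0] if isinstance(X, (list, tuple)) else X
        self.n_categories_ = _validate_scores(first).shape[-1]
        return self

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return [correct_attribution(m) for m in X]
        return correct_attribution(X)

    def angle_profiles(self, X) -> list[AngleProfile]:
        """Angle diagnostics for a batch; one profile per map."""
        if isinstance(X, (list, tuple)):
            return [gradient_angles(m) for m in X]
        arr = _validate_scores(X)
        if arr.ndim == 2:
            return [gradient_angles(arr)]
        return [gradient_angles(m) for m in arr]

    def exceedance_summary(
        self, X, thresholds: Sequence[float] = (30.0, 45.0, 60.0)
    ) -> Mapping[float, float]:
        """Mean per-map exceedance fraction at each angle threshold."""
        profiles = self.angle_profiles(X)
        per_map = [angle_exceedance(p, thresholds) for p in profiles]
        return {t: float(np.mean([d[t] for d in per_map])) for t in thresholds}
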