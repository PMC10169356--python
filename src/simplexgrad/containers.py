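"""Lightweight array containers shared across the package.

Axis convention is fixed throughout: axis 0 is sequence position (length L),
axis 1 is the category/alphabet (size A, default DNA order A, C, G, T).
Positions are 0-based everywhere, including on-disk formats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")


def _as_matrix(scores, name: str = "scores") -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (L, A) array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 2:
        raise ValueError(f"{name} needs L >= 1 and A >= 2, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class AttributionMap:
    """Per-position, per-category importance scores for one sequence.

    ``scores`` is an (L, A) real matrix; for a saliency map it is the raw
    gradient of the model output with respect to the one-hot input.
    """

    scores: np.ndarray
    alphabet: tuple[str, ...] = DNA_ALPHABET
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.scores = _as_matrix(self.scores)
        self.alphabet = tuple(self.alphabet)
        if len(self.alphabet) != self.scores.shape[1]:
            raise ValueError(
                f"alphabet size {len(self.alphabet)} does not match A={self.scores.shape[1]}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def n_categories(self) -> int:
        return self.scores.shape[1]


@dataclass
class AngleProfile:
    """Signed per-position angle (degrees) between the gradient and the simplex plane.

    ``angles[l]`` is in [-90, 90]; the sign follows the sign of the projection
    of the gradient row on the simplex normal (1/sqrt(A))(1, ..., 1).
    ``valid_mask[l]`` is False where the gradient row is the zero vector, in
    which case the angle is undefined (stored as NaN).
    """

    angles: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.angles.shape != self.valid_mask.shape or self.angles.ndim != 1:
            raise ValueError("angles and valid_mask must be matching 1-D arrays")
        valid = self.angles[self.valid_mask]
        if valid.size and (np.any(np.abs(valid) > 90 + 1e-9) or not np.all(np.isfinite(valid))):
            raise ValueError("valid angles must be finite and within [-90, 90] degrees")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class GroundTruthMatrix:
    """Per-position nucleotide probabilities with embedded motif columns.

    Rows are probability vectors; background positions are uniform (0.25 for
    DNA), so their information content is exactly zero.
    """

    probs: np.ndarray
    alphabet: tuple[str, ...] = DNA_ALPHABET

    def __post_init__(self) -> None:
        self.probs = _as_matrix(self.probs, "probs")
        self.alphabet = tuple(self.alphabet)
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each row of a ground-truth matrix must sum to 1")
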