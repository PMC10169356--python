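"""Scoring attribution maps against ground truth and ensemble proxies.

With base-resolution ground truth (the generating probability matrix M),
three similarity metrics are computed per sequence:

* cosine similarity between the flattened attribution map and M - 1/A
  (subtracting the uniform background zeroes out uninformative positions);
* interpretability AUROC and AUPR, which rank per-position grad-times-input
  scores C_i = sum_j S_ij X_ij at motif positions (information content
  I_i > 0.1 bits) against background positions (I_i = 0).

Without ground truth, an ensemble-averaged map serves as a proxy and the
per-position *ensemble difference reduction*
1 - ||after - ensemble|| / ||before - ensemble|| quantifies whether the
correction moved a map toward the proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import AttributionMap, GroundTruthMatrix


class UndefinedMetricError(ValueError):
    """A metric has no defined value for this input (e.g. no positive class)."""


def _scores(x) -> np.ndarray:
    if isinstance(x, AttributionMap):
        return x.scores
    if isinstance(x, GroundTruthMatrix):
        return x.probs
    return np.asarray(x, dtype=float)


def cosine_similarity(attr, gt) -> float:
    """Cosine between the flattened map and the centered ground truth (M - 1/A).

    Computed on the full (L, A) map.  Raises :class:`UndefinedMetricError`
    when either vector has zero norm (no motifs embedded, or an all-zero
    attribution map).
    """
    a = _scores(attr).reshape(-1)
    m = _scores(gt)
    centered = (m - 1.0 / m.shape[-1]).reshape(-1)
    if a.shape != centered.shape:
        raise ValueError(f"shape mismatch: {_scores(attr).shape} vs {m.shape}")
    na, nm = np.linalg.norm(a), np.linalg.norm(centered)
    if nm == 0:
        raise UndefinedMetricError("ground truth has no embedded motifs (zero norm)")
    if na == 0:
        raise UndefinedMetricError("attribution map has zero norm")
    return float(np.dot(a, centered) / (na * nm))


def motif_cosine_similarity(attr, gt, min_info: float = 0.0) -> float:
    """Cosine restricted to positions with information content above ``min_info``."""
    m = _scores(gt)
    keep = information_content(gt) > min_info
    if not keep.any():
        raise UndefinedMetricError("no positions above the information threshold")
    return cosine_similarity(_scores(attr)[keep], GroundTruthMatrix(probs=m[keep]))


def grad_times_input(attr, x) -> np.ndarray:
    """Per-position score of the observed nucleotide: C_i = sum_j S_ij X_ij."""
    s = _scores(attr)
    xo = np.asarray(x, dtype=float)
    if s.shape != xo.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {xo.shape}")
    if not (np.all((xo == 0) | (xo == 1)) and np.all(xo.sum(axis=-1) == 1)):
        raise ValueError("x must be one-hot (exactly one 1 per position)")
    return (s * xo).sum(axis=-1)


def information_content(gt) -> np.ndarray:
    """I_i = log2(A) - H(M_i) in bits, with 0 log 0 = 0; uniform rows give exactly 0."""
    m = _scores(gt)
    if np.any(m < 0) or not np.allclose(m.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("ground-truth rows must be probability vectors")
    a = m.shape[-1]
    return np.log2(a) - _entropy(m, base=2, axis=-1)


def interpretability_curves(
    C: np.ndarray, I: np.ndarray, threshold: float = 0.1
) -> tuple[float, float]:
    """Per-sequence (AUROC, AUPR) of grad-times-input at motif vs background positions.

    Positives are positions with I > ``threshold`` bits; negatives have
    I == 0; positions with 0 < I <= threshold belong to neither class and
    are excluded.  AUROC uses midrank tie handling; AUPR is the step-wise
    precision-recall integral (average precision).
    """
    C = np.asarray(C, dtype=float).reshape(-1)
    I = np.asarray(I, dtype=float).reshape(-1)
    if C.shape != I.shape:
        raise ValueError("C and I must have the same length")
    pos = I > threshold
    neg = I == 0
    if pos.sum() < 1 or neg.sum() < 1:
        raise UndefinedMetricError("need at least one positive and one negative position")
    keep = pos | neg
    y = pos[keep].astype(int)
    scores = C[keep]
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))


def ensemble_difference_reduction(before, after, ensemble_mean) -> np.ndarray:
    """Per-position 1 - ||after - ens|| / ||before - ens||; NaN where the before-distance is 0.

    Positive values mean the correction moved the map toward the ensemble
    proxy at that position.
    """
    b, a, e = _scores(before), _scores(after), _scores(ensemble_mean)
    if not (b.shape == a.shape == e.shape):
        raise ValueError("before, after and ensemble maps must share a shape")
    d_before = np.linalg.norm(b - e, axis=-1)
    d_after = np.linalg.norm(a - e, axis=-1)
    out = np.full(d_before.shape, np.nan)
    np.divide(d_after, d_before, out=out, where=d_before > 0)
    return 1.0 - out


def sequence_report(attr, x, gt, threshold: float = 0.1) -> dict[str, float]:
    """All ground-truth metrics for one (map, sequence, ground truth) triple."""
    C = grad_times_input(attr, x)
    I = information_content(gt)
    auroc, aupr = interpretability_curves(C, I, threshold)
    return {"cosine": cosine_similarity(attr, gt), "auroc": auroc, "aupr": aupr}


def evaluate_maps(maps: np.ndarray, X: np.ndarray, M: np.ndarray, threshold: float = 0.1) -> pd.DataFrame:
    """Per-sequence metric table for a batch of maps; undefined sequences are dropped."""
    rows = []
    for i in range(len(maps)):
        try:
            rows.append({"sequence": i, **sequence_report(maps[i], X[i], M[i], threshold)})
        except UndefinedMetricError:
            continue
    return pd.DataFrame(rows)


def improvement_summary(reports_before: pd.DataFrame, reports_after: pd.DataFrame) -> pd.DataFrame:
    """Paired after-minus-before deltas of every metric column, aggregated.

    Inputs must be index-aligned tables from :func:`evaluate_maps` (one row
    per sequence, optionally with grouping columns such as trial/model/
    method, which are carried through).  Returns one row per group with
    mean and median deltas.
    """
    if len(reports_before) != len(reports_after):
        raise ValueError("before/after reports are not paired (different lengths)")
    metrics = [c for c in ("cosine", "auroc", "aupr") if c in reports_before.columns]
    if not metrics:
        raise ValueError("no metric columns found")
    keys = [c for c in reports_before.columns if c not in metrics]
    if not reports_before[keys].reset_index(drop=True).equals(
        reports_after[keys].reset_index(drop=True)
    ):
        raise ValueError("before/after reports are not paired (key columns differ)")
    deltas = reports_after[metrics].reset_index(drop=True) - reports_before[metrics].reset_index(
        drop=True
    )
    group_cols = [c for c in keys if c not in ("sequence",)]
    table = pd.concat([reports_before[group_cols].reset_index(drop=True), deltas], axis=1)
    if group_cols:
        agg = table.groupby(group_cols)[metrics].agg(["mean", "median"])
        agg.columns = [f"delta_{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()
    stats = table[metrics].agg(["mean", "median"])
    return pd.DataFrame(
        {f"delta_{m}_{s}": [stats.loc[s, m]] for m in metrics for s in ("mean", "median")}
    )
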