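"""Optional matplotlib figures: angle diagnostics and improvement-vs-AUC scatter."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .containers import AngleProfile  # noqa: E402


def angle_histogram(profiles: list[AngleProfile], ax=None, bins: int = 90):
    """Histogram of signed gradient angles pooled over maps (typically zero-centered)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    angles = np.concatenate([p.angles[p.valid_mask] for p in profiles])
    ax.hist(angles, bins=bins, range=(-90, 90), density=True, color="#4878d0")
    ax.set_xlabel("gradient angle to simplex plane (degrees)")
    ax.set_ylabel("density")
    ax.set_xlim(-90, 90)
    return ax


def exceedance_histogram(fractions: pd.DataFrame, ax=None):
    """Per-map exceedance fractions at each threshold (columns ``frac_gt_*``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cols = [c for c in fractions.columns if c.startswith("frac_gt_")]
    for col in cols:
        ax.hist(100 * fractions[col], bins=30, alpha=0.6, label=col.replace("frac_gt_", "> "))
    ax.set_xlabel("% positions per map above threshold")
    ax.set_ylabel("maps")
    ax.legend(frameon=False)
    return ax


def improvement_scatter(report: pd.DataFrame, metric: str = "cosine", ax=None):
    """Per-trial improvement (after - before) against classification AUC.

    Expects the benchmark ``report`` table plus a ``test_auc`` column merged in,
    or any frame with columns [test_auc, delta_<metric>].
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    ycol = f"delta_{metric}" if f"delta_{metric}" in report.columns else metric
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.scatter(report["test_auc"], report[ycol], s=18, alpha=0.8)
    ax.set_xlabel("classification AUC")
    ax.set_ylabel(f"{metric} improvement after correction")
    return ax
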