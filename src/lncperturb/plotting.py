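"""Minimal plotting helpers for the core-gene heatmap matrix."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_heatmap(matrix: pd.DataFrame, path: str | Path | None = None):
    """Render the IFN-response / perturbation-effect log2FC matrix.

    Red marks positive log2 fold changes (up-regulation, or a stronger
    response in the perturbed line), blue negative.  Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.empty:
        raise ValueError("nothing to plot: empty matrix")
    vals = matrix.to_numpy(float)
    lim = float(np.nanmax(np.abs(vals))) or 1.0
    fig, ax = plt.subplots(
        figsize=(0.45 * matrix.shape[1] + 2.5, 0.22 * matrix.shape[0] + 1.5)
    )
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2FC")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
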