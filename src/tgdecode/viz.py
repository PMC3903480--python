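"""Heatmap rendering of temporal generalization matrices."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)  # noqa: E402  (headless-safe default)
import matplotlib.pyplot as plt
from matplotlib.colors import TwoSlopeNorm

from .tgm import TGMatrix


def plot_tgm(
    tgm: TGMatrix | np.ndarray,
    times: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    ax: "plt.Axes | None" = None,
    cmap: str = "RdBu_r",
    vmin: float = 0.0,
    vmax: float = 1.0,
    title: str | None = None,
):
    """Plot a generalization matrix as a chance-centered heatmap.

    Training time runs along the vertical axis and testing time along the
    horizontal axis; the diverging colormap is centered on AUC = 0.5 so red
    cells are above chance and blue below.  If ``mask`` is given,
    non-significant cells are dimmed.
    """
    if isinstance(tgm, TGMatrix):
        mat = tgm.auc
        times = tgm.train_times if times is None else times
    else:
        mat = np.asarray(tgm)
        if times is None:
            times = np.arange(mat.shape[0])
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    extent = (times[0], times[-1], times[-1], times[0])
    norm = TwoSlopeNorm(vcenter=0.5, vmin=vmin, vmax=vmax)
    shown = mat.copy()
    im = ax.imshow(shown, extent=extent, norm=norm, cmap=cmap, aspect="auto")
    if mask is not None:
        dim = np.where(mask, np.nan, 0.35)
        ax.imshow(
            dim, extent=extent, cmap="gray", vmin=0, vmax=1, alpha=0.5,
            aspect="auto",
        )
    ax.set_xlabel("testing time (s)")
    ax.set_ylabel("training time (s)")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="AUC")
    return ax
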