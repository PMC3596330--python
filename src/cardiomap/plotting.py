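"""Figure export: isochronal activation maps in the conventional style
(color-coded activation time, labelled isochrone contours)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activation_mapping import ActivationMap


def plot_activation_map(
    amap: ActivationMap,
    path,
    *,
    isochrone_spacing_ms: float = 5.0,
    title: str | None = None,
) -> Path:
    """Render an activation map with isochrones and save it as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = amap.t_act_ms
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(t, origin="upper", cmap="turbo")
    tmin, tmax = np.nanmin(t), np.nanmax(t)
    levels = np.arange(np.ceil(tmin / isochrone_spacing_ms),
                       tmax / isochrone_spacing_ms) * isochrone_spacing_ms
    if levels.size:
        cs = ax.contour(np.where(np.isnan(t), tmax + 1e3, t), levels=levels,
                        colors="k", linewidths=0.6)
        ax.clabel(cs, fmt="%.0f", fontsize=7)
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    ax.set_xlabel("pixel (col)")
    ax.set_ylabel("pixel (row)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path
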