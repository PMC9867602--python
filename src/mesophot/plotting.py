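"""PNG rendering of maps and motif montages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def render_map_png(path, values, valid=None, title="", cmap="viridis", vmin=None, vmax=None):
    """Render a per-pixel map; invalid / below-threshold pixels are gray."""
    img = np.array(values, dtype=float)
    if valid is not None:
        img[~valid] = np.nan
    fig, ax = plt.subplots(figsize=(4, 4))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(color="0.6")
    im = ax.imshow(img, cmap=cm, vmin=vmin, vmax=vmax)
    ax.set_title(title)
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def motif_montage_png(path, motifs, k: int, n_cols: int = 8):
    """L frames of motif k, left to right then top to bottom (1 s total at 40 Hz)."""
    if motifs.mask is None:
        raise ValueError("MotifSet has no mask; cannot render frames")
    L = motifs.L
    n_rows = int(np.ceil(L / n_cols))
    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(1.2 * n_cols, 1.2 * n_rows), squeeze=False
    )
    vmax = motifs.W[:, k, :].max() or 1.0
    for l in range(n_rows * n_cols):
        ax = axes[l // n_cols][l % n_cols]
        ax.axis("off")
        if l >= L:
            continue
        frame = np.full(motifs.mask.shape, np.nan)
        frame[motifs.mask] = motifs.W[:, k, l]
        ax.imshow(frame, vmin=0, vmax=vmax, cmap="inferno")
    fig.suptitle(f"motif {k}")
    fig.savefig(path, dpi=80, bbox_inches="tight")
    plt.close(fig)
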