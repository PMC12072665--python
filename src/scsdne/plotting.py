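"""Optional dot-plot of interaction calls (size = -log10 p, color = score)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .io import InteractionCall

__all__ = ["dotplot"]


def dotplot(calls: Sequence[InteractionCall], path: str | Path, max_pairs: int = 40):
    """Save a ligand-receptor dot plot; one row per pair, one column per receiver.

    Point size encodes -log10 of the p-value (zero p drawn at the plot's
    resolution floor), colour encodes the crosstalk score.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sorted(calls, key=lambda c: (c.p_value, c.latent_distance))[:max_pairs]
    if not rows:
        raise ValueError("no calls to plot")
    labels = [f"{c.ligand} → {c.receptor}" for c in rows]
    receivers = sorted({c.receiver for c in rows})
    col = {r: i for i, r in enumerate(receivers)}
    floor = 1.0 / max(len(rows), 20)
    logp = [-np.log10(max(c.p_value, floor / 10)) for c in rows]
    fig, ax = plt.subplots(figsize=(2 + 1.2 * len(receivers), 1 + 0.28 * len(rows)))
    sc = ax.scatter(
        [col[c.receiver] for c in rows],
        range(len(rows)),
        s=[30 * v + 5 for v in logp],
        c=[c.crosstalk_score for c in rows],
        cmap="viridis",
        vmin=0,
        vmax=1,
    )
    ax.set_xticks(range(len(receivers)), receivers)
    ax.set_yticks(range(len(rows)), labels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlim(-0.5, len(receivers) - 0.5)
    fig.colorbar(sc, ax=ax, label="crosstalk score")
    ax.set_title("ligand-receptor calls")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
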