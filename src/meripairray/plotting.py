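"""Nine-quadrant scatter plot (methylation vs expression log2 fold change)."""

from __future__ import annotations

import numpy as np

_MODE_COLOURS = {
    "hyper-up": "#d62728",
    "hypo-down": "#2ca02c",
    "hyper-down": "#9467bd",
    "hypo-up": "#1f77b4",
    "none": "#bbbbbb",
}


def plot_nine_quadrant(quadrants, fc_cutoff_conjoint=2.0, biotype="mRNA", ax=None):
    """Scatter transcripts in the methylation x expression log2FC plane.

    Dashed lines mark the conjoint gates at +/- log2(fold-change cutoff);
    concordant modes are highlighted in red (hyper-up) and green (hypo-down).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = quadrants[quadrants["biotype"] == biotype]
    for mode, colour in _MODE_COLOURS.items():
        sel = sub[sub["mode"] == mode]
        if sel.empty:
            continue
        ax.scatter(
            sel["meth_log2fc"],
            sel["expr_log2fc"],
            s=6,
            c=colour,
            label=f"{mode} ({len(sel)})",
            alpha=0.6,
            linewidths=0,
        )
    gate = np.log2(fc_cutoff_conjoint)
    for v in (-gate, gate):
        ax.axvline(v, ls="--", lw=0.8, c="0.4")
        ax.axhline(v, ls="--", lw=0.8, c="0.4")
    ax.set_xlabel("methylation log2 fold change (sci / sham)")
    ax.set_ylabel("expression log2 fold change (sci / sham)")
    ax.set_title(f"nine-quadrant conjoint analysis ({biotype})")
    ax.legend(fontsize=7, loc="best")
    return ax
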