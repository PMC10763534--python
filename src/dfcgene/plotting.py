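"""Small plotting helpers: contrast-vs-PC scatter and per-region curves."""

from __future__ import annotations

import numpy as np

from .association import AssociationResult, ContrastVector


def contrast_scatter(contrast: ContrastVector, pc_scores, result: AssociationResult, ax=None):
    """Scatter of z-scored contrast vs z-scored PC-1 scores with the fit line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    x = np.asarray(pc_scores, dtype=float)
    y = np.asarray(contrast.values, dtype=float)
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    ax.scatter(xz, yz, s=14, alpha=0.7)
    slope = result.r  # both axes are z-scored
    xs = np.linspace(xz.min(), xz.max(), 2)
    ax.plot(xs, slope * xs, color="crimson")
    ax.set_xlabel(f"PC-1 score (z), {result.gene_set}")
    ax.set_ylabel(f"{'/'.join(result.pair)} contrast in {result.metric} (z)")
    ax.set_title(f"r = {result.r:.3f}, p = {result.p:.2g}")
    return ax


def centrality_curves(profiles: dict, metric: str, ax=None):
    """Per-region group-average centrality curves, one line per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for (group, m), profile in sorted(profiles.items()):
        if m != metric:
            continue
        ax.plot(profile.values, label=group, lw=1)
    ax.set_xlabel("region index")
    ax.set_ylabel(metric)
    ax.legend()
    return ax
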