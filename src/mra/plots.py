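"""Generic diagnostic plots: volcano of a differential MR table and an
activity heatmap with phenotype annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PhenotypeLabels


def volcano(stats_df: pd.DataFrame, fdr_threshold: float = 0.05, ax=None):
    """Effect vs -log10(p), significant TRs highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    p = stats_df["p"].clip(lower=1e-300)
    sig = stats_df.get("fdr", p) <= fdr_threshold
    ax.scatter(stats_df["effect"][~sig], -np.log10(p[~sig]), s=8, c="grey", alpha=0.6)
    ax.scatter(stats_df["effect"][sig], -np.log10(p[sig]), s=10, c="crimson")
    ax.set_xlabel("activity difference (HIGH - LOW)")
    ax.set_ylabel("-log10 p")
    return ax


def activity_heatmap(act: pd.DataFrame, labels: PhenotypeLabels, ax=None):
    """TR x sample activity heatmap, samples grouped by phenotype class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = labels.high_samples + labels.samples_of("MEDIUM") + labels.low_samples
    order = [s for s in order if s in act.columns]
    v = act[order].to_numpy()
    lim = np.abs(v).max() or 1.0
    im = ax.imshow(v, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xlabel("samples (HIGH → LOW)")
    ax.set_ylabel("regulators")
    ax.figure.colorbar(im, ax=ax, label="activity")
    return ax
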