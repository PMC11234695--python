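"""Basic summary figures for scan results."""

from __future__ import annotations

import numpy as np

from .association import MlmaResult


def plot_manhattan(result: MlmaResult, ax=None, highlight: set[str] | None = None,
                   threshold: float | None = None):
    """Manhattan-style plot of -log10(p) against position for one scan.

    ``highlight`` marks a variant id set (e.g. the core haplotype) in a
    second colour; ``threshold`` draws the significance line. Returns the
    matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = result.summary_table.tested()
    logp = -np.log10(t["p"].to_numpy())
    pos = t["pos"].to_numpy() / 1e6
    ax.scatter(pos, logp, s=6, c="#4878a8", linewidths=0)
    if highlight:
        mask = t["id"].isin(highlight).to_numpy()
        ax.scatter(pos[mask], logp[mask], s=14, c="#2ca02c", linewidths=0,
                   label="highlighted")
    thr = threshold if threshold is not None else result.threshold
    if thr is not None:
        ax.axhline(-np.log10(thr), color="crimson", lw=0.8, ls="--")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(result.phenotype)
    return ax
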