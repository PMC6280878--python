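"""Basic profile and network plots."""

from __future__ import annotations

import numpy as np


def plot_profiles(summary, pde=None, species: str = "N", ax=None):
    """Column-averaged CA profiles over time, optionally overlaid with a
    PDE solution (dash-dot), one curve per recording time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = summary.N if species == "N" else summary.E
    for r, t in enumerate(summary.times):
        ax.plot(summary.x_grid, data[r], "k-", lw=1)
    if pde is not None:
        pdata = pde.N if species == "N" else pde.E
        for r in range(pde.times.size):
            ax.plot(pde.x_grid, pdata[r], "b-.", lw=1)
    ax.set_xlabel("x")
    ax.set_ylabel(f"{species}(x, t)")
    return ax


def plot_network(tc_grid, ec_grid, ax=None):
    """Scatter of one CA realization: ECs as red dots, TCs as blue circles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ei, ej = np.nonzero(ec_grid)
    ti, tj = np.nonzero(tc_grid)
    ax.plot(ei, ej, ".", color="red", ms=2, label="EC")
    ax.plot(ti, tj, "o", mfc="none", color="tab:blue", ms=4, label="TC")
    ax.set_xlabel("i")
    ax.set_ylabel("j")
    ax.legend(loc="upper right")
    return ax
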