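"""Optional diagnostic plots (matplotlib)."""

from __future__ import annotations

import numpy as np

from .validation import RATIO_CAP, DispersionRatios


def plot_dispersion_ratios(ratios: DispersionRatios, dimension: str = "mz",
                           ax=None, bins: int = 20):
    """Histogram of capped dispersion ratios for one dimension.

    Ratios below 1 (left, light) favour the numerator algorithm; ratios
    above 1 (right, dark) favour the denominator.  Ratios above 2 are
    stacked into the last bin.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = getattr(ratios, dimension)
    values = frame["capped"].to_numpy()
    edges = np.linspace(0.0, RATIO_CAP, bins + 1)
    ax.hist(values[values < 1.0], bins=edges, color="0.8", edgecolor="0.4",
            label="ratio < 1")
    ax.hist(values[values > 1.0], bins=edges, color="0.4", edgecolor="0.2",
            label="ratio > 1")
    ax.set_xlabel(f"dispersion ratio ({dimension}), capped at {RATIO_CAP:g}")
    ax.set_ylabel("peptides")
    ax.legend()
    return ax


def plot_iteration_histogram(iteration_counts, ax=None):
    """Frequency of annealing iterations needed per grown cluster."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    counts = np.asarray(iteration_counts)
    ax.hist(counts, bins=np.arange(0.5, counts.max() + 1.5), color="0.5",
            edgecolor="black")
    ax.set_xlabel("annealing iterations")
    ax.set_ylabel("clusters")
    return ax
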