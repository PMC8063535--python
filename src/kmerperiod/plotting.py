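"""Three-panel summary plot of a periodicity quantification run."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectral import to_frequency_histogram
from .stats import PeriodicityResult

__all__ = ["plot_periodicity"]


def plot_periodicity(
    result: PeriodicityResult,
    path=None,
    xlim: float | None = 150,
    fdr_threshold: float = 0.05,
):
    """Distogram frequencies, normalized signal, and PSD vs. the null band.

    Left: frequency histogram of pairwise motif distances. Middle: the
    smoothed, detrended signal the FFT sees. Right: observed PSD per period
    (line) over the 2.5–97.5% envelope of the shuffled-null PSDs (ribbon);
    points significant at fdr < ``fdr_threshold`` are filled.
    """
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.4), constrained_layout=True)
    dist = np.arange(1, result.distogram.max_distance + 1)

    ax = axes[0]
    ax.plot(dist, to_frequency_histogram(result.distogram), lw=0.8, color="0.2")
    ax.set_xlabel("pairwise distance (bp)")
    ax.set_ylabel("frequency")
    ax.set_title("distogram")

    ax = axes[1]
    ax.plot(dist, result.normalized_signal, lw=0.8, color="0.2")
    ax.axhline(0, lw=0.5, color="0.6")
    ax.set_xlabel("pairwise distance (bp)")
    ax.set_ylabel("normalized frequency")
    ax.set_title("normalized")
    if xlim:
        axes[0].set_xlim(0, xlim)
        axes[1].set_xlim(0, xlim)

    ax = axes[2]
    m = result.metrics
    periods = m["period"].to_numpy()
    lo, hi = np.percentile(result.null.psd_matrix, [2.5, 97.5], axis=0)
    ax.fill_between(periods, lo, hi, color="0.8", label="shuffled 95% band")
    ax.plot(periods, m["psd_observed"], color="firebrick", lw=1, label="observed")
    sig = m["fdr"] < fdr_threshold
    ax.scatter(
        periods[sig],
        m.loc[sig, "psd_observed"],
        color="firebrick",
        s=18,
        zorder=3,
        label=f"fdr < {fdr_threshold:g}",
    )
    ax.set_xlim(2, min(xlim or periods.max(), periods.max()))
    ax.set_xlabel("period (bp)")
    ax.set_ylabel("PSD")
    ax.set_title(f"{result.config.get('motif', '')} periodicity")
    ax.legend(fontsize=7, frameon=False)

    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
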