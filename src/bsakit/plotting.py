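"""Manhattan-style tracks of windowed statistics with threshold lines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import ThresholdSet, WindowProfile

_LEVEL_COLORS = {0.90: "green", 0.95: "blue", 0.99: "red"}


def plot_profile(
    profile: WindowProfile,
    threshold: ThresholdSet | None = None,
    sites=None,
    path: str | None = None,
    title: str | None = None,
):
    """Windowed statistic along the genome, with per-site dots and thresholds.

    One panel per chromosome; the smoothed track is drawn as a line, the
    optional per-site values (``sites`` from :func:`bsakit.compute_indices`)
    as dots, and the threshold(s) as horizontal/per-window lines.
    """
    chroms = list(dict.fromkeys(profile.windows["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(4 * len(chroms), 3), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes[0], chroms):
        win = profile.windows[profile.windows["chrom"] == chrom]
        mid = (win["start"] + win["end"]) / 2e6
        if sites is not None:
            sub = sites[sites["chrom"] == chrom]
            ax.plot(sub["pos"] / 1e6, sub[profile.stat], ".", ms=1, alpha=0.3, color="gray")
        ax.plot(mid, win["stat_mean"], "-", color="black", lw=1.5)
        if threshold is not None:
            thr = threshold.threshold_for(profile, 0.95) if threshold.method == "delta" else None
            if threshold.method == "ed":
                ax.axhline(threshold.ed_threshold, color="red", ls="--", lw=1)
            elif threshold.window_thresholds is not None:
                full = np.asarray(thr)[profile.windows["chrom"] == chrom]
                ax.plot(mid, full, color="blue", ls="--", lw=1)
            else:
                for lv, val in (threshold.delta_thresholds or {}).items():
                    ax.axhline(val, color=_LEVEL_COLORS.get(lv, "gray"), ls="--", lw=1)
        ax.set_xlabel(f"{chrom} (Mb)")
    axes[0][0].set_ylabel(profile.stat)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
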