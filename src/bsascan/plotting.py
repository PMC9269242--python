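"""Δ(index) scan figures: per-chromosome index tracks, window-mean Δ with
its null confidence band, the association threshold, and called regions."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .window_scan import CandidateRegion, ScanConfig, WindowStat

__all__ = ["plot_delta_tracks"]


def plot_delta_tracks(
    snp_windows: Sequence[WindowStat],
    indel_windows: Sequence[WindowStat],
    regions: Sequence[CandidateRegion],
    config: ScanConfig,
    path: str,
    chroms: Sequence[str] | None = None,
) -> None:
    """One row per chromosome: SNP and InDel window-mean Δ tracks, the CI
    band of the SNP track, the threshold line, and shaded called regions."""
    if chroms is None:
        chroms = list(dict.fromkeys(w.chrom for w in snp_windows))
    level = config.ci_levels[0]
    n = len(chroms)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.8 * n), squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        for stats, color, label in (
            (snp_windows, "tab:red", "SNP"),
            (indel_windows, "tab:blue", "InDel"),
        ):
            xs = [(w.start + w.end) / 2 for w in stats if w.chrom == chrom and w.reliable]
            ys = [w.mean_delta for w in stats if w.chrom == chrom and w.reliable]
            ax.plot(xs, ys, lw=0.8, color=color, label=label)
        band = [(w, w.ci.get(level)) for w in snp_windows if w.chrom == chrom and w.reliable and level in w.ci]
        if band:
            ax.fill_between(
                [(w.start + w.end) / 2 for w, _ in band],
                [c[0] for _, c in band],
                [c[1] for _, c in band],
                color="grey", alpha=0.3, label=f"{int(level * 100)}% null band",
            )
        ax.axhline(config.delta_threshold, color="green", ls=":", lw=1)
        ax.axhline(-config.delta_threshold, color="green", ls=":", lw=1)
        for r in regions:
            if r.chrom == chrom:
                ax.axvspan(r.start, r.end, color="orange", alpha=0.25)
        ax.set_ylim(-1.05, 1.05)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center", fontsize=8)
    axes[0, 0].legend(loc="upper right", fontsize=7, ncol=3)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.suptitle("Δ(SNP/InDel-index) sliding-window scan")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
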