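"""Profile and concordance plots (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cnv import CnvProfile

__all__ = ["plot_profile", "plot_scatter"]


def plot_profile(profile: CnvProfile, path: str, log2: bool = True) -> None:
    """Genome-wide bin ratios (points) with the segment means (line)."""
    ratios = np.array([profile.bins[i].ratio for i in profile.unmasked_index])
    seg_line = np.empty(len(ratios))
    for seg in profile.segments:
        seg_line[seg.first_bin : seg.last_bin + 1] = seg.mean_ratio
    y = np.log2(np.maximum(ratios, 1e-3)) if log2 else ratios
    ys = np.log2(np.maximum(seg_line, 1e-3)) if log2 else seg_line
    x = np.arange(len(ratios))
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(x, y, ".", ms=2, color="0.4")
    ax.plot(x, ys, "-", color="crimson", lw=1.5)
    chroms = [profile.bins[i].chrom for i in profile.unmasked_index]
    edges = [k for k in range(1, len(chroms)) if chroms[k] != chroms[k - 1]]
    for e in edges:
        ax.axvline(e - 0.5, color="0.85", lw=0.5)
    ax.set_xlabel("bin (genome order)")
    ax.set_ylabel("log2 bin ratio" if log2 else "bin ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(paired, r: float, path: str) -> None:
    """Bin-ratio scatter of two profiles with the Pearson r annotated."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(paired.ref_ratio, paired.test_ratio, ".", ms=3, alpha=0.5)
    lim = max(paired.ref_ratio.max(), paired.test_ratio.max()) * 1.05
    ax.plot([0, lim], [0, lim], "-", color="0.8", lw=1)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference bin ratio")
    ax.set_ylabel("test bin ratio")
    ax.set_title(f"Pearson r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
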