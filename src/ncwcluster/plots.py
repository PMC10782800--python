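"""Diagnostic plots: CW vs NCW comparison, permutation stability, consensus.

All plot functions are pure sinks — they read result objects and write
image files, never touching the numbers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .consensus import CDF_GRID, ConsensusResult
from .coweights import CWMatrix
from .ncw import NCWResult, StabilityTrace


def plot_compare_cw(
    cw: CWMatrix, ncw: NCWResult, coobs: np.ndarray, path: str | Path
) -> Path:
    """Scatter of NCW against CW per pair, colored by co-observation count.

    Shows how the permutation normalization spreads pairs sharing the same
    raw consensus weight: pairs backed by many informative runs keep a high
    NCW, pairs whose CW rests on few or uninformative runs drop toward 0.
    """
    triu = np.triu_indices_from(cw.values, k=1)
    x = cw.values[triu]
    y = ncw.ncw[triu]
    c = np.asarray(coobs)[triu]
    ok = ~np.isnan(x) & ~np.isnan(y)
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    sc = ax.scatter(x[ok], y[ok], c=c[ok], cmap="RdYlGn", s=14, alpha=0.8,
                    edgecolors="none")
    fig.colorbar(sc, ax=ax, label="runs with both samples observed")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("consensus weight (CW)")
    ax.set_ylabel("normalized consensus weight (NCW)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_stability(trace: StabilityTrace, path: str | Path) -> Path:
    """Per-block boxes of squared NCW changes plus the line of their sums."""
    fig, ax = plt.subplots(figsize=(5.6, 4.2))
    if len(trace.distances):
        ax.boxplot(trace.distances, positions=trace.blocks, widths=0.5,
                   showfliers=False)
        ax2 = ax.twinx()
        ax2.plot(trace.blocks, trace.sum_distance, color="C1", marker="o",
                 lw=1.2, label="sum of squared changes")
        ax2.set_ylabel("sum of squared NCW changes", color="C1")
        ax2.legend(loc="upper right", frameon=False)
    ax.set_xlabel("permutation block")
    ax.set_ylabel("per-pair squared NCW change")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_consensus(result: ConsensusResult, out_dir: str | Path) -> list[Path]:
    """Per-k consensus heatmaps plus CDF and delta-area panels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for k, kr in sorted(result.per_k.items()):
        order = np.argsort(kr.consensus_class, kind="stable")
        fig, ax = plt.subplots(figsize=(4.6, 4.2))
        im = ax.imshow(kr.consensus_matrix[np.ix_(order, order)],
                       vmin=0, vmax=1, cmap="Blues", interpolation="nearest")
        fig.colorbar(im, ax=ax, label="consensus")
        ax.set_title(f"consensus matrix, k={k}")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.tight_layout()
        p = out / f"consensus_matrix.k{k}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

    if result.cdf:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9.0, 4.0))
        for k in sorted(result.cdf):
            ax1.plot(CDF_GRID, result.cdf[k], label=f"k={k}")
        ax1.set_xlabel("consensus value")
        ax1.set_ylabel("CDF")
        ax1.legend(frameon=False, fontsize=8)
        ks = sorted(result.delta_area)
        ax2.plot(ks, [result.delta_area[k] for k in ks], marker="o")
        if result.chosen_k is not None:
            ax2.axvline(result.chosen_k, ls="--", color="grey", lw=0.8)
        ax2.set_xlabel("k")
        ax2.set_ylabel("relative change in area under CDF")
        fig.tight_layout()
        p = out / "consensus_cdf.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
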