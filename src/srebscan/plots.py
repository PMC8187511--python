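"""Minimal figures: per-column conservation track and expression bar plots."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .conserve import ColumnProfile
from .qpcr import GroupStats, RelExpression

__all__ = ["conservation_track", "expression_bars"]


def conservation_track(
    profiles: Sequence[ColumnProfile],
    path,
    clusters: Optional[Sequence[str]] = None,
    highlight: Sequence[int] = (),
) -> None:
    """Per-cluster conservation fraction along reference positions.

    ``highlight`` marks reference positions (e.g. cluster-specific sites).
    """
    usable = [p for p in profiles if not p.masked and p.ref_position is not None]
    if not usable:
        raise ValueError("no unmasked reference columns to plot")
    clusters = list(clusters or sorted(usable[0].cluster_sizes))
    fig, ax = plt.subplots(figsize=(10, 3))
    xs = [p.ref_position for p in usable]
    for c in clusters:
        ax.plot(xs, [p.conservation(c) for p in usable], lw=0.8, label=c)
    for pos in highlight:
        ax.axvline(pos, color="gold", lw=1.0, alpha=0.6)
    ax.set_xlabel("reference position (aa)")
    ax.set_ylabel("conservation")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=len(clusters))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def expression_bars(
    values: Sequence[RelExpression], stats: GroupStats, path
) -> None:
    """Mean +/- SE relative expression per group with significance letters."""
    groups = list(stats.groups)
    means = [stats.means[g] for g in groups]
    sems = [stats.sems[g] for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1, 3))
    ax.bar(groups, means, yerr=sems, capsize=3, color="#777")
    for i, g in enumerate(groups):
        ax.text(i, means[i] + sems[i], stats.tukey_letters.get(g, ""),
                ha="center", va="bottom")
    ax.set_ylabel("relative expression")
    ax.set_title(stats.gene)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
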