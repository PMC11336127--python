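"""Plotting helpers: RT histogram and cumulative-distribution overlays."""

from __future__ import annotations

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .rt_analysis import CdfWithCi, histogram

__all__ = ["plot_rt_histogram", "plot_cdfs"]


def plot_rt_histogram(rts, bin_ms: float = 5.0, ax=None, label=None):
    """Bar histogram of response times with bins aligned to ``bin_ms``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    edges, counts = histogram(rts, bin_ms)
    ax.bar(edges[:-1], counts, width=bin_ms, align="edge",
           edgecolor="none", label=label)
    ax.set_xlabel("response time (ms)")
    ax.set_ylabel("count")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_cdfs(curves: dict[str, CdfWithCi], ax=None):
    """Overlay empirical CDFs with their 95% bands, one per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for label, c in curves.items():
        line, = ax.step(c.grid_ms, c.cdf, where="post", label=label)
        ax.fill_between(c.grid_ms, c.lo, c.hi, step="post",
                        color=line.get_color(), alpha=0.2, linewidth=0)
    ax.set_xlabel("response time (ms)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax
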