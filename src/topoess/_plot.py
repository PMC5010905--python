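"""Thin matplotlib rendering of the diagnostic tables.

The plot-data tables (`trace_plot_data`, `jump_plot_data`) are the primary
interface; these helpers only turn them into figures, using the Agg canvas
so they work headless.
"""

from __future__ import annotations

import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure


def save_trace_plot(table: pd.DataFrame, path: str, metric_name: str) -> None:
    """Render a topology trace (optionally multi-chain) to an image file."""
    fig = Figure(figsize=(8, 3.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot()
    if "chain" in table.columns:
        for chain, sub in table.groupby("chain"):
            ax.plot(sub["generation"], sub["distance"], lw=0.6, label=str(chain))
        ax.legend(fontsize=7)
    else:
        ax.plot(table["generation"], table["distance"], lw=0.6, color="#20639b")
    ax.set_xlabel("sample index")
    ax.set_ylabel(f"{metric_name} to focal tree")
    ax.set_title("topology trace")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def save_jump_plot(table: pd.DataFrame, path: str, metric_name: str) -> None:
    """Render a jump distance plot to an image file."""
    fig = Figure(figsize=(5, 3.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot()
    ax.plot(
        table["interval"], table["mean_distance"], "o-", ms=3, color="#ed553b"
    )
    ax.set_xlabel("sampling interval")
    ax.set_ylabel(f"mean {metric_name}")
    ax.set_title("jump distance plot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
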