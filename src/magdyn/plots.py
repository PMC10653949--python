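"""Static SVG plots for the ordination and trajectory outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_cap", "plot_trajectories"]


def plot_cap(cap_results, path, title: str = "CAP ordination") -> Path:
    """Scatter of the first two canonical axes, coloured by group."""
    scores = cap_results.site_scores
    groups = cap_results.groups
    fig, ax = plt.subplots(figsize=(5, 4))
    y = scores.iloc[:, 1] if scores.shape[1] > 1 else pd.Series(0.0, index=scores.index)
    for g, idx in groups.groupby(groups).groups.items():
        ax.scatter(scores.loc[idx].iloc[:, 0], y.loc[idx], label=str(g), s=18, alpha=0.8)
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1] if scores.shape[1] > 1 else "")
    ax.set_title(f"{title} (m={cap_results.m}, LOO={cap_results.loo_success:.2f})")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def plot_trajectories(trajectory_results, path, functions=None) -> Path:
    """CWM means with interval bars across the treatment sequence."""
    table = trajectory_results.table
    functions = functions or sorted(table["function_id"].unique())
    order = trajectory_results.treatment_order
    ncol = min(4, len(functions))
    nrow = -(-len(functions) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    for k, fn in enumerate(functions):
        ax = axes[k // ncol][k % ncol]
        sub = table[table["function_id"] == fn].set_index("treatment").loc[order]
        x = range(len(order))
        ax.errorbar(
            x,
            sub["cwm_mean"],
            yerr=[sub["cwm_mean"] - sub["interval_low"], sub["interval_high"] - sub["cwm_mean"]],
            fmt="o-",
            capsize=2,
            ms=3,
        )
        ax.set_title(fn, fontsize=8)
        ax.set_xticks(list(x))
        ax.set_xticklabels(order, rotation=45, fontsize=6)
        ax.set_ylim(0, 1)
    for k in range(len(functions), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
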