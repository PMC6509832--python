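"""Minimal plotting: group-by-block interaction cell means.

The two headline interactions of the analysis (valence ratings and
RMSSD) are crossover patterns; this renders them as the standard
two-line interaction plot with between-participant SD whiskers.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_block_interaction(
    descriptives: pd.DataFrame, outcome: str, path: str
) -> None:
    """Plot group x block cell means of one outcome to ``path``.

    ``descriptives`` is the per-cell table of a
    :class:`~emotrace.pipeline.ReportBundle` (columns outcome, group,
    block, category, mean, std).
    """
    sub = descriptives[descriptives["outcome"] == outcome]
    if sub.empty:
        raise ValueError(f"outcome {outcome!r} not in descriptives")
    cells = (
        sub.groupby(["group", "block"], observed=True)["mean"]
        .agg(["mean"])
        .join(sub.groupby(["group", "block"], observed=True)["std"].mean())
        .reset_index()
    )
    blocks = ["short", "long"]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for group, marker in (("BPD", "o"), ("HC", "s")):
        g = cells[cells["group"] == group].set_index("block").reindex(blocks)
        ax.errorbar(
            blocks,
            g["mean"],
            yerr=g["std"],
            marker=marker,
            capsize=3,
            label=group,
        )
    ax.set_xlabel("presentation block")
    ax.set_ylabel(outcome)
    ax.set_title(f"Group x Block: {outcome}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
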