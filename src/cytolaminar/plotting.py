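"""Per-layer laminar profile plots: group medians with scatter and
significance asterisks (``*`` for p <= 0.05, ``**`` for p <= 0.01)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["significance_marker", "layer_profile_plot"]


def significance_marker(p: float) -> str:
    """Asterisk annotation for an adjusted p-value."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def layer_profile_plot(
    medians: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping: str,
    variable: str,
    layer_p: dict[str, float] | None = None,
    path=None,
):
    """Line plot of per-layer group medians of one descriptor.

    Each group gets one line through the median-of-specimen-medians per
    layer, with the individual specimen medians as scatter dots; layers
    whose (adjusted) p-value in ``layer_p`` crosses 0.05 / 0.01 are
    annotated with asterisks.
    """
    df = medians.merge(metadata[["specimen_id", grouping]], on="specimen_id")
    layers = sorted(df["layer"].unique())
    xs = {lay: i for i, lay in enumerate(layers)}
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in df.groupby(grouping):
        line = (
            sub.groupby("layer")[variable].median().reindex(layers)
        )
        ax.plot(range(len(layers)), line.to_numpy(), marker="o", label=str(group))
        ax.scatter(
            [xs[lay] for lay in sub["layer"]],
            sub[variable],
            s=12,
            alpha=0.45,
        )
    if layer_p:
        top = df[variable].max()
        for lay, p in layer_p.items():
            marker = significance_marker(p)
            if marker and lay in xs:
                ax.text(xs[lay], top, marker, ha="center", fontsize=12)
    ax.set_xticks(range(len(layers)), layers)
    ax.set_xlabel("cortical layer")
    ax.set_ylabel(variable)
    ax.legend(title=grouping, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
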