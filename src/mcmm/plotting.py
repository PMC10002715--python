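"""Basic scatter/heatmap helpers for validation and screen outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_validation_scatter", "plot_screen_heatmap"]


def plot_validation_scatter(study_table: pd.DataFrame, metabolite: str,
                            ax=None):
    """Measured vs predicted flux scatter for one metabolite, colored by
    study."""
    data = study_table[study_table["metabolite"] == metabolite]
    if data.empty:
        raise ValueError(f"no rows for metabolite {metabolite!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for study, grp in data.groupby("study_id"):
        ax.scatter(grp["predicted_flux"], grp["measured_flux"], s=18,
                   label=str(study), alpha=0.8)
    ax.set_xlabel("predicted flux (mmol/gDW/h)")
    ax.set_ylabel("measured flux")
    ax.set_title(metabolite)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_screen_heatmap(screen: pd.DataFrame, ax=None):
    """Butyrate production per (sample, intervention spec) as a heatmap."""
    pivot = screen.pivot(index="sample_id", columns="spec", values="butyrate")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * pivot.shape[1],
                                      1 + 0.4 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45,
                  ha="right", fontsize=8)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="butyrate (mmol/gDW/h)")
    return ax
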