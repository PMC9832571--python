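"""Publication-style scatter panels of mismatch vs brood cells."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import EXPONENTIAL, fit_mismatch_model


def mismatch_panels(nest_tables: dict, path) -> None:
    """One panel per species: nest mismatch vs cells with exponential fit."""
    taxa = sorted(nest_tables)
    fig, axes = plt.subplots(1, len(taxa), figsize=(3.2 * len(taxa), 3.2), squeeze=False)
    for ax, taxon in zip(axes[0], taxa):
        data = nest_tables[taxon]
        ax.scatter(data["mismatch_days"], data["brood_cells"], s=12, alpha=0.5)
        try:
            fit = fit_mismatch_model(data, taxon, EXPONENTIAL)
            grid = np.linspace(0, data["mismatch_days"].max(), 100)
            ax.plot(grid, np.exp(fit.intercept + fit.slope * grid), color="crimson")
        except Exception:  # panel stays data-only when the fit is undefined
            pass
        ax.set_title(taxon, fontsize=9)
        ax.set_xlabel("mismatch (days)")
    axes[0][0].set_ylabel("brood cells per nest")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
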