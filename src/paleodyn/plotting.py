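"""Observed-versus-simulated trajectory plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import ModelComparison
from .proxies import GenerationTable

__all__ = ["plot_trajectories"]


def plot_trajectories(
    comparison: ModelComparison, table: GenerationTable, path=None, scale: str = "raw"
):
    """Panel per candidate model: observed SPD proxy vs simulated trajectory."""
    fits = sorted(comparison.fits, key=lambda f: f.spec.name)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    years = table.years
    for ax, fit in zip(axes.ravel(), fits):
        traj = fit.simulate()
        if scale == "raw":
            obs, pred = table.column("x"), traj.x
        else:
            obs, pred = table.column("X"), traj.X
        ax.plot(years, obs, color="tab:blue", label="observed")
        ax.plot(years, pred, color="tab:red", label="predicted")
        sig2 = fit.sigma2_prediction
        title = f"model {fit.spec.name}"
        if sig2 is not None:
            title += f"  ($\\sigma^2$={sig2:.2f})"
        ax.set_title(title)
    axes[0, 0].legend(frameon=False)
    for ax in axes[1]:
        ax.set_xlabel("year AD")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
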