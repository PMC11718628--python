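"""Bias / CI-width comparison panels for experiment results."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_bias_ciwidth"]


def plot_bias_ciwidth(result, out_path, sweep: str | None = None):
    """Two-panel figure: mean bias (with MC-SE error bars) and mean CI width
    per method, against the swept parameter (sampling fraction or proxy
    correlation).  ``result`` is an ExperimentResult from a fig5-style run.
    """
    t = result.table
    if sweep is not None and "sweep" in t.columns:
        t = t[t["sweep"] == sweep]
    xcol = "fraction"
    if sweep == "rho" or (t.get("rho") is not None and t["rho"].nunique() > 1):
        xcol = "rho"
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharex=True)
    for m, g in t.groupby("method"):
        g = g.sort_values(xcol)
        axes[0].errorbar(g[xcol], g["mean_bias"], yerr=g["mc_se_bias"],
                         marker="o", capsize=2, label=m)
        axes[1].plot(g[xcol], g["mean_ci_width"], marker="o", label=m)
    axes[0].axhline(0, color="k", lw=0.6)
    axes[0].set_ylabel("mean bias")
    axes[1].set_ylabel("mean 95% CI width")
    for ax in axes:
        ax.set_xlabel(xcol)
    axes[1].legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
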