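"""Optional matplotlib figures mirroring the standard experiment layouts.

matplotlib is imported lazily so the core package stays usable without it.
"""

from __future__ import annotations

import numpy as np

from .metrics import leg_volume_transfer
from .model import SimulationTrace

__all__ = ["plot_protocol_trace", "plot_sweep", "plot_edema_grid"]


def _plt():
    import matplotlib.pyplot as plt

    return plt


def plot_protocol_trace(trace: SimulationTrace, cycle_avg_window: float = 0.6):
    """Three-panel run overview: forcing, regional volumes, cardiac output.

    CO is drawn as a moving cycle average so the per-beat pulsatility does
    not obscure the trend.
    """
    plt = _plt()
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))

    axes[0].plot(trace.t, trace.force, lw=0.3, label="force (N)")
    axes[0].plot(trace.t, trace.p_plr * 10, label="P_PLR (mmHg ×10)")
    axes[0].set_ylabel("forcing")
    axes[0].legend(loc="upper left", fontsize=8)

    axes[1].plot(trace.t, (trace.volume("C11") + trace.volume("C14")) * 1e3,
                 label="abdomen (mL)")
    axes[1].plot(trace.t, (trace.volume("C12") + trace.volume("C13")) * 1e3,
                 label="legs (mL)")
    axes[1].set_ylabel("volume (mL)")
    axes[1].legend(loc="center left", fontsize=8)

    co = trace.flow("q_aortic_valve") * 60.0
    n = max(1, int(round(cycle_avg_window / trace.sample_dt)))
    kernel = np.ones(n) / n
    axes[2].plot(trace.t, np.convolve(co, kernel, mode="same"))
    axes[2].set_ylabel("CO (L/min)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    return fig


def plot_sweep(sweep, metrics=("cpp", "co", "q_heart", "q_head")):
    """Percent-change curves of a TPF or angle sweep, one panel per metric."""
    plt = _plt()
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, metric in zip(axes.ravel(), metrics):
        ax.plot(sweep.axis, sweep.pct_change(metric), marker="o")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(f"{metric} change (%)", fontsize=9)
        ax.set_xlabel(sweep.axis_name)
    fig.tight_layout()
    return fig


def plot_edema_grid(grid, threshold: float = 25.0):
    """Pulmonary venous pressure vs angle, one curve per pump factor."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    for tpf, sub in grid.groupby("tpf"):
        sub = sub.sort_values("angle_deg")
        ax.plot(sub["angle_deg"], sub["p_ppv_mean"], marker="o",
                label=f"TPF {tpf:g}")
    ax.axhline(threshold, color="red", ls="--", lw=0.8,
               label="colloid osmotic threshold")
    ax.set_xlabel("leg elevation (deg)")
    ax.set_ylabel("mean P_ppv (mmHg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
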