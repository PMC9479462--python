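"""Plot helpers for simulation results (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .analysis import GROUP_LABELS
from .network import SimulationResult


def plot_excess_distribution(result: SimulationResult, kind: str = "glut", ax=None):
    """Excess-neurotransmitter distribution (percentile fan) over time."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    trace = result.var(f"excess_{kind}")
    qs = [5, 25, 50, 75, 95]
    bands = np.percentile(trace, qs, axis=1)
    ax.fill_between(result.times, bands[0], bands[-1], alpha=0.2, label="5-95%")
    ax.fill_between(result.times, bands[1], bands[3], alpha=0.35, label="25-75%")
    ax.plot(result.times, bands[2], lw=1.5, label="median")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"excess {'glutamate' if kind == 'glut' else 'GABA'} (a.u.)")
    ax.legend(frameon=False)
    return ax


def plot_group_scatter(summaries, ax=None):
    """Time-to-steady vs steady-state excess, coloured by synapse group."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    colors = dict(zip(GROUP_LABELS, ["tab:blue", "gold", "tab:orange", "purple"]))
    for label, sub in summaries.groupby("group"):
        ax.scatter(sub["time_to_steady"], sub["steady_excess"], s=8,
                   color=colors.get(label, "gray"), label=label)
    ax.set_xlabel("time to steady state (s)")
    ax.set_ylabel("steady-state excess (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_sweep(sweep_table, ax=None):
    """CB1R percentage of maximum against the E/I ratio."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    tab = sweep_table.sort_values("ei_ratio")
    ax.plot(tab["ei_ratio"], tab["glut_cb1r_pct"], "o-", label="glutamatergic")
    ax.plot(tab["ei_ratio"], tab["gaba_cb1r_pct"], "s-", label="GABAergic")
    ax.set_xlabel("E/I ratio")
    ax.set_ylabel("CB1R (% of maximum)")
    ax.legend(frameon=False)
    return ax
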