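"""Advisory figures mirroring the analysis outputs.

Plots are rendering-dependent conveniences; every quantitative output
is also written as CSV by the CLI, and only the CSVs feed downstream
checks.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

PATTERN_COLORS = {
    "reversible_bistable": "#d62728",
    "irreversible_bistable": "#1f77b4",
    "continuous_monostable": "#2ca02c",
    "discontinuous_monostable": "#17becf",
    "unclassified": "#7f7f7f",
}


def plot_trajectory(frame: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("L", "K", "Kact", "C", "P", "Pact"):
        ax.plot(frame["time"], frame[col], label=col)
    ax.set_xlabel("time (nondimensional)")
    ax.set_ylabel("concentration")
    ax.legend(ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bifurcation(frame: pd.DataFrame, path: str | Path) -> None:
    """Inflammation level vs stimulus; solid stable, dotted unstable."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for stab, style in (("stable", "o"), ("unstable", "."), ("marginal", "x")):
        sel = frame[frame["stability"] == stab]
        if len(sel):
            ax.plot(sel["mu"], sel["Pact"], style, ms=3 if stab != "unstable" else 2,
                    label=stab, alpha=0.8)
    ax.set_xlabel(r"external stimulus $\mu$")
    ax.set_ylabel("inflammation level [PAR2*]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(frame: pd.DataFrame, path: str | Path) -> None:
    """Pattern / mu_on / delta_mu heatmaps over the feedback grid."""
    aKs = np.sort(frame["alphaK"].unique())
    aLs = np.sort(frame["alphaL"].unique())
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    pat_idx = {p: i for i, p in enumerate(PATTERN_COLORS)}
    grid = frame.pivot_table(
        index="alphaL", columns="alphaK", values="pattern",
        aggfunc=lambda s: pat_idx[s.iloc[0]],
    ).reindex(index=aLs, columns=aKs)
    cmap = matplotlib.colors.ListedColormap(list(PATTERN_COLORS.values()))
    axes[0].pcolormesh(aKs, aLs, grid.to_numpy(), cmap=cmap, vmin=-0.5, vmax=4.5)
    axes[0].set_title("bifurcation pattern")
    for ax, col, title in (
        (axes[1], "mu_on", r"inflammation threshold $\mu_{on}$"),
        (axes[2], "delta_mu", r"bistability range $\Delta\mu$"),
    ):
        vals = frame.pivot_table(index="alphaL", columns="alphaK", values=col
                                 ).reindex(index=aLs, columns=aKs)
        m = ax.pcolormesh(aKs, aLs, vals.to_numpy())
        fig.colorbar(m, ax=ax)
        ax.set_title(title)
    for ax in axes:
        ax.set_xlabel(r"$\alpha_K$")
        ax.set_ylabel(r"$\alpha_L$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sensitivity(frame: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(frame))
    ax.bar(x - 0.2, frame["Si"], width=0.4, label="first-order $S_i$")
    ax.bar(x + 0.2, frame["STi"], width=0.4, label="total-order $S_{Ti}$")
    ax.set_xticks(x)
    ax.set_xticklabels(frame["parameter"], rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("sensitivity index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scores(frame: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    order = ["HC", "NLAD", "LAD"]
    colors = {"HC": "k", "NLAD": "tab:blue", "LAD": "tab:red"}
    rng = np.random.default_rng(0)
    for i, g in enumerate(order):
        vals = frame.loc[frame["group"] == g, "score"]
        ax.plot(i + rng.uniform(-0.12, 0.12, len(vals)), vals, "o",
                color=colors[g], label=g, alpha=0.8)
    ax.axhline(frame.loc[frame["group"] == "HC", "score"].median(),
               ls=":", c="gray")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order)
    ax.set_ylabel("inflammation score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
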