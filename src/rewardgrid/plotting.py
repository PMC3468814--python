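"""Static plot export for experiment results.

Matplotlib figures mirroring the standard views: population learning
curves, per-group curves, lock-in ratio vs choice noise, and gradient-bin
summaries.  All functions write a file and return its path; the Agg
backend is forced so plotting works headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_learning_curves(curves: pd.DataFrame, path: str | Path) -> Path:
    """Mean valuation curves over time; one line per mean_vhat_* column."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in curves.columns:
        if col.startswith("mean_vhat"):
            ax.plot(curves["step"], curves[col], label=col.removeprefix("mean_"))
    ax.set_xlabel("step")
    ax.set_ylabel("mean internal valuation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_lockin_vs_noise(sweep: pd.DataFrame, path: str | Path) -> Path:
    """Lock-in (learning) ratio as a function of epsilon, per origin group."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for origin in ("HH", "LL"):
        ax.errorbar(
            sweep["epsilon"],
            sweep[f"lockin_{origin}"],
            yerr=sweep.get(f"lockin_{origin}_se"),
            marker="o",
            capsize=3,
            label=f"{origin}-origin",
        )
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("choice noise epsilon")
    ax.set_ylabel("learning ratio (second food / first food)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_gradient_bins(by_bin: pd.DataFrame, path: str | Path) -> Path:
    """Time to learn H and lock-in ratio across initial-exposure deciles."""
    path = Path(path)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    mid = (by_bin["h_frac_low"] + by_bin["h_frac_high"]) / 2
    ax1.errorbar(mid, by_bin["mean_time_H"], yerr=by_bin["se_time_H"],
                 marker="o", capsize=3)
    ax1.set_xlabel("initial H fraction (bin midpoint)")
    ax1.set_ylabel("mean time to learn H (steps)")
    ax2.errorbar(mid, by_bin["mean_lockin"], yerr=by_bin["se_lockin"],
                 marker="o", capsize=3)
    ax2.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax2.set_xlabel("initial H fraction (bin midpoint)")
    ax2.set_ylabel("lock-in ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
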