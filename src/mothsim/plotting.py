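"""Presentation helpers: campaign summary bars and trajectory panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .domain import DEFAULT_DOMAIN, SOURCE_POSITION
from .experiment import ResultsTable

__all__ = ["plot_summary", "plot_trajectory"]

_MODE_COLORS = {"waiting": "0.7", "detecting": "tab:green",
                "surging": "tab:blue", "casting": "tab:orange",
                "sweeping": "tab:red", "done_success": "k",
                "done_failed": "k"}


def plot_summary(results: ResultsTable, out_dir: str | Path,
                 prefix: str = "summary") -> list[Path]:
    """Grouped bar charts of success rate and mean tau per model per level."""
    if len(results) == 0:
        raise ValueError("empty results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = results.models
    levels = results.levels
    width = 0.8 / len(models)
    paths = []
    for metric in ("success_rate", "tau"):
        fig, ax = plt.subplots(figsize=(7, 4))
        for i, model in enumerate(models):
            if metric == "success_rate":
                vals = [results.success_rate(model, lv) for lv in levels]
            else:
                vals = [np.mean(results.tau_values(model, lv))
                        if results.tau_values(model, lv).size else np.nan
                        for lv in levels]
            xs = np.arange(len(levels)) + i * width
            ax.bar(xs, vals, width=width, label=model)
        ax.set_xticks(np.arange(len(levels)) + 0.4 - width / 2)
        ax.set_xticklabels([f"{lv:g}" for lv in levels])
        ax.set_xlabel(results.df["variable"].iloc[0])
        ax.set_ylabel("success rate (%)" if metric == "success_rate"
                      else "mean efficient navigation time tau")
        ax.legend()
        fig.tight_layout()
        p = out / f"{prefix}_{metric}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_trajectory(trajectory: pd.DataFrame, out_path: str | Path,
                    title: str = "") -> Path:
    """x-y flight path with mode-colored segments."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for mode, seg in trajectory.groupby("mode", sort=False):
        ax.plot(seg["x"], seg["y"], ".", ms=2,
                color=_MODE_COLORS.get(mode, "k"), label=mode)
    ax.plot(*SOURCE_POSITION, "r*", ms=12, label="source")
    d = DEFAULT_DOMAIN
    ax.set_xlim(d.x_min - 0.05, d.x_max + 0.05)
    ax.set_ylim(d.y_min - 0.05, d.y_max + 0.05)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
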