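"""Figures: per-SNP scatter with fitted lines, forest plots.

Figures are drawn from the tabular outputs (single-SNP and leave-one-out
tables), not from internal state, so any external tool can regenerate them
from the TSVs the pipeline writes.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def scatter_plot(harmonized, results: list, ax=None):
    """SNP-exposure vs SNP-outcome effects with one fitted line per method.

    IVW and PWM lines pass through the origin with slope = estimate; the
    MR-Egger line uses its fitted intercept.
    """
    df = harmonized.retained if hasattr(harmonized, "retained") else harmonized
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    x = df["beta_exposure"].to_numpy(float)
    y = df["beta_outcome"].to_numpy(float)
    ax.errorbar(x, y, yerr=1.96 * df["se_outcome"], xerr=1.96 * df["se_exposure"],
                fmt="o", ms=4, color="0.3", ecolor="0.7", lw=1, capsize=0)
    grid = np.linspace(0, x.max() * 1.05, 50)
    for res in results:
        icpt = res.extras.get("intercept", 0.0)
        ax.plot(grid, icpt + res.estimate * grid, label=res.method)
    ax.axhline(0, color="0.85", lw=0.8, zorder=0)
    ax.set_xlabel("SNP effect on exposure (SD per allele)")
    ax.set_ylabel("SNP effect on outcome (log odds per allele)")
    ax.legend(frameon=False)
    return ax


def forest_plot(table: pd.DataFrame, label_col: str = "rsid",
                pooled: list | None = None, ax=None, or_scale: bool = True):
    """Forest plot of per-SNP (or leave-one-out) estimates with 95% CIs.

    ``table`` needs columns ``estimate, ci_low, ci_high`` plus ``label_col``;
    ``pooled`` MrResults are appended below a separator.
    """
    pooled = pooled or []
    n = len(table) + len(pooled)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.25 * n + 1.2))
    ys = np.arange(len(table))[::-1] + len(pooled) + 1
    est, lo, hi = (table[c].to_numpy(float) for c in ("estimate", "ci_low", "ci_high"))
    if or_scale:
        est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
    ax.errorbar(est, ys, xerr=[est - lo, hi - est], fmt="s", ms=3,
                color="0.2", ecolor="0.5", lw=1, capsize=0)
    labels = list(table[label_col])
    ypos = list(ys)
    for i, res in enumerate(pooled):
        y = len(pooled) - i - 0.5
        e, l, h = ((res.odds_ratio, res.or_low, res.or_high) if or_scale
                   else (res.estimate, res.ci_low, res.ci_high))
        ax.errorbar([e], [y], xerr=[[e - l], [h - e]], fmt="D", ms=5,
                    color="C3", ecolor="C3", lw=1.5)
        labels.append(res.method.upper())
        ypos.append(y)
    ax.axvline(1.0 if or_scale else 0.0, color="0.8", lw=0.8, zorder=0)
    if pooled:
        ax.axhline(len(pooled) + 0.25, color="0.8", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("OR per 1-SD exposure (95% CI)" if or_scale
                  else "log-OR per 1-SD exposure (95% CI)")
    if or_scale:
        ax.set_xscale("log")
    return ax


def save_figure(ax, path_base) -> list[str]:
    """Save an axes' figure as both SVG and PNG next to ``path_base``."""
    fig = ax.get_figure()
    fig.tight_layout()
    written = []
    for ext in ("svg", "png"):
        p = f"{path_base}.{ext}"
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written
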