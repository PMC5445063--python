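"""Summary tables and figures for analysed cohorts."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import pearson_ci
from .workflow import compare_groups

log = logging.getLogger(__name__)

__all__ = ["generate_report"]


def _strip_box(ax, df, metric, groups, scale=1.0, ylabel=None):
    data = [df.loc[df["group"] == g, metric].dropna().to_numpy(float) * scale for g in groups]
    ax.boxplot(data, tick_labels=groups, whis=1.5, showfliers=False)
    for i, d in enumerate(data, start=1):
        x = i + np.linspace(-0.12, 0.12, d.size)
        ax.plot(x, d, "o", ms=4, alpha=0.7)
    ax.set_ylabel(ylabel or metric)


def generate_report(results: pd.DataFrame, out_dir, region: str = "WL") -> dict:
    """Write summary.csv and three figures for a two-group results table.

    Returns a dict of written paths.  With fewer than two groups the
    comparison table and group figures are skipped with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    groups = sorted(results["group"].dropna().unique())
    wl = results[results["region"] == region]

    if len(groups) < 2:
        log.warning("fewer than two groups; comparison statistics omitted")
    else:
        metrics = [m for m in ("ki", "nki", "pat_slope", "pat_intercept", "va", "vb", "suv")
                   if m in results.columns]
        table = compare_groups(results, metrics, groups[0], groups[1], region=region)
        table.to_csv(out / "summary.csv", index=False)
        written["summary"] = out / "summary.csv"

        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        if "nki" in wl.columns:
            _strip_box(axes[0], wl, "nki", groups, 1e3, "normalised Patlak ($10^{-3}$ ml cm$^{-3}$ min$^{-1}$)")
        if "ki" in wl.columns:
            _strip_box(axes[1], wl, "ki", groups, 1e3, "corrected $K_i$ ($10^{-3}$ ml cm$^{-3}$ min$^{-1}$)")
        fig.suptitle(f"Metabolic rate, {region}")
        fig.tight_layout()
        fig.savefig(out / "fig_metabolic_rate.png", dpi=110)
        plt.close(fig)
        written["fig_metabolic_rate"] = out / "fig_metabolic_rate.png"

        fig, axes = plt.subplots(1, 3, figsize=(10, 3.6))
        for ax, (m, lab) in zip(axes, [("va", "fractional air $V_A^{CT}$"),
                                       ("vb", "fractional blood $V_B$"),
                                       ("tissue_fraction", "fractional tissue")]):
            d = wl.copy()
            if m == "tissue_fraction":
                d[m] = 1.0 - d["va"] - d["vb"]
            _strip_box(ax, d, m, groups, 1.0, lab)
        fig.tight_layout()
        fig.savefig(out / "fig_fractions.png", dpi=110)
        plt.close(fig)
        written["fig_fractions"] = out / "fig_fractions.png"

    if {"pat_intercept", "vb"} <= set(wl.columns) and len(wl) >= 4:
        fig, ax = plt.subplots(figsize=(4.4, 4))
        for g in groups:
            sub = wl[wl["group"] == g]
            ax.plot(sub["vb"], sub["pat_intercept"], "o", label=g)
        try:
            r, (lo, hi) = pearson_ci(wl["vb"], wl["pat_intercept"])
            ax.set_title(f"r = {r:.2f} [{lo:.2f} {hi:.2f}]")
        except Exception:
            pass
        ax.set_xlabel("fractional blood volume $V_B$")
        ax.set_ylabel("Patlak intercept")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fig_intercept_vs_vb.png", dpi=110)
        plt.close(fig)
        written["fig_intercept_vs_vb"] = out / "fig_intercept_vs_vb.png"
    return written
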