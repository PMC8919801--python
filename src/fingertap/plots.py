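"""Diagnostic figures for model reports.

Three plots mirror the standard way these analyses are presented:
classification probability against age or severity, signed feature
contributions as ranked bars, and predicted-vs-true severity with the
bootstrap band of the fitted line.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .models import ModelReport  # noqa: E402


def plot_probability_scatter(
    report: ModelReport,
    covariate: pd.Series,
    label: str,
    path: str | Path,
) -> None:
    """Disease-class probability vs a covariate (age or severity)."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    prob = report.oof["prob_positive"]
    for cls, marker in zip(sorted(report.oof["y_true"].unique()), "ox^s"):
        sel = report.oof["y_true"] == cls
        ax.scatter(np.asarray(covariate)[sel], prob[sel], s=14, marker=marker,
                   alpha=0.7, label=str(cls))
    ax.axhline(0.5, ls=":", c="gray", lw=1)
    ax.set_xlabel(label)
    ax.set_ylabel(f"P({report.positive_label})")
    ax.set_title(report.contrast)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contributions(
    contributions: pd.DataFrame,
    path: str | Path,
    top_only: bool = True,
) -> None:
    """Ranked signed feature-contribution bars (top 2% by default)."""
    df = contributions[contributions["top"]] if top_only else contributions
    fig, ax = plt.subplots(figsize=(5, 0.35 * max(len(df), 4) + 1))
    colors = np.where(df["contribution"] >= 0, "tab:red", "tab:blue")
    ax.barh(df["feature"][::-1], df["contribution"][::-1],
            color=colors[::-1])
    ax.axvline(0, c="k", lw=0.8)
    ax.set_xlabel("contribution (coefficient x loading)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_prediction_scatter(report: ModelReport, path: str | Path) -> None:
    """Predicted vs true score with the bootstrap 95% band of the fit line."""
    fig, ax = plt.subplots(figsize=(4, 3.6))
    y = report.oof["y_true"].astype(float)
    p = report.oof["prediction"]
    ax.scatter(y, p, s=14, alpha=0.7)
    m = report.metrics
    xs = np.asarray(m["line_x"])
    ax.fill_between(xs, m["line_band_lo"], m["line_band_hi"],
                    alpha=0.25, color="tab:orange", label="bootstrap 95% band")
    b1, b0 = np.polyfit(y, p, 1)
    ax.plot(xs, b0 + b1 * xs, c="tab:orange", lw=1.5)
    ax.set_xlabel("true score")
    ax.set_ylabel("predicted score")
    ax.set_title(f"{report.contrast}: r = {m['r']:.2f}, r2 = {m['r2']:.2f}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
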