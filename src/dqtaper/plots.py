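"""Optional matplotlib figures: forest plot, ROC curves, KM curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["forest_plot", "roc_plot", "km_plot"]


def forest_plot(fits: pd.DataFrame, path: str | Path) -> Path:
    """Forest plot of the GEE slope estimates (beta, 95% CI)."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(fits) + 1))
    ys = range(len(fits))
    for y, row in zip(ys, fits.itertuples(index=False)):
        ax.plot([row.ci_low, row.ci_high], [y, y], "-", color="tab:blue")
        ax.plot(row.beta, y, "s", color="tab:blue")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(list(ys))
    ax.set_yticklabels(
        [f"{r.outcome} ({r.method})" for r in fits.itertuples(index=False)]
    )
    ax.invert_yaxis()
    ax.set_xlabel("slope of average DQ (per DQ unit)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def roc_plot(curves: pd.DataFrame, path: str | Path) -> Path:
    """ROC curves from the long-format curve table."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for (label, weighted), grp in curves.groupby(["label", "weighted"]):
        ax.plot(
            1.0 - grp["specificity"],
            grp["sensitivity"],
            label=f"{label} ({'GEE+IPTW' if weighted else 'GEE'})",
        )
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def km_plot(survival_table: pd.DataFrame, path: str | Path) -> Path:
    """Step plot of per-group Kaplan-Meier curves."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for grp, sub in survival_table.groupby("group"):
        ax.step(sub["time"], sub["survival"], where="post", label=str(grp))
    ax.set_xlabel("months")
    ax.set_ylabel("relapse-free proportion")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
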