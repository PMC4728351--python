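"""Quick-look figures for a study report: CV panels, best-vs-second
scatter, per-trial means.  These mirror the layouts this kind of
repeatability study conventionally reports and are entirely optional —
all numbers live in the JSON/CSV report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import StudyReport


def plot_cv_panels(report: StudyReport, path: str | Path) -> Path:
    """Per-fish CVs with the mean within-CV (95% CI) and the among-CV."""
    measures = list(report.variation)
    fig, axes = plt.subplots(1, max(len(measures), 1), figsize=(3 * len(measures), 3.2),
                             squeeze=False)
    for ax, m in zip(axes[0], measures):
        r = report.variation[m]
        vals = list(r.per_fish_cv.values())
        ax.plot([0] * len(vals), vals, "o", mfc="none", color="tab:blue", alpha=0.7)
        lo, hi = r.within_cv_ci95
        ax.errorbar([1], [r.mean_within_cv], yerr=[[r.mean_within_cv - lo], [hi - r.mean_within_cv]],
                    fmt="o", color="tab:blue")
        ax.plot([2], [r.among_cv], "o", color="tab:red")
        ax.set_xticks([0, 1, 2], ["per fish", "mean within", "among"], rotation=45)
        ax.set_title(m, fontsize=9)
        ax.set_ylabel("CV")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_best_second(report: StudyReport, path: str | Path) -> Path:
    """Best vs second-best value per fish, one panel per measure."""
    measures = list(report.repeatability)
    fig, axes = plt.subplots(1, max(len(measures), 1), figsize=(3 * len(measures), 3.2),
                             squeeze=False)
    for ax, m in zip(axes[0], measures):
        r = report.repeatability[m]
        best = [p[0] for p in r.pairs.values()]
        second = [p[1] for p in r.pairs.values()]
        ax.plot(best, second, "o", color="tab:blue", alpha=0.7)
        ax.set_xlabel("best")
        ax.set_ylabel("second best")
        ax.set_title(f"{m}\nr={r.pearson_r:.2f}, p={r.pearson_p:.3g}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_trial_order(table: pd.DataFrame, path: str | Path) -> Path:
    """Raw values by trial number, one panel per measure."""
    measures = sorted(table["measure"].unique())
    fig, axes = plt.subplots(1, len(measures), figsize=(3 * len(measures), 3.2),
                             squeeze=False)
    for ax, m in zip(axes[0], measures):
        sub = table[table["measure"] == m].dropna(subset=["value"])
        groups = [g["value"].to_numpy() for _, g in sub.groupby("trial")]
        ax.boxplot(groups, positions=sorted(sub["trial"].unique()))
        ax.set_xlabel("trial")
        ax.set_title(m, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
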