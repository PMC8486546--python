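"""Optional figures: group trend curves and ROC overlays.

Matplotlib is imported lazily so the analysis stack has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluate import EvaluationTables, roc_auc


def plot_group_trends(tables: EvaluationTables, path) -> Path:
    """Mean ± SE of each predictor vs time before termination, by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gc = tables.group_comparison
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, var in zip(axes, ("complexity_bits", "hr_bpm", "map_mmhg")):
        sub = gc[gc.variable == var].sort_values("timepoint_s", ascending=False)
        for grp, mcol, scol, ncol in (
            ("syncope", "mean_yes", "sd_yes", "n_yes"),
            ("no syncope", "mean_no", "sd_no", "n_no"),
        ):
            se = sub[scol] / np.sqrt(sub[ncol])
            ax.errorbar(sub.timepoint_s, sub[mcol], yerr=se, label=grp,
                        marker="o", capsize=2)
        ax.set_title(var)
        ax.set_xlabel("time before termination (s)")
        ax.invert_xaxis()
    axes[0].legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_roc_overlays(tables: EvaluationTables, timepoints, path) -> Path:
    """Per-time-point ROC curves of the three predictors, overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = tables.timepoint_values
    fig, axes = plt.subplots(1, len(timepoints), figsize=(4 * len(timepoints), 3.8))
    axes = np.atleast_1d(axes)
    for ax, tau in zip(axes, timepoints):
        sub = values[values.timepoint_s == float(tau)]
        wide = sub.pivot(index="subject_id", columns="variable", values="value")
        lab = sub.drop_duplicates("subject_id").set_index("subject_id")["syncope"]
        complete = wide.dropna()
        y = lab.reindex(complete.index).to_numpy()
        for var in ("complexity_bits", "hr_bpm", "map_mmhg"):
            r = roc_auc(complete[var].to_numpy(), y)
            ax.plot(r.fpr, r.tpr, label=f"{var} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(f"{tau:.0f} s before termination")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
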