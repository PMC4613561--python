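"""Figure helpers: scores plots, |r|-colored coefficient plots, ROC curves
and fatty-acid composition panels. All functions return the figure and can
write it to file; styling is deliberately minimal."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .biomarkers import LoadingsReport
from .fatty_acids import CompositionSummary
from .validation import ROCCurve

_GROUP_COLORS = {"healthy": "tab:green", "benign": "tab:blue", "malignant": "tab:red",
                 "lesion": "tab:orange"}


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), bbox_inches="tight")
        plt.close(fig)
    return fig


def scores_plot(scores: np.ndarray, groups, components=(0, 1), title="scores",
                path=None):
    """2D scatter of score columns, colored by group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.asarray(groups)
    i, j = components
    for g in dict.fromkeys(groups.tolist()):
        m = groups == g
        ax.scatter(scores[m, i], scores[m, j], s=18,
                   color=_GROUP_COLORS.get(str(g)), label=str(g))
    ax.axhline(0, lw=0.5, color="0.7")
    ax.axvline(0, lw=0.5, color="0.7")
    ax.set_xlabel(f"t[{i + 1}]")
    ax.set_ylabel(f"t[{j + 1}]")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return _save(fig, path)


def coefficient_plot(report: LoadingsReport, title="coefficient plot", path=None):
    """Back-scaled coefficient trace colored by |r| (warm = significant)."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    x, y, c = report.bucket_centers, report.coefficient, np.abs(report.r)
    sc = ax.scatter(x, y, c=c, cmap="coolwarm", vmin=0, vmax=1, s=4)
    ax.axhline(0, lw=0.5, color="0.6")
    ax.invert_xaxis()  # NMR convention: ppm decreases to the right
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("coefficient")
    ax.set_title(f"{title}  (|r| cutoff {report.r_crit:.2f}, n={report.n})")
    fig.colorbar(sc, ax=ax, label="|r|")
    return _save(fig, path)


def roc_plot(curve: ROCCurve, title="ROC", path=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - curve.specificity, curve.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="0.6")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title}  AUC = {curve.auc:.3f}")
    return _save(fig, path)


def fatty_acid_panel(summary: CompositionSummary, path=None):
    """Grouped bar chart (mean +/- sd) of class molar percentages and D6D."""
    stats = summary.group_summary()
    feats = list(summary.class_percent.columns) + list(summary.indices.columns)
    groups = list(stats)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    width = 0.8 / len(groups)
    xs = np.arange(len(feats))
    for k, g in enumerate(groups):
        means = [stats[g][f]["mean"] for f in feats]
        sds = [stats[g][f]["sd"] for f in feats]
        ax.bar(xs + k * width, means, width, yerr=sds, capsize=2,
               color=_GROUP_COLORS.get(g), label=g)
    ax.set_xticks(xs + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(feats)
    ax.set_ylabel("mol % / ratio")
    ax.legend(frameon=False, fontsize=8)
    return _save(fig, path)
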