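"""Plots over experiment reports and LR results.

Each function draws on a supplied matplotlib Axes (or creates one) and
returns it, so figures compose in notebooks and scripts.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")  # rendering backend; callers may switch before import
import matplotlib.pyplot as plt
import numpy as np

from .harness import LOG_LR_STRONG, ExperimentReport

#: Rendering sentinel for LR = 0 (log10 LR = -inf) points.
LR_ZERO_SENTINEL = -50.0


def _finite(values, sentinel=LR_ZERO_SENTINEL):
    return [sentinel if not math.isfinite(v) else v for v in values]


def plot_lr_vs_allele_count(report: ExperimentReport, ax=None):
    """Known-donor and non-contributor log10 LRs against called allele count."""
    if ax is None:
        _, ax = plt.subplots()
    df = report.frame()
    if "n_alleles" not in df.columns:
        raise ValueError("report records carry no allele counts")
    contrib = df[df["is_contributor"].astype(bool)]
    noncon = df[~df["is_contributor"].astype(bool)]
    ax.scatter(contrib["n_alleles"], _finite(contrib["log10_lr"]),
               s=14, color="forestgreen", label="known donors")
    if len(noncon):
        ax.scatter(noncon["n_alleles"], _finite(noncon["log10_lr"]),
                   s=10, color="darkorange", alpha=0.5, label="non-contributors")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axhline(LOG_LR_STRONG, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("alleles detected")
    ax.set_ylabel("log10 LR")
    ax.legend(frameon=False)
    return ax


def plot_paired(report: ExperimentReport, class_a: str, class_b: str, ax=None,
                label_a: str | None = None, label_b: str | None = None):
    """Paired per-sample log10 LRs for two analysis classes, with y = x."""
    if ax is None:
        _, ax = plt.subplots()
    df = report.frame()
    a = df[df["class"] == class_a].set_index("sample_id")["log10_lr"]
    b = df[df["class"] == class_b].set_index("sample_id")["log10_lr"]
    common = a.index.intersection(b.index)
    xs = _finite(a.loc[common])
    ys = _finite(b.loc[common])
    ax.scatter(xs, ys, s=16, color="steelblue")
    lo = min(min(xs), min(ys)) - 1
    hi = max(max(xs), max(ys)) + 1
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8, ls="--")
    ax.set_xlabel(label_a or class_a)
    ax.set_ylabel(label_b or class_b)
    return ax


def plot_deconvolution(report: ExperimentReport, ax=None):
    """Grouped bars of reference ceiling / bulk standard / replicate LRs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    df = report.frame()
    donors = sorted(df["donor"].unique())
    models = ["reference_ceiling", "bulk_standard", "dscs_replicate"]
    colors = {"reference_ceiling": "black", "bulk_standard": "grey",
              "dscs_replicate": "forestgreen"}
    width = 0.27
    xs = np.arange(len(donors))
    for i, model in enumerate(models):
        heights = []
        for donor in donors:
            sel = df[(df["donor"] == donor) & (df["model"] == model)]
            if len(sel) and math.isfinite(sel.iloc[0]["log10_lr"]):
                heights.append(sel.iloc[0]["log10_lr"])
            else:
                heights.append(0.0)
        ax.bar(xs + (i - 1) * width, heights, width, color=colors[model],
               label=model.replace("_", " "))
    ax.set_xticks(xs)
    ax.set_xticklabels(donors, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("log10 LR")
    ax.legend(frameon=False, fontsize=8)
    return ax
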