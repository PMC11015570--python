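"""Condition-mean figures with within-subject error bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import RMAnovaResults

__all__ = ["plot_condition_means"]


def plot_condition_means(
    results: RMAnovaResults, path: str | Path, level: float = 0.95
) -> Path:
    """Bar plot of condition means with within-subject confidence intervals.

    Error bars are Cousineau–Morey intervals at ``level``, the appropriate
    uncertainty display for repeated-measures condition means.
    """
    ci = results.within_subject_ci(level)
    fig, ax = plt.subplots(figsize=(5, 4))
    x = range(len(ci))
    means = ci["mean"].to_numpy()
    err = (means - ci["ci_low"].to_numpy(), ci["ci_high"].to_numpy() - means)
    ax.bar(x, means, color="#7a9cc6", edgecolor="black", width=0.6)
    ax.errorbar(x, means, yerr=err, fmt="none", ecolor="black", capsize=4)
    ax.set_xticks(list(x))
    ax.set_xticklabels(ci["condition"], rotation=20, ha="right")
    label = " ".join(p for p in (results.channel, results.band) if p)
    ax.set_ylabel(f"{label} power (μV²)" if label else "power (μV²)")
    ax.set_title(f"Condition means, {int(level * 100)}% within-subject CI")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
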