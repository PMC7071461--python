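"""ROC plots for evaluation results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_mean_roc(results, path, grid_size=101):
    """One panel per classifier x scheme with the vertically averaged ROC."""
    pairs = sorted({(clf, sch) for clf, sch, _ in results.roc_points})
    if not pairs:
        raise ValueError("no ROC curves to plot")
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5),
                             squeeze=False)
    for ax, (clf, sch) in zip(axes.ravel(), pairs):
        fpr, tpr = results.mean_roc(clf, sch, grid_size=grid_size)
        ax.plot(fpr, tpr, lw=2)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(f"{clf} ({sch})")
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
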