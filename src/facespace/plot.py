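"""Plotting helpers (optional, headless-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sphere import ClassifierMap  # noqa: E402

__all__ = ["plot_classifier_map", "plot_agreement"]


def plot_classifier_map(cmap: ClassifierMap, path) -> None:
    """Exemplars (dots, colored by group) and classifiers (+) in the chart."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for spec in cmap.specs:
        sub = cmap.points.subset(spec.label)
        ax.scatter(sub.azel[:, 0], sub.azel[:, 1], s=6, alpha=0.4,
                   label=spec.label)
    ax.scatter(cmap.classifier_azel[:, 0], cmap.classifier_azel[:, 1],
               marker="+", c="k", s=60, label="classifiers")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("elevation (deg)")
    ax.set_xlim(0, 90)
    ax.set_ylim(0, 90)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_agreement(agreement_by_h: dict, path) -> None:
    """Neighbor-agreement index as a function of lateral gain h."""
    hs = sorted(agreement_by_h, key=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(hs)), [agreement_by_h[h] for h in hs], tick_label=hs)
    ax.set_xlabel("lateral gain h")
    ax.set_ylabel("neighbor agreement")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
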