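"""Cosmetic figures: chromosome histogram and a three-set overlap diagram.

Rendering is presentation-only surface; no analysis result depends on it.
"""

from __future__ import annotations

from pathlib import Path

from .groups import ChromosomeDistribution, GroupPartition
from .identification import GROUPS
from .reference import CHROMOSOME_ORDER


def chromosome_bar(dist: ChromosomeDistribution, path: str | Path) -> None:
    """Bar chart of protein counts per chromosome, in the fixed human order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    tokens = list(CHROMOSOME_ORDER)
    ax.bar(range(len(tokens)), [dist.counts[t] for t in tokens], color="#444444")
    ax.set_xticks(range(len(tokens)))
    ax.set_xticklabels(tokens, rotation=90, fontsize=8)
    ax.set_xlabel("Chromosome")
    ax.set_ylabel("Proteins")
    ax.set_title(f"Chromosome distribution ({dist.scope})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def venn_three_groups(partition: GroupPartition, path: str | Path) -> None:
    """Hand-drawn three-circle overlap diagram with region sizes.

    Circles are drawn directly with matplotlib patches; region counts are
    placed at the conventional seven positions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    centers = {"WT": (0.35, 0.6), "KO_NT": (0.65, 0.6), "KO_T": (0.5, 0.35)}
    colors = {"WT": "#1b9e77", "KO_NT": "#d95f02", "KO_T": "#7570b3"}
    # Region label anchor per membership pattern.
    anchors = {
        frozenset({"WT"}): (0.22, 0.68),
        frozenset({"KO_NT"}): (0.78, 0.68),
        frozenset({"KO_T"}): (0.5, 0.2),
        frozenset({"WT", "KO_NT"}): (0.5, 0.68),
        frozenset({"WT", "KO_T"}): (0.36, 0.42),
        frozenset({"KO_NT", "KO_T"}): (0.64, 0.42),
        frozenset(GROUPS): (0.5, 0.52),
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    for group, (x, y) in centers.items():
        ax.add_patch(Circle((x, y), 0.22, alpha=0.35, color=colors[group]))
        ax.text(x, y + 0.26, group, ha="center", fontsize=11)
    for pattern, (x, y) in anchors.items():
        size = len(partition.regions.get(pattern, ()))
        label = partition.labels.get(pattern, "")
        ax.text(x, y, f"{label}\n{size}", ha="center", va="center", fontsize=9)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)
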