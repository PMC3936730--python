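"""SVG renderings of bubble charts and lollipop maps.

Encoding follows the conventions of single-molecule accessibility
figures: one row per sequenced molecule; filled teal circles are GpC
sites the methyltransferase reached (accessible), open circles are
inaccessible sites, and a pink bar underlines each inaccessible run
large enough to accommodate a nucleosome.  Lollipop maps use filled
black circles for methylated CpG sites and open circles for
unmethylated ones.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Rectangle  # noqa: E402

ACCESSIBLE_COLOR = "#2a9d8f"   # teal
BAR_COLOR = "#f4a7c3"          # pink


def bubble_svg(structure: dict, path: str | Path,
               title: str = "") -> None:
    """Render a bubble-chart structure (see nome_stats.bubble_matrix)."""
    sites = structure["sites"]
    molecules = structure["molecules"]
    n = len(molecules)
    fig, ax = plt.subplots(figsize=(max(4, len(sites) * 0.25),
                                    max(2, n * 0.3)))
    for row, mol in enumerate(molecules):
        y = n - 1 - row
        for start, end in mol["bars"]:
            ax.add_patch(Rectangle((start, y - 0.35), end - start + 1, 0.7,
                                   facecolor=BAR_COLOR, edgecolor="none",
                                   zorder=1))
        for pos, state in zip(sites, mol["states"]):
            if state == "accessible":
                ax.plot(pos, y, "o", color=ACCESSIBLE_COLOR, ms=6, zorder=2)
            elif state == "inaccessible":
                ax.plot(pos, y, "o", mfc="white", mec="#2b5d8a", ms=6,
                        zorder=2)
            else:
                ax.plot(pos, y, "x", color="0.6", ms=4, zorder=2)
    ax.set_yticks(range(n))
    ax.set_yticklabels([m["clone_id"] for m in reversed(molecules)],
                       fontsize=6)
    ax.set_xlabel("position (bp)")
    if title:
        ax.set_title(title)
    ax.set_ylim(-1, n)
    fig.tight_layout()
    fig.savefig(str(path), format="svg")
    plt.close(fig)


def lollipop_svg(structure: dict, path: str | Path,
                 title: str = "") -> None:
    """Render a lollipop structure (see methylation.lollipop_matrix)."""
    sites = structure["sites"]
    clones = structure["clones"]
    n = len(clones)
    fig, ax = plt.subplots(figsize=(max(4, len(sites) * 0.25),
                                    max(2, n * 0.3)))
    for row, clone in enumerate(clones):
        y = n - 1 - row
        ax.axhline(y, color="0.85", lw=0.8, zorder=1)
        for pos, circle in zip(sites, clone["circles"]):
            if circle == "filled":
                ax.plot(pos, y, "o", color="black", ms=6, zorder=2)
            elif circle == "open":
                ax.plot(pos, y, "o", mfc="white", mec="black", ms=6,
                        zorder=2)
            else:
                ax.plot(pos, y, "x", color="0.6", ms=4, zorder=2)
    ax.set_yticks(range(n))
    ax.set_yticklabels([c["clone_id"] for c in reversed(clones)],
                       fontsize=6)
    ax.set_xlabel("position (bp)")
    if title:
        ax.set_title(title)
    ax.set_ylim(-1, n)
    fig.tight_layout()
    fig.savefig(str(path), format="svg")
    plt.close(fig)
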