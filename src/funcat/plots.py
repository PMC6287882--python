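"""Optional figure export: strip plots, bubble charts, 2-3-set Venn.

Figures mirror the TSV outputs; the TSVs are the primary artifact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .genesets import ComparisonResult


def strip_plot(
    result: ComparisonResult,
    path: str | Path,
    label_a: str = "reference",
    label_b: str = "other",
) -> None:
    """Paired strip plot of top-gene fold changes in two conditions.

    Fold changes are linear, on a log axis; the dotted reference line
    sits at one (no change).
    """
    fig, ax = plt.subplots(figsize=(3.2, 4.2))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for x, vals in ((0, result.values_a), (1, result.values_b)):
        jit = rng.uniform(-0.08, 0.08, size=len(vals))
        ax.scatter(np.full(len(vals), x) + jit, vals, s=18, alpha=0.8)
    for va, vb in zip(result.values_a, result.values_b):
        ax.plot([0, 1], [va, vb], color="grey", lw=0.4, alpha=0.5)
    ax.axhline(1.0, ls=":", color="black", lw=1)
    ax.set_yscale("log")
    ax.set_xticks([0, 1], [label_a, label_b])
    ax.set_ylabel("fold change")
    ax.set_title(f"KS D = {result.D:.3f}, p = {result.p:.3g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bubble_chart(df: pd.DataFrame, path: str | Path, max_rows: int = 30) -> None:
    """Category bubble chart: size = regulated gene count, colour = -log10 p.

    Expects the frame produced by ``enrichment.bubble_export``; rows
    beyond ``max_rows`` (ordered as given, i.e. by ascending p) are
    dropped for legibility.
    """
    sub = df.head(max_rows).iloc[::-1]
    fig, ax = plt.subplots(figsize=(5.5, 0.28 * len(sub) + 1.2))
    sizes = 20 + 12 * sub["gene_count"].to_numpy()
    sc = ax.scatter(
        sub["fold_enrichment"], range(len(sub)), s=sizes,
        c=sub["minus_log10_p"], cmap="viridis", alpha=0.85,
    )
    ax.set_yticks(range(len(sub)), sub["category_key"], fontsize=7)
    ax.set_xlabel("fold enrichment")
    fig.colorbar(sc, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def venn_figure(
    regions: Mapping[tuple[str, ...], frozenset],
    path: str | Path,
) -> None:
    """Simple 2-3-circle Venn with region counts (plain matplotlib)."""
    names = sorted({n for sig in regions for n in sig})
    m = len(names)
    if m not in (2, 3):
        raise ValueError("venn figures are drawn for 2 or 3 sets only")
    centers = {2: [(-0.5, 0), (0.5, 0)],
               3: [(-0.5, -0.3), (0.5, -0.3), (0, 0.55)]}[m]
    label_pos = {
        2: {("A",): (-1.0, 0), ("B",): (1.0, 0), ("A", "B"): (0, 0)},
        3: {("A",): (-1.0, -0.5), ("B",): (1.0, -0.5), ("C",): (0, 1.1),
            ("A", "B"): (0, -0.45), ("A", "C"): (-0.55, 0.3),
            ("B", "C"): (0.55, 0.3), ("A", "B", "C"): (0, 0)},
    }[m]
    rename = dict(zip("ABC", names))
    fig, ax = plt.subplots(figsize=(4, 4))
    for (x, y), name, color in zip(centers, names, ("tab:red", "tab:blue", "tab:green")):
        ax.add_patch(plt.Circle((x, y), 1.0, alpha=0.3, color=color))
        ax.annotate(name, (x, y + 1.05), ha="center", fontsize=9)
    for sig_generic, (x, y) in label_pos.items():
        sig = tuple(rename[s] for s in sig_generic)
        ax.annotate(str(len(regions.get(sig, frozenset()))), (x, y),
                    ha="center", va="center", fontsize=10)
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
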