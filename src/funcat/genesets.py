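"""Regulated gene-set selection and cross-condition comparison.

Regulated sets are cut from a differential-expression summary table at
a fold-change / FDR threshold pair (default: more than 2-fold with FDR
below 0.01, both strict).  Sets from 2-4 conditions are partitioned
into Venn regions; the strongest responders of a reference condition
are compared against another condition with a two-sample
Kolmogorov-Smirnov test on their linear fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class DifferentialTable:
    """Per-gene log2 fold change and FDR for one contrast.

    Gene ids are unique; ``fdr`` lies in [0, 1]; ``log2fc`` is finite.
    """

    def __init__(self, frame: pd.DataFrame, label: str = ""):
        required = {"gene_id", "log2fc", "fdr"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        if frame["gene_id"].duplicated().any():
            dup = frame.loc[frame["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        log2fc = pd.to_numeric(frame["log2fc"])
        fdr = pd.to_numeric(frame["fdr"])
        if not np.isfinite(log2fc).all():
            raise ValueError("log2fc contains non-finite values")
        if ((fdr < 0) | (fdr > 1)).any():
            bad = frame.loc[(fdr < 0) | (fdr > 1), "gene_id"].iloc[0]
            raise ValueError(f"fdr outside [0, 1] for gene {bad!r}")
        self.frame = pd.DataFrame(
            {"gene_id": frame["gene_id"].astype(str), "log2fc": log2fc, "fdr": fdr}
        ).reset_index(drop=True)
        self.label = label

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, float, float]],
        label: str = "",
    ) -> "DifferentialTable":
        df = pd.DataFrame(records, columns=["gene_id", "log2fc", "fdr"])
        return cls(df, label=label)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> list[str]:
        return self.frame["gene_id"].tolist()

    def lookup(self, genes: Sequence[str]) -> pd.DataFrame:
        """Rows for ``genes``, in the given order; missing genes absent."""
        sub = self.frame.set_index("gene_id")
        present = [g for g in genes if g in sub.index]
        return sub.loc[present].reset_index()


@dataclass(frozen=True)
class RegulatedSet:
    """Genes passing a direction/fold/FDR cut, with the cut recorded."""

    genes: frozenset[str]
    direction: str
    fold_threshold: float
    fdr_threshold: float
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.genes)


def select_regulated(
    table: DifferentialTable,
    direction: str,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    inclusive: bool = False,
) -> RegulatedSet:
    """Select up- or down-regulated genes.

    The default cut is strict on both sides: the up-set is genes with
    log2fc > log2(fold_threshold) *and* fdr < fdr_threshold; the
    down-set mirrors it with log2fc < -log2(fold_threshold).  Boundary
    values (exactly 2-fold, FDR exactly 0.01) are excluded unless
    ``inclusive`` is set.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    if len(table) == 0:
        logger.warning("empty differential table: regulated set is empty")
        return RegulatedSet(frozenset(), direction, fold_threshold, fdr_threshold,
                            table.label)

    cut = math.log2(fold_threshold)
    lfc = table.frame["log2fc"]
    fdr = table.frame["fdr"]
    if inclusive:
        fc_ok = lfc >= cut if direction == "up" else lfc <= -cut
        fdr_ok = fdr <= fdr_threshold
    else:
        fc_ok = lfc > cut if direction == "up" else lfc < -cut
        fdr_ok = fdr < fdr_threshold
    genes = frozenset(table.frame.loc[fc_ok & fdr_ok, "gene_id"])
    return RegulatedSet(genes, direction, fold_threshold, fdr_threshold, table.label)


def _as_named_sets(
    sets: Sequence[RegulatedSet | frozenset | set] | Mapping[str, Iterable[str]],
    labels: Sequence[str] | None = None,
) -> dict[str, frozenset[str]]:
    if isinstance(sets, Mapping):
        named = {str(k): frozenset(v) for k, v in sets.items()}
    else:
        named = {}
        for i, s in enumerate(sets):
            if isinstance(s, RegulatedSet):
                name = s.source_label or chr(ord("A") + i)
                members = s.genes
            else:
                name = chr(ord("A") + i)
                members = frozenset(s)
            if labels is not None:
                name = labels[i]
            if name in named:
                raise ValueError(f"duplicate set label {name!r}")
            named[name] = frozenset(members)
    return named


def venn_partition(
    sets: Sequence[RegulatedSet | frozenset | set] | Mapping[str, Iterable[str]],
    labels: Sequence[str] | None = None,
) -> dict[tuple[str, ...], frozenset[str]]:
    """Partition 2-4 gene sets into disjoint Venn regions.

    Returns every non-empty membership signature (2^m - 1 regions) as a
    tuple of the member-set labels, mapped to the genes exactly in
    those sets and no others.  Regions are disjoint and their union is
    the union of the inputs; a region may be empty.
    """
    named = _as_named_sets(sets, labels)
    m = len(named)
    if not (2 <= m <= 4):
        raise ValueError(f"venn_partition takes 2-4 sets, got {m}")
    names = list(named)
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, m + 1):
        for combo in combinations(names, r):
            inside = frozenset.intersection(*(named[n] for n in combo))
            outside = frozenset().union(*(named[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    return regions


def venn_counts(
    regions: Mapping[tuple[str, ...], frozenset[str]]
) -> dict[tuple[str, ...], int]:
    return {sig: len(genes) for sig, genes in regions.items()}


def top_n(table: DifferentialTable, direction: str, n: int = 20) -> list[str]:
    """Top-n genes by fold-change magnitude within one direction.

    Up-regulated genes rank by largest log2fc, down-regulated by most
    negative.  Ties break by smaller FDR, then lexicographic gene id,
    so the ranking is deterministic.  Returns min(n, available) genes.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    df = table.frame
    df = df[df["log2fc"] > 0] if direction == "up" else df[df["log2fc"] < 0]
    if len(df) == 0:
        raise ValueError(f"no genes with direction {direction!r}")
    ranked = df.assign(_mag=df["log2fc"].abs()).sort_values(
        ["_mag", "fdr", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked["gene_id"].head(n).tolist()


@dataclass(frozen=True)
class ComparisonResult:
    """Matched fold-change vectors of top-N genes in two conditions."""

    genes: tuple[str, ...]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    D: float
    p: float
    dropped: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "fold_change_reference": self.values_a,
                "fold_change_other": self.values_b,
            }
        )


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample KS statistic D: the maximum absolute ECDF difference."""
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float),
                         alternative="two-sided", method="asymp")
    return float(res.statistic)


def _sorted_ks_d(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    """KS D for pre-sorted samples via ECDF evaluation at pooled points."""
    pooled = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, pooled, side="right") / len(a_sorted)
    cdf_b = np.searchsorted(b_sorted, pooled, side="right") / len(b_sorted)
    return float(np.abs(cdf_a - cdf_b).max())


def ks_permutation_p(
    a: Sequence[float],
    b: Sequence[float],
    n_permutations: int = 100_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the two-sample KS statistic (seeded)."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    d_obs = _sorted_ks_d(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = len(a)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _sorted_ks_d(np.sort(perm[:n_a]), np.sort(perm[n_a:])) >= d_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def top_n_comparison(
    reference: DifferentialTable,
    other: DifferentialTable,
    direction: str = "up",
    n: int = 20,
    p_mode: str = "asymp",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> ComparisonResult:
    """Compare the reference condition's top-n genes across conditions.

    ``values_a`` are the linear fold changes (2**log2fc) of the
    reference's top-n genes in the reference table; ``values_b`` the
    fold changes of the same genes in ``other``.  Genes missing from
    ``other`` are dropped pairwise with a warning.  D is the two-sample
    KS statistic; p comes from the asymptotic Kolmogorov distribution,
    or from a seeded permutation test when ``p_mode='permutation'``.
    """
    genes = top_n(reference, direction, n)
    other_idx = other.frame.set_index("gene_id")
    kept = [g for g in genes if g in other_idx.index]
    dropped = tuple(g for g in genes if g not in other_idx.index)
    if dropped:
        logger.warning("%d top gene(s) missing from comparison table: %s",
                       len(dropped), ", ".join(dropped))
    if len(kept) < 2:
        raise ValueError("fewer than 2 matched genes: KS comparison undefined")

    ref_idx = reference.frame.set_index("gene_id")
    values_a = np.exp2(ref_idx.loc[kept, "log2fc"].to_numpy())
    values_b = np.exp2(other_idx.loc[kept, "log2fc"].to_numpy())
    res = stats.ks_2samp(values_a, values_b, alternative="two-sided", method="asymp")
    d = float(res.statistic)
    if p_mode == "asymp":
        p = float(min(res.pvalue, 1.0))
    elif p_mode == "permutation":
        p = ks_permutation_p(values_a, values_b, n_permutations, seed)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    return ComparisonResult(
        tuple(kept), tuple(values_a), tuple(values_b), d, p, dropped
    )
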