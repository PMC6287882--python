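"""Category over-representation scoring.

For a regulated gene set of size n drawn from an annotated universe of
N genes, a category containing K universe genes and k regulated genes
is scored with the right tail of the hypergeometric distribution —
Fisher's exact test for over-representation:

    p = sum_{x = k}^{min(n, K)} C(K, x) C(N-K, n-x) / C(N, n)

computed in log space for stability.  Fold enrichment is
(k/n) / (K/N).  Categories are tested at each of the three rollup
levels; a *tiered* analysis scores both the >2-fold regulated set
("enriched") and the >4-fold subset ("super_enriched"), the latter
highlighting categories driven by the largest expression changes.
Significance is a strict p < alpha (default 0.05); anything else is
flagged NS.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg column is available for users who want one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .annotation import AnnotationTable, background_counts
from .genesets import DifferentialTable, RegulatedSet, select_regulated

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: fold-change thresholds of the two analysis tiers
TIERS = {"enriched": 2.0, "super_enriched": 4.0}


@dataclass(frozen=True)
class ContingencyTable:
    """Margins of one category test.

    k: regulated genes in the category; n: regulated genes in the
    universe; K: universe genes in the category; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def validate(self) -> None:
        for name in ("k", "n", "K", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"margin {name} must be a non-negative integer, got {v!r}")
        if self.n > self.N:
            raise ValueError(f"margin n={self.n} exceeds N={self.N}")
        if self.K > self.N:
            raise ValueError(f"margin K={self.K} exceeds N={self.N}")
        if self.k > min(self.n, self.K):
            raise ValueError(f"margin k={self.k} exceeds min(n, K)={min(self.n, self.K)}")
        # genes outside both the set and the category must be countable
        if self.n + self.K - self.k > self.N:
            raise ValueError(f"margin k={self.k} too small for n={self.n}, K={self.K}, N={self.N}")

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.k, self.n - self.k],
            [self.K - self.k, self.N - self.K - (self.n - self.k)],
        ]


@lru_cache(maxsize=1_000_000)
def _hypergeom_right_tail(k: int, n: int, K: int, N: int) -> float:
    if k == 0:
        return 1.0
    xs = np.arange(k, min(n, K) + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
        + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def fisher_right_tail(t: ContingencyTable) -> float:
    """Right-tailed Fisher exact p: P(X >= k) under the hypergeometric null.

    Computed as a log-space sum of hypergeometric pmf terms; always in
    (0, 1].  k = 0 gives exactly 1.0 (the right tail spans the whole
    support).
    """
    t.validate()
    return _hypergeom_right_tail(t.k, t.n, t.K, t.N)


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p (optional mode)."""
    from scipy.stats import fisher_exact

    t.validate()
    return float(fisher_exact(t.as_2x2(), alternative="two-sided")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    """One category at one level: counts, p, fold enrichment, tier, flag."""

    category_key: str
    level: int
    counts: ContingencyTable
    p: float
    fold_enrichment: float
    tier: str = "enriched"
    significant: bool = False


def enrich(
    regulated: RegulatedSet | Iterable[str],
    table: AnnotationTable,
    level: int,
    alpha: float = DEFAULT_ALPHA,
    tier: str = "enriched",
    sided: str = "right",
) -> list[EnrichmentResult]:
    """Score every category at one rollup level against a gene set.

    n counts only set members present in the annotation (absent genes
    are dropped and their number logged).  Every category with at least
    one universe gene is tested.  Results are sorted by ascending p,
    then category key.
    """
    if len(table) == 0:
        raise ValueError("annotation table is empty")
    genes = regulated.genes if isinstance(regulated, RegulatedSet) else frozenset(regulated)
    expanded = table.expanded_keys
    members = [g for g in genes if g in expanded]
    n_dropped = len(genes) - len(members)
    if n_dropped:
        logger.info("%d regulated gene(s) absent from the annotation were dropped",
                    n_dropped)
    if not members:
        logger.warning("no regulated genes present in the annotation: no results")
        return []

    bg = background_counts(table, level)
    n = len(members)
    N = table.universe_size
    k_by_cat: dict[str, int] = {}
    for g in members:
        key = expanded[g][level - 1]
        k_by_cat[key] = k_by_cat.get(key, 0) + 1

    score = fisher_right_tail if sided == "right" else fisher_two_sided
    results = []
    for key, K in bg.items():
        k = k_by_cat.get(key, 0)
        t = ContingencyTable(k=k, n=n, K=K, N=N)
        p = score(t)
        fe = (k / n) / (K / N)
        results.append(
            EnrichmentResult(key, level, t, p, fe, tier, significant=bool(p < alpha))
        )
    results.sort(key=lambda r: (r.p, r.category_key))
    return results


def tiered_enrichment(
    table_de: DifferentialTable,
    annotation: AnnotationTable,
    direction: str,
    levels: Sequence[int] = (1, 2, 3),
    alpha: float = DEFAULT_ALPHA,
    fdr_threshold: float = 0.01,
    tiers: Mapping[str, float] = TIERS,
    sided: str = "right",
) -> dict[str, dict[int, list[EnrichmentResult]]]:
    """Score both analysis tiers at the requested levels.

    The enriched tier uses the >2-fold regulated set, the super-enriched
    tier the >4-fold subset (same FDR cut), so per category the super
    tier's k never exceeds the enriched tier's.
    """
    out: dict[str, dict[int, list[EnrichmentResult]]] = {}
    for tier, fold in tiers.items():
        rset = select_regulated(table_de, direction, fold, fdr_threshold)
        out[tier] = {}
        if len(rset) == 0:
            logger.warning("tier %r: no genes pass %s-fold / FDR < %s",
                           tier, fold, fdr_threshold)
            for level in levels:
                out[tier][level] = []
            continue
        for level in levels:
            out[tier][level] = enrich(rset, annotation, level, alpha, tier, sided)
    return out


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional output column)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bubble_export(
    results: Sequence[EnrichmentResult],
    padj: bool = False,
) -> pd.DataFrame:
    """Flatten results for bubble-chart plotting / TSV output.

    One row per result, in input order.  ``minus_log10_p`` is -log10(p)
    (0 when p = 1); the significance label is "NS" for categories at or
    above alpha.
    """
    df = pd.DataFrame(
        {
            "category_key": [r.category_key for r in results],
            "level": [r.level for r in results],
            "tier": [r.tier for r in results],
            "gene_count": [r.counts.k for r in results],
            "n": [r.counts.n for r in results],
            "K": [r.counts.K for r in results],
            "N": [r.counts.N for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p": [r.p for r in results],
            "minus_log10_p": [0.0 if r.p >= 1.0 else -np.log10(r.p) for r in results],
            "label": ["significant" if r.significant else "NS" for r in results],
        }
    )
    if padj and len(df):
        df.insert(9, "padj", benjamini_hochberg(df["p"].to_numpy()))
    return df
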