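"""Seeded synthetic inputs: annotation tables, differential-expression
tables with planted category enrichments, and stress-evidence matrices.

The generator emulates the statistical shape of the real inputs — a
~16,000-gene curated annotation with heavy-tailed category sizes and
three nesting levels, and per-contrast DE summaries where a few hundred
genes respond strongly (up to hundreds-fold) while the bulk sits near
zero log2 fold change — at a scale small enough for fast tests (default
5,000 genes, 40 broad categories).

Everything is deterministic under the config seed.  Each generator
derives its own independent stream from (seed, stream-id), so adding a
generator never perturbs the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationTable,
    CategoryPath,
    PATH_DELIMITER,
    STRESS_DATASETS,
    StressEvidenceMatrix,
)
from .genesets import DifferentialTable

# independent sub-stream ids per generator
_STREAM_ANNOTATION = 1
_STREAM_DE = 2
_STREAM_EVIDENCE = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic universe and one simulated contrast.

    seed
        master seed; fixed seed -> bit-identical output.
    n_genes, n_level1
        universe size and number of broad (level-1) categories.
    branching
        mean number of children per node at levels 2 and 3 (>= 1).
    depth_distribution
        probabilities that a gene's path stops at depth 1, 2 or 3.
    zipf_exponent
        category-size skew: level-1 weights proportional to 1/rank^s.
    pinned_level1
        (label, exact gene count) pairs for level-1 categories whose
        size must be fixed, e.g. a 50-gene category used for planting.
    planted
        (category key, enrichment factor >= 1) pairs: genes under the
        key are that factor more likely to be regulated.
    query_size / regulated_fraction
        number of regulated genes per contrast (fraction used when
        query_size is None).
    direction
        sign of the regulated genes' log2 fold change.
    effect_loc, effect_scale
        regulated |log2fc| = effect_loc + Exponential(effect_scale);
        the default floor 1.05 keeps every regulated gene above the
        2-fold selection cut, with an exponential tail reaching the
        hundreds-fold inductions seen in strong stress responses.
    null_log2fc_sd
        spread of the unregulated genes' log2fc around zero.
    fdr_null
        (low, high) of the uniform FDR for unregulated genes;
        regulated genes draw FDR uniformly below 0.01.
    """

    seed: int = 0
    n_genes: int = 5000
    n_level1: int = 40
    branching: float = 3.0
    depth_distribution: tuple[float, float, float] = (0.25, 0.45, 0.30)
    zipf_exponent: float = 1.0
    pinned_level1: tuple[tuple[str, int], ...] = ()
    planted: tuple[tuple[str, float], ...] = ()
    query_size: int | None = 200
    regulated_fraction: float | None = None
    direction: str = "up"
    effect_loc: float = 1.05
    effect_scale: float = 1.5
    null_log2fc_sd: float = 0.3
    fdr_null: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if abs(sum(self.depth_distribution) - 1.0) > 1e-9:
            raise ValueError("depth_distribution must sum to 1")
        if any(f < 1 for _, f in self.planted):
            raise ValueError("planted enrichment factors must be >= 1")
        if self.regulated_fraction is not None and self.regulated_fraction > 1:
            raise ValueError("regulated_fraction must be <= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def simulate_annotation(cfg: SimulationConfig) -> AnnotationTable:
    """Generate a 3-level annotated universe.

    Level-1 category weights follow a Zipf-like law (heavy tail, as in
    curated annotations where a few broad classes hold most genes).
    Pinned categories receive exactly their requested gene count at
    depth 1; the remaining genes are allocated over the generated
    hierarchy with depths drawn from ``depth_distribution``.
    """
    pinned_total = sum(size for _, size in cfg.pinned_level1)
    n_free = cfg.n_genes - pinned_total
    if cfg.n_level1 < 1 or n_free < cfg.n_level1:
        raise ValueError(
            f"infeasible config: {cfg.n_level1} level-1 categories for "
            f"{n_free} unpinned genes"
        )
    rng = _rng(cfg.seed, _STREAM_ANNOTATION)

    cats = [f"C{i + 1:02d}" for i in range(cfg.n_level1)]
    n_child2 = 1 + rng.poisson(max(cfg.branching - 1, 0), size=cfg.n_level1)
    n_child3 = {
        (i, j): 1 + rng.poisson(max(cfg.branching - 1, 0))
        for i in range(cfg.n_level1)
        for j in range(n_child2[i])
    }

    weights = 1.0 / np.arange(1, cfg.n_level1 + 1) ** cfg.zipf_exponent
    weights /= weights.sum()

    entries: dict[str, CategoryPath] = {}
    gene_no = 0

    def next_gene() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"g{gene_no:05d}"

    for label, size in cfg.pinned_level1:
        for _ in range(size):
            entries[next_gene()] = CategoryPath(label)

    # one gene per level-1 category guarantees every category is non-empty
    cat_idx = np.concatenate(
        [np.arange(cfg.n_level1),
         rng.choice(cfg.n_level1, size=n_free - cfg.n_level1, p=weights)]
    )
    depths = rng.choice([1, 2, 3], size=n_free, p=cfg.depth_distribution)
    for i, depth in zip(cat_idx, depths):
        l1 = cats[i]
        if depth == 1:
            entries[next_gene()] = CategoryPath(l1)
            continue
        j = rng.integers(n_child2[i])
        l2 = f"S{j + 1:02d}"
        if depth == 2:
            entries[next_gene()] = CategoryPath(l1, l2)
        else:
            t = rng.integers(n_child3[(i, j)])
            entries[next_gene()] = CategoryPath(l1, l2, f"T{t + 1:02d}")
    return AnnotationTable(entries)


def simulate_de_table(
    annotation: AnnotationTable, cfg: SimulationConfig
) -> DifferentialTable:
    """Simulate one contrast's DE summary with planted enrichments.

    Regulated genes are drawn without replacement with per-gene weights
    equal to the product of the planted factors whose category key
    appears among the gene's rollup keys (successive weighted draws via
    exponential race keys, i.e. Wallenius-type biased sampling).
    Regulated genes get a strong signed log2fc and FDR below 0.01;
    everything else gets near-zero log2fc and a null FDR.
    """
    genes = sorted(annotation.entries)
    n_genes = len(genes)
    if cfg.query_size is not None:
        n_reg = cfg.query_size
    else:
        if cfg.regulated_fraction is None:
            raise ValueError("either query_size or regulated_fraction is required")
        n_reg = round(cfg.regulated_fraction * n_genes)
    if n_reg > n_genes:
        raise ValueError("regulated set larger than the universe")

    all_keys = {k for keys in annotation.expanded_keys.values() for k in keys}
    for key, _ in cfg.planted:
        if key not in all_keys:
            raise ValueError(f"planted category key {key!r} not in annotation")

    weights = np.ones(n_genes)
    expanded = annotation.expanded_keys
    for key, factor in cfg.planted:
        hit = np.array([key in expanded[g] for g in genes])
        weights[hit] *= factor

    rng = _rng(cfg.seed, _STREAM_DE)
    # smallest exponential(1)/w keys == successive weighted sampling w/o replacement
    race = rng.exponential(1.0, size=n_genes) / weights
    reg_idx = np.argsort(race, kind="stable")[:n_reg]
    regulated = np.zeros(n_genes, bool)
    regulated[reg_idx] = True

    sign = 1.0 if cfg.direction == "up" else -1.0
    log2fc = rng.normal(0.0, cfg.null_log2fc_sd, size=n_genes)
    log2fc[regulated] = sign * (
        cfg.effect_loc + rng.exponential(cfg.effect_scale, size=n_reg)
    )
    fdr = rng.uniform(*cfg.fdr_null, size=n_genes)
    fdr[regulated] = rng.uniform(0.0, 0.009, size=n_reg)

    frame = pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "fdr": fdr})
    return DifferentialTable(frame, label=f"sim_seed{cfg.seed}")


def simulate_evidence_matrix(
    annotation: AnnotationTable,
    n_stresses: int = 6,
    change_prob: float = 0.3,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> StressEvidenceMatrix:
    """Independent Bernoulli "expression changed" cells per gene x stress.

    Columns default to the six reference stress exposures.  ``gene_ids``
    overrides the row set (e.g. to include unannotated genes).
    """
    if not (0.0 <= change_prob <= 1.0):
        raise ValueError("change_prob must be in [0, 1]")
    rows = list(gene_ids) if gene_ids is not None else sorted(annotation.entries)
    names = list(STRESS_DATASETS[:n_stresses])
    names += [f"stress{i + 1}" for i in range(len(names), n_stresses)]
    rng = _rng(seed, _STREAM_EVIDENCE)
    cells = rng.random((len(rows), n_stresses)) < change_prob
    return StressEvidenceMatrix(pd.DataFrame(cells, index=rows, columns=names))
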