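"""Score a gene list across single-cell clusters and compare neuronal classes.

Each cluster receives a score: the sum over the query (differentially
expressed) genes of log10-transformed cluster-level counts.  "Counts per
gene per cluster" is taken as the cluster mean count with a +1 pseudo-count
before the log10 — scale-stable across cluster sizes; a sum-of-counts mode
is available for audit.  Classes (e.g. glutamatergic vs GABAergic plus
non-neuronal) are compared with a two-sided Wilcoxon rank-sum test on the
cluster scores: the cluster, not the cell, is the sampling unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger("stressmap")

CELL_CLASSES = ("GABAergic", "glutamatergic", "non-neuronal")


@dataclass(frozen=True)
class CellClusterProfile:
    cluster_id: str
    cell_class: str
    n_cells: int
    score: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("cluster must contain >= 1 cell")
        if not np.isfinite(self.score):
            raise ValueError("cluster score must be finite")


def cluster_scores(
    counts: np.ndarray,
    gene_ids: Sequence[str],
    cluster_labels: Sequence[str],
    class_labels: Sequence[str],
    de_genes: Sequence[str],
    agg: str = "mean",
    pseudo_count: float = 1.0,
) -> list[CellClusterProfile]:
    """Per-cluster sum of log10(aggregated count + pseudo_count) over DE genes.

    ``counts`` is genes x cells (non-negative).  ``agg`` is ``mean`` (default)
    or ``sum``.  Query genes absent from the matrix are dropped with a logged
    count; an empty intersection is an error.  Each cluster must map to a
    single cell class.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    if counts.shape != (len(gene_ids), len(cluster_labels)):
        raise ValueError("counts shape does not match gene/cell labels")
    if len(class_labels) != len(cluster_labels):
        raise ValueError("cluster and class label lengths differ")
    if agg not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    hit = [gene_pos[g] for g in de_genes if g in gene_pos]
    n_missing = len(set(de_genes)) - len({g for g in de_genes if g in gene_pos})
    if n_missing:
        logger.info("%d query gene(s) absent from the count matrix dropped", n_missing)
    if not hit:
        raise ValueError("no query gene present in the count matrix")
    cluster_labels = np.asarray(cluster_labels)
    class_labels = np.asarray(class_labels)
    profiles: list[CellClusterProfile] = []
    for cluster in pd.unique(cluster_labels):
        cells = cluster_labels == cluster
        n_cells = int(cells.sum())
        if n_cells == 0:
            logger.warning("cluster %r has no cells: excluded", cluster)
            continue
        classes = set(class_labels[cells])
        if len(classes) != 1:
            raise ValueError(f"cluster {cluster!r} spans multiple cell classes {classes}")
        block = counts[np.ix_(hit, np.nonzero(cells)[0])]
        agg_counts = block.mean(axis=1) if agg == "mean" else block.sum(axis=1)
        score = float(np.log10(agg_counts + pseudo_count).sum())
        profiles.append(
            CellClusterProfile(
                cluster_id=str(cluster),
                cell_class=classes.pop(),
                n_cells=n_cells,
                score=score,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[CellClusterProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [p.cluster_id for p in profiles],
            "cell_class": [p.cell_class for p in profiles],
            "n_cells": [p.n_cells for p in profiles],
            "score": [p.score for p in profiles],
        }
    )


def class_comparison(
    profiles: Sequence[CellClusterProfile],
    group_a: set[str] = frozenset({"glutamatergic"}),
    group_b: set[str] = frozenset({"GABAergic", "non-neuronal"}),
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on cluster scores between two classes.

    Exact null distribution when the combined number of clusters is <= 20 and
    the scores are tie-free; normal approximation with tie correction
    otherwise.  Returns (W, p) with W the Mann-Whitney U of group_a.
    """
    x = [p.score for p in profiles if p.cell_class in group_a]
    y = [p.score for p in profiles if p.cell_class in group_b]
    if not x or not y:
        raise ValueError("both class groups need at least one cluster")
    n = len(x) + len(y)
    has_ties = len(set(x + y)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
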