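"""Per-cluster expression-frequency enrichment in single-cell counts.

A cell "expresses" a gene when its raw count reaches ``min_count``
(default 1: presence/absence); no normalization is applied.  For a
cluster, the statistic is the expression frequency (expressing cells /
cluster size), the enrichment fold over the all-cell frequency, and an
upper-tail hypergeometric p-value: drawing the cluster's cells from the
pool of all cells, how surprising is it to capture at least the
observed number of expressing cells.  The hypergeometric is the
simplest exchangeable null consistent with a (frequency, fold, p)
summary; the clustering itself is an input, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from difflib import get_close_matches

import numpy as np
from scipy.stats import hypergeom


@dataclass
class CountMatrix:
    """Dense or sparse cell×gene raw counts with row/column names."""

    matrix: object  # (n_cells, n_genes) ndarray or scipy.sparse
    gene_names: list[str]
    cell_ids: list[str]

    def gene_column(self, gene: str) -> np.ndarray:
        if gene not in self.gene_names:
            near = get_close_matches(gene, self.gene_names, n=3)
            raise KeyError(
                f"gene {gene!r} not in matrix"
                + (f"; nearest: {', '.join(near)}" if near else "")
            )
        j = self.gene_names.index(gene)
        col = self.matrix[:, j]
        if hasattr(col, "toarray"):
            col = col.toarray().ravel()
        return np.asarray(col).ravel()


@dataclass
class EnrichmentResult:
    gene: str
    cluster: str
    n_cells_cluster: int
    n_expressing_cluster: int
    frequency: float
    overall_frequency: float
    fold: float
    pvalue: float


def detect_expressing(counts: CountMatrix, gene: str, min_count: int = 1) -> np.ndarray:
    """Boolean per cell: raw count for ``gene`` >= ``min_count``."""
    return counts.gene_column(gene) >= min_count


def cluster_enrichment(
    expressing_flags: np.ndarray,
    cluster_labels: np.ndarray,
    cluster: str,
    gene: str = "",
) -> EnrichmentResult:
    """Frequency, fold and upper-tail hypergeometric p for one cluster.

    With N cells in total, K of them expressing, and a cluster of n
    cells containing k expressing cells:

        p = P[X >= k],  X ~ Hypergeometric(N, K, n)
    """
    flags = np.asarray(expressing_flags, dtype=bool)
    labels = np.asarray(cluster_labels)
    if flags.shape != labels.shape:
        raise ValueError("expressing flags and cluster labels differ in length")
    in_cluster = labels == cluster
    n = int(in_cluster.sum())
    if n == 0:
        raise ValueError(f"cluster {cluster!r} is empty or absent")
    N = flags.size
    K = int(flags.sum())
    k = int(flags[in_cluster].sum())
    frequency = k / n
    overall = K / N
    fold = frequency / overall if overall > 0 else (0.0 if k == 0 else np.inf)
    pvalue = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        gene=gene, cluster=str(cluster),
        n_cells_cluster=n, n_expressing_cluster=k,
        frequency=frequency, overall_frequency=overall,
        fold=fold, pvalue=min(pvalue, 1.0),
    )


def enrich_all_clusters(
    counts: CountMatrix,
    cluster_labels: np.ndarray,
    gene: str,
    min_count: int = 1,
) -> list[EnrichmentResult]:
    """Enrichment of one gene in every cluster, sorted by ascending p."""
    flags = detect_expressing(counts, gene, min_count=min_count)
    labels = np.asarray(cluster_labels)
    results = [
        cluster_enrichment(flags, labels, c, gene=gene)
        for c in sorted(set(labels.tolist()))
    ]
    results.sort(key=lambda r: (r.pvalue, -r.fold))
    return results
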