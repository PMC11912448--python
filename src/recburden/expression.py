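"""Embryonic lineage-specificity scoring of candidate genes.

Genes recurrently hit by recessive genotypes are profiled against a
cell-type x gene mean-expression matrix from embryonic (gastrulation-stage)
single-cell data. Each gene's expression vector is normalized to its
maximum across cell types ("ratio of max"); a gene is lineage-specific when
its top cell type exceeds every other cell type at least fivefold; genes
are ordered by UPGMA (average-linkage) hierarchical clustering of the
normalized rows. Lineage-restricted gene sets (e.g. cardiomyocyte-specific
genes in probands with left-sided defects) are then tested for RG
enrichment with the mutability-based binomial machinery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from recburden import burden

DEFAULT_FOLD = 5.0


def ratio_of_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene row by its maximum; all-zero rows are dropped.

    Idempotent: applying it twice equals applying it once.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    row_max = matrix.max(axis=1)
    zero = row_max == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero expression rows")
        matrix = matrix.loc[~zero]
        row_max = row_max.loc[~zero]
    return matrix.div(row_max, axis=0)


def specific_genes(matrix: pd.DataFrame, fold: float = DEFAULT_FOLD) -> pd.DataFrame:
    """Per-gene specificity flag and top cell type.

    A gene is specific when its top expression is >= fold x every other
    cell type. A tie at the maximum is never specific (ratio 1 < fold).
    Scale-invariant per row.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=1)
    top_idx = order[:, -1]
    top = values[np.arange(len(values)), top_idx]
    second = values[np.arange(len(values)), order[:, -2]]
    specific = np.where(second > 0, top >= fold * second, top > 0)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "specific": specific,
            "top_cell_type": matrix.columns.to_numpy()[top_idx],
        }
    ).set_index("gene")


def upgma_cluster(
    normalized: pd.DataFrame, metric: str = "euclidean"
) -> tuple[np.ndarray, list[str]]:
    """UPGMA (average-linkage) clustering of ratio-of-max rows.

    Returns the scipy linkage matrix and the leaf-order gene list.
    Deterministic for a fixed input; ties are broken by input order.
    """
    if len(normalized) < 2:
        raise ValueError("need >= 2 genes to cluster")
    dist = pdist(normalized.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(Z)
    return Z, [normalized.index[i] for i in leaves]


def map_homologs(
    genes: pd.Series | list[str], homolog_map: pd.DataFrame
) -> pd.Series:
    """Translate symbols through a two-column (source, target) homolog table.

    Unmapped genes are dropped (count logged via warning).
    """
    lut = homolog_map.set_index(homolog_map.columns[0])[homolog_map.columns[1]]
    s = pd.Series(list(genes))
    mapped = s.map(lut)
    n_missing = int(mapped.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} genes had no homolog mapping and were dropped")
    return mapped.dropna()


def lineage_set_enrichment(
    specific_set: set[str],
    rgs: pd.DataFrame,
    model: burden.ExpectedModel,
    cohort_samples: set[str] | None = None,
    n: int | None = None,
    unit: str = "lineage_set",
) -> burden.EnrichmentResult:
    """RG enrichment of a lineage-specific gene set in a cohort subset.

    Delegates to :func:`recburden.burden.gene_set_test`; with
    ``cohort_samples=None`` this is exactly the whole-cohort gene-set test.
    """
    sub = rgs if cohort_samples is None else rgs[rgs["sample"].isin(cohort_samples)]
    genes = set(specific_set) & set(model.expected.index)
    if not genes:
        raise ValueError("no gene in the set is covered by the expected model")
    observed = int(sub["gene"].isin(genes).sum())
    return burden.gene_set_test(genes, observed, model, n=n, unit=unit)
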