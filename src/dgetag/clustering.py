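"""Between-species log-expression-ratio matrices and hierarchical clustering.

For each gene and developmental stage the two species' replicate-mean TPM
values form a ratio TPM_species1 / TPM_species2; a zero mean on either
side is replaced by 0.01 so the log2-transformed ratio stays finite (the
substitution is recorded per cell).  Genes are then clustered on their
stage profiles with deterministic agglomerative clustering
(average linkage, Euclidean distance — the Cluster 3.0 conventions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

ZERO_SUBSTITUTE = 0.01


@dataclass
class RatioMatrix:
    """genes x stages log2 ratios plus the zero-substitution provenance."""

    values: pd.DataFrame
    substituted: pd.DataFrame  # "" | "numerator" | "denominator" | "both"


def log_ratio_matrix(
    tpm: pd.DataFrame,
    species1_reps: dict[str, Sequence[str]],
    species2_reps: dict[str, Sequence[str]],
    gene_set: Sequence[str] | None = None,
) -> RatioMatrix:
    """log2 of stage-mean TPM ratios, species 1 over species 2.

    ``species*_reps`` map stage name -> replicate library columns (the
    stage mean is the mean of exactly those replicates).  ``gene_set``
    restricts and orders the rows; genes absent from the matrix are a
    validation error.
    """
    if set(species1_reps) != set(species2_reps):
        raise ValueError("the two species must cover the same stages")
    genes = list(gene_set) if gene_set is not None else list(tpm.index)
    missing = [g for g in genes if g not in tpm.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    stages = list(species1_reps)
    vals = pd.DataFrame(index=genes, columns=stages, dtype=float)
    subs = pd.DataFrame("", index=genes, columns=stages)
    for stage in stages:
        num = tpm.loc[genes, list(species1_reps[stage])].mean(axis=1)
        den = tpm.loc[genes, list(species2_reps[stage])].mean(axis=1)
        num_zero = num == 0
        den_zero = den == 0
        num = num.where(~num_zero, ZERO_SUBSTITUTE)
        den = den.where(~den_zero, ZERO_SUBSTITUTE)
        vals[stage] = np.log2(num / den)
        subs[stage] = np.select(
            [num_zero & den_zero, num_zero, den_zero],
            ["both", "numerator", "denominator"],
            default="",
        )
    return RatioMatrix(values=vals, substituted=subs)


@dataclass
class Dendrogram:
    """Merge tree (scipy linkage matrix) and the ordered leaf labels."""

    linkage_matrix: np.ndarray
    leaf_order: list[str]
    labels: list[str]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = walk(node.get_left())
            right = walk(node.get_right())
            dl = max(node.dist - node.get_left().dist, 0.0)
            dr = max(node.dist - node.get_right().dist, 0.0)
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def hierarchical_cluster(
    matrix: RatioMatrix | pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> Dendrogram:
    """Deterministic agglomerative clustering of the ratio-matrix rows.

    Ties in merge distance are broken by lower cluster index (scipy's
    deterministic behaviour).  Non-finite entries are a validation error;
    the ratio matrix is finite by construction.
    """
    values = matrix.values if isinstance(matrix, RatioMatrix) else matrix
    if len(values) < 2:
        raise ValueError("clustering needs at least 2 genes")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("ratio matrix contains non-finite entries")
    lm = linkage(arr, method=method, metric=metric)
    labels = list(values.index)
    order = [labels[i] for i in leaves_list(lm)]
    return Dendrogram(linkage_matrix=lm, leaf_order=order, labels=labels)
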