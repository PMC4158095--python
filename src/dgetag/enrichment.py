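"""Hypergeometric term enrichment of DEG sets.

Given a gene→term annotation, a term with M annotated genes is tested
against a DEG set of n genes drawn from the N-gene annotated universe;
with m DEGs carrying the term, the enrichment P-value is the upper tail

    P = 1 − Σ_{i=0}^{m−1} C(M,i) C(N−M,n−i) / C(N,n)

(genes without any annotation are excluded from both N and n).  P-values
are adjusted across tested terms with Benjamini–Hochberg.  The same
operation serves GO terms and pathway memberships alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_P_ALPHA = 0.05
DEFAULT_Q_ALPHA = 0.05


@dataclass
class AnnotationTable:
    """gene -> set of term ids, plus term metadata."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        """All genes with at least one annotation (the formula's N)."""
        return {g for g, terms in self.gene_terms.items() if terms}

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "AnnotationTable":
        """Read a 4-column TSV: gene_id, term_id, term_name, namespace.

        This is the expected flat exchange format; converting GAF/OBO
        resources into it is up to the caller.
        """
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            names=["gene_id", "term_id", "term_name", "namespace"],
            dtype=str,
        )
        ann = cls()
        for row in df.itertuples(index=False):
            ann.gene_terms.setdefault(row.gene_id, set()).add(row.term_id)
            ann.term_names[row.term_id] = row.term_name
            ann.term_namespaces[row.term_id] = row.namespace
        return ann


def enrich(
    degs: set[str],
    annotation: AnnotationTable,
    p_alpha: float = DEFAULT_P_ALPHA,
    q_alpha: float = DEFAULT_Q_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of every annotated term.

    Returns one row per term with N, n, M, m, P, Q (Benjamini–Hochberg)
    and significance flags, sorted by P.  DEGs outside the annotated
    universe are dropped from n; terms with M = 0 are skipped.
    """
    universe = annotation.universe
    deg_in_universe = degs & universe
    n_universe = len(universe)
    n_degs = len(deg_in_universe)
    if n_degs == 0:
        warnings.warn("no DEGs fall in the annotated universe", stacklevel=2)
        return pd.DataFrame(
            columns=["term_id", "term_name", "namespace", "N", "n", "M", "m",
                     "P", "Q", "significant_p", "significant_q"]
        )
    rows = []
    for term, genes in sorted(annotation.term_genes().items()):
        big_m = len(genes)
        if big_m == 0:
            continue
        m = len(deg_in_universe & genes)
        # upper tail P(X >= m); sf(m-1) is computed in log space internally
        p = float(hypergeom.sf(m - 1, n_universe, big_m, n_degs))
        rows.append(
            {
                "term_id": term,
                "term_name": annotation.term_names.get(term, ""),
                "namespace": annotation.term_namespaces.get(term, ""),
                "N": n_universe,
                "n": n_degs,
                "M": big_m,
                "m": m,
                "P": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    _, q, _, _ = multipletests(result["P"], method="fdr_bh")
    result["Q"] = q
    result["significant_p"] = result["P"] < p_alpha
    result["significant_q"] = result["Q"] < q_alpha
    return result.sort_values(["P", "term_id"], kind="stable").reset_index(drop=True)
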