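"""Hypergeometric GO-term enrichment against an expressed-gene background.

For a study set of n genes drawn from a background of N genes, a term
annotating K background genes and k study genes is scored with the
hypergeometric upper tail P(X >= k). BH FDR is applied within each ontology
separately, and a term is flagged enriched under the dual threshold
p < 0.05 and FDR < 0.1 (strict inequalities). Annotations are used exactly
as supplied — no GO-graph ancestor propagation.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_adjust
from .tables import AnnotationTable

P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.1


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and k <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(study_genes, annotations: AnnotationTable, background,
           p_threshold: float = P_THRESHOLD,
           fdr_threshold: float = FDR_THRESHOLD,
           per_ontology_fdr: bool = True) -> pd.DataFrame:
    """Score every annotated term with at least one study hit.

    ``study_genes`` must be a subset of ``background`` (typically the union
    of expressed genes). Records are sorted by raw p ascending, ties broken
    by term id. ``per_ontology_fdr=False`` pools the three ontologies into a
    single BH family.
    """
    study = set(study_genes)
    background = set(background)
    missing = study - background
    if missing:
        raise ValueError(
            f"study gene {sorted(missing)[0]!r} absent from background")
    if not study:
        warnings.warn("empty study set; no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=["term_id", "ontology", "term_name",
                                     "k", "n", "K", "N", "p_raw", "fdr",
                                     "enriched"])
    n = len(study)
    N = len(background)
    info = annotations.term_info()
    rows = []
    for term, genes in annotations.term_to_genes().items():
        K = len(genes & background)
        k = len(genes & study)
        if k == 0:
            continue
        rows.append((term, info.loc[term, "ontology"],
                     info.loc[term, "term_name"], k, n, K, N,
                     hypergeom_upper_tail(k, n, K, N)))
    out = pd.DataFrame(rows, columns=["term_id", "ontology", "term_name",
                                      "k", "n", "K", "N", "p_raw"])
    if out.empty:
        out["fdr"] = []
        out["enriched"] = []
        return out
    out["fdr"] = 1.0
    if per_ontology_fdr:
        for ont, idx in out.groupby("ontology").groups.items():
            out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_raw"].to_numpy())
    else:
        out["fdr"] = bh_adjust(out["p_raw"].to_numpy())
    out["enriched"] = (out["p_raw"] < p_threshold) & (out["fdr"]
                                                      < fdr_threshold)
    out = out.sort_values(["p_raw", "term_id"]).reset_index(drop=True)
    return out
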