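"""GO-style gene-set term enrichment for any gene list.

Hypergeometric upper-tail test per term over an explicit background
universe, BH adjustment across all tested terms, q < 0.05 reporting and
top-5 summaries.  The annotation is taken as given — no ontology-graph
propagation.
"""

from __future__ import annotations

import warnings

import pandas as pd

from ._stats import bh_adjust, hypergeom_upper_tail
from .io import GeneSetCollection

ROW_COLUMNS = ["term_id", "term_description", "overlap", "set_size",
               "term_size", "background_size", "p", "q"]


def enrich_terms(query, annotation: GeneSetCollection, background,
                 q_max: float = 0.05) -> pd.DataFrame:
    """Enriched annotation terms for a query gene set.

    Terms are intersected with the background before testing; all terms
    with a nonempty background intersection are tested (BH across them);
    rows with zero overlap are never reported; returned rows have
    q < ``q_max`` and are sorted by (q, p, term_id).
    """
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("query empty after background intersection")
    tested = []
    for term_id, (desc, genes) in sorted(annotation.items()):
        term_genes = genes & background
        if not term_genes:
            continue
        overlap = len(term_genes & query)
        p = hypergeom_upper_tail(overlap, len(query), len(term_genes), len(background))
        tested.append({"term_id": term_id, "term_description": desc,
                       "overlap": overlap, "set_size": len(query),
                       "term_size": len(term_genes),
                       "background_size": len(background), "p": p})
    if not tested:
        return pd.DataFrame(columns=ROW_COLUMNS)
    df = pd.DataFrame(tested)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df[(df["overlap"] > 0) & (df["q"] < q_max)]
    return (df.sort_values(["q", "p", "term_id"], kind="stable")
              .reset_index(drop=True)[ROW_COLUMNS])


def top_terms(rows: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """First k rows of an already-sorted enrichment table."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return rows.head(k).reset_index(drop=True)


def shared_term_fraction(terms_a, terms_b) -> float:
    """Fraction of A's terms also present in B; 0 (with warning) if A empty."""
    a, b = set(terms_a), set(terms_b)
    if not a:
        warnings.warn("empty term set A: shared fraction defined as 0")
        return 0.0
    return len(a & b) / len(a)
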