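"""Pathway enrichment of NCN/NNCN gene sets and stage-wise category counts.

Enrichment is the classic one-sided hypergeometric over-representation test
per pathway against a flat annotated background (no GO-graph decorrelation:
the pathway universe here is a plain GMT), with p < 0.05 as the cutoff and
no multiple-testing correction by default, mirroring the raw-p convention of
the analysis this package implements; a Benjamini-Hochberg switch is
available.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .catalog import CategoryScheme, PathwayCatalog
from .diffexpr import _bh_adjust

ENRICH_ALPHA = 0.05


def enrich(
    gene_set: set[str],
    catalog: PathwayCatalog,
    background: set[str],
    alpha: float = ENRICH_ALPHA,
    bh_correct: bool = False,
    scheme: CategoryScheme | None = None,
) -> pd.DataFrame:
    """One row per pathway with overlap, sizes, hypergeometric p and the
    enriched flag; sorted by p.  ``gene_set`` must be within ``background``.
    """
    if not background:
        raise ValueError("background gene set is empty")
    stray = gene_set - background
    if stray:
        raise ValueError(
            f"gene set contains genes outside the background: {sorted(stray)[:5]}"
        )
    n_bg = len(background)
    n_set = len(gene_set)
    rows = []
    for pid, genes in catalog.pathways.items():
        pw = genes & background
        if not pw:
            continue
        k = len(gene_set & pw)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=|pathway|, n=|set|)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(pw), n_set))
        rows.append((pid, k, n_set, len(pw), n_bg, p))
    table = pd.DataFrame(
        rows, columns=["pathway", "overlap", "set_size", "pathway_size",
                       "background_size", "p"]
    ).set_index("pathway")
    table["p_adj"] = _bh_adjust(table["p"].to_numpy()) if len(table) else []
    p_eff = table["p_adj"] if bh_correct else table["p"]
    table["enriched"] = p_eff < alpha
    if scheme is not None:
        table["category"] = [scheme.assignment.get(p, "unclassified")
                             for p in table.index]
    return table.sort_values("p")


def stage_category_counts(
    enrichments: dict[str, pd.DataFrame], scheme: CategoryScheme
) -> pd.DataFrame:
    """Counts of distinct enriched pathways per category per stage.

    One column per stage plus a ``total`` column holding the distinct-union
    count across stages (a pathway enriched at several stages counts once in
    the total).  Rows follow the scheme vocabulary; a final ``Total number``
    row sums each column.
    """
    vocab = scheme.vocabulary
    counts = pd.DataFrame(0, index=vocab, columns=list(enrichments) + ["total"])
    union: dict[str, set[str]] = {c: set() for c in vocab}
    for stage, table in enrichments.items():
        hit = table.index[table["enriched"]]
        for pid in hit:
            cat = scheme.assignment.get(pid, "unclassified")
            counts.loc[cat, stage] += 1
            union[cat].add(pid)
    for cat in vocab:
        counts.loc[cat, "total"] = len(union[cat])
    counts.loc["Total number"] = counts.sum(axis=0)
    return counts
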