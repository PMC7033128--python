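"""Neural / non-neural co-expression: correlation sets, NCN and NNCN genes.

Correlations are computed on TPM within the tumor samples of one stage
(pooled mode available), with Spearman's rank coefficient by default and a
cutoff on |rho| >= 0.8 at p < 0.05.  Both the coefficient (spearman/pearson)
and whether the cutoff applies to rho or rho^2 are configurable, since
published threshold conventions differ.

Two derived gene sets drive the downstream analysis:

* **NCN** — neural genes correlated with at least one up-regulated
  non-neural gene;
* **NNCN** — up-regulated non-neural genes *positively* correlated with at
  least one expressed neural gene, "expressed" meaning nonzero TPM in at
  least half of the stage's tumor samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CategoryScheme, PathwayCatalog

logger = logging.getLogger(__name__)

CORR_THRESHOLD = 0.8
CORR_ALPHA = 0.05
EXPRESSED_FRACTION = 0.5


@dataclass
class CorrelationSet:
    """Filtered pairwise correlations between two gene lists.

    ``records`` has columns gene_a, gene_b, coefficient, p; pairs failing the
    threshold are absent.  ``method`` is spearman or pearson; when
    ``square_cutoff`` the threshold applied to rho^2 instead of |rho|.
    """

    records: pd.DataFrame
    method: str
    threshold: float
    alpha: float
    square_cutoff: bool = False
    skipped_constant: list[str] = field(default_factory=list)

    def partners_of(self, gene: str, positive_only: bool = False) -> set[str]:
        rec = self.records
        out: set[str] = set()
        rows_a = rec[rec["gene_a"] == gene]
        rows_b = rec[rec["gene_b"] == gene]
        if positive_only:
            rows_a = rows_a[rows_a["coefficient"] > 0]
            rows_b = rows_b[rows_b["coefficient"] > 0]
        out |= set(rows_a["gene_b"])
        out |= set(rows_b["gene_a"])
        return out


@dataclass
class LinkedGeneSets:
    ncn_genes: set[str]
    nncn_genes: set[str]


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation for a correlation coefficient."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlate(
    values: pd.DataFrame,
    genes_a: list[str],
    genes_b: list[str],
    method: str = "spearman",
    threshold: float = CORR_THRESHOLD,
    alpha: float = CORR_ALPHA,
    square_cutoff: bool = False,
) -> CorrelationSet:
    """All (a, b) cross-pairs passing the coefficient and p thresholds.

    ``values`` is genes x samples (TPM); ties get average ranks under
    spearman.  Constant gene vectors have no defined coefficient: their pairs
    are skipped and the genes logged.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if not genes_a or not genes_b:
        raise ValueError("gene lists must be nonempty")
    missing = (set(genes_a) | set(genes_b)) - set(values.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]} ...")
    n = values.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples to correlate")

    a = values.loc[genes_a].to_numpy(dtype=float)
    b = values.loc[genes_b].to_numpy(dtype=float)
    const_a = np.ptp(a, axis=1) == 0
    const_b = np.ptp(b, axis=1) == 0
    skipped = [g for g, c in zip(genes_a, const_a) if c]
    skipped += [g for g, c in zip(genes_b, const_b) if c]
    for g in skipped:
        logger.warning("constant expression for %s; correlations undefined", g)

    if method == "spearman":
        a = stats.rankdata(a, axis=1)
        b = stats.rankdata(b, axis=1)
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    sa = np.sqrt((az * az).sum(axis=1))
    sb = np.sqrt((bz * bz).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(sa, sb)
    r[const_a, :] = np.nan
    r[:, const_b] = np.nan
    p = _corr_pvalue(r, n)

    stat = r * r if square_cutoff else np.abs(r)
    keep = (stat >= threshold) & (p < alpha) & np.isfinite(r)
    ia, ib = np.nonzero(keep)
    records = pd.DataFrame(
        {
            "gene_a": [genes_a[i] for i in ia],
            "gene_b": [genes_b[j] for j in ib],
            "coefficient": r[ia, ib],
            "p": p[ia, ib],
        }
    )
    return CorrelationSet(records=records, method=method, threshold=threshold,
                          alpha=alpha, square_cutoff=square_cutoff,
                          skipped_constant=skipped)


def expressed_genes(
    tpm: pd.DataFrame, genes: list[str], fraction: float = EXPRESSED_FRACTION
) -> set[str]:
    """Genes with nonzero TPM in at least ``fraction`` of the given samples."""
    sub = tpm.loc[[g for g in genes if g in tpm.index]]
    frac_nonzero = (sub > 0).mean(axis=1)
    return set(sub.index[frac_nonzero >= fraction])


def derive_linked_sets(
    corr: CorrelationSet,
    de_table: pd.DataFrame,
    catalog: PathwayCatalog,
    tpm_tumor: pd.DataFrame,
) -> LinkedGeneSets:
    """NCN and NNCN sets from a neural-vs-non-neural correlation set.

    ``corr`` must have neural genes as gene_a and non-neural genes as gene_b.
    ``tpm_tumor`` holds the stage's tumor samples, used for the expressed-
    neural-gene filter.
    """
    if de_table.empty or not de_table["up_regulated"].any():
        logger.warning("no up-regulated genes; NCN/NNCN sets are empty")
        return LinkedGeneSets(set(), set())
    up = set(de_table.index[de_table["up_regulated"]])
    up_nonneural = up & catalog.nonneural_genes
    expressed_neural = expressed_genes(tpm_tumor, sorted(catalog.neural_genes))

    rec = corr.records
    ncn = set(rec.loc[rec["gene_b"].isin(up_nonneural), "gene_a"])
    pos = rec[rec["coefficient"] > 0]
    nncn = set(pos.loc[pos["gene_a"].isin(expressed_neural) &
                       pos["gene_b"].isin(up_nonneural), "gene_b"])
    return LinkedGeneSets(ncn_genes=ncn & catalog.neural_genes, nncn_genes=nncn)


#: fixed row (neural) palette order of the correlation heat-map
NEURAL_PALETTE_ORDER = (
    "neurotransmitter secretion", "neural crest development",
    "axon growth and dendrite pruning", "synapse formation",
    "neuron projection and apoptosis", "neural structure formation in CNS",
    "neuron differentiation", "development of glia", "unclassified",
)
#: fixed column (non-neural) palette order
NONNEURAL_PALETTE_ORDER = (
    "cell adhesion", "calcium sequestering", "cytokine and chemokine production",
    "regulation of cell death", "ECM synthesis", "hemopoiesis", "endocytosis",
    "DNA damage and metabolism", "organelle assembly", "cell skeleton synthesis",
    "de-development process", "unclassified",
)


def heatmap_matrix(
    corr: CorrelationSet,
    catalog: PathwayCatalog,
    neural_scheme: CategoryScheme,
    nonneural_scheme: CategoryScheme,
    neural_order: tuple[str, ...] = NEURAL_PALETTE_ORDER,
    nonneural_order: tuple[str, ...] = NONNEURAL_PALETTE_ORDER,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Dense correlation matrix ordered by category for heat-map export.

    Rows are neural genes, columns non-neural genes, both grouped in the
    fixed palette order of their scheme; cells failing the correlation filter
    are 0.  Returns (matrix, row category labels, column category labels);
    genes take the category of the first pathway (in scheme vocabulary order)
    that contains them.
    """
    from .catalog import gene_categories

    rec = corr.records
    row_genes = sorted(set(rec["gene_a"]))
    col_genes = sorted(set(rec["gene_b"]))
    row_cat = gene_categories(catalog, neural_scheme, row_genes,
                              order=neural_order)
    col_cat = gene_categories(catalog, nonneural_scheme, col_genes,
                              order=nonneural_order)
    row_rank = {c: i for i, c in enumerate(neural_order)}
    col_rank = {c: i for i, c in enumerate(nonneural_order)}
    row_genes.sort(key=lambda g: (row_rank.get(row_cat[g], len(row_rank)), g))
    col_genes.sort(key=lambda g: (col_rank.get(col_cat[g], len(col_rank)), g))

    matrix = pd.DataFrame(0.0, index=row_genes, columns=col_genes)
    for _, row in rec.iterrows():
        matrix.at[row["gene_a"], row["gene_b"]] = row["coefficient"]
    row_labels = pd.Series({g: row_cat[g] for g in row_genes}, name="category")
    col_labels = pd.Series({g: col_cat[g] for g in col_genes}, name="category")
    return matrix, row_labels, col_labels
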