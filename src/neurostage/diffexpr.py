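"""Per-stage tumor-vs-control differential expression.

Counts are normalized with median-of-ratios size factors, then each gene is
tested with Welch's t-test on log1p(normalized counts).  A gene is called
up-regulated when its tumor/control fold change exceeds 2.0 with p < 0.05
(raw p by default; Benjamini-Hochberg adjustment available as a switch).
Down-regulation is computed (the fold-change sign is informative) but plays
no role downstream, where only up-regulated genes feed the co-expression and
regression analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CONTROL, TUMOR, ExpressionCohort

FC_THRESHOLD = 2.0
DE_ALPHA = 0.05
PSEUDOCOUNT = 1.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes as rows, samples as columns).

    The per-gene reference is the geometric mean across samples; genes with a
    zero anywhere drop out of the reference (their log geometric mean is
    -inf) and contribute nothing to the medians.
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values.sum(axis=0) == 0):
        bad = counts.columns[values.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    log_geo_mean = log_values.mean(axis=1)
    usable = np.isfinite(log_geo_mean)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample; "
                         "cannot compute size factors")
    log_ratios = log_values[usable] - log_geo_mean[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their sample's median-of-ratios size factor."""
    return counts / size_factors(counts)


def test_differential(
    cohort: ExpressionCohort,
    stage: str,
    pool_controls: bool = True,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = DE_ALPHA,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Tumor-vs-control differential expression for one stage.

    Controls are pooled across all stages by default (tumor cohorts carry few
    stage-matched controls); set ``pool_controls=False`` to use only the
    stage's own controls.  Returns a per-gene table with columns
    ``log2fc, p, mean_tumor, mean_control, up_regulated``.
    """
    tumor_ids = cohort.samples(stage=stage, condition=TUMOR)
    control_ids = cohort.samples(stage=None if pool_controls else stage,
                                 condition=CONTROL)
    if len(tumor_ids) < 2 or len(control_ids) < 2:
        raise ValueError(
            f"stage {stage!r}: need >= 2 samples per group, have "
            f"{len(tumor_ids)} tumor / {len(control_ids)} control"
        )
    normalized = normalize_counts(cohort.counts[tumor_ids + control_ids])
    logged = np.log1p(normalized)
    t_log = logged[tumor_ids].to_numpy()
    c_log = logged[control_ids].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(t_log, c_log, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence

    mean_tumor = normalized[tumor_ids].mean(axis=1).to_numpy()
    mean_control = normalized[control_ids].mean(axis=1).to_numpy()
    fc = (mean_tumor + PSEUDOCOUNT) / (mean_control + PSEUDOCOUNT)
    log2fc = np.log2(fc)
    p_eff = _bh_adjust(p) if bh_correct else p
    up = (fc > fc_threshold) & (p_eff < alpha) & (mean_tumor > mean_control)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": _bh_adjust(p),
            "mean_tumor": mean_tumor,
            "mean_control": mean_control,
            "up_regulated": up,
        },
        index=cohort.counts.index,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def up_regulated_genes(de_table: pd.DataFrame) -> list[str]:
    return list(de_table.index[de_table["up_regulated"]])
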