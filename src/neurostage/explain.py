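"""Penalized multi-response regression "statistical explainability" machinery.

The central question: can the expression of a set of neural genes (the
responses, Y, m samples x k genes) be statistically represented as a linear
function of the expression of a set of non-neural genes (the candidates, X,
m x n)?  The model minimizes

    ||Y - XB||^2_F + lambda * sum_ij beta_ij^2,

i.e. a ridge-penalized multi-response least squares, solved in closed form
as B = (X'X + lambda I)^-1 X'Y on column-centered data (equivalent to an
unpenalized intercept).  Around the solver sit:

* **iterative backward elimination** — candidates whose ridge coefficients
  are insignificant (aggregated p >= alpha_drop) are removed and the model
  refit until no candidate drops;
* **the explainability call** — a neural set is *explained* by the surviving
  candidates when pooled R^2 >= 2/3, the permutation p-value is < 0.05, and
  the candidate set is minimal (no proper subset reaches the R^2 gate);
* **permutation calibration** — the p-value of a fit is the tail fraction of
  adjusted R^2 over row-permutations of Y relative to X;
* **ΔR² attribution** — a block of predictors "contributes" to a response set
  when removing it drops R^2 by more than 0.01 with a block-permutation
  p < 0.01;
* **class fractions** — per-stage fractions of selected non-neural pathways
  falling in the cell-environment vs intracellular-damage super-classes.

R^2 is pooled across the k responses (Frobenius form, matching the matrix
objective), and the adjusted version uses the trace of the ridge hat matrix
(+1 for the intercept) as effective degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CELL_ENVIRONMENT, INTRACELLULAR_DAMAGE, envclass_of

logger = logging.getLogger(__name__)

R2_GATE = 2.0 / 3.0
PERM_ALPHA = 0.05
DELTA_GATE = 0.01
CONTRIB_ALPHA = 0.01
# retention threshold for backward elimination; stricter than the 0.05 used
# for the other gates because the candidate pool is large (tens to hundreds
# of genes), where a 5% retention level keeps ~1 spurious driver per 20
# candidates each round
ALPHA_DROP = 0.01
DEFAULT_N_PERM = 1000
EXHAUSTIVE_LIMIT = 12
_EPS = 1e-12


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def minmax_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min-max scaling to [0, 1] (genes as rows).

    Genes with no dynamic range — including unexpressed all-zero genes — are
    removed (and logged) before scaling; an all-constant matrix is an error.
    """
    if values.empty:
        raise ValueError("empty expression matrix")
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    keep = hi > lo
    dropped = values.index[~keep].tolist()
    if dropped:
        logger.info("min-max normalization removed %d constant gene(s)",
                    len(dropped))
    if not keep.any():
        raise ValueError("every gene is constant; nothing to normalize")
    sub = values.loc[keep]
    return sub.sub(lo[keep], axis=0).div((hi - lo)[keep], axis=0)


def pathway_scores(values: pd.DataFrame,
                   blocks: dict[str, list[str]]) -> pd.DataFrame:
    """Average member-gene expression per pathway (pathways as rows)."""
    rows = {}
    for pid, genes in blocks.items():
        present = [g for g in genes if g in values.index]
        if present:
            rows[pid] = values.loc[present].mean(axis=0)
    if not rows:
        raise ValueError("no pathway has members in the matrix")
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# penalized fit
# ---------------------------------------------------------------------------

@dataclass
class ExplainFit:
    """State of one ridge fit of responses Y on candidates X."""

    X: np.ndarray
    Y: np.ndarray
    B: np.ndarray
    lam: float
    E: np.ndarray
    r2: float
    adj_r2: float
    edf: float
    candidates: list[str]
    responses: list[str]
    selected: list[str]
    n_iterations: int = 1
    converged: bool = True
    degenerate: bool = False
    perm_p: float | None = None


def _as_matrix(M, names_default: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), [str(c) for c in M.columns]
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M, [f"{names_default}{i}" for i in range(M.shape[1])]


def fit_penalized(X, Y, lam: float) -> ExplainFit:
    """Closed-form ridge fit with column centering.

    X and Y are samples x genes (arrays or DataFrames).  With lam = 0 the fit
    is ordinary least squares and requires full-column-rank X.
    """
    Xm, xnames = _as_matrix(X, "x")
    Ym, ynames = _as_matrix(Y, "y")
    m, n = Xm.shape
    if m < 3:
        raise ValueError("need at least 3 samples")
    if Ym.shape[0] != m:
        raise ValueError("X and Y sample counts differ")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not (np.isfinite(Xm).all() and np.isfinite(Ym).all()):
        raise ValueError("non-finite values in X or Y")

    Xc = Xm - Xm.mean(axis=0)
    Yc = Ym - Ym.mean(axis=0)
    G = Xc.T @ Xc
    A = G + lam * np.eye(n)
    if lam == 0.0 and np.linalg.matrix_rank(G, hermitian=True) < n:
        raise ValueError(
            "X'X is singular at lambda = 0 (collinear candidates); "
            "use lambda > 0"
        )
    B = np.linalg.solve(A, Xc.T @ Yc)
    E = Yc - Xc @ B
    tss = float((Yc * Yc).sum())
    rss = float((E * E).sum())
    degenerate = tss < _EPS
    r2 = 0.0 if degenerate else 1.0 - rss / tss
    edf = float(np.trace(np.linalg.solve(A, G))) + 1.0  # +1: intercept
    if m - edf > _EPS and not degenerate:
        adj_r2 = 1.0 - (1.0 - r2) * (m - 1) / (m - edf)
    else:
        adj_r2 = r2
    return ExplainFit(X=Xm, Y=Ym, B=B, lam=lam, E=E, r2=r2, adj_r2=adj_r2,
                      edf=edf, candidates=xnames, responses=ynames,
                      selected=list(xnames), degenerate=degenerate)


def choose_lambda(X, Y, grid: np.ndarray | None = None) -> float:
    """Generalized cross-validation over a log-spaced grid.

    GCV(lambda) = m * RSS / (m - edf)^2, pooled across responses; the minimum
    over the grid is returned.  Chosen once, before backward elimination, and
    held fixed through it.
    """
    if grid is None:
        grid = np.logspace(-4, 2, 13)
    Xm, _ = _as_matrix(X, "x")
    m = Xm.shape[0]
    best_lam, best_score = float(grid[0]), math.inf
    for lam in grid:
        fit = fit_penalized(X, Y, float(lam))
        rss = float((fit.E * fit.E).sum())
        denom = max(m - fit.edf, _EPS) ** 2
        score = m * rss / denom
        if score < best_score:
            best_score, best_lam = score, float(lam)
    return best_lam


def coefficient_pvalues(fit: ExplainFit) -> pd.Series:
    """Per-candidate significance aggregated across the k responses.

    Per response: t statistics from the ridge sandwich covariance
    Var(B_j) = sigma_j^2 (X'X+lI)^-1 X'X (X'X+lI)^-1 with df = m - edf;
    per candidate the minimum p across responses, Bonferroni-scaled by k.
    """
    if fit.Y.shape[1] == 0:
        raise ValueError("no responses")
    m, n = fit.X.shape
    k = fit.Y.shape[1]
    Xc = fit.X - fit.X.mean(axis=0)
    G = Xc.T @ Xc
    A = G + fit.lam * np.eye(n)
    Ainv = np.linalg.inv(A)
    M = Ainv @ G @ Ainv
    diag = np.clip(np.diag(M), _EPS, None)
    df = max(m - fit.edf, 1.0)
    sigma2 = (fit.E ** 2).sum(axis=0) / df          # per response
    var = np.outer(diag, sigma2)                    # n x k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.B / np.sqrt(np.clip(var, _EPS, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)          # n x k
    combined = np.clip(p.min(axis=1) * k, 0.0, 1.0)
    return pd.Series(combined, index=fit.candidates, name="p")


def _empty_fit(X, Y, lam: float, iterations: int) -> ExplainFit:
    Xm, xnames = _as_matrix(X, "x")
    Ym, ynames = _as_matrix(Y, "y")
    Yc = Ym - Ym.mean(axis=0)
    return ExplainFit(X=Xm[:, :0], Y=Ym, B=np.zeros((0, Ym.shape[1])),
                      lam=lam, E=Yc, r2=0.0, adj_r2=0.0, edf=1.0,
                      candidates=[], responses=ynames, selected=[],
                      n_iterations=iterations, converged=True)


def iterative_select(X_init, Y, lam: float,
                     alpha_drop: float = ALPHA_DROP) -> ExplainFit:
    """Backward elimination: fit, drop candidates with p >= alpha_drop, refit.

    Converges when a round drops nothing (or nothing is left); since the
    candidate set strictly shrinks otherwise, at most n_init rounds run.
    Returns the final fit; with every candidate eliminated the fit has an
    empty selection and r2 = 0.
    """
    if not 0.0 < alpha_drop < 1.0:
        raise ValueError("alpha_drop must be in (0, 1)")
    Xm, names = _as_matrix(X_init, "x")
    if Xm.shape[1] == 0:
        raise ValueError("no candidates")
    current = list(range(Xm.shape[1]))
    iterations = 0
    while current:
        iterations += 1
        fit = fit_penalized(Xm[:, current], Y, lam)
        fit.candidates = [names[i] for i in current]
        fit.selected = list(fit.candidates)
        pvals = coefficient_pvalues(fit).to_numpy()
        keep = [c for c, p in zip(current, pvals) if p < alpha_drop]
        if len(keep) == len(current):
            fit.n_iterations = iterations
            fit.converged = True
            return fit
        current = keep
    logger.warning("backward elimination removed every candidate")
    return _empty_fit(Xm, Y, lam, iterations)


# ---------------------------------------------------------------------------
# minimality
# ---------------------------------------------------------------------------

def _subset_r2(Xc: np.ndarray, Yc: np.ndarray, cols: tuple[int, ...],
               tss: float) -> float:
    """Unpenalized pooled R^2 of Y on the given predictor columns."""
    sub = Xc[:, list(cols)]
    coef, *_ = np.linalg.lstsq(sub, Yc, rcond=None)
    resid = Yc - sub @ coef
    return 1.0 - float((resid * resid).sum()) / tss


def check_minimality(fit: ExplainFit, r2_gate: float = R2_GATE,
                     mode: str = "exhaustive") -> tuple[bool, dict]:
    """Is the selected candidate set minimal for the R^2 gate?

    A set is minimal when no proper subset reaches the gate with an
    unpenalized fit.  ``exhaustive`` enumerates every proper nonempty subset
    (allowed up to 12 selected candidates); ``greedy`` tests leave-one-out
    subsets and, when one passes, recurses on the best passing subset — fast
    but can miss non-nested passing subsets.
    """
    n_sel = len(fit.selected)
    if n_sel == 0:
        raise ValueError("empty selection has no subsets to test")
    if mode not in ("exhaustive", "greedy"):
        raise ValueError(f"unknown minimality mode {mode!r}")
    if mode == "exhaustive" and n_sel > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{n_sel} selected candidates exceed the exhaustive limit "
            f"({EXHAUSTIVE_LIMIT}); use mode='greedy'"
        )
    Xc = fit.X - fit.X.mean(axis=0)
    Yc = fit.Y - fit.Y.mean(axis=0)
    tss = float((Yc * Yc).sum())
    if tss < _EPS:
        return True, {"mode": mode, "passing_subset": None, "n_checked": 0}

    if mode == "exhaustive":
        checked = 0
        for size in range(1, n_sel):
            for cols in itertools.combinations(range(n_sel), size):
                checked += 1
                if _subset_r2(Xc, Yc, cols, tss) >= r2_gate:
                    subset = [fit.selected[i] for i in cols]
                    return False, {"mode": mode, "passing_subset": subset,
                                   "n_checked": checked}
        return True, {"mode": mode, "passing_subset": None,
                      "n_checked": checked}

    # greedy: leave-one-out descent
    checked = 0
    current = tuple(range(n_sel))
    first_passing: list[str] | None = None
    while len(current) > 1:
        best_r2, best_sub = -math.inf, None
        for drop in current:
            cols = tuple(i for i in current if i != drop)
            checked += 1
            r2 = _subset_r2(Xc, Yc, cols, tss)
            if r2 >= r2_gate and r2 > best_r2:
                best_r2, best_sub = r2, cols
        if best_sub is None:
            break
        if first_passing is None:
            first_passing = [fit.selected[i] for i in best_sub]
        current = best_sub
    minimal = first_passing is None
    return minimal, {"mode": mode, "passing_subset": first_passing,
                     "n_checked": checked,
                     "reduced_to": [fit.selected[i] for i in current]}


# ---------------------------------------------------------------------------
# permutation p-value
# ---------------------------------------------------------------------------

def permutation_pvalue(X, Y, lam: float, n_perm: int = DEFAULT_N_PERM,
                       seed: int | np.random.Generator = 0,
                       min_n_perm: int = 100) -> float:
    """Permutation p for the fit's adjusted R^2.

    Rows of Y are permuted relative to X; each permutation is refit from
    scratch and p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    """
    if n_perm < min_n_perm:
        raise ValueError(f"n_perm must be >= {min_n_perm}")
    Xm, _ = _as_matrix(X, "x")
    Ym, _ = _as_matrix(Y, "y")
    m, n = Xm.shape
    if m < 4:
        raise ValueError("need >= 4 samples for a meaningful permutation test")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    fit = fit_penalized(Xm, Ym, lam)
    observed = fit.adj_r2
    Xc = Xm - Xm.mean(axis=0)
    Yc = Ym - Ym.mean(axis=0)
    A = Xc.T @ Xc + lam * np.eye(n)
    P = np.linalg.solve(A, Xc.T)                     # n x m
    tss = float((Yc * Yc).sum())
    if tss < _EPS:
        return 1.0
    scale = (m - 1) / max(m - fit.edf, _EPS)

    count = 0
    chunk = 512
    for start in range(0, n_perm, chunk):
        size = min(chunk, n_perm - start)
        idx = np.stack([rng.permutation(m) for _ in range(size)])
        Yp = Yc[idx]                                  # size x m x k
        Bp = np.einsum("nm,smk->snk", P, Yp)
        Ep = Yp - np.einsum("mn,snk->smk", Xc, Bp)
        rss = (Ep * Ep).sum(axis=(1, 2))
        r2p = 1.0 - rss / tss
        adj = 1.0 - (1.0 - r2p) * scale
        count += int((adj >= observed - _EPS).sum())
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# explainability call
# ---------------------------------------------------------------------------

@dataclass
class ExplainCall:
    """Verdict on whether a neural set is explained by a non-neural set."""

    explainable: bool
    r2: float
    adj_r2: float
    perm_p: float
    minimal: bool
    minimal_certificate: dict
    fit: ExplainFit
    r2_gate: float = R2_GATE


def explainability_call(
    X, Y,
    lam: float | None = None,
    alpha_drop: float = ALPHA_DROP,
    r2_gate: float = R2_GATE,
    perm_alpha: float = PERM_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    minimality_mode: str = "auto",
) -> ExplainCall:
    """Full pipeline: lambda choice (GCV), backward elimination, permutation
    p, minimality — explainable iff r2 >= gate, perm p < alpha and minimal.
    """
    if lam is None:
        lam = choose_lambda(X, Y)
    fit = iterative_select(X, Y, lam, alpha_drop=alpha_drop)
    if not fit.selected or fit.r2 < r2_gate:
        return ExplainCall(explainable=False, r2=fit.r2, adj_r2=fit.adj_r2,
                           perm_p=1.0, minimal=False,
                           minimal_certificate={"mode": "skipped"}, fit=fit,
                           r2_gate=r2_gate)
    perm_p = permutation_pvalue(fit.X, fit.Y, lam, n_perm=n_perm, seed=seed)
    fit.perm_p = perm_p
    if minimality_mode == "auto":
        minimality_mode = ("exhaustive" if len(fit.selected) <= EXHAUSTIVE_LIMIT
                           else "greedy")
    minimal, cert = check_minimality(fit, r2_gate=r2_gate,
                                     mode=minimality_mode)
    explainable = fit.r2 >= r2_gate and perm_p < perm_alpha and minimal
    return ExplainCall(explainable=explainable, r2=fit.r2, adj_r2=fit.adj_r2,
                       perm_p=perm_p, minimal=minimal,
                       minimal_certificate=cert, fit=fit, r2_gate=r2_gate)


# ---------------------------------------------------------------------------
# delta-R^2 attribution
# ---------------------------------------------------------------------------

@dataclass
class ContributionCall:
    """ΔR² verdict for one predictor block against a response set."""

    focal_block: str
    delta_r2: float
    p_value: float
    contributing: bool
    r2_full: float
    r2_reduced: float


def contribution_delta(
    Y_target, X_full,
    function_blocks: dict[str, list[str]],
    focal_function: str,
    lam: float,
    n_perm: int = 199,
    seed: int | np.random.Generator = 0,
    delta_gate: float = DELTA_GATE,
    alpha: float = CONTRIB_ALPHA,
) -> ContributionCall:
    """R^2 drop when the focal predictor block is removed from the full model.

    ``function_blocks`` maps block name -> predictor column names and must
    partition the columns of X_full.  Significance comes from permuting the
    focal block's rows (breaking its sample linkage while keeping the rest of
    X intact) and recomputing the drop; contributing iff
    delta > delta_gate and p < alpha.
    """
    Xm, names = _as_matrix(X_full, "x")
    Ym, _ = _as_matrix(Y_target, "y")
    if focal_function not in function_blocks:
        raise ValueError(f"unknown block {focal_function!r}")
    assigned = [g for block in function_blocks.values() for g in block]
    if sorted(assigned) != sorted(names):
        raise ValueError("function blocks do not partition the X columns")
    focal_cols = [names.index(g) for g in function_blocks[focal_function]]
    if not focal_cols:
        raise ValueError(f"block {focal_function!r} is empty")
    other_cols = [i for i in range(len(names)) if i not in focal_cols]

    r2_full = fit_penalized(Xm, Ym, lam).r2
    if other_cols:
        r2_red = fit_penalized(Xm[:, other_cols], Ym, lam).r2
    else:
        r2_red = 0.0
    delta = r2_full - r2_red

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    m = Xm.shape[0]
    count = 0
    for _ in range(n_perm):
        Xp = Xm.copy()
        Xp[:, focal_cols] = Xm[rng.permutation(m)][:, focal_cols]
        perm_delta = fit_penalized(Xp, Ym, lam).r2 - r2_red
        if perm_delta >= delta - _EPS:
            count += 1
    p = (1 + count) / (1 + n_perm)
    contributing = (delta > delta_gate) and (p < alpha)
    return ContributionCall(focal_block=focal_function, delta_r2=delta,
                            p_value=p, contributing=contributing,
                            r2_full=r2_full, r2_reduced=r2_red)


# ---------------------------------------------------------------------------
# stage-wise class fractions
# ---------------------------------------------------------------------------

def class_fractions(
    stage_categories: dict[str, list[str]],
    stage_order: tuple[str, ...] = ("T1N0", "T2N0", "T3N0", "N1", "N2", "N3"),
) -> pd.DataFrame:
    """Per-stage fractions of selected non-neural pathways in the two
    environment super-classes.

    Input maps stage -> the non-neural categories of the pathways selected at
    that stage.  Pathways in neither super-class count toward the denominator
    but no numerator, so the two fractions sum to <= 1.  Stages with nothing
    selected are emitted as NaN with a warning.
    """
    rows = {}
    for stage in stage_order:
        cats = stage_categories.get(stage, [])
        if not cats:
            logger.warning("stage %s: no selected pathways; fractions undefined",
                           stage)
            rows[stage] = (math.nan, math.nan)
            continue
        classes = [envclass_of(c) for c in cats]
        total = len(classes)
        rows[stage] = (
            sum(c == CELL_ENVIRONMENT for c in classes) / total,
            sum(c == INTRACELLULAR_DAMAGE for c in classes) / total,
        )
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["fraction_cell_environment", "fraction_intracellular_damage"],
    ).loc[list(stage_order)]
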