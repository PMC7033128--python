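"""End-to-end stage-wise pipeline: simulate/load -> catalogue -> differential
expression -> co-expression -> enrichment -> explainability, with per-stage
artifacts, a consolidated report and a machine-readable run manifest.

Every output is a plain-text TSV/JSON file and every number in the report is
recomputed from the inputs under the run's seed, so identical (config, seed)
pairs produce byte-identical report trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import coexpression as coex
from . import diffexpr as de
from . import enrichment as enr
from . import explain as ex
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of one pipeline run (defaults are the study values)."""

    label: str = "cohort"
    fixture_dir: str | None = None      # read a written fixture instead of simulating
    stages: tuple[str, ...] = sim.STAGES
    fc_threshold: float = 2.0
    de_alpha: float = 0.05
    pool_controls: bool = True
    corr_method: str = "spearman"
    corr_threshold: float = 0.8
    corr_square_cutoff: bool = False
    corr_alpha: float = 0.05
    enrich_alpha: float = 0.05
    r2_gate: float = 2.0 / 3.0
    delta_gate: float = 0.01
    contribution_alpha: float = 0.01
    alpha_drop: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    # simulation settings used when no fixture_dir is given
    n_blocks: int = 2
    block_nonneural: int = 5
    block_neural: int = 3
    noise_sd: float = 0.05
    n_tumor: int = 30
    n_control: int = 15

    def validate(self) -> None:
        for name, lo, hi in (("de_alpha", 0, 1), ("corr_alpha", 0, 1),
                             ("enrich_alpha", 0, 1), ("alpha_drop", 0, 1),
                             ("contribution_alpha", 0, 1),
                             ("corr_threshold", 0, 1), ("r2_gate", 0, 1)):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        unknown = set(self.stages) - set(sim.STAGES)
        if unknown:
            raise ValueError(f"unknown stage label(s): {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageResult:
    stage: str
    n_up_regulated: int
    ncn_genes: set[str]
    nncn_genes: set[str]
    enrichment: pd.DataFrame
    calls: dict[str, ex.ExplainCall]
    selected_categories: list[str] = field(default_factory=list)


def _tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: RunConfig, out_dir: Path | str) -> Path:
    """Run every stage of the analysis and write the report directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -------------------------------------------------------------
    if config.fixture_dir is not None:
        cohort = sim.read_cohort(config.fixture_dir)
        gmt_path = Path(config.fixture_dir) / "annotations.gmt"
        if not gmt_path.exists():
            raise FileNotFoundError(f"fixture has no annotations.gmt: {gmt_path}")
    else:
        sim_config = sim.planted_cohort_config(
            n_blocks=config.n_blocks,
            block_nonneural=config.block_nonneural,
            block_neural=config.block_neural, noise_sd=config.noise_sd,
            n_tumor=config.n_tumor, n_control=config.n_control,
            seed=config.seed, stages=config.stages,
        )
        cohort, truth = sim.simulate_cohort(sim_config)
        pathways = sim.default_pathway_catalog(sim_config)
        sim.write_fixture(cohort, truth, out / "fixture", pathways=pathways)
        gmt_path = out / "fixture" / "annotations.gmt"

    catalog = cat.load_catalog(gmt_path, sim.NEURAL_TERMS)
    neural8 = cat.assign_categories(catalog, "neural8")
    fig3 = cat.assign_categories(catalog, "nonneural_fig3")
    fig2 = cat.assign_categories(catalog, "nonneural_fig2")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    results: list[StageResult] = []
    stage_enrichments: dict[str, pd.DataFrame] = {}
    fit_rows = []

    for stage in config.stages:
        logger.info("[%s] differential expression", stage)
        de_table = de.test_differential(
            cohort, stage, pool_controls=config.pool_controls,
            fc_threshold=config.fc_threshold, alpha=config.de_alpha,
        )
        _tsv(de_table, out / f"de_{stage}.tsv", index_label="gene")
        up = set(de.up_regulated_genes(de_table))
        up_nonneural = sorted(up & catalog.nonneural_genes)
        logger.info("[%s] %d up-regulated (%d non-neural)", stage, len(up),
                    len(up_nonneural))

        tumor_ids = cohort.samples(stage=stage, condition=sim.TUMOR)
        tpm_tumor = cohort.tpm[tumor_ids]
        neural_genes = sorted(catalog.neural_genes & set(cohort.genes))
        if not up_nonneural:
            logger.warning("[%s] no up-regulated non-neural genes; stage empty",
                           stage)
            results.append(StageResult(stage, len(up), set(), set(),
                                       pd.DataFrame(), {}))
            continue

        corr = coex.correlate(
            tpm_tumor, neural_genes, up_nonneural,
            method=config.corr_method, threshold=config.corr_threshold,
            alpha=config.corr_alpha, square_cutoff=config.corr_square_cutoff,
        )
        _tsv(corr.records, out / f"corr_{stage}.tsv", index=False)
        linked = coex.derive_linked_sets(corr, de_table, catalog, tpm_tumor)
        logger.info("[%s] %d NCN / %d NNCN genes", stage,
                    len(linked.ncn_genes), len(linked.nncn_genes))

        matrix, row_lab, col_lab = coex.heatmap_matrix(corr, catalog,
                                                       neural8, fig3)
        _tsv(matrix, out / f"heatmap_{stage}.tsv", index_label="gene")
        pd.DataFrame({"gene": list(row_lab.index) + list(col_lab.index),
                      "axis": ["row"] * len(row_lab) + ["col"] * len(col_lab),
                      "category": list(row_lab) + list(col_lab)}
                     ).to_csv(out / f"heatmap_{stage}_categories.tsv",
                              sep="\t", index=False)

        enrichment = pd.DataFrame()
        if linked.ncn_genes:
            enrichment = enr.enrich(linked.ncn_genes, catalog,
                                    catalog.neural_genes,
                                    alpha=config.enrich_alpha, scheme=neural8)
            enrichment = enrichment[enrichment.index.isin(
                catalog.neural_pathways)]
            _tsv(enrichment, out / f"enrich_ncn_{stage}.tsv")
            stage_enrichments[stage] = enrichment
        if linked.nncn_genes:
            nncn_enr = enr.enrich(linked.nncn_genes, catalog,
                                  catalog.nonneural_genes,
                                  alpha=config.enrich_alpha, scheme=fig2)
            _tsv(nncn_enr, out / f"enrich_nncn_{stage}.tsv")

        # one regression per neural function category of the NCN genes,
        # candidates = all up-regulated non-neural genes
        calls: dict[str, ex.ExplainCall] = {}
        categories: list[str] = []
        if linked.ncn_genes and up_nonneural:
            expr = ex.minmax_normalize(
                cohort.tpm.loc[sorted(linked.ncn_genes | set(up_nonneural)),
                               tumor_ids])
            ncn_cat = cat.gene_categories(
                catalog, neural8, [g for g in sorted(linked.ncn_genes)
                                   if g in expr.index])
            x_genes = [g for g in up_nonneural if g in expr.index]
            by_cat: dict[str, list[str]] = {}
            for g, c in ncn_cat.items():
                by_cat.setdefault(c, []).append(g)
            selected_union: set[str] = set()
            for category in sorted(by_cat):
                y_genes = sorted(by_cat[category])
                if not y_genes or not x_genes:
                    continue
                call = ex.explainability_call(
                    expr.loc[x_genes].T, expr.loc[y_genes].T,
                    alpha_drop=config.alpha_drop, r2_gate=config.r2_gate,
                    n_perm=config.n_perm, seed=rng,
                )
                calls[category] = call
                selected_union.update(call.fit.selected)
                fit_rows.append({
                    "stage": stage, "neural_function": category,
                    "n_candidates": len(x_genes),
                    "n_responses": len(y_genes),
                    "n_selected": len(call.fit.selected),
                    "selected": ";".join(call.fit.selected),
                    "r2": call.r2, "adj_r2": call.adj_r2,
                    "perm_p": call.perm_p, "minimal": call.minimal,
                    "explainable": call.explainable,
                })
            selected_pathways = sorted(
                p for p, genes in catalog.pathways.items()
                if not catalog.neural_flag[p] and genes & selected_union
            )
            categories = [fig3.assignment[p] for p in selected_pathways]
        results.append(StageResult(stage, len(up), linked.ncn_genes,
                                   linked.nncn_genes, enrichment, calls,
                                   categories))

    # --- consolidated report -------------------------------------------------
    if stage_enrichments:
        table1 = enr.stage_category_counts(stage_enrichments, neural8)
        _tsv(table1, out / "category_counts_neural8.tsv", index_label="category")
    if fit_rows:
        _tsv(pd.DataFrame(fit_rows), out / "fit_report.tsv", index=False)
    fractions = ex.class_fractions(
        {r.stage: r.selected_categories for r in results},
        stage_order=tuple(config.stages),
    )
    _tsv(fractions, out / "class_fractions.tsv", index_label="stage")

    summary = pd.DataFrame(
        {
            "stage": [r.stage for r in results],
            "n_up_regulated": [r.n_up_regulated for r in results],
            "n_ncn": [len(r.ncn_genes) for r in results],
            "n_nncn": [len(r.nncn_genes) for r in results],
            "n_explainable": [sum(c.explainable for c in r.calls.values())
                              for r in results],
            "best_r2": [max((c.r2 for c in r.calls.values()),
                            default=float("nan")) for r in results],
        }
    )
    _tsv(summary, out / "summary.tsv", index=False)

    manifest = {
        "label": config.label,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "category_scheme": "neural8",
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out


def compare_cohorts(report_a: Path | str, report_b: Path | str) -> pd.DataFrame:
    """Side-by-side per-category enriched-pathway counts with ratios.

    Both report directories must have been produced under the same category
    scheme (checked via their manifests).
    """
    report_a, report_b = Path(report_a), Path(report_b)
    man_a = json.loads((report_a / "manifest.json").read_text())
    man_b = json.loads((report_b / "manifest.json").read_text())
    if man_a["category_scheme"] != man_b["category_scheme"]:
        raise ValueError(
            f"category schemes differ: {man_a['category_scheme']} vs "
            f"{man_b['category_scheme']}"
        )

    def load_counts(report: Path, label: str) -> pd.Series:
        path = report / "category_counts_neural8.tsv"
        if not path.exists():
            return pd.Series(dtype=int, name=label)
        df = pd.read_csv(path, sep="\t", index_col="category")
        return df["total"].rename(label)

    a = load_counts(report_a, man_a["label"])
    b = load_counts(report_b, man_b["label"])
    contrast = pd.concat([a, b], axis=1).fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = contrast.iloc[:, 0] / contrast.iloc[:, 1]
    contrast["ratio"] = ratio.replace([np.inf, -np.inf], np.nan)

    sum_a = pd.read_csv(report_a / "summary.tsv", sep="\t")
    sum_b = pd.read_csv(report_b / "summary.tsv", sep="\t")
    contrast.attrs["explainable_functions"] = {
        man_a["label"]: int(sum_a["n_explainable"].sum()),
        man_b["label"]: int(sum_b["n_explainable"].sum()),
    }
    return contrast
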