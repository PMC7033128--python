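"""Synthetic tumor/control cohort generator with full ground truth.

Generates stage-labelled expression cohorts with the statistical structure the
downstream analysis assumes: negative-binomial counts over log-normal baseline
means, planted up-regulated genes, latent-factor co-expression blocks, and
planted linear non-neural -> neural inducer maps with known coefficients.
Every planted feature is recorded in a :class:`GroundTruth` object so that
differential expression, co-expression, enrichment and the explainability
regression can all be validated without any external data.

Scales and conventions
----------------------
* Counts follow a negative-binomial model with a single shared dispersion
  ``alpha`` (variance = mu + alpha * mu**2), the standard bulk RNA-seq model.
* Latent factors and differential-expression effects act additively on the
  natural-log mean before count sampling.
* Planted inducer maps act on log1p-transformed expression: responder neural
  genes are stored as ``expm1(log1p(X_inducers) @ C + noise)``, a
  deterministic continuous function of their inducers.  They are not re-drawn
  from the count model and not rounded, so coefficient recovery is exact in
  the noiseless limit; the counts matrix is therefore float-valued (all other
  entries are integral).
* Stage vocabulary is fixed to the six TNM-derived labels
  ``T1N0, T2N0, T3N0, N1, N2, N3``; each stage draws from its own child RNG
  stream of the global seed, so stages are independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("T1N0", "T2N0", "T3N0", "N1", "N2", "N3")
TUMOR = "tumor"
CONTROL = "control"

#: default substrings used to flag neural pathways in a catalogue
NEURAL_TERMS: tuple[str, ...] = (
    "neur", "synap", "axon", "dendrit", "glia", "glio", "brain",
    "nervous", "cortex", "pallium", "telencephalon", "forebrain",
)


def neural_gene_name(i: int) -> str:
    return f"NRG{i:04d}"


def nonneural_gene_name(i: int) -> str:
    return f"NNG{i:04d}"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InducerBlock:
    """A planted linear map from a non-neural gene block to a neural one.

    ``coefficients[i, j]`` is the weight of non-neural member ``i`` on neural
    responder ``j``, applied to log1p expression.
    """

    nonneural: tuple[int, ...]
    neural: tuple[int, ...]
    coefficients: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if len(set(self.nonneural)) != len(self.nonneural):
            raise ValueError("duplicate non-neural indices within inducer block")
        if len(set(self.neural)) != len(self.neural):
            raise ValueError("duplicate neural indices within inducer block")
        if coef.shape != (len(self.nonneural), len(self.neural)):
            raise ValueError(
                f"coefficient matrix shape {coef.shape} does not match block "
                f"({len(self.nonneural)} non-neural x {len(self.neural)} neural)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CoexprBlock:
    """A latent-factor block adding shared Gaussian signal on the log scale."""

    neural: tuple[int, ...] = ()
    nonneural: tuple[int, ...] = ()
    loading: float = 1.0
    factor_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.factor_sd <= 0:
            raise ValueError("factor_sd must be > 0")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``n_samples_per_stage`` is either a single int pair applied to every stage
    or a mapping stage -> (n_tumor, n_control).
    """

    n_neural_genes: int = 60
    n_nonneural_genes: int = 120
    n_tumor: int = 30
    n_control: int = 15
    n_samples_per_stage: Mapping[str, tuple[int, int]] | None = None
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    inducer_map: Sequence[InducerBlock] = field(default_factory=tuple)
    coexpr_blocks: Sequence[CoexprBlock] = field(default_factory=tuple)
    base_log_mean: float = 3.5
    base_log_sd: float = 1.0
    stages: Sequence[str] = STAGES
    seed: int = 0

    def stage_sizes(self) -> dict[str, tuple[int, int]]:
        if self.n_samples_per_stage is not None:
            sizes = dict(self.n_samples_per_stage)
        else:
            sizes = {s: (self.n_tumor, self.n_control) for s in self.stages}
        for stage, (nt, nc) in sizes.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage label {stage!r}")
            if nt <= 0 or nc <= 0:
                raise ValueError(f"sample counts must be positive (stage {stage})")
        return sizes

    def validate(self) -> None:
        if self.n_neural_genes <= 0 or self.n_nonneural_genes <= 0:
            raise ValueError("gene counts must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        self.stage_sizes()
        seen_responders: set[int] = set()
        for blk in self.inducer_map:
            if max(blk.nonneural, default=-1) >= self.n_nonneural_genes:
                raise ValueError("inducer block references non-neural gene out of range")
            if max(blk.neural, default=-1) >= self.n_neural_genes:
                raise ValueError("inducer block references neural gene out of range")
            overlap = seen_responders.intersection(blk.neural)
            if overlap:
                raise ValueError(
                    f"neural responder indices {sorted(overlap)} appear in more "
                    "than one inducer block"
                )
            seen_responders.update(blk.neural)
        for blk in self.coexpr_blocks:
            if max(blk.neural, default=-1) >= self.n_neural_genes:
                raise ValueError("coexpression block neural index out of range")
            if max(blk.nonneural, default=-1) >= self.n_nonneural_genes:
                raise ValueError("coexpression block non-neural index out of range")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCohort:
    """A samples x genes expression cohort with condition and stage labels.

    ``counts`` and ``tpm`` are genes-as-rows DataFrames sharing column order
    with ``metadata['sample_id']``.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def stages(self) -> list[str]:
        return [s for s in STAGES if s in set(self.metadata["stage"])]

    def samples(self, stage: str | None = None, condition: str | None = None) -> list[str]:
        md = self.metadata
        mask = pd.Series(True, index=md.index)
        if stage is not None:
            mask &= md["stage"] == stage
        if condition is not None:
            mask &= md["condition"] == condition
        return list(md.loc[mask, "sample_id"])


@dataclass
class GroundTruth:
    """Everything the generator planted, for validation of downstream calls."""

    de_genes: set[str]
    inducer_edges: set[tuple[str, str]]
    block_membership: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": sorted(self.de_genes),
                "inducer_edges": sorted(list(e) for e in self.inducer_edges),
                "block_membership": dict(sorted(self.block_membership.items())),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            de_genes=set(obj["de_genes"]),
            inducer_edges={tuple(e) for e in obj["inducer_edges"]},
            block_membership=dict(obj["block_membership"]),
        )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def simulate_cohort(config: SimulationConfig) -> tuple[ExpressionCohort, GroundTruth]:
    """Draw one cohort and the ground truth of everything planted in it.

    Per stage: a fresh RNG stream; baseline natural-log means shared across
    stages; tumor samples of planted DE genes get ``+de_log2fc*ln 2`` on the
    log mean; latent-factor blocks add ``loading * N(0, factor_sd)`` per
    sample; counts are negative-binomial; responder neural genes are then
    overwritten with the planted linear map of their inducer block's log1p
    expression plus Gaussian noise, back-transformed through expm1.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_streams = len(config.stages) + 1
    streams = [np.random.default_rng(s) for s in root.spawn(n_streams)]
    gene_rng, stage_rngs = streams[0], streams[1:]

    neural = [neural_gene_name(i) for i in range(config.n_neural_genes)]
    nonneural = [nonneural_gene_name(i) for i in range(config.n_nonneural_genes)]
    genes = neural + nonneural
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    base_log_mu = gene_rng.normal(config.base_log_mean, config.base_log_sd, n_genes)

    # --- plant DE genes -----------------------------------------------------
    responder_cols = {
        gene_pos[neural[j]] for blk in config.inducer_map for j in blk.neural
    }
    de_genes: set[str] = set()
    if config.de_fraction > 0:
        n_de = max(1, math.ceil(config.de_fraction * n_genes))
        # inducer members are up-regulated first: the downstream candidate set
        # for the explainability regression is the up-regulated non-neural genes
        for blk in config.inducer_map:
            de_genes.update(nonneural[i] for i in blk.nonneural)
        eligible = [g for g in genes
                    if g not in de_genes and gene_pos[g] not in responder_cols]
        extra = n_de - len(de_genes)
        if extra > 0:
            de_genes.update(gene_rng.choice(eligible, size=min(extra, len(eligible)),
                                            replace=False))
    de_cols = np.array(sorted(gene_pos[g] for g in de_genes), dtype=int)

    # --- per-stage count sampling ------------------------------------------
    sizes = config.stage_sizes()
    count_blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    conditions: list[str] = []
    stage_labels: list[str] = []
    ln2 = math.log(2.0)

    for stage, rng in zip(config.stages, stage_rngs):
        nt, nc = sizes[stage]
        m = nt + nc
        is_tumor = np.array([True] * nt + [False] * nc)
        log_mu = np.tile(base_log_mu, (m, 1))
        if de_cols.size:
            log_mu[np.ix_(is_tumor, de_cols)] += config.de_log2fc * ln2
        for blk in config.coexpr_blocks:
            cols = [gene_pos[neural[i]] for i in blk.neural]
            cols += [gene_pos[nonneural[i]] for i in blk.nonneural]
            factor = rng.normal(0.0, blk.factor_sd, m)
            log_mu[:, cols] += blk.loading * factor[:, None]
        counts = _nb_sample(rng, np.exp(log_mu), config.nb_dispersion)
        for blk in config.inducer_map:
            x_cols = [gene_pos[nonneural[i]] for i in blk.nonneural]
            y_cols = [gene_pos[neural[i]] for i in blk.neural]
            z = np.log1p(counts[:, x_cols])
            t = z @ blk.coefficients
            if blk.noise_sd > 0:
                t = t + rng.normal(0.0, blk.noise_sd, t.shape)
            counts[:, y_cols] = np.maximum(np.expm1(t), 0.0)
        count_blocks.append(counts)
        sample_ids += [f"{stage}_{'T' if t else 'C'}{i:03d}"
                       for i, t in enumerate(is_tumor)]
        conditions += [TUMOR if t else CONTROL for t in is_tumor]
        stage_labels += [stage] * m

    all_counts = np.vstack(count_blocks).T  # genes x samples
    counts_df = pd.DataFrame(all_counts, index=pd.Index(genes, name="gene"),
                             columns=sample_ids)
    tpm_df = counts_df / counts_df.sum(axis=0) * 1e6
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "condition": conditions, "stage": stage_labels}
    )

    membership: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    for b, blk in enumerate(config.inducer_map):
        bid = f"inducer_{b}"
        for i in blk.nonneural:
            membership[nonneural[i]] = f"{bid}:nonneural"
        for j in blk.neural:
            membership[neural[j]] = f"{bid}:neural"
        for bi, i in enumerate(blk.nonneural):
            for bj, j in enumerate(blk.neural):
                if blk.coefficients[bi, bj] != 0.0:
                    edges.add((nonneural[i], neural[j]))
    for b, blk in enumerate(config.coexpr_blocks):
        bid = f"coexpr_{b}"
        for i in blk.neural:
            membership.setdefault(neural[i], bid)
        for i in blk.nonneural:
            membership.setdefault(nonneural[i], bid)

    truth = GroundTruth(de_genes=de_genes, inducer_edges=edges,
                        block_membership=membership)
    return ExpressionCohort(counts_df, tpm_df, metadata), truth


def planted_cohort_config(
    n_blocks: int = 2,
    block_nonneural: int = 5,
    block_neural: int = 3,
    noise_sd: float = 0.05,
    n_neural_genes: int = 60,
    n_nonneural_genes: int = 120,
    n_tumor: int = 30,
    n_control: int = 15,
    de_fraction: float = 0.1,
    factor_sd: float = 0.8,
    seed: int = 0,
    stages: Sequence[str] = STAGES,
) -> SimulationConfig:
    """A standard planted-structure configuration.

    Inducer blocks occupy the front of both gene universes; each block's
    non-neural members share a latent co-expression factor (so that the block
    behaves like a co-regulated pathway) and drive their neural responders
    through positive coefficients with rows summing to ~1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    blocks: list[InducerBlock] = []
    coexpr: list[CoexprBlock] = []
    for b in range(n_blocks):
        nn = tuple(range(b * block_nonneural, (b + 1) * block_nonneural))
        nr = tuple(range(b * block_neural, (b + 1) * block_neural))
        coef = rng.uniform(0.5, 1.5, (block_nonneural, block_neural))
        coef /= coef.sum(axis=0, keepdims=True)
        blocks.append(InducerBlock(nonneural=nn, neural=nr,
                                   coefficients=coef, noise_sd=noise_sd))
        coexpr.append(CoexprBlock(nonneural=nn, loading=1.0, factor_sd=factor_sd))
    return SimulationConfig(
        n_neural_genes=n_neural_genes,
        n_nonneural_genes=n_nonneural_genes,
        n_tumor=n_tumor,
        n_control=n_control,
        de_fraction=de_fraction,
        inducer_map=tuple(blocks),
        coexpr_blocks=tuple(coexpr),
        seed=seed,
        stages=stages,
    )


# ---------------------------------------------------------------------------
# fixture pathways
# ---------------------------------------------------------------------------

#: neural-category names used for generated pathway labels (Table-1 vocabulary)
_NEURAL_PATHWAY_NAMES = (
    "synapse formation", "neurotransmitter secretion", "neural crest development",
    "axon growth and dendrite pruning", "neuron projection and apoptosis",
    "neural structure formation in CNS", "neuron differentiation",
    "development of glia",
)
#: non-neural category names cycled for generated non-neural pathways
_NONNEURAL_PATHWAY_NAMES = (
    "cytokine and chemokine production", "cell skeleton synthesis",
    "cell adhesion", "DNA damage and metabolism", "calcium sequestering",
    "organelle assembly", "hemopoiesis", "ECM synthesis",
)


def default_pathway_catalog(
    config: SimulationConfig, chunk: int = 15
) -> dict[str, list[str]]:
    """Deterministic pathway sets over the simulated gene universe.

    Each inducer block becomes a dedicated neural pathway (responders) and a
    dedicated non-neural pathway (inducers), named with category keywords so
    the catalogue's keyword rules bin them; remaining genes are chunked into
    filler pathways.
    """
    neural = [neural_gene_name(i) for i in range(config.n_neural_genes)]
    nonneural = [nonneural_gene_name(i) for i in range(config.n_nonneural_genes)]
    pathways: dict[str, list[str]] = {}
    used_n: set[int] = set()
    used_nn: set[int] = set()
    for b, blk in enumerate(config.inducer_map):
        nname = _NEURAL_PATHWAY_NAMES[b % len(_NEURAL_PATHWAY_NAMES)]
        nnname = _NONNEURAL_PATHWAY_NAMES[b % len(_NONNEURAL_PATHWAY_NAMES)]
        pathways[f"{nname} block {b}"] = [neural[i] for i in blk.neural]
        pathways[f"{nnname} block {b}"] = [nonneural[i] for i in blk.nonneural]
        used_n.update(blk.neural)
        used_nn.update(blk.nonneural)
    rest_n = [neural[i] for i in range(config.n_neural_genes) if i not in used_n]
    rest_nn = [nonneural[i] for i in range(config.n_nonneural_genes)
               if i not in used_nn]
    for c, start in enumerate(range(0, len(rest_n), chunk)):
        name = _NEURAL_PATHWAY_NAMES[(c + 3) % len(_NEURAL_PATHWAY_NAMES)]
        pathways[f"{name} background {c}"] = rest_n[start:start + chunk]
    for c, start in enumerate(range(0, len(rest_nn), chunk)):
        name = _NONNEURAL_PATHWAY_NAMES[(c + 3) % len(_NONNEURAL_PATHWAY_NAMES)]
        pathways[f"{name} background {c}"] = rest_nn[start:start + chunk]
    return pathways


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_gmt(pathways: Mapping[str, Sequence[str]], path: Path | str) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def write_fixture(
    cohort: ExpressionCohort,
    truth: GroundTruth,
    directory: Path | str,
    pathways: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, Path]:
    """Write a cohort as plain-text fixture files.

    Emits counts.tsv, tpm.tsv, metadata.tsv, truth.json and (when pathway sets
    are given) annotations.gmt; all round-trip losslessly through
    :func:`read_cohort` / :func:`read_truth`.
    """
    if cohort.counts.empty:
        raise ValueError("cohort has no genes; refusing to write empty fixture")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "tpm": directory / "tpm.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    cohort.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    cohort.tpm.to_csv(paths["tpm"], sep="\t", index_label="gene")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    if pathways is not None:
        paths["gmt"] = directory / "annotations.gmt"
        write_gmt(pathways, paths["gmt"])
    return paths


def read_cohort(directory: Path | str) -> ExpressionCohort:
    directory = Path(directory)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="gene")
    tpm = pd.read_csv(directory / "tpm.tsv", sep="\t", index_col="gene")
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t")
    required = {"sample_id", "condition", "stage"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing column(s): {sorted(missing)}")
    return ExpressionCohort(counts=counts, tpm=tpm, metadata=metadata)


def read_truth(path: Path | str) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
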