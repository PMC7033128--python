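"""Pathway catalogue: neural/non-neural gene classes and category binnings.

A :class:`PathwayCatalog` is built from a GMT file plus a list of neural
keyword terms; a gene is *neural* if it belongs to at least one
neural-flagged pathway (classification by inclusion, so a gene with both
neural and non-neural annotations is neural).  Category schemes bin pathways
into the fixed reporting vocabularies (the eight neural categories, the four
developmental groups, the non-neural category sets, and the two-way
cell-environment / intracellular-damage super-classes) via an ordered,
first-match-wins keyword rule table shipped as editable YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

NEURAL = "neural"
NONNEURAL = "non-neural"
UNCLASSIFIED = "unclassified"

#: the two environment super-classes plus the fall-through
CELL_ENVIRONMENT = "cell-environment interaction"
INTRACELLULAR_DAMAGE = "intracellular damage processing"
NEITHER = "neither"

#: non-neural categories composing each super-class
_ENVCLASS_MEMBERS = {
    CELL_ENVIRONMENT: {
        "cytokine and chemokine production", "cell adhesion",
        "calcium sequestering", "hemopoiesis", "ECM synthesis",
    },
    INTRACELLULAR_DAMAGE: {
        "cell skeleton synthesis", "DNA damage and metabolism",
        "organelle assembly",
    },
}

SCHEME_NAMES = ("neural8", "groups4", "nonneural_fig2", "nonneural_fig3",
                "envclass2")


@dataclass
class PathwayCatalog:
    """Pathway -> gene sets with neural flags and the derived gene classes."""

    pathways: dict[str, set[str]]
    neural_flag: dict[str, bool]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_class: dict[str, str] = {}
        for pid, genes in self.pathways.items():
            for g in genes:
                if self.neural_flag.get(pid, False):
                    self.gene_class[g] = NEURAL
                else:
                    self.gene_class.setdefault(g, NONNEURAL)

    @property
    def neural_genes(self) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == NEURAL}

    @property
    def nonneural_genes(self) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == NONNEURAL}

    @property
    def neural_pathways(self) -> set[str]:
        return {p for p, f in self.neural_flag.items() if f}

    def genes_of(self, pathway_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for pid in pathway_ids:
            out |= self.pathways[pid]
        return out


@dataclass
class CategoryScheme:
    """One binning of pathways into a fixed category vocabulary."""

    name: str
    assignment: dict[str, str]
    keyword_rules: list[tuple[tuple[str, ...], str]]

    @property
    def vocabulary(self) -> list[str]:
        seen: list[str] = []
        for _, cat in self.keyword_rules:
            if cat not in seen:
                seen.append(cat)
        seen.append(UNCLASSIFIED)
        return seen

    def categories_of(self, pathway_ids: Iterable[str]) -> dict[str, str]:
        return {p: self.assignment[p] for p in pathway_ids}


def parse_gmt(path: Path | str) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT file into (pathway -> genes, pathway -> description)."""
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected >= 3 tab-separated fields, got {len(fields)})"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = set(genes)
            descriptions[name] = desc
    if not pathways:
        raise ValueError(f"{path}: empty GMT file")
    return pathways, descriptions


def load_catalog(
    gmt_path: Path | str, neural_term_list: Sequence[str]
) -> PathwayCatalog:
    """Build a catalogue, neural-flagging pathways whose id or description
    contains any of the given terms (case-insensitive substring match)."""
    pathways, descriptions = parse_gmt(gmt_path)
    terms = [t.lower() for t in neural_term_list]
    flags = {
        pid: any(t in f"{pid} {descriptions.get(pid, '')}".lower() for t in terms)
        for pid in pathways
    }
    return PathwayCatalog(pathways=pathways, neural_flag=flags,
                          descriptions=descriptions)


def _load_rules(rules_path: Path | str | None = None) -> dict[str, list]:
    if rules_path is not None:
        text = Path(rules_path).read_text()
    else:
        text = (resources.files("neurostage") / "data" / "category_rules.yaml"
                ).read_text()
    return yaml.safe_load(text)


def assign_categories(
    catalog: PathwayCatalog,
    scheme_name: str,
    rules_path: Path | str | None = None,
) -> CategoryScheme:
    """Bin every pathway of the catalogue under the named scheme.

    First matching keyword rule wins; pathways matching no rule are labelled
    ``unclassified``.  Matching is a case-insensitive substring search over
    the pathway id and its description.
    """
    all_rules = _load_rules(rules_path)
    if scheme_name not in all_rules:
        raise ValueError(
            f"unknown category scheme {scheme_name!r}; "
            f"known: {sorted(all_rules)}"
        )
    rules = [(tuple(r["keywords"]), str(r["category"]))
             for r in all_rules[scheme_name]]
    assignment: dict[str, str] = {}
    for pid in catalog.pathways:
        text = f"{pid} {catalog.descriptions.get(pid, '')}".lower()
        for keywords, cat in rules:
            if any(k.lower() in text for k in keywords):
                assignment[pid] = cat
                break
        else:
            assignment[pid] = UNCLASSIFIED
    return CategoryScheme(name=scheme_name, assignment=assignment,
                          keyword_rules=rules)


def gene_categories(
    catalog: PathwayCatalog,
    scheme: CategoryScheme,
    genes: Iterable[str] | None = None,
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Category per gene: the first category (in scheme vocabulary order, or
    the given order) among the categories of the pathways containing it."""
    if order is None:
        order = scheme.vocabulary
    rank = {c: i for i, c in enumerate(order)}
    gene_cats: dict[str, set[str]] = {}
    for pid, members in catalog.pathways.items():
        cat = scheme.assignment.get(pid, UNCLASSIFIED)
        for g in members:
            gene_cats.setdefault(g, set()).add(cat)
    universe = gene_cats if genes is None else genes
    out: dict[str, str] = {}
    for g in universe:
        cats = gene_cats.get(g, set())
        out[g] = min(cats, key=lambda c: rank.get(c, len(rank))) if cats \
            else UNCLASSIFIED
    return out


def envclass_of(nonneural_category: str) -> str:
    """Map a non-neural category to its environment super-class.

    Cytokine/chemokine production, cell adhesion, calcium sequestering,
    hemopoiesis and ECM synthesis are cell-environment interactions; cell
    skeleton synthesis, DNA damage and metabolism, and organelle assembly are
    intracellular damage processing; anything else is ``neither``.
    """
    for cls, members in _ENVCLASS_MEMBERS.items():
        if nonneural_category in members:
            return cls
    return NEITHER
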