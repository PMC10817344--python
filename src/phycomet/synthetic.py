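"""Synthetic datasets with controlled statistical structure.

Emulates the shape of a multi-assembly comparative study of algal metabolism:
several taxonomic classes of genome assemblies (plus optional
transcriptome-like groups with extra annotation dropout), a catalogue of
boolean module definitions, class-structured KO presence/absence with planted
differential modules, a ladderised species tree with per-node duplication
events whose gene annotations are enriched for a node-specific category, and
syntactically valid BUSCO / RepeatMasker / protein-FASTA fixtures.

Everything is drawn from a seeded integer-state generator (numpy PCG64), so a
fixed seed reproduces every file byte-for-byte on any platform.  What the
generator does **not** emulate: real sequences, annotation error correlated
with evolutionary distance, or KEGG's actual module catalogue — the planted
signals are clean by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from phycomet.completeness import AnnotationSet
from phycomet.duplication import DuplicationRecord, write_duplications
from phycomet.module_model import (
    And,
    Atom,
    Expr,
    ModuleDefinition,
    Or,
    write_module_table,
)

__all__ = [
    "GroupSpec",
    "DuplicationSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_modules",
    "generate_annotations",
    "generate_duplications",
    "generate_qc_fixtures",
    "generate_dataset",
    "write_fixture_dir",
]

_MODULE_CLASSES = (
    ("Amino acid metabolism", "Aromatic amino acid metabolism"),
    ("Carbohydrate metabolism", "Other carbohydrate metabolism"),
    ("Lipid metabolism", "Sterol biosynthesis"),
    ("Energy metabolism", "Carbon fixation"),
    ("Nucleotide metabolism", "Purine metabolism"),
    ("Metabolism of cofactors and vitamins", "Cofactor and vitamin metabolism"),
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GroupSpec:
    """One assembly group: a taxonomic class (or transcriptome source cohort)."""

    label: str
    n_assemblies: int
    source: str = "genome"  # genome | 1KP | MMETSP


@dataclass(frozen=True)
class DuplicationSpec:
    tree_shape: str = "ladder"
    events_per_node: tuple[int, int] = (8, 24)
    n_categories: int = 8
    enrichment_odds: float = 5.0
    genes_per_side: tuple[int, int] = (1, 3)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; the defaults define the standard study-like
    conditions exercised by the test suite.

    Four genome classes of eight assemblies each, 200 modules of 2–6 blocks,
    a 0.9 baseline KO presence, and ten planted differential modules whose
    KOs are knocked out of one class with probability 0.9 — a clean analogue
    of class-specific pathway loss.  Transcriptome-like groups (source
    ``1KP``/``MMETSP``) lose surviving KOs at their source's dropout rate.
    """

    seed: int = 0
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("Florideophyceae", 8),
        GroupSpec("Bangiophyceae", 8),
        GroupSpec("Cyanidiophyceae", 8),
        GroupSpec("Porphyridiophyceae", 8),
    )
    n_modules: int = 200
    blocks_per_module: tuple[int, int] = (2, 6)
    p_or_alternative: float = 0.3
    p_complex: float = 0.2
    complex_size: tuple[int, int] = (2, 4)
    p_core_present: float = 0.9
    # (module index, affected group label, knockout probability)
    differential_specs: tuple[tuple[int, str, float], ...] | None = None
    dropout_1kp: float = 0.3
    dropout_mmetsp: float = 0.1
    duplication: DuplicationSpec = field(default_factory=DuplicationSpec)

    def __post_init__(self) -> None:
        for p in (self.p_or_alternative, self.p_complex, self.p_core_present,
                  self.dropout_1kp, self.dropout_mmetsp):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.differential_specs is None:
            labels = [g.label for g in self.groups]
            object.__setattr__(
                self,
                "differential_specs",
                tuple((i, labels[i % len(labels)], 0.9) for i in range(10)),
            )

    def assembly_ids(self) -> list[str]:
        return [
            f"{g.label[:4]}_{i + 1:02d}"
            for g in self.groups
            for i in range(g.n_assemblies)
        ]

    def group_assignment(self) -> dict[str, str]:
        return {
            f"{g.label[:4]}_{i + 1:02d}": g.label
            for g in self.groups
            for i in range(g.n_assemblies)
        }

    def source_assignment(self) -> dict[str, str]:
        return {
            f"{g.label[:4]}_{i + 1:02d}": g.source
            for g in self.groups
            for i in range(g.n_assemblies)
        }


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    modules: list[ModuleDefinition]
    annotations: list[AnnotationSet]
    group_assignment: dict[str, str]
    source_assignment: dict[str, str]
    tree_newick: str
    duplications: list[DuplicationRecord]
    gene_categories: dict[str, tuple[str, ...]]
    category_names: dict[str, str]
    enriched_category: dict[str, str]  # node label -> planted category
    busco_texts: dict[str, str]
    repeat_texts: dict[str, str]
    fasta_texts: dict[str, str]

    @property
    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "assembly_id": a,
                "group": self.group_assignment[a],
                "source": self.source_assignment[a],
            }
            for a in sorted(self.group_assignment)
        ]
        return pd.DataFrame(rows).set_index("assembly_id")


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

def _draw_alternative(config: SyntheticConfig, rng: np.random.Generator,
                      next_ko) -> Expr:
    if rng.random() < config.p_complex:
        lo, hi = config.complex_size
        size = int(rng.integers(lo, hi + 1))
        return And(tuple(Atom(next_ko()) for _ in range(size)))
    return Atom(next_ko())


def generate_modules(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[ModuleDefinition]:
    """Draw ``n_modules`` module definitions with unique synthetic ids and
    KO ids, all parseable by the module grammar."""
    counter = [0]

    def next_ko() -> str:
        counter[0] += 1
        return f"K{counter[0]:05d}"

    modules = []
    lo, hi = config.blocks_per_module
    for idx in range(config.n_modules):
        n_blocks = int(rng.integers(lo, hi + 1))
        blocks: list[Expr] = []
        for _ in range(n_blocks):
            primary = _draw_alternative(config, rng, next_ko)
            if rng.random() < config.p_or_alternative:
                alt = _draw_alternative(config, rng, next_ko)
                blocks.append(Or((primary, alt)))
            else:
                blocks.append(primary)
        module_class, category = _MODULE_CLASSES[idx % len(_MODULE_CLASSES)]
        modules.append(
            ModuleDefinition(
                module_id=f"M9{idx + 1:04d}",
                name=f"synthetic module {idx + 1}",
                module_class=module_class,
                module_category=category,
                blocks=tuple(blocks),
            )
        )
    return modules


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    modules: Sequence[ModuleDefinition],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[AnnotationSet], dict[str, str]]:
    """Per-assembly KO sets with planted group-differential knockouts.

    Each assembly receives each module KO independently with
    ``p_core_present``; differential knockouts then remove the KOs of the
    designated modules from assemblies of the affected group with the stated
    probability; finally, source-specific dropout removes surviving KOs from
    transcriptome-like assemblies.  Returns the annotation sets (wrapped in a
    thin one-gene-per-KO map) and the assembly -> group assignment.
    """
    from phycomet.module_model import ko_universe

    groups = config.group_assignment()
    sources = config.source_assignment()
    knockouts: dict[str, list[tuple[frozenset[str], float]]] = {}
    for module_index, group_label, prob in config.differential_specs:
        kos = frozenset(ko_universe(modules[module_index], include_optional=True))
        knockouts.setdefault(group_label, []).append((kos, prob))
    dropout_by_source = {"genome": 0.0, "1KP": config.dropout_1kp,
                         "MMETSP": config.dropout_mmetsp}
    all_kos = sorted(
        {ko for m in modules for ko in ko_universe(m, include_optional=True)}
    )

    annotations = []
    for assembly_id in config.assembly_ids():
        group = groups[assembly_id]
        dropout = dropout_by_source.get(sources[assembly_id], 0.0)
        present = set()
        for ko in all_kos:
            if rng.random() < config.p_core_present:
                present.add(ko)
        for kos, prob in knockouts.get(group, ()):
            for ko in sorted(kos & present):
                if rng.random() < prob:
                    present.discard(ko)
        if dropout > 0.0:
            for ko in sorted(present):
                if rng.random() < dropout:
                    present.discard(ko)
        gene_to_ko = {
            f"{assembly_id}_g{i + 1:05d}": (ko,)
            for i, ko in enumerate(sorted(present))
        }
        annotations.append(AnnotationSet.from_genes(assembly_id, gene_to_ko))
    return annotations, groups


# ---------------------------------------------------------------------------
# Duplications
# ---------------------------------------------------------------------------

def _ladder_newick(leaves: Sequence[str]) -> tuple[str, list[str]]:
    """Ladder (caterpillar) tree with labelled internal nodes N1..N{k}."""
    if len(leaves) < 2:
        raise ValueError("a tree needs at least two leaves")
    internal = [f"N{i}" for i in range(1, len(leaves))]
    newick = leaves[0]
    for i, leaf in enumerate(leaves[1:], start=1):
        label = internal[len(leaves) - 1 - i]
        newick = f"({newick},{leaf}){label}"
    return newick + ";", internal


def generate_duplications(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, list[DuplicationRecord], dict[str, tuple[str, ...]],
           dict[str, str], dict[str, str]]:
    """Species tree, duplication table, and per-gene category annotations.

    Events are drawn per node (terminal and internal) uniformly in the
    configured range, supports uniform on [0, 1] so a 0.5 filter keeps about
    half.  Each duplicated gene is assigned one category, the node's planted
    category with odds ``enrichment_odds`` against a uniform background.
    Returns (newick, records, gene->categories, category names, node->planted
    category).
    """
    spec = config.duplication
    if spec.tree_shape != "ladder":
        raise ValueError(f"unsupported tree shape {spec.tree_shape!r}")
    leaves = config.assembly_ids()
    newick, internal = _ladder_newick(leaves)
    nodes = internal + leaves

    half = spec.n_categories // 2
    categories = [f"IPR9{i:05d}" for i in range(1, half + 1)] + [
        f"GO:99{i:05d}" for i in range(1, spec.n_categories - half + 1)
    ]
    category_names = {c: f"synthetic category {c}" for c in categories}
    enriched = {node: categories[i % len(categories)] for i, node in enumerate(nodes)}

    weights_by_node = {}
    for node in nodes:
        w = np.ones(len(categories))
        w[categories.index(enriched[node])] = spec.enrichment_odds
        weights_by_node[node] = w / w.sum()

    records: list[DuplicationRecord] = []
    gene_categories: dict[str, tuple[str, ...]] = {}
    lo, hi = spec.events_per_node
    glo, ghi = spec.genes_per_side
    og = 0
    for node in nodes:
        n_events = int(rng.integers(lo, hi + 1))
        for e in range(n_events):
            og += 1
            support = float(np.round(rng.random(), 4))
            genes = []
            for side in ("a", "b"):
                n_genes = int(rng.integers(glo, ghi + 1))
                genes.append(
                    tuple(f"{node}_e{e + 1}{side}{j + 1}" for j in range(n_genes))
                )
            for gene in genes[0] + genes[1]:
                cat = str(rng.choice(categories, p=weights_by_node[node]))
                gene_categories[gene] = (cat,)
            records.append(
                DuplicationRecord(
                    orthogroup=f"OG{og:07d}",
                    species_tree_node=node,
                    gene_tree_node=f"n{og}",
                    support=support,
                    type="Terminal" if node in leaves else "Non-Terminal",
                    genes_1=genes[0],
                    genes_2=genes[1],
                )
            )
    return newick, records, gene_categories, category_names, enriched


# ---------------------------------------------------------------------------
# QC fixtures
# ---------------------------------------------------------------------------

_BUSCO_TEMPLATE = """\
# BUSCO version is: 5.4.3
# The lineage dataset is: eukaryota_odb10 (Creation date: 2020-09-10, number of genomes: 70, number of BUSCOs: 255)
# Summarized benchmarking in BUSCO notation for file {assembly}.fa
# BUSCO was run in mode: proteins

\t***** Results: *****

\tC:{c:.1f}%[S:{s:.1f}%,D:{d:.1f}%],F:{f:.1f}%,M:{m:.1f}%,n:{n}
"""


def _busco_text(assembly: str, rng: np.random.Generator) -> str:
    c = float(np.round(rng.uniform(20.0, 95.0), 1))
    d = float(np.round(rng.uniform(0.0, min(5.0, c)), 1))
    s = round(c - d, 1)
    f = float(np.round(rng.uniform(0.0, min(15.0, 100.0 - c)), 1))
    m = round(100.0 - c - f, 1)
    return _BUSCO_TEMPLATE.format(assembly=assembly, c=c, s=s, d=d, f=f, m=m, n=255)


def _tbl_text(assembly: str, rng: np.random.Generator) -> str:
    genome_len = int(rng.integers(5_000_000, 50_000_000))
    retro = float(np.round(rng.uniform(0.0, 15.0), 2))
    dna = float(np.round(rng.uniform(0.0, 10.0), 2))
    simple = float(np.round(rng.uniform(0.0, 5.0), 2))
    uncl = float(np.round(rng.uniform(0.0, 20.0), 2))
    lowc = float(np.round(rng.uniform(0.0, 2.0), 2))
    total = round(retro + dna + simple + uncl + lowc, 2)
    masked = int(genome_len * total / 100)

    def bp(pct: float) -> int:
        return int(genome_len * pct / 100)

    return (
        "==================================================\n"
        f"file name: {assembly}.fa\n"
        "sequences:           500\n"
        f"total length:   {genome_len} bp  ({genome_len} bp excl N/X-runs)\n"
        "GC level:         45.00 %\n"
        f"bases masked:   {masked} bp ( {total:.2f} %)\n"
        "==================================================\n"
        "               number of      length   percentage\n"
        "               elements*    occupied  of sequence\n"
        "--------------------------------------------------\n"
        f"Retroelements          120       {bp(retro)} bp    {retro:.2f} %\n"
        f"   LINEs:               60       {bp(retro) // 2} bp    {retro / 2:.2f} %\n"
        f"   LTR elements:        60       {bp(retro) // 2} bp    {retro / 2:.2f} %\n"
        "\n"
        f"DNA transposons         80       {bp(dna)} bp    {dna:.2f} %\n"
        "\n"
        f"Unclassified:           50       {bp(uncl)} bp    {uncl:.2f} %\n"
        "\n"
        f"Total interspersed repeats:      {bp(retro + dna + uncl)} bp   "
        f"{retro + dna + uncl:.2f} %\n"
        "\n"
        "Small RNA:               0            0 bp    0.00 %\n"
        "Satellites:              0            0 bp    0.00 %\n"
        f"Simple repeats:        200       {bp(simple)} bp    {simple:.2f} %\n"
        f"Low complexity:         30       {bp(lowc)} bp    {lowc:.2f} %\n"
    )


def _fasta_text(assembly: str, rng: np.random.Generator) -> str:
    n_proteins = int(rng.integers(40, 120))
    lines = []
    for i in range(n_proteins):
        length = int(rng.integers(100, 700))
        residues = "".join(
            _AMINO_ACIDS[j] for j in rng.integers(0, len(_AMINO_ACIDS), size=length)
        )
        if rng.random() < 0.5:
            residues += "*"
        lines.append(f">{assembly}_p{i + 1:05d}")
        lines.extend(residues[k: k + 60] for k in range(0, len(residues), 60))
    return "\n".join(lines) + "\n"


def generate_qc_fixtures(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """BUSCO short-summary, RepeatMasker ``.tbl`` and protein-FASTA texts per
    assembly; the written values equal the drawn values, so parsing
    round-trips exactly."""
    busco, tbl, fasta = {}, {}, {}
    for assembly in config.assembly_ids():
        busco[assembly] = _busco_text(assembly, rng)
        tbl[assembly] = _tbl_text(assembly, rng)
        fasta[assembly] = _fasta_text(assembly, rng)
    return busco, tbl, fasta


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate every component under independent seeded streams derived from
    ``config.seed``."""
    config = config or SyntheticConfig()
    rng_modules = np.random.default_rng([config.seed, 1])
    rng_ann = np.random.default_rng([config.seed, 2])
    rng_dup = np.random.default_rng([config.seed, 3])
    rng_qc = np.random.default_rng([config.seed, 4])

    modules = generate_modules(config, rng_modules)
    annotations, groups = generate_annotations(modules, config, rng_ann)
    newick, duplications, gene_categories, category_names, enriched = (
        generate_duplications(config, rng_dup)
    )
    busco, tbl, fasta = generate_qc_fixtures(config, rng_qc)
    return SyntheticDataset(
        config=config,
        modules=modules,
        annotations=annotations,
        group_assignment=groups,
        source_assignment=config.source_assignment(),
        tree_newick=newick,
        duplications=duplications,
        gene_categories=gene_categories,
        category_names=category_names,
        enriched_category=enriched,
        busco_texts=busco,
        repeat_texts=tbl,
        fasta_texts=fasta,
    )


def write_fixture_dir(dataset: SyntheticDataset, path: str | Path) -> None:
    """Emit a complete fixture directory.

    Layout: ``modules.tsv``, ``annotations/<assembly>.tsv``, ``metadata.tsv``,
    ``Duplications.tsv``, ``tree.nwk``, ``gene_annotations.tsv``,
    ``busco/<assembly>.txt``, ``repeats/<assembly>.tbl``,
    ``proteins/<assembly>.faa`` and ``config.json`` as the reproducibility
    record.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    write_module_table(dataset.modules, root / "modules.tsv")
    (root / "annotations").mkdir(exist_ok=True)
    for ann in dataset.annotations:
        with open(root / "annotations" / f"{ann.assembly_id}.tsv", "w") as handle:
            handle.write("gene_id\tko\n")
            for gene in sorted(ann.gene_to_ko or {}):
                for ko in ann.gene_to_ko[gene]:
                    handle.write(f"{gene}\t{ko}\n")
    dataset.metadata.to_csv(root / "metadata.tsv", sep="\t")
    write_duplications(dataset.duplications, root / "Duplications.tsv")
    (root / "tree.nwk").write_text(dataset.tree_newick + "\n")
    with open(root / "gene_annotations.tsv", "w") as handle:
        handle.write("gene_id\tnamespace\tcategory_id\tcategory_name\n")
        for gene in sorted(dataset.gene_categories):
            for cat in dataset.gene_categories[gene]:
                ns = "GO" if cat.startswith("GO:") else "InterPro"
                handle.write(
                    f"{gene}\t{ns}\t{cat}\t{dataset.category_names.get(cat, '')}\n"
                )
    for sub, texts, suffix in (
        ("busco", dataset.busco_texts, ".txt"),
        ("repeats", dataset.repeat_texts, ".tbl"),
        ("proteins", dataset.fasta_texts, ".faa"),
    ):
        (root / sub).mkdir(exist_ok=True)
        for assembly, text in texts.items():
            (root / sub / f"{assembly}{suffix}").write_text(text)
    config_dict = dataclasses.asdict(dataset.config)
    (root / "config.json").write_text(json.dumps(config_dict, indent=2) + "\n")
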