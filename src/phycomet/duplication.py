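"""Gene-duplication events on a species tree, integrated with functional
annotation.

Duplication events are consumed from an OrthoFinder-style ``Duplications.tsv``
(one event per row, with the species-tree node it maps to, a support value in
[0, 1] — the fraction of descendant species retaining both copies — and the
two descendant gene lists).  Events are filtered at a support threshold
(default 0.5, inclusive: "at least 50% support"), totalled per node, and the
duplicated genes of each node are cross-tabulated with their functional
categories (InterPro entries or GO terms).

Two framings coexist deliberately: node *totals* count events, while category
integration counts distinct duplicated genes (a gene appearing in several
events of one node counts once; a gene with several categories counts once
per category).  No ontology traversal is performed — GO ancestors are not
propagated; categories are opaque namespaced identifiers.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from phycomet.compare import StatTestResult, stat_tests

__all__ = [
    "DuplicationRecord",
    "NodeDuplicationSummary",
    "read_duplications",
    "write_duplications",
    "read_species_tree",
    "filter_support",
    "node_totals",
    "integrate_annotations",
    "compare_node_groups",
    "read_gene_categories",
    "write_node_summaries",
    "write_itol_piechart",
]

_DUPLICATIONS_COLUMNS = (
    "Orthogroup",
    "Species Tree Node",
    "Gene Tree Node",
    "Support",
    "Type",
    "Genes 1",
    "Genes 2",
)


@dataclass(frozen=True)
class DuplicationRecord:
    orthogroup: str
    species_tree_node: str
    gene_tree_node: str
    support: float
    type: str
    genes_1: tuple[str, ...]
    genes_2: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(
                f"{self.orthogroup}: support {self.support} outside [0, 1]"
            )
        if not self.genes_1 or not self.genes_2:
            raise ValueError(f"{self.orthogroup}: empty descendant gene list")

    @property
    def genes(self) -> frozenset[str]:
        """Union of both descendant gene lists."""
        return frozenset(self.genes_1) | frozenset(self.genes_2)


@dataclass(frozen=True)
class NodeDuplicationSummary:
    node: str
    total_events: int
    distinct_genes: int
    category_counts: Mapping[str, int]
    unannotated_genes: int

    @property
    def category_proportions(self) -> dict[str, float]:
        total = sum(self.category_counts.values())
        if total == 0:
            return {}
        return {c: n / total for c, n in self.category_counts.items()}

    @property
    def log10_radius(self) -> float:
        """Display radius proportional to log10 of the event total."""
        return math.log10(self.total_events) if self.total_events > 0 else 0.0


def _split_genes(cell: str) -> tuple[str, ...]:
    return tuple(g.strip() for g in cell.split(",") if g.strip())


def read_duplications(path: str | Path) -> list[DuplicationRecord]:
    """Read an OrthoFinder-dialect ``Duplications.tsv``.

    Header columns: Orthogroup, Species Tree Node, Gene Tree Node, Support,
    Type, Genes 1, Genes 2; gene lists are comma-separated.  A missing column
    raises a format error naming it; an empty file returns an empty list with
    a warning.
    """
    records: list[DuplicationRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty duplications file", stacklevel=2)
            return []
        missing = [c for c in _DUPLICATIONS_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                support = float(row["Support"])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed support value {row['Support']!r}"
                ) from None
            records.append(
                DuplicationRecord(
                    orthogroup=row["Orthogroup"],
                    species_tree_node=row["Species Tree Node"],
                    gene_tree_node=row["Gene Tree Node"],
                    support=support,
                    type=row["Type"],
                    genes_1=_split_genes(row["Genes 1"]),
                    genes_2=_split_genes(row["Genes 2"]),
                )
            )
    if not records:
        warnings.warn(f"{path}: no duplication records", stacklevel=2)
    return records


def write_duplications(records: Iterable[DuplicationRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_DUPLICATIONS_COLUMNS) + "\n")
        for r in records:
            handle.write(
                "\t".join(
                    (
                        r.orthogroup,
                        r.species_tree_node,
                        r.gene_tree_node,
                        f"{r.support:g}",
                        r.type,
                        ", ".join(r.genes_1),
                        ", ".join(r.genes_2),
                    )
                )
                + "\n"
            )


def read_species_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick species tree with labelled internal nodes; labels
    (internal and leaf) must be unique."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    labels = _tree_labels(tree)
    seen: set[str] = set()
    dupes: set[str] = set()
    for label in labels:
        if label in seen:
            dupes.add(label)
        seen.add(label)
    if dupes:
        raise ValueError(f"duplicate node labels in tree: {', '.join(sorted(dupes))}")
    return tree


def _tree_labels(tree: dendropy.Tree) -> list[str]:
    labels = []
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            labels.append(node.taxon.label)
        elif node.label:
            labels.append(node.label)
    return labels


def filter_support(
    records: Sequence[DuplicationRecord], min_support: float = 0.5
) -> list[DuplicationRecord]:
    """Keep events with support >= ``min_support`` (inclusive boundary)."""
    if not 0.0 <= min_support <= 1.0:
        raise ValueError(f"min_support must be in [0, 1], got {min_support}")
    return [r for r in records if r.support >= min_support]


def node_totals(
    records: Sequence[DuplicationRecord], tree: dendropy.Tree | None = None
) -> dict[str, int]:
    """Event count per species-tree node.

    When a tree is supplied, every tree node appears in the result (zero when
    no events map to it) and records pointing at unknown labels raise an
    error listing the offenders.
    """
    totals: dict[str, int] = {}
    if tree is not None:
        totals = {label: 0 for label in _tree_labels(tree)}
        unknown = sorted(
            {r.species_tree_node for r in records if r.species_tree_node not in totals}
        )
        if unknown:
            raise ValueError(
                f"duplication records reference unknown tree nodes: {', '.join(unknown)}"
            )
    for r in records:
        totals[r.species_tree_node] = totals.get(r.species_tree_node, 0) + 1
    return totals


def integrate_annotations(
    records: Sequence[DuplicationRecord],
    gene_categories: Mapping[str, Sequence[str]],
) -> list[NodeDuplicationSummary]:
    """Per-node functional summary of duplicated genes.

    The duplicated gene set of a node is the union of both descendant gene
    lists over all of its events.  Each distinct gene adds one count to each
    of its categories; genes missing from the map are tallied as unannotated.
    Output is sorted by node label and independent of record order.
    """
    node_genes: dict[str, set[str]] = {}
    node_events: dict[str, int] = {}
    for r in records:
        node_genes.setdefault(r.species_tree_node, set()).update(r.genes)
        node_events[r.species_tree_node] = node_events.get(r.species_tree_node, 0) + 1
    summaries = []
    for node in sorted(node_genes):
        counts: dict[str, int] = {}
        unannotated = 0
        for gene in node_genes[node]:
            categories = gene_categories.get(gene)
            if not categories:
                unannotated += 1
                continue
            for cat in set(categories):
                counts[cat] = counts.get(cat, 0) + 1
        summaries.append(
            NodeDuplicationSummary(
                node=node,
                total_events=node_events[node],
                distinct_genes=len(node_genes[node]),
                category_counts=dict(sorted(counts.items())),
                unannotated_genes=unannotated,
            )
        )
    return summaries


def compare_node_groups(
    totals: Mapping[str, int], groups: Mapping[str, str]
) -> StatTestResult:
    """Welch t test comparing per-node duplication totals between two groups
    of terminal nodes (each group needs at least two nodes)."""
    nodes = [n for n in sorted(totals) if n in groups]
    values = [float(totals[n]) for n in nodes]
    labels = [groups[n] for n in nodes]
    return stat_tests(values, labels)["welch_t"]


def read_gene_categories(
    path: str | Path, namespace: str | None = None
) -> dict[str, tuple[str, ...]]:
    """Read a gene-annotation TSV:
    ``gene_id<TAB>namespace<TAB>category_id<TAB>category_name``.

    Returns gene -> category ids; pass ``namespace`` (e.g. ``"InterPro"`` or
    ``"GO"``) to restrict to one annotation universe.
    """
    mapping: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            gene, ns, category_id, _name = fields
            if namespace is not None and ns != namespace:
                continue
            mapping.setdefault(gene, []).append(category_id)
    return {g: tuple(cats) for g, cats in mapping.items()}


def write_node_summaries(
    summaries: Sequence[NodeDuplicationSummary], path: str | Path
) -> None:
    """Long-format TSV: one row per node x category, plus per-node totals."""
    with open(path, "w") as handle:
        handle.write(
            "node\ttotal_events\tdistinct_genes\tunannotated_genes\tcategory\tgene_count\n"
        )
        for s in sorted(summaries, key=lambda s: s.node):
            base = f"{s.node}\t{s.total_events}\t{s.distinct_genes}\t{s.unannotated_genes}"
            if not s.category_counts:
                handle.write(base + "\t\t0\n")
                continue
            for cat in sorted(s.category_counts):
                handle.write(base + f"\t{cat}\t{s.category_counts[cat]}\n")


def write_itol_piechart(
    summaries: Sequence[NodeDuplicationSummary],
    path: str | Path,
    top_k: int | None = None,
) -> None:
    """iTOL DATASET_PIECHART annotation text for per-node category counts.

    Pie radii scale with log10 of the node's event total.  ``top_k`` keeps
    only the k most abundant categories per node (ties broken alphabetically);
    by default all categories are exported.
    """
    all_categories: list[str] = sorted(
        {c for s in summaries for c in _top_categories(s, top_k)}
    )
    with open(path, "w") as handle:
        handle.write("DATASET_PIECHART\nSEPARATOR TAB\n")
        handle.write("DATASET_LABEL\tduplicated gene categories\n")
        handle.write("COLOR\t#1f78b4\n")
        handle.write("FIELD_LABELS\t" + "\t".join(all_categories) + "\n")
        handle.write(
            "FIELD_COLORS\t"
            + "\t".join(_itol_color(i) for i in range(len(all_categories)))
            + "\n"
        )
        handle.write("DATA\n")
        for s in sorted(summaries, key=lambda s: s.node):
            kept = _top_categories(s, top_k)
            values = [str(s.category_counts.get(c, 0) if c in kept else 0)
                      for c in all_categories]
            radius = f"{max(s.log10_radius, 0.1) * 10:.2f}"
            handle.write(f"{s.node}\t0.5\t{radius}\t" + "\t".join(values) + "\n")


def _top_categories(s: NodeDuplicationSummary, top_k: int | None) -> set[str]:
    if top_k is None:
        return set(s.category_counts)
    ranked = sorted(s.category_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {c for c, _ in ranked[:top_k]}


def _itol_color(i: int) -> str:
    palette = (
        "#1f78b4", "#33a02c", "#e31a1c", "#ff7f00", "#6a3d9a",
        "#b15928", "#a6cee3", "#b2df8a", "#fb9a99", "#fdbf6f",
    )
    return palette[i % len(palette)]
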