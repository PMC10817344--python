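"""Module-completeness grading from per-assembly KO annotation sets.

Each module is graded on a five-point scale per assembly:

====== ============ ==============================================
grade  category     meaning
====== ============ ==============================================
1      COMPLETE     every block satisfied
2      MISSING_1    one block missing
3      MISSING_2    two blocks missing
4      INCOMPLETE   at least one block present, more than two missing
5      ABSENT       no KO of the module present in the assembly
====== ============ ==============================================

A block is satisfied only when some alternative of its boolean expression is
fully present — for a complex every required subunit must be there.  When a
multi-KO block is *partially* present, the module is additionally graded on
KO "steps" (each required KO of the chosen alternative counting as one step,
equivalent to a block) and the better of the two gradings is kept.  This step
re-grading can never promote a module with a missing step to COMPLETE.

Two completeness standards are exposed: *strict* (grade 1) and *loose*
(grade 1 or 2, i.e. at most one block missing).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phycomet.module_model import (
    And,
    Atom,
    Expr,
    ModuleDefinition,
    Or,
    _validate_ko,
    ko_universe,
)

__all__ = [
    "Category",
    "AnnotationSet",
    "CompletenessResult",
    "GradeMatrix",
    "satisfied",
    "step_credit",
    "grade_module",
    "grade_matrix",
    "read_ko_annotations",
    "write_grade_matrix",
]

#: Combinatorial guard for step-credit enumeration.
MAX_BLOCK_ATOMS = 64


class Category(enum.IntEnum):
    """Completeness category; the integer value is the 1–5 grade."""

    COMPLETE = 1
    MISSING_1 = 2
    MISSING_2 = 3
    INCOMPLETE = 4
    ABSENT = 5


@dataclass(frozen=True)
class AnnotationSet:
    """The KO content of one assembly, optionally with the gene-level map."""

    assembly_id: str
    kos: frozenset[str]
    gene_to_ko: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        kos = frozenset(_validate_ko(k) for k in self.kos)
        object.__setattr__(self, "kos", kos)
        if self.gene_to_ko is not None:
            mapped = frozenset(k for v in self.gene_to_ko.values() for k in v)
            if mapped != kos:
                raise ValueError(
                    f"{self.assembly_id}: gene_to_ko values disagree with the KO set"
                )

    @classmethod
    def from_genes(
        cls, assembly_id: str, gene_to_ko: Mapping[str, Sequence[str]]
    ) -> "AnnotationSet":
        mapping = {g: tuple(_validate_ko(k) for k in ks) for g, ks in gene_to_ko.items()}
        kos = frozenset(k for ks in mapping.values() for k in ks)
        return cls(assembly_id=assembly_id, kos=kos, gene_to_ko=mapping)


@dataclass(frozen=True)
class CompletenessResult:
    module_id: str
    assembly_id: str
    blocks_total: int
    blocks_present: int
    steps_total: int
    steps_present: int
    category: Category
    step_graded: bool = False

    @property
    def grade(self) -> int:
        return int(self.category)

    @property
    def strictly_complete(self) -> bool:
        return self.category == Category.COMPLETE

    @property
    def loosely_complete(self) -> bool:
        return self.category <= Category.MISSING_1


def satisfied(expr: Expr, kos: frozenset[str] | set[str]) -> bool:
    """Boolean satisfaction of a block expression by a KO set.

    Optional subunits are always treated as present; every required subunit
    of a complex must be present for the complex to count.
    """
    if isinstance(expr, Atom):
        return expr.optional or expr.ko in kos
    if isinstance(expr, And):
        return all(satisfied(c, kos) for c in expr.children)
    return any(satisfied(c, kos) for c in expr.children)


def _count_atoms(expr: Expr) -> int:
    if isinstance(expr, Atom):
        return 1
    return sum(_count_atoms(c) for c in expr.children)


def _choices(expr: Expr) -> list[frozenset[str]]:
    """All KO sets that satisfy the expression, one per OR-resolution.

    Optional atoms contribute no requirement.  Supersets of other choices are
    pruned afterwards so only minimal satisfying sets remain.
    """
    if isinstance(expr, Atom):
        return [frozenset()] if expr.optional else [frozenset({expr.ko})]
    if isinstance(expr, Or):
        seen: list[frozenset[str]] = []
        for child in expr.children:
            for choice in _choices(child):
                if choice not in seen:
                    seen.append(choice)
        return seen
    combined: list[frozenset[str]] = [frozenset()]
    for child in expr.children:
        combined = [
            base | extra for base in combined for extra in _choices(child)
        ]
    out: list[frozenset[str]] = []
    for choice in combined:
        if choice not in out:
            out.append(choice)
    return out


def _minimal(choices: list[frozenset[str]]) -> list[frozenset[str]]:
    return [c for c in choices if not any(o < c for o in choices)]


def step_credit(block: Expr, kos: frozenset[str] | set[str]) -> tuple[int, int]:
    """KO-step credit for a block: ``(steps_present, steps_total)``.

    Among the minimal satisfying KO sets of the block, the one maximising the
    fraction of KOs present is chosen; ties are broken by fewer total steps,
    then by the lexicographically smallest KO list.  A fully optional block
    yields ``(0, 0)``.
    """
    n_atoms = _count_atoms(block)
    if n_atoms > MAX_BLOCK_ATOMS:
        raise ValueError(
            f"block has {n_atoms} KO atoms; refusing step enumeration beyond "
            f"{MAX_BLOCK_ATOMS}"
        )
    kos = frozenset(kos)
    best: tuple[float, int, tuple[str, ...]] | None = None
    best_counts = (0, 0)
    for choice in _minimal(_choices(block)):
        total = len(choice)
        present = len(choice & kos)
        fraction = 1.0 if total == 0 else present / total
        key = (-fraction, total, tuple(sorted(choice)))
        if best is None or key < best:
            best = key
            best_counts = (present, total)
    return best_counts


def _categorize(present: int, total: int) -> Category:
    if present == 0:
        return Category.ABSENT
    missing = total - present
    if missing == 0:
        return Category.COMPLETE
    if missing == 1:
        return Category.MISSING_1
    if missing == 2:
        return Category.MISSING_2
    return Category.INCOMPLETE


def grade_module(module: ModuleDefinition, ann: AnnotationSet) -> CompletenessResult:
    """Grade one module against one assembly's KO set.

    The block-based category is computed first; if any block is partially
    satisfied through a multi-KO expression, a step-based category over the
    summed step credits is also computed and the better (numerically lower)
    of the two is kept.  A module is ABSENT only when the assembly carries
    none of the module's required KOs.
    """
    if module.blocks_total == 0:
        raise ValueError(f"{module.module_id}: module has no blocks")
    kos = ann.kos
    blocks_present = sum(1 for b in module.blocks if satisfied(b, kos))
    category = _categorize(blocks_present, module.blocks_total)

    steps_present = 0
    steps_total = 0
    partial_block = False
    for block in module.blocks:
        present, total = step_credit(block, kos)
        steps_present += present
        steps_total += total
        if 0 < present < total:
            partial_block = True

    step_graded = False
    if partial_block:
        step_category = _categorize(steps_present, steps_total)
        if step_category < category:
            category = step_category
            step_graded = True

    return CompletenessResult(
        module_id=module.module_id,
        assembly_id=ann.assembly_id,
        blocks_total=module.blocks_total,
        blocks_present=blocks_present,
        steps_total=steps_total,
        steps_present=steps_present,
        category=category,
        step_graded=step_graded,
    )


@dataclass
class GradeMatrix:
    """All pairwise grading results plus tabular views."""

    results: dict[tuple[str, str], CompletenessResult]
    grades: pd.DataFrame  # assemblies x modules, integer grades
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for assembly_id in self.grades.index:
            res = [r for (a, _), r in self.results.items() if a == assembly_id]
            rows.append(
                {
                    "assembly_id": assembly_id,
                    "complete_strict": sum(r.strictly_complete for r in res),
                    "complete_loose": sum(r.loosely_complete for r in res),
                }
            )
        self.summary = pd.DataFrame(rows).set_index("assembly_id")


def grade_matrix(
    modules: Sequence[ModuleDefinition], annotations: Sequence[AnnotationSet]
) -> GradeMatrix:
    """Grade every module against every assembly.

    Returns the full result map together with an assemblies x modules integer
    grade table and per-assembly counts of strictly and loosely complete
    modules.  Duplicate assembly ids are rejected.
    """
    assembly_ids = [a.assembly_id for a in annotations]
    if len(set(assembly_ids)) != len(assembly_ids):
        dupes = sorted({a for a in assembly_ids if assembly_ids.count(a) > 1})
        raise ValueError(f"duplicate assembly ids: {', '.join(dupes)}")
    module_ids = [m.module_id for m in modules]
    results: dict[tuple[str, str], CompletenessResult] = {}
    table = []
    for ann in annotations:
        row = []
        for module in modules:
            res = grade_module(module, ann)
            results[(ann.assembly_id, module.module_id)] = res
            row.append(res.grade)
        table.append(row)
    grades = pd.DataFrame(table, index=assembly_ids, columns=module_ids, dtype=int)
    grades.index.name = "assembly_id"
    return GradeMatrix(results=results, grades=grades)


def read_ko_annotations(path: str | Path, assembly_id: str | None = None) -> AnnotationSet:
    """Read a KO annotation TSV (``gene_id<TAB>KO``, one row per gene–KO link).

    Multiple KOs per gene are expressed as multiple rows.  A header line
    starting with ``gene_id`` is tolerated.  The assembly id defaults to the
    file stem.
    """
    path = Path(path)
    if assembly_id is None:
        assembly_id = path.stem
    gene_to_ko: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            gene, ko = fields
            if lineno == 1 and gene == "gene_id":
                continue
            gene_to_ko.setdefault(gene, []).append(_validate_ko(ko))
    return AnnotationSet.from_genes(assembly_id, gene_to_ko)


def write_grade_matrix(matrix: GradeMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write the assemblies x modules integer grade table as TSV."""
    grades = matrix.grades if isinstance(matrix, GradeMatrix) else matrix
    grades.to_csv(path, sep="\t")
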