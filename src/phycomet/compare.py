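"""Cross-group comparison of module completion and presence/absence patterns.

Assemblies are grouped by taxonomic class or order (or by transcriptome
source), per-group completion rates are computed per module, and modules
whose rates vary strongly across groups (population standard deviation at or
above a threshold, 0.2 by default) are selected for inspection.  Core module
sets per group — modules loosely complete in at least half of a group's
assemblies — are intersected Venn-style.  Binary presence/absence of a KO or
block is associated with a binary group indicator through the phi
coefficient, the Pearson correlation of two 0/1 vectors, so that perfect
concordance prints as +1.00 and perfect anti-concordance as -1.00.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phycomet.completeness import AnnotationSet, CompletenessResult, GradeMatrix, satisfied
from phycomet.module_model import ModuleDefinition

__all__ = [
    "GroupCompletionProfile",
    "CorrelationResult",
    "StatTestResult",
    "completion_rate",
    "group_completion_profiles",
    "variable_modules",
    "core_module_sets",
    "presence_group_correlation",
    "block_presence_matrix",
    "stat_tests",
    "write_profiles",
    "write_variable_modules",
    "write_venn_regions",
    "write_correlations",
]


@dataclass(frozen=True)
class GroupCompletionProfile:
    """Per-group completion rates for one module and their cross-group spread."""

    module_id: str
    rates: Mapping[str, float]  # group label -> completion rate in [0, 1]
    sd: float  # population SD (n denominator) across group rates
    variable: bool  # sd >= selection threshold


@dataclass(frozen=True)
class CorrelationResult:
    """Phi association between a binary feature and a binary group indicator.

    ``phi`` is None (and ``undefined`` True) when either vector is constant,
    i.e. a margin of the 2x2 table is zero.
    """

    feature_id: str
    grouping: str
    phi: float | None
    undefined: bool = False


@dataclass(frozen=True)
class StatTestResult:
    statistic: float | None
    pvalue: float | None
    df: float | None = None
    error: str | None = None


def completion_rate(
    results: Iterable[CompletenessResult], loose: bool = True
) -> float:
    """Fraction of assemblies in which the module is complete.

    ``loose=True`` counts modules with at most one block missing (grade <= 2);
    ``loose=False`` counts only fully complete modules (grade 1).
    """
    results = list(results)
    if not results:
        raise ValueError("completion rate of an empty group is undefined")
    if loose:
        return sum(r.loosely_complete for r in results) / len(results)
    return sum(r.strictly_complete for r in results) / len(results)


def _group_members(
    matrix: GradeMatrix, groups: Mapping[str, str]
) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for assembly_id in matrix.grades.index:
        if assembly_id not in groups:
            raise ValueError(f"assembly {assembly_id!r} has no group assignment")
        members.setdefault(groups[assembly_id], []).append(assembly_id)
    return members


def group_completion_profiles(
    matrix: GradeMatrix,
    groups: Mapping[str, str],
    loose: bool = True,
    sd_threshold: float = 0.2,
) -> list[GroupCompletionProfile]:
    """Per-module, per-group completion rates with cross-group population SD.

    Only modules that are loosely complete in at least one assembly overall
    are eligible; others carry no completion signal and are dropped.  The SD
    uses the n denominator (standard deviation of the population of group
    rates).  Requires at least two groups.
    """
    members = _group_members(matrix, groups)
    if len(members) < 2:
        raise ValueError("at least two groups are required for a comparison")
    labels = sorted(members)
    profiles: list[GroupCompletionProfile] = []
    for module_id in matrix.grades.columns:
        module_results = [
            matrix.results[(a, module_id)] for a in matrix.grades.index
        ]
        if not any(r.loosely_complete for r in module_results):
            continue
        rates = {
            label: completion_rate(
                (matrix.results[(a, module_id)] for a in members[label]), loose=loose
            )
            for label in labels
        }
        sd = float(np.std(list(rates.values()), ddof=0))
        profiles.append(
            GroupCompletionProfile(
                module_id=module_id,
                rates=rates,
                sd=sd,
                variable=sd >= sd_threshold,
            )
        )
    return profiles


def variable_modules(
    profiles: Sequence[GroupCompletionProfile], sd_threshold: float = 0.2
) -> list[GroupCompletionProfile]:
    """Modules whose cross-group rate SD meets the threshold, most variable
    first (ties broken by module id)."""
    if not 0.0 <= sd_threshold <= 1.0:
        raise ValueError(f"sd_threshold must be in [0, 1], got {sd_threshold}")
    selected = [p for p in profiles if p.sd >= sd_threshold]
    return sorted(selected, key=lambda p: (-p.sd, p.module_id))


def core_module_sets(
    matrix: GradeMatrix,
    groups: Mapping[str, str],
    prevalence: float = 0.5,
) -> tuple[dict[str, set[str]], dict[tuple[str, ...], int]]:
    """Per-group core module sets and their Venn-region cardinalities.

    A module belongs to a group's core set when it is loosely complete in at
    least ``prevalence`` of that group's assemblies (inclusive boundary).
    The second return value maps each non-empty combination of group labels
    (sorted tuple) to the number of modules found in exactly those groups.
    """
    if not 0.0 < prevalence <= 1.0:
        raise ValueError(f"prevalence must be in (0, 1], got {prevalence}")
    members = _group_members(matrix, groups)
    core: dict[str, set[str]] = {}
    for label, assemblies in members.items():
        modules = set()
        for module_id in matrix.grades.columns:
            n_loose = sum(
                matrix.results[(a, module_id)].loosely_complete for a in assemblies
            )
            if n_loose >= prevalence * len(assemblies):
                modules.add(module_id)
        core[label] = modules
    labels = sorted(core)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            inside = set.intersection(*(core[l] for l in combo))
            outside = set().union(*(core[l] for l in labels if l not in combo))
            regions[combo] = len(inside - outside)
    return core, regions


def presence_group_correlation(
    presence: Sequence[int],
    indicator: Sequence[int],
    feature_id: str = "",
    grouping: str = "",
) -> CorrelationResult:
    """Phi coefficient between a binary presence vector and a binary group
    indicator.

    Computed from the 2x2 contingency closed form
    ``(n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)``, which equals the
    Pearson correlation of the raw 0/1 vectors.  +1 means the feature is
    present in exactly the indicated group, -1 the complementary pattern.
    Returns an undefined-flagged result when either vector is constant.
    """
    x = np.asarray(presence, dtype=int)
    y = np.asarray(indicator, dtype=int)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} presence vs {y.shape[0]} indicator")
    if x.size < 2:
        raise ValueError("at least two assemblies are required")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("presence and indicator vectors must be binary 0/1")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    row1, row0 = n11 + n10, n01 + n00
    col1, col0 = n11 + n01, n10 + n00
    denom = math.sqrt(row1 * row0 * col1 * col0)  # exact integer product
    if denom == 0.0:
        return CorrelationResult(feature_id, grouping, phi=None, undefined=True)
    phi = (n11 * n00 - n10 * n01) / denom
    return CorrelationResult(feature_id, grouping, phi=float(phi))


def block_presence_matrix(
    modules: Sequence[ModuleDefinition], annotations: Sequence[AnnotationSet]
) -> pd.DataFrame:
    """Binary assemblies x blocks table; feature ids are
    ``module_id.block_index`` with 1-based indices in definition order."""
    columns = [
        f"{m.module_id}.{i}" for m in modules for i in range(1, m.blocks_total + 1)
    ]
    rows = []
    for ann in annotations:
        row = []
        for module in modules:
            for block in module.blocks:
                row.append(int(satisfied(block, ann.kos)))
        rows.append(row)
    frame = pd.DataFrame(
        rows, index=[a.assembly_id for a in annotations], columns=columns, dtype=int
    )
    frame.index.name = "assembly_id"
    return frame


# ---------------------------------------------------------------------------
# Classical tests (Welch t, one-way ANOVA, Levene)
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> StatTestResult:
    n1, n2 = len(a), len(b)
    v1 = float(np.var(a, ddof=1))
    v2 = float(np.var(b, ddof=1))
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if float(np.mean(a)) == float(np.mean(b)):
            return StatTestResult(statistic=0.0, pvalue=1.0, df=float(n1 + n2 - 2))
        return StatTestResult(
            None, None, error="zero within-group variance with unequal means"
        )
    t = (float(np.mean(a)) - float(np.mean(b))) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatTestResult(statistic=t, pvalue=float(p), df=float(df))


def _anova(groups: list[np.ndarray]) -> StatTestResult:
    all_values = np.concatenate(groups)
    grand = float(np.mean(all_values))
    ss_between = sum(len(g) * (float(np.mean(g)) - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - np.mean(g)) ** 2)) for g in groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return StatTestResult(statistic=0.0, pvalue=1.0)
        return StatTestResult(
            None, None, error="zero within-group sum of squares; F is unbounded"
        )
    f, p = stats.f_oneway(*groups)
    df = float(len(all_values) - len(groups))
    return StatTestResult(statistic=float(f), pvalue=float(p), df=df)


def _levene(groups: list[np.ndarray], center: str = "mean") -> StatTestResult:
    # classic Levene centres on the group mean; "median" gives Brown-Forsythe
    centred = [np.abs(g - np.mean(g)) for g in groups]
    if all(float(np.var(z, ddof=0)) == 0.0 for z in centred) and len(
        {float(np.mean(z)) for z in centred}
    ) == 1:
        return StatTestResult(statistic=0.0, pvalue=1.0)
    try:
        w, p = stats.levene(*groups, center=center)
    except ValueError as exc:  # degenerate shapes
        return StatTestResult(None, None, error=str(exc))
    if not np.isfinite(w):
        return StatTestResult(None, None, error="Levene statistic is unbounded")
    return StatTestResult(statistic=float(w), pvalue=float(p))


def stat_tests(
    values: Sequence[float], groups: Sequence[str], levene_center: str = "mean"
) -> dict[str, StatTestResult]:
    """Welch t (two groups), one-way ANOVA F, and Levene W.

    ``values`` and ``groups`` are parallel sequences.  Every group must hold
    at least two values for the variance-based statistics; the Welch t is
    reported only for exactly two groups.  ``levene_center`` switches between
    classic Levene (``"mean"``, default) and Brown-Forsythe (``"median"``).
    """
    if len(values) != len(groups):
        raise ValueError("values and groups must have the same length")
    by_group: dict[str, list[float]] = {}
    for v, g in zip(values, groups):
        by_group.setdefault(g, []).append(float(v))
    if len(by_group) < 2:
        raise ValueError("at least two groups are required")
    arrays = {g: np.asarray(vs, dtype=float) for g, vs in sorted(by_group.items())}
    if any(len(a) < 2 for a in arrays.values()):
        small = sorted(g for g, a in arrays.items() if len(a) < 2)
        raise ValueError(f"groups with fewer than two values: {', '.join(small)}")
    ordered = list(arrays.values())
    out: dict[str, StatTestResult] = {}
    if len(ordered) == 2:
        out["welch_t"] = _welch_t(ordered[0], ordered[1])
    else:
        out["welch_t"] = StatTestResult(
            None, None, error="Welch t requires exactly two groups"
        )
    out["one_way_anova_F"] = _anova(ordered)
    out["levene_W"] = _levene(ordered, center=levene_center)
    return out


# ---------------------------------------------------------------------------
# Deterministic TSV exports
# ---------------------------------------------------------------------------

def write_profiles(
    profiles: Sequence[GroupCompletionProfile], path: str | Path
) -> None:
    """Long-format TSV: ``module_id, group, rate`` in sorted order."""
    with open(path, "w") as handle:
        handle.write("module_id\tgroup\trate\n")
        for p in sorted(profiles, key=lambda p: p.module_id):
            for group in sorted(p.rates):
                handle.write(f"{p.module_id}\t{group}\t{p.rates[group]:.6g}\n")


def write_variable_modules(
    profiles: Sequence[GroupCompletionProfile], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("module_id\tsd\tvariable\n")
        for p in sorted(profiles, key=lambda p: (-p.sd, p.module_id)):
            handle.write(f"{p.module_id}\t{p.sd:.6g}\t{int(p.variable)}\n")


def write_venn_regions(
    regions: Mapping[tuple[str, ...], int], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("groups\tn_modules\n")
        for combo in sorted(regions, key=lambda c: (len(c), c)):
            handle.write("&".join(combo) + f"\t{regions[combo]}\n")


def write_correlations(
    correlations: Sequence[CorrelationResult], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("feature_id\tgrouping\tphi\tundefined\n")
        for c in sorted(correlations, key=lambda c: (c.feature_id, c.grouping)):
            phi = "" if c.phi is None else f"{c.phi:.6g}"
            handle.write(f"{c.feature_id}\t{c.grouping}\t{phi}\t{int(c.undefined)}\n")
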