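"""Assembly quality control: BUSCO summaries, RepeatMasker tables, protein
statistics, and the completeness gate used to admit assemblies into the
comparative analyses.

The gate admits an assembly when its BUSCO complete fraction is at least
``min_complete`` (default 35%) and its missing fraction is strictly below
``max_missing`` (default 50%); both thresholds are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "BuscoScore",
    "RepeatSummary",
    "ProteinStats",
    "parse_busco_summary",
    "qc_gate",
    "parse_repeatmasker_tbl",
    "protein_stats",
    "write_qc_table",
]

REPEAT_CATEGORIES = (
    "retroelements",
    "dna_transposons",
    "simple_repeats",
    "unclassified",
    "other",
)


@dataclass(frozen=True)
class BuscoScore:
    """Percentages from a BUSCO short summary (complete = single + duplicated)."""

    assembly_id: str
    complete_pct: float
    single_pct: float
    duplicated_pct: float
    fragmented_pct: float
    missing_pct: float
    n_markers: int

    def __post_init__(self) -> None:
        if abs(self.complete_pct - (self.single_pct + self.duplicated_pct)) > 0.1:
            raise ValueError(
                f"{self.assembly_id}: complete != single + duplicated beyond rounding"
            )
        total = self.complete_pct + self.fragmented_pct + self.missing_pct
        if abs(total - 100.0) > 0.2:
            raise ValueError(
                f"{self.assembly_id}: C+F+M = {total:.2f}, not ~100 within rounding"
            )


@dataclass(frozen=True)
class RepeatSummary:
    assembly_id: str
    total_masked_pct: float
    retroelements: float = 0.0
    dna_transposons: float = 0.0
    simple_repeats: float = 0.0
    unclassified: float = 0.0
    other: float = 0.0


@dataclass(frozen=True)
class ProteinStats:
    assembly_id: str
    protein_count: int
    mean_length_aa: float | None  # None for an empty proteome


_BUSCO_LINE = re.compile(
    r"C:(?P<c>\d+(?:\.\d+)?)%\[S:(?P<s>\d+(?:\.\d+)?)%,D:(?P<d>\d+(?:\.\d+)?)%\],"
    r"F:(?P<f>\d+(?:\.\d+)?)%,M:(?P<m>\d+(?:\.\d+)?)%,n:(?P<n>\d+)"
)


def parse_busco_summary(text: str, assembly_id: str = "") -> BuscoScore:
    """Parse a BUSCO ``short_summary`` text.

    Extracts the percentages from the standard summary line, e.g.
    ``C:62.2%[S:60.0%,D:2.2%],F:10.0%,M:27.8%,n:255``.
    """
    m = _BUSCO_LINE.search(text)
    if m is None:
        raise ValueError("no BUSCO summary line (C:..%[S:..,D:..],F:..,M:..,n:..) found")
    return BuscoScore(
        assembly_id=assembly_id,
        complete_pct=float(m.group("c")),
        single_pct=float(m.group("s")),
        duplicated_pct=float(m.group("d")),
        fragmented_pct=float(m.group("f")),
        missing_pct=float(m.group("m")),
        n_markers=int(m.group("n")),
    )


def qc_gate(
    score: BuscoScore, min_complete: float = 35.0, max_missing: float = 50.0
) -> bool:
    """Assembly-quality gate: complete >= ``min_complete`` and missing
    strictly < ``max_missing`` (both in percent)."""
    return score.complete_pct >= min_complete and score.missing_pct < max_missing


_PERCENT = re.compile(r"(\d+(?:\.\d+)?)\s*%")

_TBL_SECTIONS = {
    "Retroelements": "retroelements",
    "DNA transposons": "dna_transposons",
    "Simple repeats": "simple_repeats",
    "Unclassified": "unclassified",
    # everything else named in the .tbl footer pools into "other"
    "Small RNA": "other",
    "Satellites": "other",
    "Low complexity": "other",
    "Rolling-circles": "other",
}


def parse_repeatmasker_tbl(text: str, assembly_id: str = "") -> RepeatSummary:
    """Parse a RepeatMasker ``.tbl`` summary into collated repeat categories.

    Top-level section rows (Retroelements, DNA transposons, Simple repeats,
    Unclassified) are read directly; the remaining named categories pool into
    ``other``.  Indented subcategory rows (SINEs, LINEs, ...) are ignored.
    The ``bases masked`` line supplies the total and must be present.
    """
    values = {c: 0.0 for c in REPEAT_CATEGORIES}
    total: float | None = None
    for line in text.splitlines():
        if line.startswith("bases masked"):
            pm = _PERCENT.search(line)
            if pm is None:
                raise ValueError("bases masked line lacks a percentage")
            total = float(pm.group(1))
            continue
        if not line or line[0].isspace():
            continue
        for section, category in _TBL_SECTIONS.items():
            if line.startswith(section):
                pm = _PERCENT.search(line)
                if pm is not None:
                    values[category] += float(pm.group(1))
                break
    if total is None:
        raise ValueError("no 'bases masked' line found in .tbl text")
    return RepeatSummary(assembly_id=assembly_id, total_masked_pct=total, **values)


def protein_stats(path: str | Path, assembly_id: str | None = None) -> ProteinStats:
    """Protein count and mean length (aa) from a FASTA file.

    Stop characters (``*``) are stripped before lengths are taken; no length
    filtering is applied.  An empty file yields count 0 and an undefined mean
    (None).
    """
    path = Path(path)
    if assembly_id is None:
        assembly_id = path.stem
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: malformed FASTA, expected '>' header")
            break
    lengths = [
        len(str(rec.seq).replace("*", "")) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not lengths:
        return ProteinStats(assembly_id=assembly_id, protein_count=0, mean_length_aa=None)
    return ProteinStats(
        assembly_id=assembly_id,
        protein_count=len(lengths),
        mean_length_aa=sum(lengths) / len(lengths),
    )


def write_qc_table(
    scores: Sequence[BuscoScore],
    path: str | Path,
    repeats: Iterable[RepeatSummary] = (),
    proteins: Iterable[ProteinStats] = (),
    min_complete: float = 35.0,
    max_missing: float = 50.0,
) -> pd.DataFrame:
    """Per-assembly QC table (TSV): BUSCO metrics, gate verdict, and any
    available repeat and protein statistics."""
    rows = {
        s.assembly_id: {
            "assembly_id": s.assembly_id,
            "busco_complete_pct": s.complete_pct,
            "busco_single_pct": s.single_pct,
            "busco_duplicated_pct": s.duplicated_pct,
            "busco_fragmented_pct": s.fragmented_pct,
            "busco_missing_pct": s.missing_pct,
            "busco_n_markers": s.n_markers,
            "qc_pass": int(qc_gate(s, min_complete, max_missing)),
        }
        for s in scores
    }
    for r in repeats:
        row = rows.setdefault(r.assembly_id, {"assembly_id": r.assembly_id})
        row["repeat_total_masked_pct"] = r.total_masked_pct
        for c in REPEAT_CATEGORIES:
            row[f"repeat_{c}_pct"] = getattr(r, c)
    for p in proteins:
        row = rows.setdefault(p.assembly_id, {"assembly_id": p.assembly_id})
        row["protein_count"] = p.protein_count
        row["mean_protein_length_aa"] = p.mean_length_aa
    frame = pd.DataFrame([rows[a] for a in sorted(rows)]).set_index("assembly_id")
    frame.to_csv(path, sep="\t")
    return frame
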