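"""Independent brute-force oracles for the test suite.

These evaluate module-definition *strings* directly — satisfaction by
textual translation into a Python boolean expression, step credit by
exhaustive truth-table enumeration over atom subsets — so they share no code
path with the package's parser or grader.
"""

from __future__ import annotations

import itertools
import re

_KO = re.compile(r"K\d{5}")
_OPTIONAL_KO = re.compile(r"-K\d{5}")


def split_top_level(definition: str) -> list[str]:
    """Split a definition into top-level space-separated terms, dropping
    bare ``--`` skip terms."""
    terms: list[str] = []
    depth = 0
    current = ""
    for ch in definition:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == " " and depth == 0:
            if current:
                terms.append(current)
            current = ""
        else:
            current += ch
    if current:
        terms.append(current)
    return [t for t in terms if t != "--"]


def _to_python(expr: str, present: set[str]) -> str:
    out = expr.replace(" ", " and ")  # spaces (incl. inside parens) are AND
    out = _OPTIONAL_KO.sub("True", out)  # optional atoms never gate
    out = _KO.sub(lambda m: "True" if m.group(0) in present else "False", out)
    return out.replace(",", " or ").replace("+", " and ")


def block_satisfied(block: str, kos: set[str]) -> bool:
    """Truth-table satisfaction of one block string via Python eval."""
    return bool(eval(_to_python(block, set(kos))))  # noqa: S307 - test oracle


def block_atoms(block: str) -> list[str]:
    """Required (non-optional) KO atoms of a block, deduplicated, in order."""
    seen: list[str] = []
    for m in _KO.finditer(block):
        ko = m.group(0)
        if m.start() > 0 and block[m.start() - 1] == "-":
            continue  # optional subunit
        if ko not in seen:
            seen.append(ko)
    return seen


def step_credit_oracle(block: str, kos: set[str]) -> tuple[int, int]:
    """Brute-force step credit: enumerate every subset of the block's atoms,
    keep the minimal satisfying ones, then apply the documented tie-break
    (max fraction present, min size, lexicographically smallest)."""
    atoms = block_atoms(block)
    satisfying = [
        frozenset(s)
        for r in range(len(atoms) + 1)
        for s in itertools.combinations(atoms, r)
        if block_satisfied(block, set(s))
    ]
    minimal = [s for s in satisfying if not any(o < s for o in satisfying)]
    best_key = None
    best = (0, 0)
    for choice in minimal:
        total = len(choice)
        present = len(choice & set(kos))
        fraction = 1.0 if total == 0 else present / total
        key = (-fraction, total, tuple(sorted(choice)))
        if best_key is None or key < best_key:
            best_key = key
            best = (present, total)
    return best


def grade_oracle(definition: str, kos: set[str]) -> int:
    """Brute-force 1-5 grade of a whole definition string."""

    def categorize(present: int, total: int) -> int:
        if present == 0:
            return 5
        missing = total - present
        return {0: 1, 1: 2, 2: 3}.get(missing, 4)

    blocks = split_top_level(definition)
    blocks_present = sum(block_satisfied(b, kos) for b in blocks)
    grade = categorize(blocks_present, len(blocks))
    steps = [step_credit_oracle(b, kos) for b in blocks]
    if any(0 < p < t for p, t in steps):
        step_grade = categorize(sum(p for p, _ in steps), sum(t for _, t in steps))
        grade = min(grade, step_grade)
    return grade


def random_definition(rng, ko_pool: list[str], max_blocks: int = 6,
                      max_atoms_per_block: int = 6) -> str:
    """Random definition string over a small KO pool (depth <= 3 nesting)."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for _ in range(n_blocks):
        budget = int(rng.integers(1, max_atoms_per_block + 1))
        blocks.append(_random_block(rng, ko_pool, budget))
    return " ".join(blocks)


def _random_block(rng, pool, budget: int) -> str:
    n_alternatives = int(rng.integers(1, min(3, budget) + 1))
    sizes = _partition(rng, budget, n_alternatives)
    alternatives = []
    for size in sizes:
        if size == 1:
            alternatives.append(str(rng.choice(pool)))
        elif rng.random() < 0.3:
            # nested group with spaces: inner AND of two sub-expressions
            left = _partition(rng, size, 2)
            inner = " ".join(
                "+".join(str(rng.choice(pool)) for _ in range(k)) for k in left
            )
            alternatives.append(f"({inner})")
        else:
            alternatives.append("+".join(str(rng.choice(pool)) for _ in range(size)))
    return ",".join(alternatives)


def _partition(rng, total: int, parts: int) -> list[int]:
    sizes = [1] * parts
    for _ in range(total - parts):
        sizes[int(rng.integers(0, parts))] += 1
    return sizes
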