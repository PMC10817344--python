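"""Parsing and representation of KEGG-style metabolic module definitions.

A module definition is an ordered sequence of *blocks*, each block being one
enzymatic step of the pathway.  Definitions are written in a compact boolean
dialect over KO (KEGG Orthology) identifiers:

* top-level terms separated by spaces are consecutive blocks (all required);
* ``,`` separates alternative ways of completing a block (OR);
* ``+`` joins subunits of a complex, all of which are required (AND);
  ``+`` binds tighter than ``,``;
* a component prefixed with ``-`` is an optional subunit and is excluded from
  both satisfaction requirements and step counts;
* a bare ``--`` term denotes an undefined step and is skipped entirely
  (it is not counted as a block);
* parentheses group recursively; spaces inside parentheses form nested AND
  groups but do not split top-level blocks.

Real KEGG flat-file DEFINITION lines parse under this dialect, but the
dialect as documented here — not any external service's behaviour — is the
contract implemented and tested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = [
    "KO_PATTERN",
    "Atom",
    "And",
    "Or",
    "Expr",
    "ModuleDefinition",
    "ModuleParseError",
    "parse_definition",
    "ko_universe",
    "serialize",
    "read_module_table",
    "write_module_table",
    "read_kegg_flatfile",
]

#: Valid KO identifier: the letter K followed by exactly five digits.
KO_PATTERN = re.compile(r"^K\d{5}$")


class ModuleParseError(ValueError):
    """Raised when a module definition string cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


def _validate_ko(token: str, position: int | None = None) -> str:
    ko = token.upper()
    if not KO_PATTERN.match(ko):
        raise ModuleParseError(f"malformed KO identifier {token!r}", position)
    return ko


@dataclass(frozen=True)
class Atom:
    """A single KO leaf; ``optional`` subunits never gate satisfaction."""

    ko: str
    optional: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "ko", _validate_ko(self.ko))


@dataclass(frozen=True)
class And:
    """Conjunction: every child must be satisfied (complex or nested group)."""

    children: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND node requires at least two children")


@dataclass(frozen=True)
class Or:
    """Disjunction: any one child satisfies the block alternative."""

    children: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR node requires at least two children")


Expr = Union[Atom, And, Or]


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module: metadata plus an ordered list of block expressions."""

    module_id: str
    name: str = ""
    module_class: str = ""
    module_category: str = ""
    blocks: tuple[Expr, ...] = field(default=())

    @property
    def blocks_total(self) -> int:
        return len(self.blocks)

    @property
    def definition(self) -> str:
        return serialize(self)


# ---------------------------------------------------------------------------
# Tokenizer / recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"(\s+)|([(),+\-])|([A-Za-z0-9.:]+)")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Return (kind, value, position) triples.

    Kinds: ``SPACE``, ``PUNCT`` (one of ``(),+-``), ``WORD``.
    """
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ModuleParseError(f"unexpected character {text[pos]!r}", pos)
        if m.group(1):
            tokens.append(("SPACE", " ", pos))
        elif m.group(2):
            tokens.append(("PUNCT", m.group(2), pos))
        else:
            tokens.append(("WORD", m.group(3), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def at_punct(self, *values: str) -> bool:
        tok = self.peek()
        return tok is not None and tok[0] == "PUNCT" and tok[1] in values

    # sequence := element (SPACE element)*  — elements may be `--` skips
    def parse_sequence(self, closing: bool) -> list[Expr]:
        elements: list[Expr] = []
        while True:
            tok = self.peek()
            if tok is None:
                break
            if tok[0] == "SPACE":
                self.advance()
                continue
            if closing and self.at_punct(")"):
                break
            if self._try_skip_marker():
                continue
            elements.append(self.parse_or())
        return elements

    def _try_skip_marker(self) -> bool:
        """Consume a bare ``--`` term (an undefined step) if present."""
        if not self.at_punct("-"):
            return False
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
        if nxt is not None and nxt[0] == "PUNCT" and nxt[1] == "-":
            after = self.tokens[self.i + 2] if self.i + 2 < len(self.tokens) else None
            if after is None or after[0] == "SPACE" or (after[0] == "PUNCT" and after[1] == ")"):
                self.advance()
                self.advance()
                return True
        return False

    def parse_or(self) -> Expr:
        parts = [self.parse_complex()]
        while self.at_punct(","):
            self.advance()
            parts.append(self.parse_complex())
        if len(parts) == 1:
            return parts[0]
        return Or(tuple(_flatten(parts, Or)))

    def parse_complex(self) -> Expr:
        parts = [self.parse_component(optional=self._eat_optional_marker())]
        while self.at_punct("+", "-"):
            _, sep, _ = self.advance()
            optional = sep == "-" or self._eat_optional_marker()
            parts.append(self.parse_component(optional=optional))
        if len(parts) == 1:
            return parts[0]
        return And(tuple(_flatten(parts, And)))

    def _eat_optional_marker(self) -> bool:
        if self.at_punct("-"):
            self.advance()
            return True
        return False

    def parse_component(self, optional: bool) -> Expr:
        tok = self.peek()
        if tok is None:
            raise ModuleParseError("unexpected end of definition", len(self.text))
        kind, value, pos = tok
        if kind == "WORD":
            self.advance()
            return Atom(_validate_ko(value, pos), optional=optional)
        if kind == "PUNCT" and value == "(":
            self.advance()
            inner = self.parse_sequence(closing=True)
            closer = self.peek()
            if closer is None or closer[0] != "PUNCT" or closer[1] != ")":
                raise ModuleParseError("unbalanced parentheses: missing ')'", pos)
            self.advance()
            if not inner:
                raise ModuleParseError("empty parenthesized group", pos)
            expr = inner[0] if len(inner) == 1 else And(tuple(_flatten(inner, And)))
            return _mark_optional(expr) if optional else expr
        raise ModuleParseError(f"unexpected token {value!r}", pos)


def _flatten(parts: Iterable[Expr], kind: type) -> Iterator[Expr]:
    """Merge nested same-type nodes so the tree has a canonical shape."""
    for part in parts:
        if isinstance(part, kind):
            yield from part.children
        else:
            yield part


def _mark_optional(expr: Expr) -> Expr:
    if isinstance(expr, Atom):
        return replace(expr, optional=True)
    return type(expr)(tuple(_mark_optional(c) for c in expr.children))


def parse_definition(
    text: str,
    module_id: str = "",
    name: str = "",
    module_class: str = "",
    module_category: str = "",
) -> ModuleDefinition:
    """Parse a definition string into a :class:`ModuleDefinition`.

    Top-level space-separated terms become blocks; see the module docstring
    for the full dialect.  Raises :class:`ModuleParseError` on unbalanced
    parentheses, malformed KO tokens, or a definition with no blocks left
    after ``--`` skip terms are removed.
    """
    if not text or not text.strip():
        raise ModuleParseError("empty definition")
    parser = _Parser(_tokenize(text), text)
    blocks = parser.parse_sequence(closing=False)
    leftover = parser.peek()
    if leftover is not None:
        raise ModuleParseError(
            f"unbalanced parentheses: unexpected {leftover[1]!r}", leftover[2]
        )
    if not blocks:
        raise ModuleParseError("definition has no blocks after skip rules")
    return ModuleDefinition(
        module_id=module_id,
        name=name,
        module_class=module_class,
        module_category=module_category,
        blocks=tuple(blocks),
    )


# ---------------------------------------------------------------------------
# Queries and serialization
# ---------------------------------------------------------------------------

def _expr_kos(expr: Expr, include_optional: bool) -> Iterator[str]:
    if isinstance(expr, Atom):
        if include_optional or not expr.optional:
            yield expr.ko
    else:
        for child in expr.children:
            yield from _expr_kos(child, include_optional)


def ko_universe(module: ModuleDefinition, include_optional: bool = False) -> set[str]:
    """All KO ids referenced by the module's blocks (optional ones excluded
    by default, since they never gate completeness)."""
    kos: set[str] = set()
    for block in module.blocks:
        kos.update(_expr_kos(block, include_optional))
    return kos


def _serialize_expr(expr: Expr, parent: str) -> str:
    if isinstance(expr, Atom):
        return ("-" if expr.optional else "") + expr.ko
    if isinstance(expr, Or):
        inner = ",".join(_serialize_expr(c, "or") for c in expr.children)
        # OR binds looser than AND: parenthesize inside a complex
        return f"({inner})" if parent == "and" else inner
    inner = "+".join(_serialize_expr(c, "and") for c in expr.children)
    return inner


def serialize(module: ModuleDefinition) -> str:
    """Canonical definition string: blocks joined by spaces, complexes by
    ``+``, alternatives by ``,``; re-parsing yields a structurally identical
    module."""
    return " ".join(_serialize_expr(block, "top") for block in module.blocks)


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("module_id", "name", "module_class", "module_category", "definition")


def read_module_table(path: str | Path) -> list[ModuleDefinition]:
    """Read a tab-separated module table.

    One record per line: ``module_id<TAB>name<TAB>class<TAB>category<TAB>
    definition``.  A header line repeating the column names is tolerated.
    """
    modules: list[ModuleDefinition] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == _TABLE_COLUMNS[0]:
                continue
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            module_id, name, module_class, module_category, definition = fields
            modules.append(
                parse_definition(
                    definition,
                    module_id=module_id,
                    name=name,
                    module_class=module_class,
                    module_category=module_category,
                )
            )
    return modules


def write_module_table(modules: Iterable[ModuleDefinition], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_TABLE_COLUMNS) + "\n")
        for m in modules:
            handle.write(
                "\t".join(
                    (m.module_id, m.name, m.module_class, m.module_category, serialize(m))
                )
                + "\n"
            )


def read_kegg_flatfile(path: str | Path) -> list[ModuleDefinition]:
    """Read modules from KEGG flat-file style records.

    Recognises ``ENTRY`` (module id), ``NAME``, ``DEFINITION`` and ``CLASS``
    lines; records are separated by ``///``.  A CLASS line of the form
    ``Pathway modules; Lipid metabolism; Sterol biosynthesis`` maps its last
    two segments to module_class and module_category.
    """
    modules: list[ModuleDefinition] = []
    record: dict[str, str] = {}

    def flush() -> None:
        if not record:
            return
        if "ENTRY" not in record or "DEFINITION" not in record:
            raise ValueError("flat-file record missing ENTRY or DEFINITION line")
        class_parts = [p.strip() for p in record.get("CLASS", "").split(";") if p.strip()]
        module_class = class_parts[-2] if len(class_parts) >= 2 else (
            class_parts[0] if class_parts else ""
        )
        module_category = class_parts[-1] if len(class_parts) >= 2 else ""
        modules.append(
            parse_definition(
                record["DEFINITION"],
                module_id=record["ENTRY"].split()[0],
                name=record.get("NAME", ""),
                module_class=module_class,
                module_category=module_category,
            )
        )
        record.clear()

    with open(path) as handle:
        current_key: str | None = None
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("///"):
                flush()
                current_key = None
                continue
            if not line.strip():
                continue
            if line[0] not in (" ", "\t"):
                parts = line.split(None, 1)
                current_key = parts[0]
                record[current_key] = parts[1].strip() if len(parts) > 1 else ""
            elif current_key is not None:
                # continuation line: KEGG wraps long fields with indentation
                record[current_key] += " " + line.strip()
    flush()
    return modules
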