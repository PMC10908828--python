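"""Atom selection algebra.

A small deterministic selection language over chain id, author residue
number ranges (inclusive), residue name, and atom name, with boolean
combinators.  Evaluation on a structure always yields a sorted atom-index
array; it is order-independent and idempotent.

Grammar (case-insensitive keywords)::

    expr     := or_expr
    or_expr  := and_expr ('or' and_expr)*
    and_expr := unary ('and' unary)*
    unary    := 'not' unary | '(' expr ')' | primitive
    primitive:= 'chain' ID+ | 'resseq' RANGE+ | 'resname' ID+ | 'name' ID+
              | 'protein' | 'hetero' | 'all' | 'none'

where RANGE is ``5``, ``342-349`` or a comma list ``1-3,7``.  Example:
``"chain A and resseq 342-349"``.  Referencing an absent chain yields an
empty set with a warning (not an error) so pipeline configs stay portable.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np

from chapdyn.core_io import MolecularStructure

__all__ = ["Selection", "parse_selection", "apply_selection"]

_KEYWORDS = {
    "and", "or", "not", "(", ")",
    "chain", "resseq", "resname", "name", "protein", "hetero", "all", "none",
}


class Selection:
    """Predicate tree node; supports ``&``, ``|`` and ``~`` combinators."""

    def __init__(self, fn: Callable[[MolecularStructure], np.ndarray], label: str):
        self._fn = fn
        self.label = label

    def mask(self, structure: MolecularStructure) -> np.ndarray:
        m = self._fn(structure)
        return np.asarray(m, dtype=bool)

    def indices(self, structure: MolecularStructure) -> np.ndarray:
        """Sorted atom indices selected on ``structure``."""
        return np.nonzero(self.mask(structure))[0]

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(lambda s: self.mask(s) & other.mask(s), f"({self.label} and {other.label})")

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(lambda s: self.mask(s) | other.mask(s), f"({self.label} or {other.label})")

    def __invert__(self) -> "Selection":
        return Selection(lambda s: ~self.mask(s), f"(not {self.label})")

    def __repr__(self) -> str:
        return f"<Selection {self.label}>"


def _chain_sel(chains: Sequence[str]) -> Selection:
    chain_set = set(chains)

    def fn(s: MolecularStructure) -> np.ndarray:
        present = set(s.chains)
        missing = chain_set - present
        if missing:
            warnings.warn(
                f"selection references absent chain(s) {sorted(missing)}; "
                "matching atoms only among present chains",
                stacklevel=2,
            )
        return np.array([a.chain_id in chain_set for a in s.atoms])

    return Selection(fn, f"chain {' '.join(chains)}")


def _parse_ranges(tokens: Sequence[str]) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    for tok in tokens:
        for part in tok.split(","):
            if not part:
                continue
            if "-" in part[1:]:  # allow leading minus of negative start
                cut = part.index("-", 1)
                lo, hi = int(part[:cut]), int(part[cut + 1:])
            else:
                lo = hi = int(part)
            if hi < lo:
                raise ValueError(f"invalid residue range {part!r}")
            ranges.append((lo, hi))
    return ranges


def _resseq_sel(tokens: Sequence[str]) -> Selection:
    ranges = _parse_ranges(tokens)

    def fn(s: MolecularStructure) -> np.ndarray:
        return np.array([any(lo <= a.res_seq <= hi for lo, hi in ranges) for a in s.atoms])

    return Selection(fn, f"resseq {' '.join(tokens)}")


def _field_sel(field: str, values: Sequence[str]) -> Selection:
    vals = set(values)
    return Selection(
        lambda s: np.array([getattr(a, field) in vals for a in s.atoms]),
        f"{field} {' '.join(values)}",
    )


def _tokenize(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> Selection:
        sel = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r} in selection expression")
        return sel

    def parse_or(self) -> Selection:
        left = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            left = left | self.parse_and()
        return left

    def parse_and(self) -> Selection:
        left = self.parse_unary()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            left = left & self.parse_unary()
        return left

    def parse_unary(self) -> Selection:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.next()
            return ~self.parse_unary()
        if tok == "(":
            self.next()
            sel = self.parse_or()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in selection expression")
            return sel
        return self.parse_primitive()

    def _collect_values(self, what: str) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek().lower() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise ValueError(f"selection keyword {what!r} requires at least one value")
        return vals

    def parse_primitive(self) -> Selection:
        tok = self.next().lower()
        if tok == "chain":
            return _chain_sel(self._collect_values("chain"))
        if tok == "resseq":
            return _resseq_sel(self._collect_values("resseq"))
        if tok == "resname":
            return _field_sel("res_name", self._collect_values("resname"))
        if tok == "name":
            return _field_sel("name", self._collect_values("name"))
        if tok == "protein":
            return Selection(lambda s: np.array([not a.het for a in s.atoms]), "protein")
        if tok == "hetero":
            return Selection(lambda s: np.array([a.het for a in s.atoms]), "hetero")
        if tok == "all":
            return Selection(lambda s: np.ones(s.n_atoms, dtype=bool), "all")
        if tok == "none":
            return Selection(lambda s: np.zeros(s.n_atoms, dtype=bool), "none")
        raise ValueError(f"unknown selection keyword {tok!r}")


def parse_selection(expr: str) -> Selection:
    """Parse a selection expression string into a :class:`Selection`."""
    tokens = _tokenize(expr)
    if not tokens:
        raise ValueError("empty selection expression")
    return _Parser(tokens).parse()


def apply_selection(structure: MolecularStructure, expr: "str | Selection") -> np.ndarray:
    """Evaluate a selection (string or tree) -> sorted atom-index array."""
    sel = parse_selection(expr) if isinstance(expr, str) else expr
    return sel.indices(structure)
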