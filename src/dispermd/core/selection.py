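"""Minimal atom-selection language.

Grammar (keywords are case-insensitive, values are not)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | "(" expr ")" | primary
    primary  := "resname" NAME+ | "element" NAME+ | "molid" INT[-INT]+ | "all"

Multiple values after a keyword are OR-ed: ``resname API POL`` matches
either residue name.  Selections are evaluated against a
:class:`~dispermd.topology.SystemTopology` and are deterministic and
order-independent.  An empty result raises ``SelectionError`` — silent
empty groups are forbidden.
"""

from __future__ import annotations

import numpy as np

from .types import GroupSelection

__all__ = ["select_group", "SelectionError"]

_KEYWORDS = {"resname", "element", "molid", "all", "and", "or", "not", "(", ")"}


class SelectionError(ValueError):
    pass


def _tokenize(spec: str) -> list[str]:
    out = []
    for raw in spec.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], top):
        self.tokens = tokens
        self.pos = 0
        self.top = top
        self.n = top.n_atoms

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek().lower() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError("keyword requires at least one value")
        return vals

    def primary(self) -> np.ndarray:
        key = self.next().lower()
        if key == "all":
            return np.ones(self.n, dtype=bool)
        if key == "resname":
            vals = set(self._values())
            return np.array([r in vals for r in self.top.residue_names])
        if key == "element":
            vals = {v.capitalize() for v in self._values()}
            return np.array([e.capitalize() in vals for e in self.top.elements])
        if key == "molid":
            ids: set[int] = set()
            for v in self._values():
                if "-" in v[1:]:
                    lo, hi = v.split("-", 1)
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(v))
            return np.isin(self.top.molecule_ids, sorted(ids))
        raise SelectionError(f"unknown selection keyword {key!r}")


def select_group(topology, spec: str, label: str | None = None) -> GroupSelection:
    """Evaluate a selection expression against a topology.

    Raises :class:`SelectionError` if the expression parses to an empty
    set of atoms.
    """
    tokens = _tokenize(spec)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    mol_ids = frozenset(int(m) for m in np.unique(topology.molecule_ids[idx]))
    return GroupSelection(
        label=label if label is not None else spec,
        atom_indices=frozenset(int(i) for i in idx),
        molecule_ids=mol_ids,
    )
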