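"""Atom selection mini-language.

Grammar (whitespace separated)::

    expr    :=  term ("or" term)*
    term    :=  factor ("and" factor)*
    factor  :=  "not" factor | "(" expr ")" | key value+
    key     :=  "name" | "resname" | "resnum" | "monomer" | "element"
    value   :=  token | int | int ":" int      (inclusive range, numeric keys)

``resnum`` matches *monomer-local* residue numbers: a structure built with
the concatenated numbering convention stores residue ``r + offset·m`` for
residue ``r`` of monomer ``m``, and ``resnum 106`` selects that residue in
every monomer (106, 242, 378, ... for the default offset of 136).
Non-protein atoms (``monomer_index == -1``) match on their stored number.

Resolution is deterministic: the returned indices are sorted and unique.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["Selection", "SelectionError", "select"]

_KEYS = {"name", "resname", "resnum", "monomer", "element"}
_NUMERIC_KEYS = {"resnum", "monomer"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionError(ValueError):
    """Raised on a malformed selection expression."""


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression plus sorted unique indices."""

    expression: str
    indices: np.ndarray

    def __len__(self) -> int:
        return int(self.indices.size)


def _tokenize(expression: str) -> list[str]:
    if not expression or not expression.strip():
        raise SelectionError("empty selection expression")
    return _TOKEN_RE.findall(expression)


class _Parser:
    def __init__(self, tokens: list[str], structure):
        self.tokens = tokens
        self.pos = 0
        self.st = structure
        # monomer-local residue numbers
        off = structure.numbering_offset
        mono = structure.monomer_index
        local = structure.residue_number.astype(np.int64).copy()
        prot = mono >= 0
        local[prot] = local[prot] - off * mono[prot].astype(np.int64)
        self.local_resnum = local

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        if tok in _KEYS:
            return self.primary(self.take())
        raise SelectionError(f"unexpected token {tok!r}")

    def primary(self, key: str) -> np.ndarray:
        values = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYS or tok in ("and", "or", "not", "(", ")"):
                break
            values.append(self.take())
        if not values:
            raise SelectionError(f"key {key!r} needs at least one value")
        n = self.st.n_atoms
        mask = np.zeros(n, dtype=bool)
        if key in _NUMERIC_KEYS:
            field = self.local_resnum if key == "resnum" else self.st.monomer_index
            for v in values:
                if ":" in v:
                    lo_s, _, hi_s = v.partition(":")
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(f"bad numeric range {v!r}") from None
                    mask |= (field >= lo) & (field <= hi)
                else:
                    try:
                        iv = int(v)
                    except ValueError:
                        raise SelectionError(
                            f"bad numeric value {v!r} for key {key!r}"
                        ) from None
                    mask |= field == iv
        else:
            field = {
                "name": self.st.atom_name,
                "resname": self.st.residue_name,
                "element": self.st.element,
            }[key]
            field_up = np.char.upper(field.astype(str))
            for v in values:
                mask |= field_up == v.upper()
        return mask


def select(structure, expression: str) -> Selection:
    """Resolve ``expression`` against ``structure``.

    Returns a :class:`Selection` with sorted unique indices.  An empty
    result is allowed; the caller decides whether that is an error.
    """
    tokens = _tokenize(expression)
    mask = _Parser(tokens, structure).parse()
    return Selection(expression=expression, indices=np.flatnonzero(mask))
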