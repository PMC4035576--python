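"""Atom selection over :class:`~mdpost.structure.Structure`.

The grammar is the MDAnalysis selection language restricted to what the
analyses need — atom name, residue number/range, residue name, chain —
combined with AND/OR/NOT (case-insensitive).  ``chain X`` is accepted as
an alias for ``chainID X``.
"""

from __future__ import annotations

import re

import numpy as np

from .io import to_universe
from .structure import Structure

__all__ = ["select", "SelectionError"]


class SelectionError(ValueError):
    """Raised when a selection expression cannot be parsed or resolved."""


_KEYWORD_RE = re.compile(r"\b(AND|OR|NOT)\b", flags=re.IGNORECASE)
_CHAIN_RE = re.compile(r"\bchain\b(?!ID)", flags=re.IGNORECASE)


def _normalise(expression: str) -> str:
    expr = _KEYWORD_RE.sub(lambda m: m.group(0).lower(), expression)
    return _CHAIN_RE.sub("chainID", expr)


def select(structure: Structure, expression: str) -> np.ndarray:
    """Resolve ``expression`` to a sorted integer index array.

    Deterministic and order-preserving: indices come back in structure
    order, so ``structure.subset(select(s, expr))`` keeps atom order.
    """
    if not expression or not expression.strip():
        raise SelectionError("empty selection expression")
    u = to_universe(structure)
    try:
        ag = u.select_atoms(_normalise(expression))
    except Exception as exc:  # MDAnalysis raises its own SelectionError
        raise SelectionError(f"bad selection {expression!r}: {exc}") from None
    return np.asarray(ag.indices, dtype=int)
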