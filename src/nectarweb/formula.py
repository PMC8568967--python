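"""Model terms and design matrices for the mixed-model machinery.

A :class:`Term` is a product of powers of named covariates, e.g. a linear
term ``fdis``, a quadratic ``fdis^2`` or an interaction ``nectar:fdis``.
Terms carry just enough structure to express marginality: a term dominates
another when it contains it (equal or higher power for every variable), which
drives both candidate-set enumeration and type-II testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "linear",
    "quadratic",
    "interaction",
    "dominates",
    "lower_order_terms",
    "design_matrix",
    "formula_label",
]

INTERCEPT_NAME = "(Intercept)"


@dataclass(frozen=True, order=True)
class Term:
    """A fixed-effect term: product of powers of covariates."""

    powers: tuple[tuple[str, int], ...]  # sorted ((variable, power), ...)

    @property
    def name(self) -> str:
        parts = []
        for var, pw in self.powers:
            parts.append(var if pw == 1 else f"{var}^{pw}")
        return ":".join(parts)

    @property
    def order(self) -> int:
        return sum(pw for _, pw in self.powers)

    def column(self, data) -> np.ndarray:
        """Covariate column; ``data`` is any mapping of name -> array."""
        col: np.ndarray | None = None
        for var, pw in self.powers:
            arr = np.asarray(data[var], dtype=float) ** pw
            col = arr if col is None else col * arr
        assert col is not None  # a Term has at least one factor
        return col

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def linear(var: str) -> Term:
    return Term(((var, 1),))


def quadratic(var: str) -> Term:
    return Term(((var, 2),))


def interaction(*vars_: str) -> Term:
    return Term(tuple(sorted((v, 1) for v in vars_)))


def _power_map(t: Term) -> dict[str, int]:
    return dict(t.powers)


def dominates(big: Term, small: Term) -> bool:
    """True iff ``small`` is a strictly lower-order component of ``big``.

    Every variable of ``small`` appears in ``big`` with at least the same
    power, and the terms differ.  E.g. ``fdis^2`` dominates ``fdis``;
    ``threshold:fdis^2`` dominates ``threshold``, ``fdis``, ``fdis^2`` and
    ``threshold:fdis``.
    """
    if big == small:
        return False
    bp, sp = _power_map(big), _power_map(small)
    return all(bp.get(v, 0) >= p for v, p in sp.items())


def lower_order_terms(t: Term, pool: list[Term]) -> list[Term]:
    """Pool terms that ``t`` dominates (its marginality requirements)."""
    return [s for s in pool if dominates(t, s)]


def design_matrix(
    data: pd.DataFrame, terms: tuple[Term, ...] | list[Term]
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept-first design matrix for the given terms."""
    cols = [np.ones(len(data))]
    names = [INTERCEPT_NAME]
    for t in terms:
        cols.append(t.column(data))
        names.append(t.name)
    return np.column_stack(cols), names


def formula_label(terms: tuple[Term, ...] | list[Term]) -> str:
    """Human-readable formula string, e.g. ``~ 1 + nectar + fdis^2``."""
    if not terms:
        return "~ 1"
    return "~ 1 + " + " + ".join(t.name for t in terms)
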