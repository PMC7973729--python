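"""Modified Needleman-Wunsch distance for weighted, group-constrained strings.

This is a *minimising* global-alignment dynamic program over activity
strings.  Each step cost depends on the expert-supplied activity weights
``w`` (in ``[1, 2]``) and the penalty scheme ``(m, s, g, ns)``:

====================  =======================================================
step                  cost added at cell ``(i, j)`` (``x = X[i-1][j-1]``)
====================  =======================================================
match (same code)     ``D = x * m + x / (x + w)``
swap (same group)     ``D = x + s + |w_i - w_j|``
no-swap (diff group)  ``D = x + ns + w_i + w_j``
gap in either string  ``L = X[i-1][j] + g + w_i`` / ``T = X[i][j-1] + g + w_j``
====================  =======================================================

with ``X[i][j] = min(D, L, T)`` and boundary cells accruing ``g + w`` per
consumed character.  The match step is multiplicative in the previous cell so
that a zero prefix cost propagates (identical strings score 0) and its
increment ``x / (x + w)`` is always below 1, decreasing in the weight of the
matched activity and increasing in the cost already accrued: matches of
important activities, and matches early in the string, are rewarded most.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .catalog import ActivityCatalog, CatalogError, Pathway, PenaltyScheme

__all__ = ["ScoreMatrix", "AlignmentStep", "Alignment", "mnw_matrix", "mnw_distance", "mnw_traceback"]

#: Absolute tolerance for floating comparisons in the traceback.
ATOL = 1e-9


def _codes(p: "Pathway | str") -> str:
    return p.codes if isinstance(p, Pathway) else p


@dataclass(frozen=True)
class ScoreMatrix:
    """Filled DP matrix for a pathway pair; ``values`` is (|a|+1, |b|+1)."""

    values: np.ndarray
    a: str
    b: str

    @property
    def distance(self) -> float:
        return float(self.values[-1, -1])


@dataclass(frozen=True)
class AlignmentStep:
    """One traceback step: match/swap/no_swap consume a character from each
    string; gap_in_a consumes from b only, gap_in_b from a only."""

    kind: Literal["match", "swap", "no_swap", "gap_in_a", "gap_in_b"]
    code_a: str | None
    code_b: str | None
    cost: float


@dataclass(frozen=True)
class Alignment:
    """An optimal alignment: ordered steps whose costs replay the distance."""

    steps: tuple[AlignmentStep, ...]
    distance: float

    def as_strings(self) -> tuple[str, str]:
        """The two gapped rows of the alignment, '-' marking gaps."""
        row_a = "".join(s.code_a or "-" for s in self.steps)
        row_b = "".join(s.code_b or "-" for s in self.steps)
        return row_a, row_b

    def pretty(self) -> str:
        row_a, row_b = self.as_strings()
        return f"{row_a}\n{row_b}"


def _step_costs(
    ca: str, cb: str, x: float, catalog: ActivityCatalog, pen: PenaltyScheme
) -> tuple[float, str]:
    """Diagonal-step cost from predecessor value ``x`` and the step kind."""
    wa = catalog.weight(ca)
    wb = catalog.weight(cb)
    if ca == cb:
        return x * pen.m + x / (x + wa), "match"
    if catalog.same_group(ca, cb):
        return x + pen.s + abs(wa - wb), "swap"
    return x + pen.ns + wa + wb, "no_swap"


def mnw_matrix(
    a: "Pathway | str",
    b: "Pathway | str",
    catalog: ActivityCatalog,
    pen: PenaltyScheme | None = None,
) -> ScoreMatrix:
    """Fill the modified Needleman-Wunsch matrix for pathways ``a`` and ``b``."""
    if pen is None:
        pen = PenaltyScheme()
    sa, sb = _codes(a), _codes(b)
    catalog.validate_pathway(sa)
    catalog.validate_pathway(sb)
    n, m = len(sa), len(sb)
    X = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        X[i, 0] = X[i - 1, 0] + pen.g + catalog.weight(sa[i - 1])
    for j in range(1, m + 1):
        X[0, j] = X[0, j - 1] + pen.g + catalog.weight(sb[j - 1])
    for i in range(1, n + 1):
        wa = catalog.weight(sa[i - 1])
        for j in range(1, m + 1):
            wb = catalog.weight(sb[j - 1])
            d, _ = _step_costs(sa[i - 1], sb[j - 1], X[i - 1, j - 1], catalog, pen)
            left = X[i - 1, j] + pen.g + wa
            top = X[i, j - 1] + pen.g + wb
            X[i, j] = min(d, left, top)
    return ScoreMatrix(values=X, a=sa, b=sb)


def mnw_distance(
    a: "Pathway | str",
    b: "Pathway | str",
    catalog: ActivityCatalog,
    pen: PenaltyScheme | None = None,
) -> float:
    """Modified Needleman-Wunsch distance: symmetric, non-negative, 0 iff a == b."""
    return mnw_matrix(a, b, catalog, pen).distance


def mnw_traceback(
    matrix: ScoreMatrix,
    catalog: ActivityCatalog,
    pen: PenaltyScheme | None = None,
) -> Alignment:
    """Recover one optimal alignment from a filled matrix.

    Ties between the diagonal, up and left predecessors are broken in that
    order, preferring diagonal (match/swap) moves, so the result is
    deterministic.  Replaying the step costs reproduces the final cell.
    """
    if pen is None:
        pen = PenaltyScheme()
    X, sa, sb = matrix.values, matrix.a, matrix.b
    i, j = len(sa), len(sb)
    steps: list[AlignmentStep] = []
    while i > 0 or j > 0:
        here = X[i, j]
        if i > 0 and j > 0:
            ca, cb = sa[i - 1], sb[j - 1]
            d, kind = _step_costs(ca, cb, X[i - 1, j - 1], catalog, pen)
            if abs(here - d) <= ATOL:
                steps.append(AlignmentStep(kind, ca, cb, here - X[i - 1, j - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0:
            ca = sa[i - 1]
            up = X[i - 1, j] + pen.g + catalog.weight(ca)
            if abs(here - up) <= ATOL:
                steps.append(AlignmentStep("gap_in_b", ca, None, pen.g + catalog.weight(ca)))
                i -= 1
                continue
        if j > 0:
            cb = sb[j - 1]
            left = X[i, j - 1] + pen.g + catalog.weight(cb)
            if abs(here - left) <= ATOL:
                steps.append(AlignmentStep("gap_in_a", None, cb, pen.g + catalog.weight(cb)))
                j -= 1
                continue
        raise CatalogError(
            f"inconsistent score matrix at cell ({i}, {j}): no predecessor explains {here!r}"
        )
    steps.reverse()
    return Alignment(steps=tuple(steps), distance=matrix.distance)
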