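"""Activity catalogs: alphabet, expert groupings, rankings and derived weights.

A clinical pathway is encoded as a string of single-letter activity codes.
Domain experts contribute two pieces of context that the weighted alignment
distance consumes:

* **groups** — activities that occur at a similar point of the care process
  and are therefore allowed to substitute ("swap") for one another in an
  alignment;
* **ranks** — a strict importance order, 0 = most important.  Ranks are
  converted affinely to weights in ``[1, 2]``: the least important activity
  gets weight 1 and each step up in importance adds ``1/(N-1)``, so the most
  important activity gets weight 2.

The module also validates penalty schemes ``(m, s, g, ns)`` against the
guideline constraints that keep per-step costs ordered as
match < swap < gap < no-swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import pandas as pd

__all__ = [
    "Activity",
    "ActivityCatalog",
    "PenaltyScheme",
    "Pathway",
    "CatalogError",
    "ranks_to_weights",
    "build_catalog",
    "validate_penalties",
    "read_catalog",
    "write_catalog",
]


class CatalogError(ValueError):
    """Invalid catalog definition or a code not present in the catalog."""


def ranks_to_weights(ranks: Mapping[str, int], n: int | None = None) -> dict[str, float]:
    """Convert expert importance ranks to activity weights.

    Parameters
    ----------
    ranks
        Mapping of activity code to rank; ranks must be a permutation of
        ``0 .. N-1`` with 0 the most important activity.
    n
        Number of activities; defaults to ``len(ranks)``.

    Returns
    -------
    dict
        ``code -> 1 + (N - 1 - rank) / (N - 1)``, so rank 0 maps to 2.0 and
        rank N-1 maps to 1.0.
    """
    if n is None:
        n = len(ranks)
    if n < 2:
        raise CatalogError("at least two ranked activities are required (N >= 2)")
    if len(ranks) != n:
        raise CatalogError(f"expected {n} ranks, got {len(ranks)}")
    if sorted(ranks.values()) != list(range(n)):
        raise CatalogError(f"ranks must be a permutation of 0..{n - 1}")
    return {code: 1.0 + (n - 1 - rank) / (n - 1) for code, rank in ranks.items()}


@dataclass(frozen=True)
class Activity:
    """One care-process step: its letter code, swap group, rank and weight."""

    code: str
    group: Hashable
    rank: int
    weight: float


@dataclass(frozen=True)
class PenaltyScheme:
    """The four alignment cost parameters.

    ``m`` multiplies the previous cell in the match step (must be 1 so a zero
    prefix cost propagates), ``s`` is the swap penalty, ``g`` the gap penalty
    and ``ns`` the no-swap penalty.  Guideline constraints: ``m = 1``,
    ``g > 1``, ``1 < s <= g`` and ``ns = 2g + 1``; the smallest compliant
    scheme is ``(1, 2, 2, 5)``.
    """

    m: float = 1.0
    s: float = 2.0
    g: float = 2.0
    ns: float = 5.0
    check: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.check:
            violations = validate_penalties(self)
            if violations:
                raise CatalogError(
                    "invalid penalty scheme: " + "; ".join(violations)
                )

    @classmethod
    def unchecked(cls, m: float, s: float, g: float, ns: float) -> "PenaltyScheme":
        """Build a scheme without guideline validation (for experimentation)."""
        return cls(m=m, s=s, g=g, ns=ns, check=False)

    @property
    def name(self) -> str:
        """Compact tag such as ``MNW_1225`` used in result tables."""

        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        return "MNW_" + "".join(fmt(v) for v in (self.m, self.g, self.s, self.ns))


def validate_penalties(scheme: PenaltyScheme) -> list[str]:
    """Check a penalty scheme against the guideline constraints.

    Returns a list of human-readable violations; an empty list means the
    scheme is compliant (m=1, g>1, 1<s<=g, ns=2g+1).
    """
    violations: list[str] = []
    if scheme.m != 1:
        violations.append("m must be 1")
    if not scheme.g > 1:
        violations.append("g must exceed 1")
    if not (1 < scheme.s <= scheme.g):
        violations.append("s must satisfy 1 < s <= g")
    if scheme.ns != 2 * scheme.g + 1:
        violations.append("ns must equal 2g + 1")
    return violations


class ActivityCatalog:
    """The activity alphabet with swap groups and rank-derived weights."""

    def __init__(self, activities: Iterable[Activity]):
        self._activities: dict[str, Activity] = {}
        for act in activities:
            if len(act.code) != 1:
                raise CatalogError(f"activity code must be a single character: {act.code!r}")
            if act.code in self._activities:
                raise CatalogError(f"duplicate activity code {act.code!r}")
            self._activities[act.code] = act
        if not self._activities:
            raise CatalogError("catalog must contain at least one activity")

    @property
    def n(self) -> int:
        return len(self._activities)

    @property
    def codes(self) -> list[str]:
        return list(self._activities)

    def __contains__(self, code: str) -> bool:
        return code in self._activities

    def __getitem__(self, code: str) -> Activity:
        try:
            return self._activities[code]
        except KeyError:
            raise CatalogError(f"unknown activity code {code!r}") from None

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self._activities.values())

    def weight(self, code: str) -> float:
        return self[code].weight

    def same_group(self, a: str, b: str) -> bool:
        """True when two activities may swap (same expert group)."""
        return self[a].group == self[b].group

    def validate_pathway(self, codes: str) -> None:
        for c in codes:
            if c not in self:
                raise CatalogError(f"unknown activity code {c!r} in pathway {codes!r}")

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a DataFrame with columns activity, group, rank, weight."""
        return pd.DataFrame(
            {
                "activity": [a.code for a in self],
                "group": [a.group for a in self],
                "rank": [a.rank for a in self],
                "weight": [a.weight for a in self],
            }
        )

    def __repr__(self) -> str:
        return f"ActivityCatalog({self.n} activities, {len(set(a.group for a in self))} groups)"


def build_catalog(
    groups: Mapping[str, Hashable], ranks: Mapping[str, int]
) -> ActivityCatalog:
    """Assemble a catalog from a group map and a rank map over the same codes."""
    if set(groups) != set(ranks):
        missing = set(groups) ^ set(ranks)
        raise CatalogError(f"groups and ranks must cover the same codes; mismatch: {sorted(missing)}")
    weights = ranks_to_weights(ranks)
    return ActivityCatalog(
        Activity(code=c, group=groups[c], rank=ranks[c], weight=weights[c])
        for c in groups
    )


@dataclass(frozen=True)
class Pathway:
    """One patient trace: an ordered string of activity codes."""

    codes: str
    id: str | None = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be positive")

    def __str__(self) -> str:
        return self.codes

    def __len__(self) -> int:
        return len(self.codes)


def read_catalog(path: str | Path) -> ActivityCatalog:
    """Read a catalog from CSV with columns ``activity,group,rank``."""
    df = pd.read_csv(path, dtype={"activity": str})
    required = {"activity", "group", "rank"}
    if not required.issubset(df.columns):
        raise CatalogError(f"catalog file must have columns {sorted(required)}")
    groups = dict(zip(df["activity"], df["group"]))
    ranks = dict(zip(df["activity"], df["rank"].astype(int)))
    return build_catalog(groups, ranks)


def write_catalog(catalog: ActivityCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, index=False)
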