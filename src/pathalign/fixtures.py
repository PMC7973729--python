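"""Built-in fixtures: the case-study activity catalog and the two samples.

The catalog covers the 15 lung-cancer pathway activities with their expert
swap groups and importance ranks; ``sample1`` and ``sample2`` are the small
pathway collections used for the worked clustering examples.  Element order
in the samples is meaningful: initial medoid indices (0 = ``ABC``,
5 = ``DIJ``, 10 = ``ABKOCEF``) refer to these positions.
"""

from __future__ import annotations

from .catalog import ActivityCatalog, build_catalog
from .io import PathwayTable

__all__ = ["load_fixture", "CATALOG_GROUPS", "CATALOG_RANKS", "SAMPLE1", "SAMPLE2"]

#: Expert swap groups: activities in the same group may substitute in an alignment.
CATALOG_GROUPS: dict[str, int] = {
    "A": 0, "B": 0, "C": 0, "O": 0,
    "D": 1,
    "E": 2, "F": 2,
    "G": 3, "H": 3,
    "I": 4, "J": 4,
    "K": 5, "L": 5, "N": 5,
    "M": 6,
}

#: Expert importance ranks, 0 = most important.
CATALOG_RANKS: dict[str, int] = {
    "A": 2, "B": 0, "C": 1, "D": 12, "E": 10, "F": 9, "G": 7, "H": 6,
    "I": 13, "J": 14, "K": 3, "L": 5, "M": 8, "N": 11, "O": 4,
}

SAMPLE1: tuple[str, ...] = (
    "ABC", "ABCK", "ABCL", "ABCO", "ABKC",
    "DIJ", "DIJK", "DIJL", "DIJO", "DIKJ",
)

SAMPLE2: tuple[str, ...] = SAMPLE1 + (
    "ABKOCEF", "ABOKCEF", "ABKOCFE", "ABOKCFE", "ABKECOF", "ABKCOEF",
)


def load_fixture(name: str) -> "PathwayTable | ActivityCatalog":
    """Return a built-in fixture by name: ``sample1``, ``sample2`` or ``catalog``."""
    if name == "catalog":
        return build_catalog(CATALOG_GROUPS, CATALOG_RANKS)
    if name == "sample1":
        return PathwayTable.from_strings(SAMPLE1)
    if name == "sample2":
        return PathwayTable.from_strings(SAMPLE2)
    raise KeyError(f"unknown fixture {name!r}; available: sample1, sample2, catalog")
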