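"""Classic string distances used as comparison baselines.

Eight standard metrics over plain strings: Levenshtein, Damerau-Levenshtein,
Jaro, Jaro-Winkler, (score-based) Needleman-Wunsch, n-gram Jaccard, n-gram
cosine and longest-common-subsequence distance.  All are symmetric,
non-negative and zero on identical strings.  A registry maps metric names to
bound ``distance(a, b)`` callables so the clustering layer and the CLI can
address any metric, including the modified Needleman-Wunsch, uniformly.
"""

from __future__ import annotations

from collections import Counter
from math import floor, sqrt
from typing import Callable

from .catalog import PenaltyScheme
from .mnw import mnw_distance

__all__ = [
    "DegenerateInputError",
    "levenshtein",
    "damerau_levenshtein",
    "jaro_distance",
    "jaro_winkler_distance",
    "needleman_wunsch_distance",
    "jaccard_ngram_distance",
    "cosine_ngram_distance",
    "lcs_length",
    "lcs_distance",
    "METRICS",
    "get_metric",
]


class DegenerateInputError(ValueError):
    """Input on which the metric is mathematically undefined."""


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b``."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def damerau_levenshtein(a: str, b: str) -> int:
    """Edit distance that additionally allows transposition of adjacent
    characters (unrestricted Damerau-Levenshtein, Lowrance-Wagner DP)."""
    da: dict[str, int] = {}
    n, m = len(a), len(b)
    maxdist = n + m
    # H is (n+2) x (m+2) with a sentinel row/column holding maxdist
    H = [[maxdist] * (m + 2)]
    H.append([maxdist] + list(range(m + 1)))
    for i in range(1, n + 1):
        H.append([maxdist, i] + [0] * m)
    for i in range(1, n + 1):
        db = 0
        for j in range(1, m + 1):
            k = da.get(b[j - 1], 0)
            ell = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            H[i + 1][j + 1] = min(
                H[i][j] + cost,  # substitution / match
                H[i + 1][j] + 1,  # insertion
                H[i][j + 1] + 1,  # deletion
                H[k][ell] + (i - k - 1) + 1 + (j - ell - 1),  # transposition
            )
        da[a[i - 1]] = i
    return H[n + 1][m + 1]


def _jaro_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    # matching tolerance: characters count as a match when equal and no more
    # than T positions apart, T = floor(max(|a|,|b|)/2) - 1
    tol = max(0, floor(max(la, lb) / 2) - 1)
    matched_a = [False] * la
    matched_b = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - tol), min(lb, i + tol + 1)
        for j in range(lo, hi):
            if not matched_b[j] and b[j] == ca:
                matched_a[i] = matched_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: half the number of out-of-order matched pairs
    seq_a = [c for c, f in zip(a, matched_a) if f]
    seq_b = [c for c, f in zip(b, matched_b) if f]
    t = sum(ca != cb for ca, cb in zip(seq_a, seq_b)) / 2
    return (m / la + m / lb + (m - t) / m) / 3


def jaro_distance(a: str, b: str) -> float:
    """1 minus the Jaro similarity; in ``[0, 1]``."""
    return 1.0 - _jaro_similarity(a, b)


def jaro_winkler_distance(a: str, b: str, p: float = 0.1) -> float:
    """Jaro distance discounted by a common-prefix bonus.

    ``sim_w = sim_j + l * p * (1 - sim_j)`` with ``l`` the common-prefix
    length capped at 4 and scaling factor ``p <= 0.25``.  Following the
    classic Winkler reference implementation, the bonus is only applied to
    pairs that are already similar (``sim_j > 0.7``) and both longer than 3
    characters; other pairs keep the plain Jaro distance.
    """
    if p > 0.25:
        raise ValueError("winkler scaling factor p must not exceed 0.25")
    sim = _jaro_similarity(a, b)
    if sim > 0.7 and len(a) > 3 and len(b) > 3:
        l = 0
        for ca, cb in zip(a[:4], b[:4]):
            if ca != cb:
                break
            l += 1
        sim += l * p * (1.0 - sim)
    return 1.0 - sim


def needleman_wunsch_distance(
    a: str, b: str, match: float = 1.0, swap: float = -1.0, gap: float = -1.0
) -> float:
    """Classic score-maximising Needleman-Wunsch, reported as a distance.

    The optimal global alignment score ``S`` (match/mismatch/gap scores as
    given) is converted to a distance via ``max(|a|, |b|) * match - S``, which
    is 0 on identical strings and non-negative whenever ``match >= swap`` and
    ``match >= gap``.
    """
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else swap)
            cur[j] = max(diag, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return max(n, m) * match - prev[m]


def _ngrams(s: str, n: int) -> list[str]:
    return [s[i : i + n] for i in range(len(s) - n + 1)]


def jaccard_ngram_distance(a: str, b: str, n: int = 2) -> float:
    """1 minus the Jaccard index of the two n-gram sets (default bigrams)."""
    if n < 1:
        raise ValueError("n-gram size must be >= 1")
    A, B = set(_ngrams(a, n)), set(_ngrams(b, n))
    union = A | B
    if not union:
        return 0.0
    return (len(union) - len(A & B)) / len(union)


def cosine_ngram_distance(a: str, b: str, n: int = 2) -> float:
    """1 minus the cosine similarity of the two n-gram count vectors.

    Raises :class:`DegenerateInputError` when either string yields no
    n-grams (zero-norm vector), e.g. a single-activity pathway under bigrams.
    """
    if n < 1:
        raise ValueError("n-gram size must be >= 1")
    ca, cb = Counter(_ngrams(a, n)), Counter(_ngrams(b, n))
    if not ca or not cb:
        raise DegenerateInputError(
            f"cosine distance undefined: a string shorter than n={n} has a zero-norm n-gram vector"
        )
    if ca == cb:
        return 0.0
    dot = sum(ca[g] * cb.get(g, 0) for g in ca)
    return 1.0 - dot / (sqrt(sum(v * v for v in ca.values())) * sqrt(sum(v * v for v in cb.values())))


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence (not necessarily contiguous)."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def lcs_distance(a: str, b: str) -> int:
    """What remains of the longer string once the LCS is removed:
    ``max(|a|, |b|) - LCS(a, b)``."""
    return max(len(a), len(b)) - lcs_length(a, b)


#: Registry of metric factories.  Each factory accepts metric-specific
#: keyword parameters and returns a ``distance(a, b)`` callable.
METRICS: dict[str, Callable[..., Callable[[str, str], float]]] = {
    "levenshtein": lambda: levenshtein,
    "damerau_levenshtein": lambda: damerau_levenshtein,
    "jaro": lambda: jaro_distance,
    "jaro_winkler": lambda p=0.1: (lambda a, b: jaro_winkler_distance(a, b, p=p)),
    "needleman_wunsch": lambda match=1.0, swap=-1.0, gap=-1.0: (
        lambda a, b: needleman_wunsch_distance(a, b, match=match, swap=swap, gap=gap)
    ),
    "jaccard": lambda n=2: (lambda a, b: jaccard_ngram_distance(a, b, n=n)),
    "cosine": lambda n=2: (lambda a, b: cosine_ngram_distance(a, b, n=n)),
    "lcs": lambda: lcs_distance,
    "mnw": lambda catalog, pen=None: (
        lambda a, b, _c=catalog, _p=pen if pen is not None else PenaltyScheme(): mnw_distance(a, b, _c, _p)
    ),
}


def get_metric(name: str, **params) -> Callable[[str, str], float]:
    """Look up a metric by name and bind its parameters.

    ``mnw`` requires ``catalog`` (an :class:`ActivityCatalog`) and accepts an
    optional ``pen`` (:class:`PenaltyScheme`, default the minimal compliant
    scheme ``(1, 2, 2, 5)``).
    """
    try:
        factory = METRICS[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; available: {', '.join(sorted(METRICS))}"
        ) from None
    return factory(**params)
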