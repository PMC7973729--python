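# pathalign

Weighted, group-constrained string distances and k-medoids clustering for
clinical pathway data.

## The problem

A patient's journey through a care process — referral, scans, MDT meeting,
diagnosis, treatment — can be encoded as a string of single-letter activity
codes ordered by date (one letter per activity, e.g. `ABC`). Clustering
these strings into a few representative pathways is a standard way to distil
guideline-style "typical routes" from messy event logs. Classic string
metrics (Levenshtein, Jaro, LCS, ...) treat every letter alike: inserting a
chest X-ray costs the same as inserting an MDT meeting, so many clinically
different pairs collapse onto the same distance and clusters separate
poorly.

`pathalign` implements a **modified Needleman–Wunsch distance** that injects
expert context into the alignment costs, plus the eight classic metrics it
is compared against, and a k-medoids + silhouette clustering harness.

## The distance

Experts supply two inputs per activity:

* a **group** — activities occurring at a similar point of the pathway;
  only same-group activities may substitute ("swap") in an alignment;
* a **rank** (0 = most important), converted affinely to a weight
  `w = 1 + (N−1−rank)/(N−1) ∈ [1, 2]`.

With penalty parameters `(m, s, g, ns)` the minimising dynamic program is,
for cell `(i, j)` with `x = X[i−1][j−1]`:

```
match   (aᵢ = bⱼ):            D = x·m + x/(x + w)
swap    (same group):          D = x + s + |wᵢ − wⱼ|
no-swap (different groups):    D = x + ns + wᵢ + wⱼ
gaps:                          L = X[i−1][j] + g + wᵢ,   T = X[i][j−1] + g + wⱼ
X[i][j] = min(D, L, T)
```

Boundary cells accrue `g + w` per consumed character. The guideline
constraints `m = 1`, `g > 1`, `1 < s ≤ g`, `ns = 2g + 1` keep every step
ordered match < swap < gap < no-swap; the smallest compliant scheme is
`(1, 2, 2, 5)`. The multiplicative match term makes identical prefixes cost
exactly 0, keeps each match increment below 1, rewards matches of important
activities, and makes a late match cost more than an early one.

## Worked example

```python
from pathalign import (PenaltyScheme, get_metric, k_medoids, load_fixture,
                       mnw_distance, mnw_matrix, mnw_traceback, pairwise_matrix)

cat = load_fixture("catalog")          # 15 activities, expert groups + ranks
pen = PenaltyScheme(m=1, s=2, g=2, ns=5)

mnw_distance("ABC", "ABCK", cat, pen)  # 3.786  = gap (2) + weight of K (1.786)
mnw_distance("ABC", "DIJ", cat, pen)   # 21.0   three no-swap substitutions

m = mnw_matrix("ABKOGNCH", "ABC", cat, pen)
print(mnw_traceback(m, cat, pen).pretty())
# ABKOGNCH
# AB----C-
```

The traceback keeps `B` matched to `B` and gaps over `K, O, G, N` even
though `B` and `O` share a group — a gap is cheaper here than the allowed
swap, which preserves the later `C`–`C` match.

Clustering ten sample pathways (five `ABC`-like, five `DIJ`-like) with
k-medoids started from medoids 0 (`ABC`) and 5 (`DIJ`):

```python
s1 = load_fixture("sample1").pathways
res = k_medoids(pairwise_matrix(s1, get_metric("mnw", catalog=cat, pen=pen)), [0, 5])
# medoids (0, 5) -> 'ABC', 'DIJ'; sizes (5, 5); silhouette 0.76128
```

The medoids stay put and the 5/5 split scores silhouette 0.76128 —
higher than Levenshtein's 0.65789 on the same data, reflecting the extra
separation the weighted costs provide.

A `pathalign` command-line tool wraps the same pipeline:
`pathalign extract` (event log → pathway table), `distance`, `cluster`,
`validate` and `fixtures`; see `pathalign --help`.

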