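# Methods

## Model

A clinical pathway is a string over a finite alphabet of single-letter
activity codes, obtained by sorting one patient's dated activities and
concatenating their codes. The package's central object is a global
alignment distance over such strings whose step costs carry expert context:

* **Groups** partition the alphabet; only same-group activities may
  substitute for each other ("swap"). Cross-group substitution ("no-swap")
  is priced so high that the dynamic program prefers two gaps instead.
* **Ranks** (0 = most important) are converted to weights by
  `w(r) = 1 + (N−1−r)/(N−1)`, an affine map onto `[1, 2]` with increments of
  `1/(N−1)`. Requires `N ≥ 2`; a one-activity catalog is rejected because
  the increment is undefined.

The recurrence minimises, with `x = X[i−1][j−1]`:

| step | cost |
|---|---|
| match | `x·m + x/(x + w)` |
| swap | `x + s + \|wᵢ − wⱼ\|` |
| no-swap | `x + ns + wᵢ + wⱼ` |
| gap | predecessor `+ g + w` of the gapped character |

Boundary rows and columns accrue `g + w` per consumed character — the
natural extension of the gap recurrence to an empty prefix, and the one
consistent with the worked matrices the implementation reproduces.

The match term deserves comment, since a plain reading of its typeset form
is ambiguous. The implemented form `x·m + x/(x + w)` is the unique reading
that (i) propagates a zero prefix cost (identical strings score exactly 0),
(ii) bounds every match increment below 1, and (iii) reproduces all six
printed worked-example cells (3.143, 3.763, 3.571, 4.221, 6.714, 7.491) to
3 d.p. Its consequences are the distance's characteristic features: matches
of important activities are cheaper (`x/(x+w)` decreasing in `w`), and a
match later in a string costs more (increasing in `x`).

## Penalty guidelines

`m = 1`, `g > 1`, `1 < s ≤ g`, `ns = 2g + 1`. Under these, per-step costs
order strictly: match `< 1 ≤ s ≤` swap `≤ s+1 ≤ g+1 ≤` gap `≤ g+2 < ns+2 ≤`
no-swap, because weights live in `[1, 2]`. `m` must be exactly 1 or the
multiplicative term breaks the zero-propagation property. Validation is
strict by default; `PenaltyScheme.unchecked` exists for experimentation
(e.g. probing `ns ≠ 2g+1`), and a compliance report can be produced with
`validate_penalties`. The two schemes used throughout the examples are
`(1, 2, 2, 5)` (the minimum) and `(1, 2, 9, 19)` (wider swap/gap separation,
better cluster contrast).

## Traceback

The alignment is recovered from the filled matrix bottom-right to origin.
Ties are broken diagonal-first (match/swap), then the up move, then the
left move, giving deterministic alignments; tie order cannot change the
distance itself. Floating comparisons use absolute tolerance 1e-9.
Distances are kept at full precision; rounding (3 d.p. for distances,
5 d.p. for silhouettes) is display-only.

## Baseline metrics

The eight comparison metrics are implemented from their textbook
definitions: Levenshtein and unrestricted Damerau–Levenshtein
(Lowrance–Wagner), Jaro and Jaro–Winkler, score-based Needleman–Wunsch,
bigram Jaccard and cosine, and LCS distance `max(|a|,|b|) − LCS`.
Conventions worth noting:

* **Jaro**: matching tolerance `max(0, ⌊max(|a|,|b|)/2⌋ − 1)`;
  transpositions are half the out-of-order matched pairs.
* **Jaro–Winkler** follows the classic Winkler reference implementation:
  the prefix bonus `l·p·(1 − sim)` (prefix capped at 4, `p ≤ 0.25`) applies
  only when the Jaro similarity exceeds 0.7 and both strings are longer
  than 3 characters. This convention — shared by the common reference
  libraries — is what reproduces the published sample clustering scores;
  the plain always-boost variant shifts them by ~0.01.
* **Needleman–Wunsch** is a similarity score; the conversion
  `distance = max(|a|,|b|)·match − S` is this package's choice (the
  standard "maximum minus similarity" form). No published value pins the
  conversion down, so NW distances are documented rather than verified
  against external tables.
* **Cosine** raises a degenerate-input error on zero-norm vectors (a
  pathway shorter than the n-gram size), mirroring the known
  division-by-zero failure on single-activity pathways.
* The bigram Jaccard worked example in the source material prints 5/6, but
  its own seven-component bigram vectors imply 6/7; the enumeration (6/7)
  is implemented and the discrepancy left documented rather than patched.

## Clustering

k-medoids uses the Voronoi (assign/update) iteration from **fixed,
user-supplied initial medoids**: assignment sends each point to its nearest
medoid (ties to the lowest medoid index), update moves each cluster's
medoid to the member minimising total within-cluster distance (ties to the
lowest point index), until the medoid set is stable. The within-cluster
cost is asserted non-increasing every iteration. Runs involve no
randomness. Iteration counts are reported but are variant-specific
(PAM-style swap search would differ) and are not comparable across
implementations.

Silhouette scores are computed by scikit-learn on the precomputed distance
matrix (singleton clusters score 0); the test suite checks it against a
naive double-loop implementation of `(b − a)/max(a, b)` to 1e-12. The
k-sweep runs a range of k and ranks results by silhouette, with the caveat
that silhouette tends to favour k = 2 even when more clusters are
meaningful — it validates cohesion/separation, not clinical utility.

Pathways are clustered as unique strings; multiplicities (patients per
pathway) are carried through for reporting but do not weight the distance
matrix.

## Synthetic event logs

`generate_synthetic_log` emulates the variation real pathway data shows —
differing length, position and order — by drawing skeleton pathways and
perturbing each patient's copy with per-position insertion, deletion and
adjacent-swap noise (defaults 0.05/0.05/0.10, modest rates so skeleton
identity remains recoverable), then emitting one dated event per day. It is
seeded and fully reproducible. It does **not** emulate calendar structure
(waiting-time distributions, same-day bursts), activity-dependent branching
or censoring; passing tests on synthetic logs therefore demonstrate the
extraction/distance/clustering plumbing, not robustness to real
event-log pathology.

## Problem sizes

The exhaustive cross-checks run at small scale chosen to be enumerable:
alignment-path enumeration over all string pairs up to length 4 on a
5-letter catalog (~305k pairs), breadth-first edit-script search up to
length 4 on 3 letters, and subsequence enumeration up to length 5 on 2
letters. The clustering examples use the two built-in samples (10 and 16
pathways). Larger inputs go through the same code paths with no
algorithmic change (all DPs are O(|a|·|b|); the pairwise matrix is
O(n²) metric calls).

## Known limitations

* The distance is not length-normalised; long pathways dominate unless the
  caller normalises downstream.
* No affine or position-dependent gap scheme.
* Groups and ranks must come from experts; nothing is learned from data.
* The no-swap penalty validation treats `ns ≠ 2g + 1` as a violation even
  though larger values are merely unnecessary rather than harmful; use the
  unchecked constructor to explore them.
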