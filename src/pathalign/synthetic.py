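"""Seeded synthetic event-log generator.

Real pathway collections show variation in the length, position and order of
activities: patients share a handful of skeleton routes but individual traces
drift by skipped steps, extra steps and locally reordered steps.  The
generator emulates exactly that: each patient draws a skeleton pathway and
the string is perturbed by per-position insertion, deletion and
adjacent-swap noise, then rendered as dated event records (one activity per
day) so it round-trips through :func:`pathalign.io.extract_pathways`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import ActivityCatalog
from .io import EventRecord

__all__ = ["NoiseModel", "generate_synthetic_log"]


@dataclass(frozen=True)
class NoiseModel:
    """Per-position perturbation probabilities."""

    insertion: float = 0.05
    deletion: float = 0.05
    swap: float = 0.10

    def __post_init__(self) -> None:
        for name in ("insertion", "deletion", "swap"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} probability must be in [0, 1], got {p}")


def _perturb(codes: str, noise: NoiseModel, alphabet: Sequence[str], rng: np.random.Generator) -> str:
    out = list(codes)
    # adjacent swaps first, then deletions, then insertions
    i = 0
    while i < len(out) - 1:
        if rng.random() < noise.swap:
            out[i], out[i + 1] = out[i + 1], out[i]
            i += 2  # a swapped pair is not re-swapped
        else:
            i += 1
    out = [c for c in out if rng.random() >= noise.deletion]
    with_insertions: list[str] = []
    for c in out:
        if rng.random() < noise.insertion:
            with_insertions.append(str(rng.choice(alphabet)))
        with_insertions.append(c)
    if not with_insertions:  # a pathway must contain at least one activity
        with_insertions.append(codes[0])
    return "".join(with_insertions)


def generate_synthetic_log(
    catalog: ActivityCatalog,
    n_patients: int,
    seed: int,
    skeletons: Sequence[str],
    noise: NoiseModel | None = None,
    start_date: str = "2020-01-01",
) -> list[EventRecord]:
    """Generate a reproducible event log from skeleton pathways.

    Each patient draws one skeleton uniformly at random, perturbs it under
    the noise model and records one activity per consecutive day starting at
    ``start_date``.  With zero noise every patient reproduces a skeleton
    exactly.
    """
    if noise is None:
        noise = NoiseModel()
    if n_patients < 1:
        raise ValueError("n_patients must be positive")
    for s in skeletons:
        catalog.validate_pathway(s)
    rng = np.random.default_rng(seed)
    alphabet = catalog.codes
    t0 = pd.Timestamp(start_date)
    records: list[EventRecord] = []
    for p in range(n_patients):
        skeleton = skeletons[int(rng.integers(len(skeletons)))]
        trace = _perturb(skeleton, noise, alphabet, rng)
        for day, code in enumerate(trace):
            records.append(
                EventRecord(
                    patient_id=f"P{p:04d}",
                    activity=code,
                    timestamp=t0 + pd.Timedelta(days=day),
                )
            )
    return records
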