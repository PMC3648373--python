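"""Protein activity from expression curves via the 3-sigma principle.

A protein is taken to be active at the time points where its expression
is at or above a gene-specific harmonic threshold blending the curve's
mean ``u`` and ``u + 3*sigma``:

    u        = mean(EV_1..EV_n)
    sigma^2  = population variance (denominator n)
    F        = 1 / (1 + sigma^2)          (fluctuation weight)
    Active_TH = u*F + (u + 3*sigma)*(1-F)

Flat curves (sigma^2 = 0) give F = 1 and threshold = u, so every point is
active.  Highly fluctuating curves push the threshold toward u+3*sigma;
when the threshold exceeds the curve's maximum no active point can be
inferred and the protein is assigned the wildcard time point 0, meaning
"potentially active at any time".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from jitrefine.io import ExpressionProfile

WILDCARD = 0  # special time point for proteins whose activity cannot be inferred


@dataclass(frozen=True)
class ThresholdRecord:
    """Per-gene threshold statistics (expression units unless noted)."""

    mean: float
    variance: float  # population variance, squared units
    fluctuation: float  # F = 1/(1+variance), dimensionless in (0, 1]
    threshold: float


@dataclass
class ActivityTable:
    """Map protein -> set of active time points in {0, 1..n}.

    Every set is non-empty; a set containing the wildcard point 0
    contains only 0.  Proteins absent from the table are treated as
    wildcard (``get`` returns ``{0}``).
    """

    active: dict[str, frozenset[int]]
    n: int
    category_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.active = {p: frozenset(s) for p, s in self.active.items()}
        for p, s in self.active.items():
            if not s:
                raise ValueError(f"empty active set for {p!r}")
            if WILDCARD in s and s != {WILDCARD}:
                raise ValueError(f"wildcard set for {p!r} must be exactly {{0}}")
            if max(s) > self.n:
                raise ValueError(f"active point beyond n={self.n} for {p!r}")

    def __getitem__(self, protein: str) -> frozenset[int]:
        return self.active[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.active

    def get(self, protein: str) -> frozenset[int]:
        return self.active.get(protein, frozenset({WILDCARD}))

    def is_wildcard(self, protein: str) -> bool:
        return self.get(protein) == {WILDCARD}


def threshold(values: Iterable[float]) -> ThresholdRecord:
    """Compute the 3-sigma activity threshold for one expression vector."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 time points")
    if not np.isfinite(arr).all():
        raise ValueError("expression values must be finite")
    u = float(arr.mean())
    var = float(arr.var())  # population variance, denominator n
    f = 1.0 / (1.0 + var)
    th = u * f + (u + 3.0 * math.sqrt(var)) * (1.0 - f)
    return ThresholdRecord(mean=u, variance=var, fluctuation=f, threshold=th)


def active_points(values: Iterable[float], record: ThresholdRecord) -> frozenset[int]:
    """1-based time points where expression >= the activity threshold."""
    arr = np.asarray(list(values), dtype=float)
    return frozenset(int(i) for i in np.flatnonzero(arr >= record.threshold) + 1)


def build_activity_table(
    profile: ExpressionProfile,
    proteins: Iterable[str] | None = None,
) -> ActivityTable:
    """Deduce the active time point set of each requested protein.

    A protein absent from the profile, or whose threshold exceeds every
    expression value (empty active set), gets the wildcard set ``{0}``.
    ``category_counts`` on the result tallies the three outcomes:
    ``inferred``, ``uninferred`` (present but empty active set) and
    ``missing`` (no expression row).
    """
    requested = list(proteins) if proteins is not None else profile.genes
    table: dict[str, frozenset[int]] = {}
    counts = {"inferred": 0, "uninferred": 0, "missing": 0}
    for p in requested:
        if p not in profile:
            table[p] = frozenset({WILDCARD})
            counts["missing"] += 1
            continue
        vec = profile.vector(p)
        pts = active_points(vec, threshold(vec))
        if pts:
            table[p] = pts
            counts["inferred"] += 1
        else:
            table[p] = frozenset({WILDCARD})
            counts["uninferred"] += 1
    return ActivityTable(active=table, n=profile.n, category_counts=counts)
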