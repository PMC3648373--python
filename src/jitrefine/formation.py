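"""Just-in-time complex formation model.

A complex ``C`` can form in the contiguous interval ``[S, S+K]`` of cycle
time points when subunits join step by step: writing ``AP_i(C)`` for the
members of ``C`` active at time point ``i``, the boolean formation test
``FC(C, S, K)`` holds iff

1. for every ``j = 0..K-1`` the running union ``AP_S ∪ .. ∪ AP_{S+j}``
   shares at least one protein with ``AP_{S+j+1}`` (each step docks onto
   the growing assembly), and
2. the union over the whole interval equals ``C`` (every subunit is
   active at some point of the interval).

The co-active (overlapping) rate of a formation interval averages, over
its steps, ``|assembled ∩ AP_next| / min(|assembled|, |AP_next|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from jitrefine.activity import WILDCARD, ActivityTable
from jitrefine.io import ComplexCatalog

import pandas as pd

WildcardMode = Literal["strict", "permissive"]


@dataclass
class FormationResult:
    """Outcome of searching all intervals ``[S, S+K]`` for one complex."""

    formable: bool
    intervals: list[tuple[int, int]]  # all (S, K) with FC true
    best_interval: tuple[int, int] | None = None
    best_overlap: float | None = None  # max OL over true intervals


@dataclass
class CatalogFormationStats:
    """Catalog-level formation summary (the two Table-style columns)."""

    n_assessed: int
    n_formable: int
    fraction_formable: float
    mean_overlap: float  # mean best OL over formable complexes; 0.0 if none
    per_complex: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_complex)


def active_members(
    complex_: Iterable[str],
    activity: ActivityTable,
    i: int,
    wildcard: WildcardMode = "strict",
) -> frozenset[str]:
    """``AP_i(C)``: members of the complex active at time point ``i``.

    In strict mode wildcard proteins (``Active = {0}``) appear only at
    ``i = 0``; in permissive mode they are additionally counted as active
    at every real time point ``i >= 1``.
    """
    if not 0 <= i <= activity.n:
        raise ValueError(f"time point {i} out of range 0..{activity.n}")
    members = set(complex_)
    out = {p for p in members if i in activity.get(p)}
    if wildcard == "permissive" and i >= 1:
        out |= {p for p in members if activity.get(p) == {WILDCARD}}
    return frozenset(out)


def is_formable(
    complex_: Iterable[str],
    activity: ActivityTable,
    S: int,
    K: int,
    wildcard: WildcardMode = "strict",
) -> bool:
    """Evaluate the formation test FC(C, S, K)."""
    complex_ = frozenset(complex_)
    if not complex_:
        raise ValueError("empty complex")
    if S < 1 or K < 0 or S + K > activity.n:
        raise ValueError(f"interval [S={S}, S+K={S + K}] out of range 1..{activity.n}")
    union = set(active_members(complex_, activity, S, wildcard))
    for j in range(K):
        nxt = active_members(complex_, activity, S + j + 1, wildcard)
        if not (union & nxt):
            return False  # condition 1: step j+1 does not dock onto the assembly
        union |= nxt
    return union == complex_  # condition 2: everyone joined


def formation_overlap(
    complex_: Iterable[str],
    activity: ActivityTable,
    S: int,
    K: int,
    wildcard: WildcardMode = "strict",
) -> float:
    """Mean per-step overlapping rate OL(C) over the interval [S, S+K].

    Defined for intervals where FC holds; a single-point interval (K=0)
    has no merge steps and returns 1.0 by convention.
    """
    complex_ = frozenset(complex_)
    if K == 0:
        return 1.0
    union = set(active_members(complex_, activity, S, wildcard))
    rates = []
    for i in range(1, K + 1):
        nxt = active_members(complex_, activity, S + i, wildcard)
        denom = min(len(union), len(nxt))
        if denom == 0:
            raise ValueError("formation overlap undefined: empty step set (FC false)")
        rates.append(len(union & nxt) / denom)
        union |= nxt
    return sum(rates) / K


def find_formation(
    complex_: Iterable[str],
    activity: ActivityTable,
    wildcard: WildcardMode = "strict",
) -> FormationResult:
    """Search every interval [S, S+K] within the cycle for formability.

    ``best_overlap`` is the maximum OL over the FC-true intervals; the
    reported ``best_interval`` breaks OL ties by smallest K, then
    smallest S, making the result deterministic.
    """
    complex_ = frozenset(complex_)
    n = activity.n
    hits: list[tuple[float, int, int]] = []  # (OL, K, S)
    intervals: list[tuple[int, int]] = []
    for S in range(1, n + 1):
        for K in range(0, n - S + 1):
            if is_formable(complex_, activity, S, K, wildcard):
                intervals.append((S, K))
                hits.append((formation_overlap(complex_, activity, S, K, wildcard), K, S))
    if not hits:
        return FormationResult(formable=False, intervals=[])
    ol, k, s = min(hits, key=lambda t: (-t[0], t[1], t[2]))
    return FormationResult(
        formable=True, intervals=intervals, best_interval=(s, k), best_overlap=ol
    )


def catalog_formation_stats(
    catalog: ComplexCatalog,
    activity: ActivityTable,
    wildcard: WildcardMode = "strict",
) -> CatalogFormationStats:
    """Fraction of complexes formable in a contiguous interval and their
    mean best co-active rate; complexes of size < 2 are not assessed."""
    records = []
    for idx, c in enumerate(catalog):
        if len(c) < 2:
            continue
        res = find_formation(c, activity, wildcard)
        records.append(
            {
                "index": idx,
                "size": len(c),
                "formable": res.formable,
                "S": res.best_interval[0] if res.formable else None,
                "K": res.best_interval[1] if res.formable else None,
                "OL": res.best_overlap,
            }
        )
    if not records:
        raise ValueError("no complexes assessed (all below size 2)")
    formable = [r for r in records if r["formable"]]
    mean_ol = sum(r["OL"] for r in formable) / len(formable) if formable else 0.0
    return CatalogFormationStats(
        n_assessed=len(records),
        n_formable=len(formable),
        fraction_formable=len(formable) / len(records),
        mean_overlap=mean_ol,
        per_complex=records,
    )
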