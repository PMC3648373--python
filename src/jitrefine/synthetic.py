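"""Ground-truth benchmark generators.

Everything the other modules consume can be generated here with a known
answer: expression curves whose 3-sigma activity equals a requested time
point set, networks containing planted complexes whose members' activity
windows follow a just-in-time schedule, and contaminated predictions
(planted complexes plus adjacent but never-co-active proteins).

Expression curves are spike-plus-baseline, not sinusoids: under the
3-sigma threshold a spike's activity set is analytically controllable,
which is all the method exercises.  All generators are deterministic
given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from jitrefine.activity import WILDCARD, ActivityTable, threshold
from jitrefine.io import ComplexCatalog, ExpressionProfile, Network

import networkx as nx


@lru_cache(maxsize=None)
def _spike_amplitude(n: int, k: int, baseline: float, noise_sd: float) -> float:
    """Spike amplitude placing the 3-sigma threshold strictly between
    baseline + 3*noise_sd and spike - 3*noise_sd (grid search; the
    threshold depends only on how many of the n points are spiked)."""
    mask = np.zeros(n)
    mask[:k] = 1.0
    hi = max(1000.0, 200.0 * noise_sd)
    best_a, best_margin = None, -math.inf
    for a in np.geomspace(1e-3, hi, 800):
        th = threshold(baseline + a * mask).threshold
        margin = min(th - baseline, (baseline + a) - th)
        if margin > best_margin:
            best_margin, best_a = margin, a
    eps = 1e-9 * max(1.0, baseline)
    if best_margin <= 3.0 * noise_sd + eps:
        raise ValueError(
            f"no spike amplitude separates activity set of size {k}/{n} "
            f"at noise_sd={noise_sd}"
        )
    return float(best_a)


def _spike_curve(n: int, points: frozenset[int], baseline: float, noise_sd: float) -> np.ndarray:
    """One-cycle curve whose active set is exactly ``points``."""
    k = len(points)
    if k == n:
        return np.full(n, baseline)
    mask = np.zeros(n)
    mask[[p - 1 for p in points]] = 1.0
    return baseline + _spike_amplitude(n, k, baseline, noise_sd) * mask


def _wildcard_curve(n: int, noise_sd: float) -> np.ndarray:
    """One-cycle curve whose threshold exceeds its maximum (no active point)."""
    k = 2 if n >= 4 else 1
    mask = np.zeros(n)
    mask[-k:] = 1.0
    hi = max(1e4, 1e3 * max(noise_sd, 1.0))
    for a in np.geomspace(1.0, hi, 400):
        vec = a * mask
        if threshold(vec).threshold > a + 3.0 * noise_sd + 1e-9:
            return vec
    raise ValueError(f"cannot construct an uninferrable curve for n={n}")


def generate_expression(
    targets: Mapping[str, frozenset[int] | set[int]],
    n: int = 12,
    cycles: int = 3,
    noise_sd: float = 0.0,
    baseline: float = 5.0,
    seed: int | None = None,
) -> ExpressionProfile:
    """Generate curves whose 3-sigma activity matches per-protein targets.

    Each target is either a subset of ``{1..n}`` (the time points that
    must come out active) or ``{0}`` (activity must be uninferrable).
    Curves are tiled over ``cycles`` successive cycles with additive
    Gaussian noise of ``noise_sd``; at ``noise_sd = 0`` the round trip
    through :func:`jitrefine.activity.build_activity_table` reproduces
    the targets exactly.
    """
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for protein in sorted(targets):
        tset = frozenset(targets[protein])
        if not tset:
            raise ValueError(f"empty target set for {protein!r}")
        if WILDCARD in tset:
            if tset != {WILDCARD}:
                raise ValueError(f"wildcard target for {protein!r} must be exactly {{0}}")
            cycle = _wildcard_curve(n, noise_sd)
        else:
            if max(tset) > n or min(tset) < 1:
                raise ValueError(f"target points for {protein!r} outside 1..{n}")
            cycle = _spike_curve(n, tset, baseline, noise_sd)
        samples = np.tile(cycle, cycles)
        if noise_sd > 0:
            samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
        rows.append(samples)
        index.append(protein)
    samples_df = pd.DataFrame(np.asarray(rows), index=index)
    samples_df.columns = [f"T{j:02d}" for j in range(1, n * cycles + 1)]
    return ExpressionProfile.from_samples(samples_df, cycles=cycles)


@dataclass
class SyntheticBenchmark:
    """A planted-complex benchmark with full ground truth."""

    network: Network
    catalog: ComplexCatalog  # the planted (true) complexes, in order
    activity_targets: dict[str, frozenset[int]]
    decoys: dict[int, list[str]]  # complex index -> adjacent never-co-active proteins
    intervals: list[tuple[int, int]]  # (S, K) formation interval per complex
    n: int

    def activity_table(self) -> ActivityTable:
        """Ground-truth activity without going through expression curves."""
        return ActivityTable(active=dict(self.activity_targets), n=self.n)


def _schedule(members: list[str], ov_min: float, n: int, rng: np.random.Generator):
    """Per-time-point member subsets following a just-in-time schedule.

    With ov_min > 0 the schedule drops the longest-present member and
    adds one new member per step, so consecutive subsets of size ``s``
    overlap at (s-1)/s >= ov_min; with ov_min = 0 the interval is two
    disjoint halves (not formable: no step docks onto the assembly).
    """
    m = len(members)
    if ov_min == 0.0:
        half = (m + 1) // 2
        schedule = [list(members[:half]), list(members[half:])]
    else:
        s_min = m if ov_min >= 1.0 else max(2, math.ceil(1.0 / (1.0 - ov_min)))
        L = max(1, min(m - s_min + 1, 4, n - 2))
        s = m - (L - 1)
        current = list(members[:s])
        schedule = [list(current)]
        for t in range(1, L):
            current = current[1:] + [members[s + t - 1]]
            schedule.append(list(current))
    L = len(schedule)
    S = int(rng.integers(1, n - L + 2))
    return S, schedule


def generate_planted_catalog(
    n_complexes: int,
    size_range: tuple[int, int] = (3, 8),
    n: int = 12,
    ov_min: float = 0.7,
    seed: int | None = None,
    n_decoys_per_complex: int = 3,
    n_background: int = 20,
) -> SyntheticBenchmark:
    """Plant just-in-time complexes in a network with decoy neighbours.

    Each complex is a clique whose members' activity windows follow a
    contiguous schedule with consecutive overlap >= ``ov_min``; each also
    gets ``n_decoys_per_complex`` neighbour proteins active only outside
    the complex's formation interval (contamination candidates), and the
    network carries extra background proteins as distractors.  Complexes
    share no proteins, so recovery checks are unambiguous.
    """
    if not 0.0 <= ov_min <= 1.0:
        raise ValueError("ov_min must be in [0, 1]")
    if size_range[0] < 3:
        raise ValueError("planted complexes must have size >= 3")
    if n < 4:
        raise ValueError("need at least 4 time points to place decoys")
    rng = np.random.default_rng(seed)
    network = nx.Graph()
    targets: dict[str, frozenset[int]] = {}
    complexes: list[frozenset[str]] = []
    decoys: dict[int, list[str]] = {}
    intervals: list[tuple[int, int]] = []
    pid = 0

    def fresh() -> str:
        nonlocal pid
        pid += 1
        return f"P{pid:05d}"

    for ci in range(n_complexes):
        m = int(rng.integers(size_range[0], size_range[1] + 1))
        members = [fresh() for _ in range(m)]
        S, schedule = _schedule(members, ov_min, n, rng)
        L = len(schedule)
        intervals.append((S, L - 1))
        windows: dict[str, set[int]] = {p: set() for p in members}
        for off, ap in enumerate(schedule):
            for p in ap:
                windows[p].add(S + off)
        for p in members:
            targets[p] = frozenset(windows[p])
        network.add_edges_from(
            (members[i], members[j]) for i in range(m) for j in range(i + 1, m)
        )
        complexes.append(frozenset(members))
        # decoy neighbours: adjacent to the complex but never co-active with it
        outside = sorted(set(range(1, n + 1)) - set(range(S, S + L)))
        decoys[ci] = []
        for _ in range(n_decoys_per_complex):
            q = fresh()
            anchor = members[int(rng.integers(0, m))]
            network.add_edge(q, anchor)
            n_pts = int(rng.integers(1, min(2, len(outside)) + 1))
            pts = rng.choice(outside, size=n_pts, replace=False)
            targets[q] = frozenset(int(t) for t in pts)
            decoys[ci].append(q)

    background = [fresh() for _ in range(n_background)]
    for q in background:
        other = background[int(rng.integers(0, len(background)))]
        if other == q:
            other = background[(background.index(q) + 1) % len(background)]
        network.add_edge(q, other)
        if rng.random() < 0.2:
            targets[q] = frozenset({WILDCARD})
        else:
            n_pts = int(rng.integers(1, 4))
            pts = rng.choice(np.arange(1, n + 1), size=n_pts, replace=False)
            targets[q] = frozenset(int(t) for t in pts)

    return SyntheticBenchmark(
        network=network,
        catalog=ComplexCatalog(complexes, label="planted"),
        activity_targets=targets,
        decoys=decoys,
        intervals=intervals,
        n=n,
    )


def contaminate(
    catalog: ComplexCatalog,
    network: Network,
    activity: ActivityTable,
    k_spurious: int | tuple[int, int] = 1,
    seed: int | None = None,
) -> ComplexCatalog:
    """Add spurious members to every complex of a catalog.

    Each complex gains up to ``k_spurious`` proteins (an int, or an
    inclusive ``(lo, hi)`` range sampled per complex) that are adjacent
    to some member in the network — so the contaminated induced subgraph
    stays connected — but whose active time points are disjoint from all
    members' active points (and not wildcard).  Complexes with no
    eligible contaminant are kept unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    if isinstance(k_spurious, tuple):
        lo, hi = k_spurious
    else:
        lo = hi = int(k_spurious)
    if lo < 0 or hi < lo:
        raise ValueError("invalid k_spurious")
    out: list[frozenset[str]] = []
    for idx, members in enumerate(catalog):
        member_times: set[int] = set()
        for p in members:
            member_times |= set(activity.get(p)) - {WILDCARD}
        neighbours = sorted(
            {
                q
                for p in members
                if p in network
                for q in network.neighbors(p)
            }
            - set(members)
        )
        eligible = [
            q
            for q in neighbours
            if not activity.is_wildcard(q) and not (set(activity.get(q)) & member_times)
        ]
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        if k == 0:
            out.append(members)
            continue
        if not eligible:
            warnings.warn(f"complex {idx}: no eligible contaminant, skipped", stacklevel=2)
            out.append(members)
            continue
        chosen = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
        out.append(members | {str(q) for q in chosen})
    return ComplexCatalog(out, label=f"{catalog.label}#contaminated")
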