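"""Split/assemble refinement of predicted protein complexes.

Splitting restricts a predicted complex to the members active at each
time point of its active time set and takes connected components of the
complex's induced subgraph there, yielding per-time-point sub-clusters.
Assembling re-joins sub-clusters across *adjacent* time points whenever
their overlap ``OV(a, b) = |a ∩ b| / min(|a|, |b|)`` reaches a threshold
``T``; sub-clusters at the wildcard time point 0 may join a sub-cluster
at any time point.  Members never co-active with the rest of the complex
end up in small unmerged sub-clusters and are dropped, so refinement
removes spurious proteins and can emit several new complexes per input.

Processing order is canonical everywhere (time ascending, then sorted
member list), so refinement is deterministic: the same inputs produce
byte-identical catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from jitrefine.activity import WILDCARD, ActivityTable
from jitrefine.io import ComplexCatalog, Network


@dataclass(frozen=True)
class SubCluster:
    """A connected set of complex members co-active at one time point."""

    time: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("sub-cluster must be non-empty")


@dataclass
class RefinementConfig:
    """Tunables of the refinement.

    T
        Overlap threshold in [0, 1] above which adjacent sub-clusters
        merge; default 0.6 (just above the typical co-active rate of
        curated complexes, ~0.5-0.6).
    min_refine_size
        Complexes smaller than this pass through unchanged (default 3:
        splitting a pair can only yield itself or two singletons).
    min_output_size
        Final complexes smaller than this are dropped (default 2;
        reference catalogs consist of two or more proteins).
    """

    T: float = 0.6
    min_refine_size: int = 3
    min_output_size: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must be in [0, 1]")
        if self.min_refine_size < 3:
            raise ValueError("min_refine_size must be >= 3")


def active_time_set(complex_: Iterable[str], activity: ActivityTable) -> frozenset[int]:
    """Union of the members' active time point sets (may include 0)."""
    out: set[int] = set()
    for p in complex_:
        out |= activity.get(p)
    return frozenset(out)


def cluster_overlap(a: Iterable[str], b: Iterable[str]) -> float:
    """OV(a, b) = |a ∩ b| / min(|a|, |b|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("cluster overlap of an empty set is undefined")
    return len(a & b) / min(len(a), len(b))


def split_complex(
    complex_: Iterable[str],
    network: Network,
    activity: ActivityTable,
) -> list[SubCluster]:
    """Split a complex into per-time-point connected sub-clusters.

    For each time point ``t`` of the complex's active time set, members
    not active at ``t`` are removed and each connected component of what
    remains (in the complex's induced subgraph of the full network)
    becomes a sub-cluster; ``t = 0`` collects the wildcard members.
    Members absent from the network are isolated vertices and yield
    singleton sub-clusters; singletons are kept at this stage.
    """
    members = frozenset(complex_)
    induced = nx.Graph()
    induced.add_nodes_from(members)
    induced.add_edges_from(
        (u, v) for u, v in network.subgraph(members & set(network.nodes)).edges()
    )
    out: list[SubCluster] = []
    for t in sorted(active_time_set(members, activity)):
        if t == WILDCARD:
            present = {p for p in members if activity.get(p) == {WILDCARD}}
        else:
            present = {p for p in members if t in activity.get(p)}
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(induced.subgraph(present))),
            key=lambda c: sorted(c),
        )
        out.extend(SubCluster(time=t, members=c) for c in comps)
    return out


def assemble(
    subclusters: Iterable[SubCluster],
    T: float = 0.6,
    min_output_size: int = 2,
) -> list[frozenset[str]]:
    """Assemble sub-clusters across adjacent time points into complexes.

    Wildcard phase: each time-0 sub-cluster is unioned into every
    sub-cluster at a real time point it overlaps at >= T; time-0
    sub-clusters that combined at least once are then deleted (unmerged
    ones survive as candidates).

    Temporal sweep: for each real time point ``i`` ascending, each
    sub-cluster at ``i`` is unioned into every sub-cluster at ``i + 1``
    it overlaps at >= T; sub-clusters that combined are deleted after
    time ``i`` is processed, so unions cascade forward one pass.

    The surviving sub-clusters become candidate complexes; those below
    ``min_output_size`` are dropped and identical sets deduplicated
    (first occurrence kept).
    """
    groups: dict[int, list[set[str]]] = {}
    for sc in subclusters:
        groups.setdefault(sc.time, []).append(set(sc.members))
    for t in groups:
        groups[t].sort(key=lambda c: sorted(c))
    real_times = sorted(t for t in groups if t != WILDCARD)

    # wildcard phase
    zero_survivors: list[set[str]] = []
    for z in groups.pop(WILDCARD, []):
        zf = frozenset(z)
        combined = False
        for t in real_times:
            for target in groups[t]:
                if cluster_overlap(zf, target) >= T:
                    target |= zf
                    combined = True
        if not combined:
            zero_survivors.append(z)

    # temporal sweep over adjacent pairs (i, i+1); no wrap-around
    for i in real_times:
        targets = groups.get(i + 1)
        if targets is None:
            continue
        survivors: list[set[str]] = []
        for src in groups[i]:
            combined = False
            for target in targets:
                if cluster_overlap(src, target) >= T:
                    target |= src
                    combined = True
            if not combined:
                survivors.append(src)
        groups[i] = survivors

    candidates = zero_survivors + [c for t in real_times for c in groups[t]]
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for c in candidates:
        cf = frozenset(c)
        if len(cf) >= min_output_size and cf not in seen:
            seen.add(cf)
            out.append(cf)
    return out


def refine_complex(
    complex_: Iterable[str],
    network: Network,
    activity: ActivityTable,
    config: RefinementConfig | None = None,
) -> list[frozenset[str]]:
    """Split then assemble one predicted complex."""
    config = config or RefinementConfig()
    return assemble(
        split_complex(complex_, network, activity),
        T=config.T,
        min_output_size=config.min_output_size,
    )


def refine_catalog(
    catalog: ComplexCatalog,
    network: Network,
    activity: ActivityTable,
    config: RefinementConfig | None = None,
) -> ComplexCatalog:
    """Refine every complex of a catalog and deduplicate the results.

    Complexes below ``min_refine_size`` pass through unchanged; the
    concatenated outputs are globally deduplicated by set equality,
    preserving first-occurrence order.
    """
    config = config or RefinementConfig()
    refined: list[frozenset[str]] = []
    for c in catalog:
        if len(c) < config.min_refine_size:
            refined.append(c)
        else:
            refined.extend(refine_complex(c, network, activity, config))
    return ComplexCatalog(refined, label=f"{catalog.label}#refined").deduplicated()
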