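"""Readers and writers for the three plain-text input formats.

Formats
-------
Edge list
    Two whitespace-separated protein identifier columns per line; extra
    columns (confidence scores, annotations) are ignored; ``#`` starts a
    comment line.  Self-interactions and repeated pairs (in either
    orientation) are discarded on read.
Expression matrix
    TSV with a header row; first column is the gene identifier, the
    remaining columns are samples in cycle-major time order (t1..tn of
    cycle 1, then cycle 2, ...).  Reading averages the cycles down to a
    single cycle of ``n = samples / cycles`` time points.
Complex catalog
    One complex per line as whitespace-separated protein identifiers.

Identifiers are opaque, case-sensitive strings; no name normalisation is
applied.  All containers iterate in a deterministic canonical order:
proteins lexicographically, complexes in input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

Network = nx.Graph  # undirected simple graph over protein identifiers


@dataclass
class ExpressionProfile:
    """Cycle-averaged expression curves, one gene per row.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with ``n`` columns (the
        1-based time points of one cycle), finite floats.
    samples
        Optional raw sample matrix (genes x n*cycles) the profile was
        averaged from; kept so synthetic data can be serialised in the
        same layout real exports use.
    """

    values: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("expression profile needs at least 2 time points")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.values.columns = range(1, self.values.shape[1] + 1)

    @property
    def n(self) -> int:
        """Number of time points per cycle."""
        return self.values.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    def vector(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def subset(self, genes: Iterable[str]) -> "ExpressionProfile":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionProfile(self.values.loc[keep].copy())

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, cycles: int) -> "ExpressionProfile":
        """Average a raw sample matrix over ``cycles`` successive cycles.

        Entry ``i`` of the result is the arithmetic mean of samples
        ``i, i+n, i+2n, ...`` (cycle-major layout).
        """
        if cycles < 1:
            raise ValueError("cycles must be >= 1")
        n_samples = samples.shape[1]
        if n_samples % cycles != 0:
            raise ValueError(
                f"sample count {n_samples} is not divisible by cycles={cycles}"
            )
        n = n_samples // cycles
        arr = samples.to_numpy(dtype=float).reshape(len(samples), cycles, n)
        mean = pd.DataFrame(arr.mean(axis=1), index=samples.index)
        return cls(mean, samples=samples.copy())


@dataclass
class ComplexCatalog:
    """Ordered list of protein complexes (non-empty protein sets)."""

    complexes: list[frozenset[str]]
    label: str = ""

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be non-empty")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def deduplicated(self, label: str | None = None) -> "ComplexCatalog":
        """Drop repeated member sets, keeping first occurrences in order."""
        seen: set[frozenset[str]] = set()
        uniq = []
        for c in self.complexes:
            if c not in seen:
                seen.add(c)
                uniq.append(c)
        return ComplexCatalog(uniq, label=label if label is not None else self.label)


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | Path) -> Network:
    """Read an undirected PPIN from a two-column edge list.

    Self-loops are dropped and duplicate pairs (including reversed
    orientation) collapse to a single edge.  The node set is the union of
    endpoints of the surviving edges.
    """
    g = nx.Graph()
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"{path}: line {lineno}: expected at least 2 columns")
        a, b = tokens[0], tokens[1]
        if a == b:
            continue  # self-interaction
        g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges")
    return g


def write_network(network: Network, path: str | Path, header: str | None = None) -> None:
    """Write an edge list in canonical order (sorted endpoint pairs)."""
    edges = sorted(tuple(sorted(e)) for e in network.edges())
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_expression(path: str | Path, cycles: int = 3) -> ExpressionProfile:
    """Read a gene x sample TSV and average the cycles to one cycle."""
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a header row and >= 2 sample columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ValueError(f"{path}: non-numeric value for gene {gene!r}, column {col!r}")
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value for gene {gene!r}")
    numeric.index = numeric.index.astype(str)
    return ExpressionProfile.from_samples(numeric, cycles=cycles)


def write_expression(profile: ExpressionProfile, path: str | Path, header: str | None = None) -> None:
    """Write the raw sample matrix (or the averaged cycle if none kept)."""
    table = profile.samples if profile.samples is not None else profile.values
    table = table.copy()
    table.columns = [f"T{j:02d}" for j in range(1, table.shape[1] + 1)]
    table.index.name = "gene"
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", float_format="%.6g")


def read_complexes(path: str | Path, label: str | None = None) -> ComplexCatalog:
    """Read a catalog: one complex per line, members whitespace-separated.

    Within-line duplicate identifiers collapse to one (with a warning);
    blank lines are skipped; line order is preserved.
    """
    complexes: list[frozenset[str]] = []
    for lineno, line in _data_lines(path):
        tokens = line.split()
        members = frozenset(tokens)
        if len(members) < len(tokens):
            warnings.warn(
                f"{path}: line {lineno}: duplicate identifiers within a complex collapsed",
                stacklevel=2,
            )
        complexes.append(members)
    return ComplexCatalog(complexes, label=label if label is not None else str(path))


def write_complexes(catalog: ComplexCatalog, path: str | Path, header: str | None = None) -> None:
    """Write one complex per line, members sorted lexicographically."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for c in catalog:
            fh.write(" ".join(sorted(c)) + "\n")
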