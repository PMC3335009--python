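"""County adjacency structures and the CAR prior precision they induce.

Adjacency between regions (counties) drives the structured spatial term of
the models in :mod:`starpanel.star_model`: conditional on its neighbors, a
county's structured effect is normal with mean equal to the neighbor average
and variance inversely proportional to the neighbor count.  The unscaled
precision of that intrinsic conditional autoregressive (CAR) prior is the
graph Laplacian assembled by :func:`car_precision`.

Graphs are read and written in the plain-text GAL spatial-weights format, or
read from a two-column edge-list CSV.  Region identifiers are opaque strings
(FIPS codes pass through unchanged); county order is file order and is
preserved everywhere downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "GalFormatError",
    "read_gal",
    "write_gal",
    "read_edge_csv",
    "car_precision",
    "connected_components",
]


class GalFormatError(ValueError):
    """Raised when a GAL file or edge list violates the adjacency contract."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbor structure over an ordered set of counties.

    Attributes
    ----------
    county_ids
        Ordered region identifiers; the ordering fixes row/column order of
        every matrix built from the graph.
    neighbors
        Per-county frozenset of neighboring county *indices* (positions in
        ``county_ids``).
    """

    county_ids: tuple[str, ...]
    neighbors: tuple[frozenset[int], ...] = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.county_ids)
        if len(set(self.county_ids)) != n:
            raise GalFormatError("duplicate county ids")
        if len(self.neighbors) != n:
            raise GalFormatError("neighbors length does not match county_ids")
        for c, omega in enumerate(self.neighbors):
            if c in omega:
                raise GalFormatError(f"self-loop at county {self.county_ids[c]!r}")
            for cp in omega:
                if not 0 <= cp < n:
                    raise GalFormatError(
                        f"neighbor index {cp} out of range for county "
                        f"{self.county_ids[c]!r}"
                    )
                if c not in self.neighbors[cp]:
                    raise GalFormatError(
                        "asymmetric adjacency: "
                        f"{self.county_ids[cp]!r} is a neighbor of "
                        f"{self.county_ids[c]!r} but not conversely"
                    )

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def neighbor_count(self) -> np.ndarray:
        """N_c = |omega_c| for every county (0 for islands)."""
        return np.array([len(omega) for omega in self.neighbors], dtype=int)

    @property
    def islands(self) -> list[int]:
        """Indices of counties with no neighbors."""
        return [c for c, omega in enumerate(self.neighbors) if not omega]

    def index_of(self, county_id: str) -> int:
        return self.county_ids.index(county_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_counties))
        for c, omega in enumerate(self.neighbors):
            g.add_edges_from((c, cp) for cp in omega if cp > c)
        return g

    @classmethod
    def from_edges(
        cls, county_ids: list[str] | tuple[str, ...], edges: list[tuple[int, int]]
    ) -> "AdjacencyGraph":
        """Build a graph from index pairs; edges are symmetrized."""
        n = len(county_ids)
        omega: list[set[int]] = [set() for _ in range(n)]
        for a, b in edges:
            if a == b:
                raise GalFormatError(f"self-loop edge ({a}, {b})")
            omega[a].add(b)
            omega[b].add(a)
        return cls(tuple(county_ids), tuple(frozenset(s) for s in omega))


def read_gal(path) -> AdjacencyGraph:
    """Read a GAL spatial-weights file.

    The header is either a bare region count or the 4-token
    ``0 <count> <shapefile> <idvar>`` variant; each region then contributes
    an ``<id> <n_neighbors>`` line followed by a line of neighbor ids (blank
    or absent when the region is an island).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines = raw  # blank lines kept: islands may have empty neighbor rows
    if not lines or not lines[0].strip():
        raise GalFormatError(f"{path}: missing GAL header")
    head = lines[0].split()
    try:
        n = int(head[1]) if len(head) > 1 else int(head[0])
    except ValueError as exc:
        raise GalFormatError(f"{path}: malformed header {lines[0]!r}") from exc

    ids: list[str] = []
    raw_neighbors: list[list[str]] = []
    pos = 1
    for _ in range(n):
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            raise GalFormatError(f"{path}: truncated file, expected {n} regions")
        header = lines[pos].split()
        if len(header) != 2:
            raise GalFormatError(
                f"{path}, line {pos + 1}: expected '<id> <n_neighbors>', got "
                f"{lines[pos]!r}"
            )
        rid, count_s = header
        try:
            count = int(count_s)
        except ValueError as exc:
            raise GalFormatError(
                f"{path}, line {pos + 1}: bad neighbor count {count_s!r}"
            ) from exc
        pos += 1
        if count == 0:
            # island: neighbor line may be blank or omitted entirely
            if pos < len(lines) and not lines[pos].strip():
                pos += 1
            nbrs: list[str] = []
        else:
            if pos >= len(lines):
                raise GalFormatError(f"{path}: missing neighbor line for {rid!r}")
            nbrs = lines[pos].split()
            if len(nbrs) != count:
                raise GalFormatError(
                    f"{path}, line {pos + 1}: region {rid!r} declares {count} "
                    f"neighbors but lists {len(nbrs)}"
                )
            pos += 1
        ids.append(rid)
        raw_neighbors.append(nbrs)

    index = {rid: i for i, rid in enumerate(ids)}
    omega = []
    for rid, nbrs in zip(ids, raw_neighbors):
        idx = set()
        for nb in nbrs:
            if nb not in index:
                raise GalFormatError(f"{path}: unknown neighbor id {nb!r} of {rid!r}")
            idx.add(index[nb])
        omega.append(frozenset(idx))
    try:
        return AdjacencyGraph(tuple(ids), tuple(omega))
    except GalFormatError as exc:
        raise GalFormatError(f"{path}: {exc}") from exc


def write_gal(graph: AdjacencyGraph, path) -> None:
    """Write ``graph`` in GAL format so that :func:`read_gal` inverts it."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{graph.n_counties}\n")
        for c, omega in enumerate(graph.neighbors):
            fh.write(f"{graph.county_ids[c]} {len(omega)}\n")
            fh.write(" ".join(graph.county_ids[cp] for cp in sorted(omega)) + "\n")


def read_edge_csv(path, county_ids: list[str] | None = None) -> AdjacencyGraph:
    """Read adjacency from a 2-column ``from_id,to_id`` edge-list CSV.

    One-directional edges are symmetrized with a warning.  ``county_ids``
    fixes the county universe and order; when omitted, counties appear in
    first-occurrence order and isolated counties cannot be represented.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise GalFormatError(f"{path}: edge list needs 2 columns, got {df.shape[1]}")
    a_col, b_col = df.columns[:2]
    if county_ids is None:
        seen: dict[str, None] = {}
        for rid in pd.concat([df[a_col], df[b_col]]):
            seen.setdefault(rid)
        county_ids = list(seen)
    index = {rid: i for i, rid in enumerate(county_ids)}
    pairs = set()
    for a, b in zip(df[a_col], df[b_col]):
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise GalFormatError(f"{path}: edge references unknown county {missing!r}")
        if a == b:
            raise GalFormatError(f"{path}: self-loop edge for county {a!r}")
        pairs.add((index[a], index[b]))
    one_way = {(a, b) for a, b in pairs if (b, a) not in pairs}
    if one_way:
        warnings.warn(
            f"{len(one_way)} one-directional edge(s) symmetrized on read",
            stacklevel=2,
        )
    return AdjacencyGraph.from_edges(county_ids, sorted(pairs))


def car_precision(graph: AdjacencyGraph) -> sparse.csr_matrix:
    """Unscaled intrinsic-CAR precision Q (the graph Laplacian).

    ``Q[c, c] = N_c`` and ``Q[c, c'] = -1`` for neighbors.  The implied full
    conditional of the structured effect s_c given its neighbors is normal
    with mean the neighbor average and variance ``sigma2_str / N_c``.
    Islands yield an all-zero row; their structured effect is fixed at zero
    at sampling time.
    """
    n = graph.n_counties
    rows, cols, vals = [], [], []
    for c, omega in enumerate(graph.neighbors):
        rows.append(c)
        cols.append(c)
        vals.append(float(len(omega)))
        for cp in omega:
            rows.append(c)
            cols.append(cp)
            vals.append(-1.0)
    if graph.islands:
        logger.warning(
            "graph has %d island(s); their structured effect is fixed at 0",
            len(graph.islands),
        )
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def connected_components(graph: AdjacencyGraph) -> list[list[int]]:
    """Partition county indices into connected components.

    Islands form singleton components.  Components are ordered by their
    smallest member, members ascending, so the partition is deterministic.
    """
    comps = nx.connected_components(graph.to_networkx())
    return sorted((sorted(comp) for comp in comps), key=lambda c: c[0])
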