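"""Core domain types and I/O for species-habitat networks.

A species-habitat network starts from a single site x species abundance
matrix: integer counts of individuals of each species observed at each
habitat patch, with every patch carrying exactly one habitat label. From
it we derive

* a **bipartite** weighted network (patch nodes, species nodes, links
  weighted by abundance), and
* a **unipartite** projection (patch nodes only, two patches linked with
  weight equal to the number of species they share).

The CSV dialect is the one used for published species-habitat tables:
first column the site identifier, second column the habitat type, one
further column per species, integer cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "BipartiteNetwork",
    "UnipartiteNetwork",
    "Partition",
    "NullEnsemble",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "build_bipartite",
    "project_unipartite",
    "export_graph",
    "read_graph",
]


class MatrixFormatError(ValueError):
    """Raised when an abundance table violates the expected dialect."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """Validated site x species integer count matrix with habitat labels.

    Parameters
    ----------
    site_ids:
        Ordered unique site (patch) labels, one per row of ``counts``.
    habitat_of:
        Mapping from site label to its habitat type.
    species_ids:
        Ordered unique species labels, one per column of ``counts``.
    counts:
        Non-negative integer matrix, ``counts[i, j]`` = individuals of
        species ``j`` observed at site ``i`` (pooled over sampling rounds).
    """

    site_ids: tuple[str, ...]
    habitat_of: Mapping[str, str]
    species_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise MatrixFormatError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise MatrixFormatError(
                    f"non-integer count at site {self.site_ids[bad[0]]!r}, "
                    f"species {self.species_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise MatrixFormatError(
                f"negative count at site {self.site_ids[i]!r}, "
                f"species {self.species_ids[j]!r}"
            )
        object.__setattr__(self, "site_ids", tuple(map(str, self.site_ids)))
        object.__setattr__(self, "species_ids", tuple(map(str, self.species_ids)))
        if len(set(self.site_ids)) != len(self.site_ids):
            raise MatrixFormatError("duplicate site labels")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise MatrixFormatError("duplicate species labels")
        if counts.shape != (len(self.site_ids), len(self.species_ids)):
            raise MatrixFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        missing = [s for s in self.site_ids if s not in self.habitat_of]
        if missing:
            raise MatrixFormatError(f"missing habitat label for site(s) {missing}")
        object.__setattr__(
            self, "habitat_of", {s: str(self.habitat_of[s]) for s in self.site_ids}
        )
        if counts.size and (counts.sum(axis=1) == 0).any():
            empty = [s for s, t in zip(self.site_ids, counts.sum(axis=1)) if t == 0]
            raise MatrixFormatError(
                f"site(s) with zero total abundance: {empty}; "
                "drop them with drop_empty() or fix the input"
            )
        if counts.size and (counts.sum(axis=0) == 0).any():
            empty = [s for s, t in zip(self.species_ids, counts.sum(axis=0)) if t == 0]
            raise MatrixFormatError(
                f"species never observed: {empty}; "
                "drop them with drop_empty() or fix the input"
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def total_individuals(self) -> int:
        return int(self.counts.sum())

    @property
    def habitats(self) -> tuple[str, ...]:
        """Habitat label per site, aligned with ``site_ids``."""
        return tuple(self.habitat_of[s] for s in self.site_ids)

    def is_binary(self) -> bool:
        return bool(np.isin(self.counts, (0, 1)).all())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.species_ids))
        df.insert(0, "habitat", list(self.habitats))
        df.insert(0, "site", list(self.site_ids))
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        site_col: str = "site",
        habitat_col: str = "habitat",
        drop_empty: bool = False,
    ) -> "AbundanceMatrix":
        for col in (site_col, habitat_col):
            if col not in df.columns:
                raise MatrixFormatError(
                    f"expected column {col!r}; found {list(df.columns[:5])}..."
                )
        species = [c for c in df.columns if c not in (site_col, habitat_col)]
        if not species:
            raise MatrixFormatError("no species columns found")
        sites = df[site_col].astype(str).tolist()
        if df[habitat_col].isna().any():
            bad = df.loc[df[habitat_col].isna(), site_col].tolist()
            raise MatrixFormatError(f"missing habitat label for site(s) {bad}")
        habitat_of = dict(zip(sites, df[habitat_col].astype(str)))
        try:
            counts = df[species].to_numpy(dtype=float)
        except ValueError as exc:
            raise MatrixFormatError(f"non-numeric count cell: {exc}") from exc
        if np.isnan(counts).any():
            i, j = np.argwhere(np.isnan(counts))[0]
            raise MatrixFormatError(
                f"missing count at site {sites[i]!r}, species {species[j]!r}"
            )
        if drop_empty:
            keep_r = counts.sum(axis=1) > 0
            keep_c = counts.sum(axis=0) > 0
            if not keep_r.all() or not keep_c.all():
                warnings.warn(
                    f"dropping {int((~keep_r).sum())} empty site(s) and "
                    f"{int((~keep_c).sum())} unobserved species",
                    stacklevel=2,
                )
            sites = [s for s, k in zip(sites, keep_r) if k]
            species = [s for s, k in zip(species, keep_c) if k]
            counts = counts[np.ix_(keep_r, keep_c)]
        mat = cls(tuple(sites), habitat_of, tuple(species), counts)
        if mat.is_binary() and mat.counts.size > 4:
            warnings.warn(
                "matrix is binary (0/1): abundance-weighted metrics "
                "(weighted NODF, Barber modularity weights) degenerate on "
                "incidence data",
                stacklevel=2,
            )
        return mat


def read_abundance_matrix(
    path: str | Path,
    site_col: str = "site",
    habitat_col: str = "habitat",
    drop_empty: bool = False,
) -> AbundanceMatrix:
    """Read a site x species abundance CSV (site id, habitat, species...)."""
    df = pd.read_csv(path)
    return AbundanceMatrix.from_dataframe(
        df, site_col=site_col, habitat_col=habitat_col, drop_empty=drop_empty
    )


def write_abundance_matrix(mat: AbundanceMatrix, path: str | Path) -> None:
    mat.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class BipartiteNetwork:
    """Weighted two-mode network: habitat patches vs species.

    ``weights[i, s]`` is the abundance of species ``s`` at patch ``i``; a
    zero cell means no link. Row strengths ``s_i``, column strengths
    ``t_s`` and the grand total ``W`` are the quantities entering Barber's
    bipartite modularity.
    """

    patch_nodes: tuple[str, ...]
    species_nodes: tuple[str, ...]
    weights: np.ndarray
    habitat_of: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_links(self) -> int:
        return int((self.weights > 0).sum())

    @property
    def row_strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_strengths(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())


def build_bipartite(mat: AbundanceMatrix) -> BipartiteNetwork:
    """Build the weighted bipartite patch-species network from counts."""
    if mat.counts.size == 0:
        raise ValueError("cannot build a network from an empty matrix")
    return BipartiteNetwork(
        patch_nodes=mat.site_ids,
        species_nodes=mat.species_ids,
        weights=mat.counts.copy(),
        habitat_of=dict(mat.habitat_of),
    )


@dataclass(frozen=True)
class UnipartiteNetwork:
    """One-mode patch network; edge weight = number of shared species.

    ``weights`` is a symmetric integer matrix with zero diagonal; a zero
    off-diagonal cell means the two patches share no species (no edge).
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    habitat_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node count")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.diagonal(w).any():
            raise ValueError("self-edges are not allowed")

    @property
    def degrees(self) -> np.ndarray:
        """k_i: number of incident edges with weight > 0."""
        return (self.weights > 0).sum(axis=1)

    @property
    def strengths(self) -> np.ndarray:
        """s_i: sum of incident edge weights."""
        return self.weights.sum(axis=1)

    def edges(self) -> Iterable[tuple[str, str, int]]:
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                if w > 0:
                    yield self.nodes[i], self.nodes[j], int(w)

    def to_igraph(self):
        import igraph as ig

        edges = list(self.edges())
        g = ig.Graph()
        g.add_vertices(len(self.nodes))
        g.vs["name"] = list(self.nodes)
        if self.habitat_of:
            g.vs["habitat"] = [self.habitat_of.get(n, "") for n in self.nodes]
        idx = {n: i for i, n in enumerate(self.nodes)}
        g.add_edges([(idx[a], idx[b]) for a, b, _ in edges])
        g.es["weight"] = [w for _, _, w in edges]
        return g


def project_unipartite(net: BipartiteNetwork) -> UnipartiteNetwork:
    """Project the bipartite network onto patches.

    Two patches are linked iff at least one species occurs (count > 0) at
    both; the edge weight is the number of such shared species
    (presence-based, not abundance-based).
    """
    presence = (net.weights > 0).astype(np.int64)
    shared = presence @ presence.T
    np.fill_diagonal(shared, 0)
    return UnipartiteNetwork(
        nodes=net.patch_nodes,
        weights=shared,
        habitat_of=dict(net.habitat_of),
    )


@dataclass(frozen=True)
class Partition:
    """Assignment of nodes to communities/modules with its quality score."""

    assignment: Mapping[str, int]
    quality: float
    algorithm: str
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(len(ids))):
            # relabel to contiguous ids starting at 0, stable in first-seen order
            remap: dict[int, int] = {}
            new = {}
            for node in self.assignment:
                c = self.assignment[node]
                if c not in remap:
                    remap[c] = len(remap)
                new[node] = remap[c]
            object.__setattr__(self, "assignment", new)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def membership(self, nodes: Sequence[str]) -> list[int]:
        missing = [n for n in nodes if n not in self.assignment]
        if missing:
            raise KeyError(f"partition missing node(s): {missing}")
        return [self.assignment[n] for n in nodes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.assignment), "community": list(self.assignment.values())}
        )


@dataclass(frozen=True)
class NullEnsemble:
    """Null distribution of one statistic over fixed-margin randomizations."""

    statistic: str
    null_values: np.ndarray
    observed: float
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.null_values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def sd(self) -> float:
        # population sd of the null values
        return float(np.std(self.null_values))

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    @property
    def z(self) -> float:
        """(observed - null mean) / null sd; NaN when the null is degenerate."""
        if self.degenerate:
            return float("nan")
        return (self.observed - self.mean) / self.sd


# -- graph export ---------------------------------------------------------


def _to_networkx(net: BipartiteNetwork | UnipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    if isinstance(net, BipartiteNetwork):
        for p in net.patch_nodes:
            g.add_node(p, mode="patch", habitat=net.habitat_of.get(p, ""))
        for s in net.species_nodes:
            g.add_node(s, mode="species")
        rows, cols = np.nonzero(net.weights)
        for i, j in zip(rows, cols):
            g.add_edge(
                net.patch_nodes[i], net.species_nodes[j], weight=int(net.weights[i, j])
            )
    else:
        for p in net.nodes:
            g.add_node(p, mode="patch", habitat=net.habitat_of.get(p, ""))
        for a, b, w in net.edges():
            g.add_edge(a, b, weight=w)
    return g


def export_graph(
    net: BipartiteNetwork | UnipartiteNetwork,
    path: str | Path,
    fmt: str = "edgelist",
) -> None:
    """Write a network as a TSV weighted edge list or GraphML.

    Both formats round-trip node labels, habitat attributes and integer
    edge weights.
    """
    g = _to_networkx(net)
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for a, b, data in sorted(g.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data['weight']}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def read_graph(path: str | Path, fmt: str = "edgelist") -> nx.Graph:
    path = Path(path)
    if fmt == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                a, b, w = line.rstrip("\n").split("\t")
                g.add_edge(a, b, weight=int(w))
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unsupported format {fmt!r}")
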