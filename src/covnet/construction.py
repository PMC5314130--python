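"""Association matrices and density thresholding.

For each group, the association matrix R holds the Pearson correlation
r_ij of regional gray-matter volumes between regions i and j across that
group's subjects.  Binary undirected graphs are obtained by keeping, at a
target density D, exactly the E = round(D * N(N-1)/2) largest off-diagonal
correlations (signed, not absolute), so both groups are always compared at
identical edge counts.

Tie handling and rounding are pinned so edge counts and edge sets are
bit-reproducible: ties in r are broken by lexicographic (i, j) node-index
order, and E uses round-half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SubjectVolumeTable
from .exceptions import DegenerateDataError, InputValidationError
from .grid import DensityGrid


@dataclass
class AssociationMatrix:
    """Symmetric region x region Pearson correlation matrix for one group.

    The diagonal is stored as 0 and never used: self-connections are
    excluded from the analysis.
    """

    r: np.ndarray
    region_names: list
    group_label: str
    n_subjects: int

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise InputValidationError("association matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise InputValidationError("association matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise InputValidationError("correlations must lie in [-1, 1]")
        np.fill_diagonal(self.r, 0.0)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.region_names, columns=self.region_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.10g")


@dataclass
class BinaryGraph:
    """Undirected, unweighted adjacency at one network density."""

    adjacency: np.ndarray
    density: float
    n_edges: int = field(default=None)
    connected: bool = field(default=None)
    region_names: list | None = None

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if not np.array_equal(adj, adj.T):
            raise InputValidationError("adjacency must be symmetric (undirected)")
        adj = (adj != 0).astype(np.uint8)
        np.fill_diagonal(adj, 0)
        self.adjacency = adj
        edges = int(adj.sum()) // 2
        if self.n_edges is None:
            self.n_edges = edges
        elif self.n_edges != edges:
            raise InputValidationError(
                f"edge count mismatch: stated {self.n_edges}, actual {edges}")
        if self.connected is None:
            self.connected = is_connected(adj)

    @classmethod
    def from_adjacency(cls, adj, region_names=None) -> "BinaryGraph":
        adj = np.asarray(adj)
        n = adj.shape[0]
        pairs = n * (n - 1) // 2
        edges = int((adj != 0).sum()) // 2
        density = edges / pairs if pairs else 0.0
        return cls(adjacency=adj, density=density, region_names=region_names)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_csv(self, path) -> None:
        names = self.region_names or [f"N{i}" for i in range(self.n_nodes)]
        pd.DataFrame(self.adjacency, index=names, columns=names).to_csv(path)


# ----------------------------------------------------------------------
# low-level helpers (shared with the permutation engine)

def is_connected(adj: np.ndarray) -> bool:
    """Breadth-first sweep from node 0."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    if n == 0:
        return True
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    frontier = seen.copy()
    while frontier.any():
        nxt = adj[frontier].any(axis=0) & ~seen
        seen |= nxt
        frontier = nxt
    return bool(seen.all())


def edge_count(n_nodes: int, density: float) -> int:
    """E = round(D * N(N-1)/2), half away from zero."""
    pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * pairs + 0.5))


def pair_order(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices sorted by descending r, ties by (i, j)."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = r[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def edge_rank_matrix(r: np.ndarray) -> np.ndarray:
    """rank[i, j] = position of pair (i, j) in the deterministic top-E order;
    the diagonal gets a sentinel rank that is never selected."""
    n = r.shape[0]
    oi, oj = pair_order(r)
    rank = np.full((n, n), n * n, dtype=np.int64)
    seq = np.arange(oi.size)
    rank[oi, oj] = seq
    rank[oj, oi] = seq
    return rank


def adjacency_stack(r: np.ndarray, e_counts: np.ndarray) -> np.ndarray:
    """Boolean (n_density, N, N) stack of nested top-E adjacencies."""
    rank = edge_rank_matrix(r)
    e = np.asarray(e_counts, dtype=np.int64)
    return rank[None, :, :] < e[:, None, None]


# ----------------------------------------------------------------------
# public operations

def compute_association_matrix(table: SubjectVolumeTable, group: str) -> AssociationMatrix:
    """Pearson-correlate regional volumes across one group's subjects."""
    sub = table.group_values(group)
    sds = sub.std(axis=0)
    if np.any(sds == 0):
        region = table.region_names[int(np.argmin(sds))]
        raise DegenerateDataError(
            f"region {region!r} is constant within group {group!r}")
    r = np.corrcoef(sub, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return AssociationMatrix(r=r, region_names=list(table.region_names),
                             group_label=group, n_subjects=sub.shape[0])


def threshold_to_density(assoc: AssociationMatrix, density: float) -> BinaryGraph:
    """Keep the E largest signed off-diagonal correlations."""
    if not 0 < density <= 1:
        raise InputValidationError(f"density must lie in (0, 1], got {density}")
    n = assoc.n_regions
    e = edge_count(n, density)
    if e == 0:
        raise DegenerateDataError(f"density {density} too low for N={n}: E rounds to 0")
    oi, oj = pair_order(assoc.r)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[oi[:e], oj[:e]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density, n_edges=e,
                       region_names=list(assoc.region_names))


def density_sweep(assoc: AssociationMatrix, grid: DensityGrid) -> list:
    """One BinaryGraph per grid density; edge sets nested across the sweep."""
    return [threshold_to_density(assoc, d) for d in grid.values]


def min_connected_density(assoc_a: AssociationMatrix, assoc_b: AssociationMatrix,
                          grid: DensityGrid) -> float:
    """Smallest grid density at which both groups' graphs are connected."""
    if assoc_a.n_regions != assoc_b.n_regions:
        raise InputValidationError("association matrices have different region counts")
    for d in grid.values:
        ga = threshold_to_density(assoc_a, d)
        gb = threshold_to_density(assoc_b, d)
        if ga.connected and gb.connected:
            return d
    sizes = []
    for g in (threshold_to_density(assoc_a, grid.values[-1]),
              threshold_to_density(assoc_b, grid.values[-1])):
        n_comp, labels = _components(g.adjacency)
        sizes.append(int(np.bincount(labels).max()))
    raise DegenerateDataError(
        f"networks fragmented at every grid density up to {grid.values[-1]}; "
        f"largest components at d_max: {sizes[0]}/{assoc_a.n_regions} (group "
        f"{assoc_a.group_label}), {sizes[1]}/{assoc_b.n_regions} (group "
        f"{assoc_b.group_label})")


def _components(adj: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy.sparse.csgraph import connected_components
    return connected_components(np.asarray(adj), directed=False)[:2]
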