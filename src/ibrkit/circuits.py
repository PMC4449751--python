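"""Circuit-theory effective resistance on resistance rasters.

The raster is treated as a resistor network: every unmasked cell is a node,
neighbouring cells are joined by a resistor whose resistance is the mean of
the two cell resistances (scaled by sqrt(2) for diagonal neighbours under
8-connectivity), and the effective resistance between two focal nodes — in
ohms, integrating current over *all* paths — is used as a dispersal distance.

Effective resistance between nodes s and t is obtained by injecting a unit
current at s, extracting it at t, grounding one node, solving the Kirchhoff
system ``L v = e_s - e_t`` for the node potentials, and reading off
``v_s - v_t``; equivalently ``(e_s - e_t)^T L^+ (e_s - e_t)`` for the graph
Laplacian L. One sparse factorization is reused across all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import factorized

from .errors import ConnectivityError, ParameterError
from .popgen import PairwiseMatrix
from .raster import Raster

__all__ = [
    "FocalGroup",
    "ResistorNetwork",
    "build_network",
    "effective_resistance",
    "pairwise_resistance_matrix",
    "effective_resistance_dense",
]


@dataclass(frozen=True)
class FocalGroup:
    """A focal sampling location (e.g. a lek group) in map coordinates."""

    id: str
    x: float
    y: float


class ResistorNetwork:
    """Sparse resistor network built from a resistance raster.

    Attributes
    ----------
    laplacian
        CSR graph Laplacian over unmasked cells (conductance-weighted).
    node_of_cell
        ``(nrows, ncols)`` int array mapping cells to node ids (-1 = masked).
    """

    def __init__(self, laplacian: sparse.csr_matrix, node_of_cell: np.ndarray,
                 raster: Raster):
        self.laplacian = laplacian
        self.node_of_cell = node_of_cell
        self.raster = raster
        self._solve = None

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]

    def node_at(self, x: float, y: float) -> int:
        """Node id of the unmasked cell containing map point (x, y)."""
        row, col = self.raster.index_of(x, y)
        node = int(self.node_of_cell[row, col])
        if node < 0:
            raise ParameterError(f"point ({x}, {y}) falls on a nodata cell")
        return node

    def check_connected(self, nodes: list[int]) -> None:
        n_comp, labels = connected_components(self.laplacian, directed=False)
        if n_comp > 1 and len(set(labels[nodes])) > 1:
            raise ConnectivityError("focal nodes fall in different network components")

    def _grounded_solver(self):
        """LU solve of the Laplacian with node 0 grounded (cached)."""
        if self._solve is None:
            reduced = self.laplacian[1:, 1:].tocsc()
            self._solve = factorized(reduced)
        return self._solve


_OFFSETS_4 = [(0, 1), (1, 0)]
_OFFSETS_8 = [(0, 1), (1, 0), (1, 1), (1, -1)]


def build_network(r: Raster, connectivity: int = 8) -> ResistorNetwork:
    """Build the resistor network of a strictly positive resistance raster.

    Each edge between neighbouring cells a and b gets resistance
    ``(r_a + r_b) / 2``, multiplied by sqrt(2) for diagonal neighbours under
    8-connectivity; edge conductance is the reciprocal.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    vals = r.values
    mask = r.mask
    if np.nanmin(vals) <= 0 if r.n_valid else True:
        raise ParameterError("resistance raster must be strictly positive")
    node_of_cell = -np.ones(vals.shape, dtype=np.int64)
    rows, cols = np.nonzero(~mask)
    node_of_cell[rows, cols] = np.arange(rows.size)

    src, dst, cond = [], [], []
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    for di, dj in offsets:
        scale = np.sqrt(2.0) if di != 0 and dj != 0 else 1.0
        a_sl = (slice(max(0, -di), vals.shape[0] - max(0, di)),
                slice(max(0, -dj), vals.shape[1] - max(0, dj)))
        b_sl = (slice(max(0, di), vals.shape[0] - max(0, -di) + (0 if di <= 0 else 0)),
                slice(max(0, dj), vals.shape[1] - max(0, -dj)))
        # cells a at (i, j) connect to b at (i + di, j + dj)
        a_nodes = node_of_cell[a_sl]
        b_nodes = node_of_cell[b_sl]
        a_vals = vals[a_sl]
        b_vals = vals[b_sl]
        ok = (a_nodes >= 0) & (b_nodes >= 0)
        res = scale * (a_vals[ok] + b_vals[ok]) / 2.0
        src.append(a_nodes[ok])
        dst.append(b_nodes[ok])
        cond.append(1.0 / res)

    n = rows.size
    if n == 0:
        raise ParameterError("raster has no unmasked cells")
    i = np.concatenate(src)
    j = np.concatenate(dst)
    c = np.concatenate(cond)
    adj = sparse.coo_matrix((c, (i, j)), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    lap = sparse.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    return ResistorNetwork(lap.tocsr(), node_of_cell, r)


def effective_resistance(net: ResistorNetwork, s: int, t: int) -> float:
    """Effective resistance in ohms between nodes ``s`` and ``t``."""
    if s == t:
        raise ParameterError("s and t must differ")
    net.check_connected([s, t])
    solve = net._grounded_solver()
    b = np.zeros(net.n_nodes)
    b[s] += 1.0
    b[t] -= 1.0
    v = np.zeros(net.n_nodes)
    v[1:] = solve(b[1:])
    return float(v[s] - v[t])


def effective_resistance_dense(net: ResistorNetwork, s: int, t: int) -> float:
    """Dense Moore–Penrose pseudoinverse route; oracle for small networks.

    Uses the symmetric eigendecomposition with an explicit relative cutoff:
    a connected Laplacian has exactly one zero eigenvalue, and numpy's
    default singular-value cutoff can spuriously drop small *physical*
    eigenvalues on heterogeneous networks.
    """
    lplus = np.linalg.pinv(net.laplacian.toarray(), hermitian=True, rcond=1e-12)
    e = np.zeros(net.n_nodes)
    e[s] += 1.0
    e[t] -= 1.0
    return float(e @ lplus @ e)


def _merge_focal_regions(
    net: ResistorNetwork, groups: list[FocalGroup], buffer: float
) -> tuple[ResistorNetwork, list[int]]:
    """Short-circuit all cells within ``buffer`` of each focal point.

    Member cells of one group collapse into a single zero-internal-resistance
    supernode (parallel conductances summed); cells claimed by two groups are
    an error naming the groups.
    """
    raster = net.raster
    rows, cols = np.nonzero(~raster.mask)
    xs = raster.origin[0] + (cols + 0.5) * raster.cell_size
    ys = raster.origin[1] + (raster.nrows - rows - 0.5) * raster.cell_size
    owner = -np.ones(net.n_nodes, dtype=np.int64)
    for k, g in enumerate(groups):
        member = np.hypot(xs - g.x, ys - g.y) <= buffer
        clash = member & (owner >= 0)
        if np.any(clash):
            other = groups[int(owner[np.nonzero(clash)[0][0]])].id
            raise ParameterError(
                f"focal buffers of {other!r} and {g.id!r} overlap"
            )
        owner[member] = k
        if not np.any(member):  # fall back to the containing cell
            nid = net.node_at(g.x, g.y)
            if owner[nid] >= 0:
                raise ParameterError(
                    f"focal buffers of {groups[int(owner[nid])].id!r} and "
                    f"{g.id!r} overlap"
                )
            owner[nid] = k
    # supernodes first, remaining nodes after
    new_id = -np.ones(net.n_nodes, dtype=np.int64)
    new_id[owner >= 0] = owner[owner >= 0]
    free = np.nonzero(owner < 0)[0]
    new_id[free] = len(groups) + np.arange(free.size)
    adj = (-net.laplacian).tocoo()
    keep = adj.row != adj.col
    i, j, c = new_id[adj.row[keep]], new_id[adj.col[keep]], adj.data[keep]
    off = i != j  # internal edges of a supernode vanish
    n_new = len(groups) + free.size
    merged = sparse.coo_matrix((c[off], (i[off], j[off])), shape=(n_new, n_new))
    merged = merged.tocsr()
    lap = sparse.diags(np.asarray(merged.sum(axis=1)).ravel()) - merged
    out = ResistorNetwork(lap.tocsr(), net.node_of_cell, raster)
    return out, list(range(len(groups)))


def pairwise_resistance_matrix(
    r: Raster,
    groups: list[FocalGroup],
    connectivity: int = 8,
    focal_buffer: float | None = None,
) -> PairwiseMatrix:
    """Pairwise effective resistance (ohms) between all focal groups.

    Groups are single focal cells by default; ``focal_buffer`` (map units)
    instead short-circuits every cell within that radius of a group into one
    region node, for sensitivity analysis of the point-vs-region choice. One
    grounded factorization is shared across pairs; the result is identical
    to independent per-pair solves.
    """
    if len(groups) < 2:
        raise ParameterError("need at least two focal groups")
    net = build_network(r, connectivity=connectivity)
    if focal_buffer is not None:
        net, nodes = _merge_focal_regions(net, groups, focal_buffer)
    else:
        nodes = [net.node_at(g.x, g.y) for g in groups]
        seen: dict[int, str] = {}
        for g, node in zip(groups, nodes):
            if node in seen:
                raise ParameterError(
                    f"focal groups {seen[node]!r} and {g.id!r} fall on the same cell"
                )
            seen[node] = g.id
    net.check_connected(nodes)
    solve = net._grounded_solver()

    # Potentials for unit injection at each focal node (grounded at node 0);
    # R_eff(s, t) then assembles from pairwise differences by linearity.
    pots = np.zeros((len(nodes), net.n_nodes))
    for k, node in enumerate(nodes):
        b = np.zeros(net.n_nodes)
        b[node] = 1.0
        pots[k, 1:] = solve(b[1:])

    m = len(groups)
    values = np.zeros((m, m))
    for a in range(m):
        for b_ in range(a + 1, m):
            v = pots[a] - pots[b_]
            reff = v[nodes[a]] - v[nodes[b_]]
            values[a, b_] = values[b_, a] = reff
    return PairwiseMatrix(
        group_ids=[g.id for g in groups], values=values, kind="resistance-ohms"
    )
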