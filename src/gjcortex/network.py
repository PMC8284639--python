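"""Construction of the cortical lattice, gap-junction topologies, recurrent
adjacency and the LGN projection.

Cells live on a square grid with periodic boundary conditions, indexed
row-major, so that on a 20x20 grid cell 0 touches cells 1 and 19 along its
row and cells 20 and 380 across the vertical wrap.  Each cell is
independently excitatory with probability 1 - p_inhibitory.  Gap junctions
(GJs) join excitatory cells only, either as a random disjoint pairing
("pairwise" mode) or as within-sister-group Erdos-Renyi edges ("sister"
mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "NetworkGraph",
    "build_lattice",
    "build_pairwise_gj",
    "build_sister_gj",
    "build_recurrent_mask",
    "build_lgn_projection",
    "wrapped_grid_distance",
    "save_graph",
    "load_graph",
]


@dataclass
class NetworkGraph:
    """Static wiring of one model cortex.

    Attributes
    ----------
    n_cells : int
        Number of cortical cells (a perfect square).
    grid_side : int
        Side length of the periodic square grid.
    positions : (n_cells, 2) int array
        Row-major (row, col) grid coordinates of each cell.
    is_excitatory : (n_cells,) bool array
        Cell-type labels.
    gj_edges : (m, 2) int array
        Unordered excitatory GJ pairs, each row sorted, rows unique.
    sister_group : (n_cells,) int array or None
        Sister-group index in 0..n_groups-1 for excitatory cells, -1 for
        inhibitory cells; None when no sister structure was built.
    recurrent_mask : (n_cells, n_cells) bool array or None
        recurrent_mask[post, pre] marks an allowed chemical synapse.
    lgn_map : (n_cells, n_lgn) bool array or None
        lgn_map[cell, a] marks an LGN synapse with label ``a`` onto ``cell``.
    lgn_weights_inh : (n_cells, n_lgn) float array or None
        Fixed feedforward strengths for inhibitory cells (zero rows for
        excitatory cells, whose feedforward weights are plastic).
    """

    n_cells: int
    grid_side: int
    positions: np.ndarray
    is_excitatory: np.ndarray
    gj_edges: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )
    sister_group: np.ndarray | None = None
    recurrent_mask: np.ndarray | None = None
    lgn_map: np.ndarray | None = None
    lgn_weights_inh: np.ndarray | None = None

    @property
    def excitatory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_excitatory)

    @property
    def inhibitory_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_excitatory)

    @property
    def n_lgn(self) -> int:
        if self.lgn_map is None:
            raise ValueError("LGN projection has not been built")
        return self.lgn_map.shape[1]

    def gj_partners(self, cell: int) -> np.ndarray:
        """GJ partners of ``cell`` (empty for uncoupled or inhibitory cells)."""
        e = self.gj_edges
        return np.concatenate([e[e[:, 0] == cell, 1], e[e[:, 1] == cell, 0]])

    def gj_degree(self) -> np.ndarray:
        """GJ degree per cell (zeros for cells without junctions)."""
        deg = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(deg, self.gj_edges.ravel(), 1)
        return deg

    def validate(self) -> None:
        """Assert the structural invariants of the wiring."""
        assert self.grid_side**2 == self.n_cells
        e = self.gj_edges
        if e.size:
            assert np.all(e[:, 0] != e[:, 1]), "GJ self-edge"
            assert np.all(self.is_excitatory[e.ravel()]), "GJ on inhibitory cell"
            key = e.min(axis=1) * self.n_cells + e.max(axis=1)
            assert len(np.unique(key)) == len(e), "duplicate GJ edge"
        if self.sister_group is not None and e.size:
            assert np.all(
                self.sister_group[e[:, 0]] == self.sister_group[e[:, 1]]
            ), "GJ edge across sister groups"
        if self.recurrent_mask is not None:
            assert not np.any(np.diag(self.recurrent_mask)), "recurrent self-loop"


def _normalize_edges(edges: np.ndarray) -> np.ndarray:
    """Canonical unordered edge list: each row sorted, rows lexsorted."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order]


def build_lattice(
    n_cells: int, p_inhibitory: float = 0.2, rng_seed: int | np.random.Generator = 0
) -> NetworkGraph:
    """Lay cells out row-major on a periodic square grid and draw types.

    Each cell is independently inhibitory with probability ``p_inhibitory``
    (a Bernoulli draw, not an exact split).

    Raises
    ------
    ValueError
        If ``n_cells`` is not a perfect square.
    """
    side = int(round(np.sqrt(n_cells)))
    if side * side != n_cells:
        raise ValueError(
            f"n_cells={n_cells} is not a perfect square; the model requires a "
            "square grid (e.g. 400 -> 20x20, 256 -> 16x16)"
        )
    if not 0.0 <= p_inhibitory <= 1.0:
        raise ValueError("p_inhibitory must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    rows, cols = np.divmod(np.arange(n_cells), side)
    positions = np.stack([rows, cols], axis=1)
    is_excitatory = rng.random(n_cells) >= p_inhibitory
    return NetworkGraph(
        n_cells=n_cells,
        grid_side=side,
        positions=positions,
        is_excitatory=is_excitatory,
    )


def build_pairwise_gj(
    graph: NetworkGraph,
    fraction_coupled: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random disjoint GJ pairing over the excitatory population.

    Shuffles the excitatory cells, keeps the first
    ``floor(fraction_coupled * n_E)`` of them (rounded down to an even
    count) and pairs them consecutively, so every coupled cell has exactly
    one partner and the expected coupled fraction equals
    ``fraction_coupled``.
    """
    if not 0.0 <= fraction_coupled <= 1.0:
        raise ValueError("fraction_coupled must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    exc = graph.excitatory_ids.copy()
    rng.shuffle(exc)
    n_take = int(np.floor(fraction_coupled * len(exc)))
    n_take -= n_take % 2
    chosen = exc[:n_take]
    edges = chosen.reshape(-1, 2)
    return _normalize_edges(edges)


def build_sister_gj(
    graph: NetworkGraph,
    n_groups: int = 6,
    p_gj: float = 0.05,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign sister groups and couple within-group pairs independently.

    Every excitatory cell joins one of ``n_groups`` groups uniformly at
    random; each unordered within-group pair then becomes a GJ edge with
    probability ``p_gj``.

    Returns
    -------
    sister_group : (n_cells,) int array (-1 for inhibitory cells)
    gj_edges : (m, 2) int array
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if not 0.0 <= p_gj <= 1.0:
        raise ValueError("p_gj must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    sister = np.full(graph.n_cells, -1, dtype=np.int64)
    exc = graph.excitatory_ids
    sister[exc] = rng.integers(0, n_groups, size=len(exc))
    edges = []
    for g in range(n_groups):
        members = exc[sister[exc] == g]
        if len(members) < 2:
            continue
        iu, ju = np.triu_indices(len(members), k=1)
        hit = rng.random(len(iu)) < p_gj
        edges.append(np.stack([members[iu[hit]], members[ju[hit]]], axis=1))
    if edges:
        gj_edges = _normalize_edges(np.concatenate(edges, axis=0))
    else:
        gj_edges = np.empty((0, 2), dtype=np.int64)
    return sister, gj_edges


def wrapped_grid_distance(
    positions: np.ndarray, grid_side: int
) -> np.ndarray:
    """Pairwise Euclidean distance on the periodic grid."""
    d = np.abs(positions[:, None, :] - positions[None, :, :]).astype(float)
    d = np.minimum(d, grid_side - d)
    return np.sqrt((d**2).sum(axis=-1))


def build_recurrent_mask(
    graph: NetworkGraph, ee_radius: float | None = None
) -> np.ndarray:
    """Allowed chemical synapses, ``mask[post, pre]``.

    E->E synapses are all-to-all when ``ee_radius`` is None, otherwise
    restricted to periodic-wrapped Euclidean grid distance <= ``ee_radius``
    (inclusive).  E->I, I->E and I->I are always all-to-all.  The diagonal
    is False.
    """
    n = graph.n_cells
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    if ee_radius is not None:
        if ee_radius <= 0:
            raise ValueError("ee_radius must be positive or None")
        if ee_radius > graph.grid_side / 2:
            warnings.warn(
                f"ee_radius={ee_radius} exceeds half the grid side "
                f"({graph.grid_side / 2}); the E->E mask degenerates to "
                "all-to-all",
                stacklevel=2,
            )
        dist = wrapped_grid_distance(graph.positions, graph.grid_side)
        exc = graph.is_excitatory
        ee = np.outer(exc, exc)
        mask &= ~ee | (dist <= ee_radius)
        np.fill_diagonal(mask, False)
    return mask


def build_lgn_projection(
    graph: NetworkGraph,
    n_lgn: int = 1000,
    p_connect: float = 0.25,
    rng_seed: int | np.random.Generator = 0,
    g_lgn_max: float = 0.02,
    inh_weight_frac: float = 0.18,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the feedforward LGN projection.

    Every (cell, label) connection is present independently with probability
    ``p_connect``.  Inhibitory cells receive fixed strengths drawn uniformly
    on [0, ``inh_weight_frac * g_lgn_max``]; excitatory feedforward strengths
    are plastic and initialized by the plasticity module.

    Returns
    -------
    lgn_map : (n_cells, n_lgn) bool array
    lgn_weights_inh : (n_cells, n_lgn) float array
        Fixed strengths on inhibitory rows, zeros elsewhere.
    """
    rng = np.random.default_rng(rng_seed)
    lgn_map = rng.random((graph.n_cells, n_lgn)) < p_connect
    w_inh = np.zeros((graph.n_cells, n_lgn))
    inh = graph.inhibitory_ids
    w_inh[inh] = rng.uniform(0.0, inh_weight_frac * g_lgn_max, (len(inh), n_lgn))
    w_inh *= lgn_map
    return lgn_map, w_inh


# ---------------------------------------------------------------------------
# serialization

def save_graph(group: h5py.Group, graph: NetworkGraph) -> None:
    """Write a NetworkGraph into an open HDF5 group."""
    group.attrs["n_cells"] = graph.n_cells
    group.attrs["grid_side"] = graph.grid_side
    group.create_dataset("positions", data=graph.positions)
    group.create_dataset("is_excitatory", data=graph.is_excitatory)
    group.create_dataset("gj_edges", data=graph.gj_edges)
    if graph.sister_group is not None:
        group.create_dataset("sister_group", data=graph.sister_group)
    if graph.recurrent_mask is not None:
        group.create_dataset(
            "recurrent_mask", data=np.packbits(graph.recurrent_mask)
        )
    if graph.lgn_map is not None:
        pairs = np.argwhere(graph.lgn_map)
        group.create_dataset("lgn_pairs", data=pairs)
        group.attrs["n_lgn"] = graph.lgn_map.shape[1]
    if graph.lgn_weights_inh is not None:
        pairs = np.argwhere(graph.lgn_weights_inh > 0)
        group.create_dataset("lgn_inh_pairs", data=pairs)
        group.create_dataset(
            "lgn_inh_values",
            data=graph.lgn_weights_inh[pairs[:, 0], pairs[:, 1]],
        )


def load_graph(group: h5py.Group) -> NetworkGraph:
    """Read a NetworkGraph back from an HDF5 group written by save_graph."""
    n = int(group.attrs["n_cells"])
    graph = NetworkGraph(
        n_cells=n,
        grid_side=int(group.attrs["grid_side"]),
        positions=group["positions"][()],
        is_excitatory=group["is_excitatory"][()].astype(bool),
        gj_edges=group["gj_edges"][()].reshape(-1, 2),
    )
    if "sister_group" in group:
        graph.sister_group = group["sister_group"][()]
    if "recurrent_mask" in group:
        bits = np.unpackbits(group["recurrent_mask"][()], count=n * n)
        graph.recurrent_mask = bits.reshape(n, n).astype(bool)
    if "lgn_pairs" in group:
        n_lgn = int(group.attrs["n_lgn"])
        lgn_map = np.zeros((n, n_lgn), dtype=bool)
        pairs = group["lgn_pairs"][()]
        lgn_map[pairs[:, 0], pairs[:, 1]] = True
        graph.lgn_map = lgn_map
        w_inh = np.zeros((n, n_lgn))
        if "lgn_inh_pairs" in group:
            ip = group["lgn_inh_pairs"][()]
            w_inh[ip[:, 0], ip[:, 1]] = group["lgn_inh_values"][()]
        graph.lgn_weights_inh = w_inh
    return graph


def export_gj_edges_csv(path, graph: NetworkGraph) -> None:
    """CSV edge-list export of the GJ topology for inspection."""
    import pandas as pd

    df = pd.DataFrame(graph.gj_edges, columns=["cell_a", "cell_b"])
    if graph.sister_group is not None and len(df):
        df["sister_group"] = graph.sister_group[df["cell_a"]]
    df.to_csv(path, index=False)
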