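"""Minimum free-energy paths on gridded 2D surfaces.

The path criterion is the global minimax path: among all node sequences
connecting two basins under 8-connected moves (periodic wrap on periodic
axes), pick the one whose highest free energy is lowest; ties are broken
by smallest accumulated free energy along the path, then by fewest nodes.
A lexicographic-key Dijkstra makes the search exact and deterministic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fes import FESGrid


@dataclass(frozen=True)
class Basin:
    """A local free-energy minimum on the grid."""

    node: tuple[int, int]
    free_energy: float
    depth: float  # barrier to the lowest saddle toward any deeper basin


@dataclass
class Path:
    """Ordered grid nodes of a minimum free-energy path."""

    nodes: list[tuple[int, int]]
    coords: np.ndarray       # (n, 2) CV coordinates
    energies: np.ndarray     # (n,) kcal/mol
    arc_length: np.ndarray   # (n,) cumulative, CV units (periodic-aware)

    def __post_init__(self):
        n = len(self.nodes)
        if not (len(self.coords) == len(self.energies) == len(self.arc_length) == n):
            raise ValueError("path arrays must share the node count")
        if n and np.any(np.diff(self.arc_length) < 0):
            raise ValueError("arc length must be non-decreasing")

    def __len__(self) -> int:
        return len(self.nodes)


def _neighbors(i: int, j: int, shape: tuple[int, int], periodic: tuple[bool, bool]):
    n0, n1 = shape
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii, jj = i + di, j + dj
            if periodic[0]:
                ii %= n0
            elif not 0 <= ii < n0:
                continue
            if periodic[1]:
                jj %= n1
            elif not 0 <= jj < n1:
                continue
            yield ii, jj


def find_minima(fes: FESGrid, depth_threshold: float = 0.0) -> list[Basin]:
    """Strict local minima, filtered by basin depth, sorted by free energy.

    Depth is the persistence of the basin: the free energy of the lowest
    saddle connecting it to any strictly deeper basin, minus the basin
    minimum.  The global minimum has infinite depth.  A flat grid has no
    strict minima and yields an empty list.
    """
    F = fes.values
    shape = F.shape
    periodic = (fes.axes[0].periodic, fes.axes[1].periodic)
    minima = [
        (i, j)
        for i in range(shape[0])
        for j in range(shape[1])
        if all(F[i, j] < F[ii, jj] for ii, jj in _neighbors(i, j, shape, periodic))
    ]
    if not minima:
        return []
    # persistence by flooding nodes in ascending energy (union-find)
    order = sorted(
        ((i, j) for i in range(shape[0]) for j in range(shape[1])),
        key=lambda n: (F[n], n),
    )
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    root_min: dict[tuple[int, int], tuple[int, int]] = {}
    death: dict[tuple[int, int], float] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    minima_set = set(minima)
    for node in order:
        parent[node] = node
        root_min[node] = node if node in minima_set else None
        for nb in _neighbors(*node, shape, periodic):
            if nb not in parent:
                continue
            ra, rb = find(node), find(nb)
            if ra == rb:
                continue
            ma, mb = root_min[ra], root_min[rb]
            # keep the component owning the deeper minimum; the other dies here
            def key(m):
                return (math.inf, m) if m is None else (F[m], m)
            if key(ma) <= key(mb):
                keep, lose = ra, rb
            else:
                keep, lose = rb, ra
            lost_min = root_min[lose]
            if lost_min is not None and lost_min not in death:
                death[lost_min] = F[node] - F[lost_min]
            parent[lose] = keep
            root_min[keep] = min(root_min[keep], root_min[lose], key=key) if root_min[lose] else root_min[keep]
    basins = []
    for m in minima:
        depth = death.get(m, math.inf)
        if depth > depth_threshold:
            basins.append(Basin(node=m, free_energy=float(F[m]), depth=depth))
    basins.sort(key=lambda b: (b.free_energy, b.node))
    return basins


def _arc_lengths(coords: np.ndarray, fes: FESGrid) -> np.ndarray:
    if len(coords) == 0:
        return np.zeros(0)
    steps = np.zeros(len(coords))
    for d, ax in enumerate(fes.axes):
        delta = np.diff(coords[:, d])
        if ax.periodic:
            delta = delta - ax.span * np.round(delta / ax.span)
        steps[1:] += delta**2
    return np.cumsum(np.sqrt(steps))


def find_mfep(fes: FESGrid, start: tuple[int, int] | Basin, end: tuple[int, int] | Basin) -> Path:
    """Globally optimal minimax path between two grid nodes.

    Optimizes the lexicographic key (max F along path, total accumulated
    F, node count); the key is monotone under path extension, so a
    label-setting Dijkstra is exact.
    """
    s = start.node if isinstance(start, Basin) else tuple(start)
    e = end.node if isinstance(end, Basin) else tuple(end)
    F = fes.values
    shape = F.shape
    for node in (s, e):
        if not (0 <= node[0] < shape[0] and 0 <= node[1] < shape[1]):
            raise ValueError(f"node {node} outside grid of shape {shape}")
    periodic = (fes.axes[0].periodic, fes.axes[1].periodic)
    best: dict[tuple[int, int], tuple[float, float, int]] = {}
    prev: dict[tuple[int, int], tuple[int, int] | None] = {}
    start_key = (float(F[s]), float(F[s]), 1)
    heap = [(start_key, s, None)]
    while heap:
        key, node, parent = heapq.heappop(heap)
        if node in best:
            continue
        best[node] = key
        prev[node] = parent
        if node == e:
            break
        kmax, ksum, kcnt = key
        for nb in _neighbors(*node, shape, periodic):
            if nb in best:
                continue
            fn = float(F[nb])
            heapq.heappush(heap, ((max(kmax, fn), ksum + fn, kcnt + 1), nb, node))
    if e not in best:
        raise RuntimeError("end node unreachable")  # cannot happen on a connected grid
    nodes = []
    cur: tuple[int, int] | None = e
    while cur is not None:
        nodes.append(cur)
        cur = prev[cur]
    nodes.reverse()
    coords = np.array(
        [[fes.axes[0].nodes[i], fes.axes[1].nodes[j]] for i, j in nodes]
    ).reshape(len(nodes), 2)
    energies = np.array([F[n] for n in nodes])
    return Path(nodes=nodes, coords=coords, energies=energies, arc_length=_arc_lengths(coords, fes))


def barrier_and_reaction_energy(path: Path) -> tuple[float, float, int]:
    """(dG_act, dG_rxn, transition-state index) from a path energy profile.

    dG_act = max F - F(first node); dG_rxn = F(last) - F(first); the
    transition state is the first occurrence of the maximum.
    """
    if len(path) == 0:
        raise ValueError("empty path")
    F = path.energies
    ts = int(np.argmax(F))
    return float(F[ts] - F[0]), float(F[-1] - F[0]), ts


def profile_along_path(
    path: Path,
    table: pd.DataFrame,
    bin_width: float,
    cv_columns: tuple[str, str] = ("cv1", "cv2"),
) -> pd.DataFrame:
    """Running averages of per-frame observables along the path arc length.

    Each table row is assigned to the nearest path node in CV space; node
    values are then averaged within consecutive arc-length bins of the
    given width.  Bins with no data are flagged (``n=0``, observables
    NaN), never interpolated.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(path) == 0:
        raise ValueError("empty path")
    pts = table[list(cv_columns)].to_numpy(dtype=float)
    obs_cols = [c for c in table.columns if c not in cv_columns]
    # nearest path node per observation
    d2 = ((pts[:, None, :] - path.coords[None, :, :]) ** 2).sum(axis=2)
    node_of = np.argmin(d2, axis=1)
    s_of = path.arc_length[node_of]
    total = float(path.arc_length[-1]) if len(path) > 1 else 0.0
    n_bins = max(1, int(math.ceil(total / bin_width))) if total > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width
    which = np.clip(np.digitize(s_of, edges) - 1, 0, n_bins - 1)
    out = {
        "s_mid": edges[:-1] + bin_width / 2.0,
        "n": np.bincount(which, minlength=n_bins),
    }
    for c in obs_cols:
        sums = np.bincount(which, weights=table[c].to_numpy(dtype=float), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            out[c] = np.where(out["n"] > 0, sums / np.maximum(out["n"], 1), np.nan)
    return pd.DataFrame(out)


def write_path(path: Path, dest, cv_names: tuple[str, str] = ("cv1", "cv2")) -> None:
    """Text table: node index, CV coordinates, free energy, arc length."""
    from pathlib import Path as _P

    if isinstance(dest, (str, _P)):
        with open(dest, "w") as fh:
            write_path(path, fh, cv_names)
            return
    dest.write(f"# node i j {cv_names[0]} {cv_names[1]} free_energy arc_length\n")
    for k, (i, j) in enumerate(path.nodes):
        dest.write(
            f"{k} {i} {j} {path.coords[k, 0]:.10g} {path.coords[k, 1]:.10g} "
            f"{path.energies[k]:.10g} {path.arc_length[k]:.10g}\n"
        )
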