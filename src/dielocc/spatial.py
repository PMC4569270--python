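"""Voronoi-tessellation adjacency and the intrinsic CAR spatial prior.

Each camera station gets an "influence" polygon from the Voronoi
tessellation of the station coordinates; stations whose (clipped) polygons
share a boundary segment of positive length are neighbors.  The spatial
term U_i of the occurrence model follows an intrinsic Gaussian conditional
autoregressive (CAR) prior on that neighbor graph:

    log p(U | tau) = -(tau/2) * sum_{(a,b) adjacent} (U_a - U_b)^2 + const

which is invariant to adding a constant to U, so a sum-to-zero constraint
is imposed during sampling.

Unbounded outer cells are clipped to the convex hull of the stations
buffered by the mean nearest-neighbor distance, so boundary adjacency is
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, MultiPoint

__all__ = ["Adjacency", "voronoi_adjacency", "car_logdensity", "pairwise_deviance"]

_MIN_SHARED_LENGTH = 1e-9  # meters; a shared point is not a boundary


@dataclass(frozen=True)
class Adjacency:
    """Symmetric, irreflexive neighbor structure over camera stations."""

    n_sites: int
    edges: tuple[tuple[int, int], ...]  # (a, b) with a < b
    site_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        for a, b in self.edges:
            if not (0 <= a < b < self.n_sites):
                raise ValueError(f"bad edge ({a}, {b}) for n={self.n_sites}")

    @property
    def neighbor_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.n_sites)]
        for a, b in self.edges:
            out[a].add(b)
            out[b].add(a)
        return out

    def matrix(self) -> np.ndarray:
        A = np.zeros((self.n_sites, self.n_sites), dtype=int)
        for a, b in self.edges:
            A[a, b] = A[b, a] = 1
        return A

    def n_components(self) -> int:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_sites))
        g.add_edges_from(self.edges)
        return nx.number_connected_components(g)

    def coloring(self) -> list[np.ndarray]:
        """Greedy graph coloring: index arrays of mutually non-adjacent
        sites, used for vectorized single-site CAR updates."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_sites))
        g.add_edges_from(self.edges)
        colors = nx.greedy_color(g, strategy="largest_first")
        n_colors = max(colors.values(), default=0) + 1
        return [
            np.array([i for i, c in colors.items() if c == k], dtype=int)
            for k in range(n_colors)
        ]

    def to_edge_frame(self) -> pd.DataFrame:
        ids = self.site_ids or tuple(str(i) for i in range(self.n_sites))
        return pd.DataFrame(
            {"site_id_a": [ids[a] for a, _ in self.edges],
             "site_id_b": [ids[b] for _, b in self.edges]}
        )

    def to_winbugs(self) -> dict[str, list[int]]:
        """WinBUGS-style ``adj``/``num``/``weights`` triple (1-based)."""
        nbrs = self.neighbor_sets
        adj: list[int] = []
        num: list[int] = []
        for i in range(self.n_sites):
            ordered = sorted(nbrs[i])
            adj.extend(j + 1 for j in ordered)
            num.append(len(ordered))
        return {"adj": adj, "num": num, "weights": [1] * len(adj)}


def _collinear_chain(coords: np.ndarray, site_ids) -> Adjacency:
    # degenerate pattern: all stations on one line; Voronoi cells are
    # parallel slabs, so neighbors are consecutive along the line
    center = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(center, full_matrices=False)
    t = center @ vt[0]
    order = np.argsort(t, kind="stable")
    edges = tuple(
        (min(int(order[i]), int(order[i + 1])), max(int(order[i]), int(order[i + 1])))
        for i in range(len(order) - 1)
    )
    return Adjacency(len(coords), tuple(sorted(set(edges))), tuple(site_ids))


def voronoi_adjacency(
    coords: np.ndarray,
    site_ids: list[str] | None = None,
    bound=None,
) -> Adjacency:
    """Neighbor graph of camera stations via Voronoi tessellation.

    Two stations are adjacent iff their Voronoi cells, clipped to
    ``bound`` (a shapely polygon; default: convex hull of the stations
    buffered by the mean nearest-neighbor distance), share a boundary
    segment of positive length.

    Parameters
    ----------
    coords : (n, 2) array of projected coordinates in meters.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 stations for a tessellation")
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("duplicate station coordinates")
    ids = tuple(site_ids) if site_ids is not None else tuple(str(i) for i in range(n))
    if len(ids) != n:
        raise ValueError("site_ids length mismatch")

    tree = cKDTree(coords)
    nn_dist, _ = tree.query(coords, k=2)
    mean_nn = float(nn_dist[:, 1].mean())

    center = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(center, tol=1e-9 * max(1.0, np.abs(center).max())) < 2:
        return _collinear_chain(coords, ids)

    if bound is None:
        bound = MultiPoint(coords).convex_hull.buffer(mean_nn)

    vor = Voronoi(coords)
    span = float(np.ptp(coords, axis=0).max()) + 4 * mean_nn
    far = 4.0 * span
    centroid = coords.mean(axis=0)

    edges: set[tuple[int, int]] = set()
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            seg = LineString([vor.vertices[v1], vor.vertices[v2]])
        else:
            # semi-infinite ridge: extend from the finite vertex along the
            # outward normal of the generating pair (scipy's plotting rule)
            vfin = vor.vertices[v2 if v1 < 0 else v1]
            t = coords[p2] - coords[p1]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = coords[[p1, p2]].mean(axis=0)
            direction = np.sign(np.dot(midpoint - centroid, normal)) or 1.0
            seg = LineString([vfin, vfin + direction * normal * far])
        clipped = seg.intersection(bound)
        if clipped.length > _MIN_SHARED_LENGTH:
            a, b = sorted((int(p1), int(p2)))
            edges.add((a, b))
    return Adjacency(n, tuple(sorted(edges)), ids)


def pairwise_deviance(U: np.ndarray, adjacency: Adjacency) -> float:
    """Sum of squared differences over adjacent pairs."""
    U = np.asarray(U, dtype=float)
    if U.shape != (adjacency.n_sites,):
        raise ValueError("U length must equal the number of sites")
    if not adjacency.edges:
        return 0.0
    e = np.asarray(adjacency.edges)
    d = U[e[:, 0]] - U[e[:, 1]]
    return float(d @ d)


def car_logdensity(U: np.ndarray, adjacency: Adjacency, tau: float) -> float:
    """Intrinsic-CAR log density of the spatial field, up to a constant.

    Returns −(τ/2)·Σ_{(a,b) adjacent} (U_a − U_b)²; invariant to adding a
    constant to U, which is why the sampler recenters U to sum to zero.
    """
    if tau <= 0:
        raise ValueError("CAR precision tau must be positive")
    return -0.5 * tau * pairwise_deviance(U, adjacency)
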