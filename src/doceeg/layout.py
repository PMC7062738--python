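"""Sensor layouts and channel adjacency.

A :class:`SensorLayout` stands in for a high-density scalp net (the studies
this package supports use 256-channel geodesic nets reduced to 224 scalp
electrodes).  Layouts are fully synthetic: channels are placed on a ring, a
grid or a spherical cap, and neighborhood is derived geometrically.  The
adjacency relation is what downstream cluster-based statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, distance_matrix


@dataclass
class SensorLayout:
    """Channel labels, positions and a symmetric, irreflexive adjacency."""

    channel_ids: list[str]
    positions_2d: np.ndarray  # (n, 2) unitless scalp projection
    positions_3d: np.ndarray  # (n, 3) head-surface coordinates
    adjacency: np.ndarray  # (n, n) boolean, symmetric, zero diagonal

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def validate(self) -> None:
        n = self.n_channels
        if self.positions_2d.shape != (n, 2) or self.positions_3d.shape != (n, 3):
            raise ValueError("position array shapes do not match channel count")
        if not np.all(np.isfinite(self.positions_2d)) or not np.all(
            np.isfinite(self.positions_3d)
        ):
            raise ValueError("positions must be finite")
        a = self.adjacency
        if a.shape != (n, n) or a.dtype != bool:
            raise ValueError("adjacency must be a boolean (n, n) matrix")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("adjacency must be irreflexive")
        if n >= 3 and not np.all(a.sum(axis=0) >= 1):
            raise ValueError("every channel needs at least one neighbor")

    def to_json_dict(self) -> dict:
        return {
            "channels": [
                {
                    "id": cid,
                    "x": float(self.positions_3d[i, 0]),
                    "y": float(self.positions_3d[i, 1]),
                    "z": float(self.positions_3d[i, 2]),
                    "neighbors": [self.channel_ids[j] for j in self.neighbors(i)],
                }
                for i, cid in enumerate(self.channel_ids)
            ]
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SensorLayout":
        ids = [c["id"] for c in d["channels"]]
        idx = {cid: i for i, cid in enumerate(ids)}
        pos3 = np.array([[c["x"], c["y"], c["z"]] for c in d["channels"]], float)
        adj = np.zeros((len(ids), len(ids)), bool)
        for i, c in enumerate(d["channels"]):
            for nb in c["neighbors"]:
                adj[i, idx[nb]] = True
        adj |= adj.T
        return cls(ids, pos3[:, :2].copy(), pos3, adj)


def _positions(n_channels: int, geometry: str) -> tuple[np.ndarray, np.ndarray]:
    if geometry == "ring":
        ang = 2 * np.pi * np.arange(n_channels) / n_channels
        p2 = np.column_stack([np.cos(ang), np.sin(ang)])
        p3 = np.column_stack([p2, np.zeros(n_channels)])
    elif geometry == "grid":
        side = int(np.ceil(np.sqrt(n_channels)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        p2 = np.column_stack([gx.ravel(), gy.ravel()])[:n_channels].astype(float)
        p3 = np.column_stack([p2, np.zeros(n_channels)])
    elif geometry == "spherical-cap":
        # Fibonacci spiral on the upper cap of a unit sphere: even coverage at
        # any n, mimicking a geodesic sensor net down-projected to the scalp.
        k = np.arange(n_channels)
        z = 1.0 - 0.7 * (k + 0.5) / n_channels  # cap from pole down to z=0.3
        r = np.sqrt(1.0 - z**2)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        ang = golden * k
        p3 = np.column_stack([r * np.cos(ang), r * np.sin(ang), z])
        p2 = p3[:, :2] / (1.0 + p3[:, 2:3])  # stereographic projection
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return p2, p3


def _delaunay_adjacency(p2: np.ndarray) -> np.ndarray:
    n = len(p2)
    adj = np.zeros((n, n), bool)
    if n == 3:
        adj[:] = True
        np.fill_diagonal(adj, False)
        return adj
    # jitter-free Delaunay fails on perfectly collinear grids of width 1
    tri = Delaunay(p2, qhull_options="QJ")
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adj[a, b] = True
    return adj


def make_layout(
    n_channels: int,
    geometry: str = "spherical-cap",
    neighbor_rule: str = "delaunay",
    *,
    k: int = 4,
    radius: float | None = None,
) -> SensorLayout:
    """Build a deterministic synthetic sensor layout.

    Parameters
    ----------
    n_channels : number of channels, at least 3.
    geometry : ``ring``, ``grid`` or ``spherical-cap``.
    neighbor_rule : ``delaunay`` (on the 2-D projection), ``k-nearest``
        (mutualized so the relation stays symmetric), or ``radius``.
    k : neighbor count for ``k-nearest``.
    radius : cutoff for ``radius``; defaults to 1.01x the median
        nearest-neighbor distance times 1.5.
    """
    if n_channels < 3:
        raise ValueError("n_channels must be >= 3")
    p2, p3 = _positions(n_channels, geometry)
    dist = distance_matrix(p2, p2)
    if neighbor_rule == "delaunay":
        adj = _delaunay_adjacency(p2)
    elif neighbor_rule == "k-nearest":
        adj = np.zeros((n_channels, n_channels), bool)
        order = np.argsort(dist, axis=1, kind="stable")
        for i in range(n_channels):
            adj[i, order[i, 1 : k + 1]] = True
        adj |= adj.T  # closure keeps symmetry
    elif neighbor_rule == "radius":
        if radius is None:
            nn = np.sort(dist, axis=1)[:, 1]
            radius = 1.5 * float(np.median(nn)) * 1.01
        adj = (dist > 0) & (dist <= radius)
    else:
        raise ValueError(f"unknown neighbor_rule {neighbor_rule!r}")
    np.fill_diagonal(adj, False)
    ids = [f"E{i + 1}" for i in range(n_channels)]
    layout = SensorLayout(ids, p2, p3, adj)
    layout.validate()
    return layout
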