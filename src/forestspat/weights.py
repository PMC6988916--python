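"""Sphere-of-influence (SOI) spatial weights.

Two units are SOI neighbours when the circles centred on their centroids,
each with radius equal to the centroid's nearest-neighbour distance,
intersect in two places: |r_i - r_j| < d(i, j) < r_i + r_j with strict
inequalities (tangent circles touch in one place and do not qualify).
The SOI graph is symmetric, needs no shared borders (it links close
islands), and always contains the nearest-neighbour graph.

Row standardization divides each unit's neighbour weights by its degree,
so a spatially lagged variable WX is the neighbour average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import squareform, pdist

from .crs import great_circle_matrix

METRICS = ("planar", "geodesic")


def _distance_matrix(points: np.ndarray, metric: str) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise ValueError("need an (n>=2, 2) array of coordinates")
    if metric == "planar":
        return squareform(pdist(points))
    if metric == "geodesic":
        return great_circle_matrix(points)
    raise ValueError(f"metric must be one of {METRICS}")


def soi_neighbors(points: np.ndarray, metric: str = "planar") -> sp.csr_matrix:
    """Binary symmetric SOI adjacency for point coordinates.

    ``points`` holds projected (x, y) metres for the planar metric or
    (lon, lat) degrees for the geodesic one.  Coincident points make the
    nearest-neighbour radius degenerate and raise, listing the pair.
    """
    d = _distance_matrix(points, metric)
    n = len(d)
    off = d + np.diag(np.full(n, np.inf))
    zero_i, zero_j = np.nonzero(off == 0.0)
    if len(zero_i):
        i, j = int(zero_i[0]), int(zero_j[0])
        raise ValueError(f"coincident points: indices {min(i, j)} and {max(i, j)}")
    r = off.min(axis=1)
    rsum = r[:, None] + r[None, :]
    rdiff = np.abs(r[:, None] - r[None, :])
    adj = (d < rsum) & (d > rdiff)
    np.fill_diagonal(adj, False)
    return sp.csr_matrix(adj.astype(np.int8))


def row_standardize(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """W with each neighbour weight 1/degree; isolated units raise."""
    adjacency = sp.csr_matrix(adjacency)
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    isolated = np.nonzero(deg == 0)[0]
    if len(isolated):
        raise ValueError(f"isolated units cannot be row-standardized: {isolated.tolist()}")
    return sp.diags(1.0 / deg) @ adjacency


def summarize_weights(adjacency: sp.spmatrix) -> dict:
    """Connectivity summary: N, directed link count, averages, histogram.

    ``n_links`` counts ordered pairs (a mutual pair contributes two), so
    ``avg_links = n_links / N`` is each unit's mean neighbour count and
    ``pct_nonzero = 100 * n_links / N^2`` includes the zero diagonal in
    its denominator.
    """
    adjacency = sp.csr_matrix(adjacency)
    n = adjacency.shape[0]
    deg = np.asarray(adjacency.sum(axis=1)).ravel().astype(int)
    n_links = int(deg.sum())
    hist = {int(k): int((deg == k).sum()) for k in range(1, deg.max() + 1)} if n_links else {}
    return {
        "n": n,
        "n_links": n_links,
        "avg_links": n_links / n,
        "pct_nonzero": 100.0 * n_links / n**2,
        "neighbor_histogram": hist,
    }


@dataclass
class SpatialWeights:
    """SOI neighbour structure bound to a pinned unit order."""

    ids: list[str]
    adjacency: sp.csr_matrix
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.adjacency = sp.csr_matrix(self.adjacency)
        n = self.adjacency.shape[0]
        if len(self.ids) != n:
            raise ValueError("ids and adjacency size mismatch")
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("self-links are not allowed")

    @classmethod
    def from_points(cls, ids: Sequence[str], points: np.ndarray,
                    metric: str = "planar") -> "SpatialWeights":
        return cls(list(ids), soi_neighbors(points, metric=metric))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def W(self) -> sp.csr_matrix:
        return row_standardize(self.adjacency)

    @property
    def summaries(self) -> dict:
        return summarize_weights(self.adjacency)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized W.

        W = D^-1 A is similar to the symmetric D^-1/2 A D^-1/2, so its
        spectrum is real and is computed through the symmetric form; the
        maximum is 1 by row standardization.  Cached per instance.
        """
        if self._eigenvalues is None:
            d = self.degrees.astype(float)
            scale = sp.diags(1.0 / np.sqrt(d))
            sym = (scale @ self.adjacency @ scale).toarray()
            self._eigenvalues = np.linalg.eigvalsh(sym)
        return self._eigenvalues

    def lambda_bounds(self) -> tuple[float, float]:
        """Admissible interval (1/omega_min, 1) for the error coefficient."""
        eigs = self.eigenvalues()
        omega_min = eigs.min()
        lower = 1.0 / omega_min if omega_min < 0 else -np.inf
        return lower, 1.0

    # -- serialization ------------------------------------------------------

    def to_gal(self, path: str | Path) -> None:
        """Write the neighbour lists in GAL format."""
        adj = self.adjacency.tolil()
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, unit in enumerate(self.ids):
                neigh = adj.rows[i]
                fh.write(f"{unit} {len(neigh)}\n")
                if neigh:
                    fh.write(" ".join(self.ids[j] for j in neigh) + "\n")

    @classmethod
    def from_gal(cls, path: str | Path) -> "SpatialWeights":
        with open(path) as fh:
            tokens_by_line = [line.split() for line in fh if line.strip()]
        n = int(tokens_by_line[0][0])
        ids: list[str] = []
        neighbor_names: list[list[str]] = []
        line = 1
        for _ in range(n):
            unit, count = tokens_by_line[line][0], int(tokens_by_line[line][1])
            names = tokens_by_line[line + 1] if count else []
            if len(names) != count:
                raise ValueError(f"GAL entry for {unit} promises {count} neighbours")
            ids.append(unit)
            neighbor_names.append(names)
            line += 2 if count else 1
        index = {unit: i for i, unit in enumerate(ids)}
        rows, cols = [], []
        for i, names in enumerate(neighbor_names):
            for name in names:
                rows.append(i)
                cols.append(index[name])
        adj = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                            shape=(n, n))
        return cls(ids, adj)

    def to_triplet_csv(self, path: str | Path) -> None:
        """Write the row-standardized weights as (from, to, weight) triplets."""
        coo = self.W.tocoo()
        with open(path, "w") as fh:
            fh.write("from,to,weight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.ids[i]},{self.ids[j]},{float(w)!r}\n")
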