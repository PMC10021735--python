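"""Grid-based shortest-water-path oracle, independent of the visibility graph.

Discretises the sea into square cells (a cell is free iff it intersects no
island), connects free cells with a 16-move neighbourhood (rook, bishop and
knight steps whose swept cells are all free) and runs sparse Dijkstra.
Knight moves keep the metric distortion of the grid below ~3%, so the
oracle over-estimates the true shortest water path by at most about 3%
plus a few cell widths of snapping/discretisation slack.
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.strtree import STRtree

# (di, dj, weight_in_cells, intermediate cells that must be free)
_MOVES = [
    (1, 0, 1.0, []),
    (0, 1, 1.0, []),
    (1, 1, math.sqrt(2), []),
    (1, -1, math.sqrt(2), []),
    (2, 1, math.sqrt(5), [(1, 0), (1, 1)]),
    (2, -1, math.sqrt(5), [(1, 0), (1, -1)]),
    (1, 2, math.sqrt(5), [(0, 1), (1, 1)]),
    (1, -2, math.sqrt(5), [(0, -1), (1, -1)]),
]


class RasterWaterOracle:
    def __init__(self, islands, bounds, cell=0.5):
        self.cell = cell
        minx, miny, maxx, maxy = bounds
        self.minx, self.miny = minx, miny
        self.ni = int(math.ceil((maxx - minx) / cell))
        self.nj = int(math.ceil((maxy - miny) / cell))
        xs0 = minx + cell * np.repeat(np.arange(self.ni), self.nj)
        ys0 = miny + cell * np.tile(np.arange(self.nj), self.ni)
        boxes = shapely.box(xs0, ys0, xs0 + cell, ys0 + cell)
        tree = STRtree(islands)
        blocked_idx = np.unique(tree.query(boxes, predicate="intersects")[0])
        free = np.ones(self.ni * self.nj, dtype=bool)
        free[blocked_idx] = False
        self.free = free.reshape(self.ni, self.nj)

        # sparse undirected graph over free cells
        idx = -np.ones((self.ni, self.nj), dtype=np.int64)
        order = np.argwhere(self.free)
        idx[order[:, 0], order[:, 1]] = np.arange(len(order))
        self._cell_of_node = order
        self._node_of_cell = idx
        rows, cols, data = [], [], []
        for di, dj, w, inter in _MOVES:
            src = np.argwhere(self.free)
            dst = src + (di, dj)
            ok = (
                (dst[:, 0] >= 0) & (dst[:, 0] < self.ni)
                & (dst[:, 1] >= 0) & (dst[:, 1] < self.nj)
            )
            src, dst = src[ok], dst[ok]
            ok = self.free[dst[:, 0], dst[:, 1]]
            src, dst = src[ok], dst[ok]
            for ii, jj in inter:
                mid = src + (ii, jj)
                ok = (
                    (mid[:, 0] >= 0) & (mid[:, 0] < self.ni)
                    & (mid[:, 1] >= 0) & (mid[:, 1] < self.nj)
                )
                ok &= np.where(ok, self.free[np.clip(mid[:, 0], 0, self.ni - 1),
                                             np.clip(mid[:, 1], 0, self.nj - 1)], False)
                src, dst = src[ok], dst[ok]
            rows.append(idx[src[:, 0], src[:, 1]])
            cols.append(idx[dst[:, 0], dst[:, 1]])
            data.append(np.full(len(src), w * self.cell))
        n = len(order)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        self.graph = coo_matrix(
            (np.concatenate([data, data]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n, n),
        ).tocsr()

    def snap(self, x, y):
        """(node, snap_distance) of the nearest free cell center."""
        centers = (
            self.minx + (self._cell_of_node[:, 0] + 0.5) * self.cell,
            self.miny + (self._cell_of_node[:, 1] + 0.5) * self.cell,
        )
        d2 = (centers[0] - x) ** 2 + (centers[1] - y) ** 2
        k = int(np.argmin(d2))
        return k, float(math.sqrt(d2[k]))

    def distances_from(self, nodes):
        """Dijkstra distance matrix (len(nodes), n_free_cells)."""
        return dijkstra(self.graph, indices=np.asarray(nodes), directed=False)
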