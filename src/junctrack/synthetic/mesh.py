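"""Polygonal cell-sheet mesh with t1 (neighbor-exchange) surgery.

The tissue generator keeps an explicit vertex mesh: vertex positions (µm,
x = image column, y = image row), cells as sets of vertex ids, and interior
interfaces as a map from the unordered cell pair to its two endpoint
vertices.  Cell polygons are recovered by angular ordering about the cell
centroid (cells stay near-convex under the scripted kinematics), which keeps
the t1 connectivity surgery to simple set updates.

A t1 flip of the interface between cells (a, b) with endpoints (u, w) and
side cells c (third cell at u) and d (third cell at w) collapses u and w to
their midpoint and re-splits perpendicular to the old interface: a and b each
retain a single new vertex, c and d gain the new interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Pair = frozenset


def _perp(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


@dataclass
class PolygonMesh:
    positions: np.ndarray                     # (n_vertices, 2) µm
    cells: dict[int, set[int]]                # cell id -> vertex ids
    edges: dict[frozenset, list[int]]         # {cell_a, cell_b} -> [u, w]

    # ------------------------------------------------------------ construction
    @classmethod
    def hex_grid(cls, rows: int, cols: int, edge_len_um: float) -> "PolygonMesh":
        """Regular honeycomb of rows×cols cells with vertical left/right sides.

        Cell ids are 1-based, cid = i*cols + j + 1 for grid position (i, j);
        horizontally adjacent cells share a vertical interface (θ = 0°).
        """
        if rows < 4 or cols < 4:
            raise ValueError("grid must be at least 4x4 so interior cells exist")
        a = edge_len_um
        sq3 = np.sqrt(3.0)
        hex_angles = np.radians([30, 90, 150, 210, 270, 330])
        offsets = a * np.stack([np.cos(hex_angles), np.sin(hex_angles)], axis=1)

        vindex: dict[tuple[int, int], int] = {}
        verts: list[np.ndarray] = []
        cells: dict[int, set[int]] = {}
        tol = a * 1e-3
        for i in range(rows):
            for j in range(cols):
                cx = sq3 * a * (j + 0.5 * (i % 2)) + sq3 * a
                cy = 1.5 * a * i + 2 * a
                cid = i * cols + j + 1
                vids = set()
                for off in offsets:
                    p = np.array([cx, cy]) + off
                    key = (int(round(p[0] / tol)), int(round(p[1] / tol)))
                    if key not in vindex:
                        vindex[key] = len(verts)
                        verts.append(p)
                    vids.add(vindex[key])
                cells[cid] = vids

        mesh = cls(np.array(verts), cells, {})
        mesh._rebuild_edges()
        return mesh

    def _rebuild_edges(self) -> None:
        self.edges = {}
        cids = sorted(self.cells)
        for i, a in enumerate(cids):
            for b in cids[i + 1:]:
                shared = self.cells[a] & self.cells[b]
                if len(shared) == 2:
                    self.edges[Pair((a, b))] = sorted(shared)

    # ---------------------------------------------------------------- queries
    def vertex_cells(self, vid: int) -> set[int]:
        return {cid for cid, vs in self.cells.items() if vid in vs}

    def vertex_cell_index(self) -> dict[int, set[int]]:
        idx: dict[int, set[int]] = {}
        for cid, vs in self.cells.items():
            for v in vs:
                idx.setdefault(v, set()).add(cid)
        return idx

    def boundary_cells(self) -> set[int]:
        """Cells with at least one vertex not shared by three cells."""
        idx = self.vertex_cell_index()
        return {cid for cid, vs in self.cells.items()
                if any(len(idx[v]) < 3 for v in vs)}

    def centroid(self, cid: int, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        return pos[sorted(self.cells[cid])].mean(axis=0)

    def polygon(self, cid: int, positions: np.ndarray | None = None) -> np.ndarray:
        """Cell outline as an angularly ordered (n, 2) coordinate array."""
        pos = self.positions if positions is None else positions
        vids = sorted(self.cells[cid])
        pts = pos[vids]
        ctr = pts.mean(axis=0)
        order = np.argsort(np.arctan2(pts[:, 1] - ctr[1], pts[:, 0] - ctr[0]))
        return pts[order]

    def edge_vector(self, pair: frozenset) -> tuple[np.ndarray, float]:
        u, w = self.edges[pair]
        d = self.positions[w] - self.positions[u]
        return d, float(np.hypot(*d))

    def edge_theta_image(self, pair: frozenset) -> float:
        """Image-frame orientation angle of an interface, degrees in (-90, 90]."""
        d, length = self.edge_vector(pair)
        if length == 0:
            return float("nan")
        th = np.degrees(np.arctan2(d[0], d[1]))
        th = (th + 90.0) % 180.0 - 90.0
        return 90.0 if th == -90.0 else float(th)

    # ---------------------------------------------------------------- surgery
    def can_flip(self, pair: frozenset) -> bool:
        """Whether a t1 flip of this interface is topologically safe."""
        if pair not in self.edges:
            return False
        a, b = sorted(pair)
        u, w = self.edges[pair]
        idx = self.vertex_cell_index()
        cu, cw = idx.get(u, set()), idx.get(w, set())
        if len(cu) != 3 or len(cw) != 3:
            return False
        c = (cu - pair)
        d = (cw - pair)
        if len(c) != 1 or len(d) != 1:
            return False
        c, d = c.pop(), d.pop()
        if c == d or Pair((c, d)) in self.edges:
            return False
        # collapsing (u, w) removes a vertex from a and b
        if len(self.cells[a]) <= 3 or len(self.cells[b]) <= 3:
            return False
        return True

    def t1_flip(self, pair: frozenset, new_len_um: float) -> tuple[frozenset, tuple[int, int]]:
        """Perform the neighbor exchange; returns (new cell pair, new vertex ids).

        Caller must have checked :meth:`can_flip`.
        """
        a, b = sorted(pair)
        u, w = self.edges[pair]
        idx = self.vertex_cell_index()
        c = (idx[u] - pair).pop()
        d = (idx[w] - pair).pop()

        pu, pw = self.positions[u], self.positions[w]
        m = 0.5 * (pu + pw)
        dvec = pw - pu
        norm = np.hypot(*dvec)
        if norm == 0:
            # degenerate: pick the direction toward c as reference
            dvec = self.centroid(c) - m
            norm = np.hypot(*dvec) or 1.0
        n_hat = _perp(dvec / norm)

        ca = self.centroid(a)
        sign = 1.0 if float(np.dot(n_hat, ca - m)) >= 0 else -1.0
        pa_pos = m + sign * 0.5 * new_len_um * n_hat
        pb_pos = m - sign * 0.5 * new_len_um * n_hat
        pa = len(self.positions)
        pb = pa + 1
        self.positions = np.vstack([self.positions, pa_pos[None], pb_pos[None]])

        self.cells[a] = (self.cells[a] - {u, w}) | {pa}
        self.cells[b] = (self.cells[b] - {u, w}) | {pb}
        self.cells[c] = (self.cells[c] - {u}) | {pa, pb}
        self.cells[d] = (self.cells[d] - {w}) | {pa, pb}

        del self.edges[pair]
        for epair, vids in self.edges.items():
            for old in (u, w):
                if old in vids:
                    repl = pa if a in epair else pb
                    vids[vids.index(old)] = repl
        new_pair = Pair((c, d))
        self.edges[new_pair] = [pa, pb]
        return new_pair, (pa, pb)

    def clamp_edge(self, pair: frozenset, min_len_um: float) -> None:
        """Push an interface's endpoints apart to a minimum length (no flip)."""
        u, w = self.edges[pair]
        d, length = self.edge_vector(pair)
        if length >= min_len_um:
            return
        m = 0.5 * (self.positions[u] + self.positions[w])
        if length == 0:
            d = np.array([0.0, 1.0])
            length = 1.0
        u_hat = d / length
        self.positions[u] = m - 0.5 * min_len_um * u_hat
        self.positions[w] = m + 0.5 * min_len_um * u_hat

    # --------------------------------------------------------------- geometry
    def cell_area(self, cid: int, positions: np.ndarray | None = None) -> float:
        poly = self.polygon(cid, positions)
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
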