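"""Hexagonal-lattice tissue construction and exact polygon / shape-tensor math.

Everything here is shared by the two vertex-model solvers and by the
morphometrics stage: building the initial regular honeycomb, shoelace
area/perimeter, area-weighted polygon moments, and the gyration-tensor
elongation and orientation summary used to quantify cell shape.

Lengths are dimensionless: the unit of length is the square root of the
target cell area, so every cell of the initial lattice has area exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HEX_SIDE",
    "HEX_PERIMETER",
    "Tissue2D",
    "ShapeTensorSummary",
    "build_hex_lattice",
    "polygon_measures",
    "polygon_moments",
    "shape_summary",
    "fold_angle_deg",
    "write_off",
    "write_vtk",
]

# Side length of a regular hexagon of unit area: A = (3*sqrt(3)/2) s^2 = 1.
HEX_SIDE: float = float(np.sqrt(2.0 / (3.0 * np.sqrt(3.0))))
# Perimeter of that hexagon, 6 s = 3.72242...; the reference value for the
# target perimeter p0 = 3.7 "just below the perimeter of a regular hexagon".
HEX_PERIMETER: float = 6.0 * HEX_SIDE


class DegeneratePolygonError(ValueError):
    """Polygon has too few points or zero extent."""


class OrientationError(ValueError):
    """Polygon loop is not counterclockwise (signed area <= 0)."""


@dataclass
class Tissue2D:
    """A polygonal cell mesh evolved by the 2D vertex model.

    Attributes
    ----------
    positions : (V, 2) float array
        Vertex positions in units of sqrt(target area).
    cells : (N, 6) int array
        Counterclockwise vertex-index loops; the lattice is hexagonal and
        neighbor relations never change (no T1 transitions), so every cell
        keeps six vertices for its whole life.
    is_plate, constricting, frozen : (N,) bool arrays
        Region membership, apical-constriction flag, and the immobile
        outermost ring enforcing fixed boundary conditions.
    p0 : (N,) float array
        Per-cell target perimeter; constricting cells carry the reduced
        value (10% of baseline).
    k_p : float
        Perimeter elasticity modulus (dimensionless).
    grid_index : (N, 2) int array
        (column, row) of each cell in the generating lattice; used for
        edge-group selection and hinge layouts, never by the dynamics.
    """

    positions: np.ndarray
    cells: np.ndarray
    is_plate: np.ndarray
    constricting: np.ndarray
    frozen: np.ndarray
    p0: np.ndarray
    k_p: float
    grid_index: np.ndarray
    plate_spec: tuple[int, int]
    tissue_spec: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def free_vertex_mask(self) -> np.ndarray:
        """True for vertices not belonging to any frozen cell."""
        free = np.ones(self.n_vertices, dtype=bool)
        free[self.cells[self.frozen].ravel()] = False
        return free

    def cell_polygons(self) -> np.ndarray:
        """Vertex coordinates gathered per cell, shape (N, 6, 2)."""
        return self.positions[self.cells]

    def areas(self) -> np.ndarray:
        P = self.cell_polygons()
        Q = np.roll(P, -1, axis=1)
        return 0.5 * np.sum(P[..., 0] * Q[..., 1] - Q[..., 0] * P[..., 1], axis=1)

    def perimeters(self) -> np.ndarray:
        P = self.cell_polygons()
        E = np.roll(P, -1, axis=1) - P
        return np.linalg.norm(E, axis=2).sum(axis=1)

    def centers(self) -> np.ndarray:
        """Vertex-average cell centers, shape (N, 2)."""
        return self.cell_polygons().mean(axis=1)

    def copy(self) -> "Tissue2D":
        return Tissue2D(
            positions=self.positions.copy(),
            cells=self.cells.copy(),
            is_plate=self.is_plate.copy(),
            constricting=self.constricting.copy(),
            frozen=self.frozen.copy(),
            p0=self.p0.copy(),
            k_p=self.k_p,
            grid_index=self.grid_index.copy(),
            plate_spec=tuple(self.plate_spec),
            tissue_spec=tuple(self.tissue_spec),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "platefold-tissue2d",
            "version": 1,
            "vertices": self.positions.tolist(),
            "cells": self.cells.tolist(),
            "is_plate": self.is_plate.astype(int).tolist(),
            "constricting": self.constricting.astype(int).tolist(),
            "frozen": self.frozen.astype(int).tolist(),
            "p0": self.p0.tolist(),
            "k_p": self.k_p,
            "grid_index": self.grid_index.tolist(),
            "plate_spec": list(self.plate_spec),
            "tissue_spec": list(self.tissue_spec),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "Tissue2D":
        if d.get("format") != "platefold-tissue2d":
            raise ValueError("not a platefold 2D tissue record")
        return cls(
            positions=np.asarray(d["vertices"], dtype=float),
            cells=np.asarray(d["cells"], dtype=np.intp),
            is_plate=np.asarray(d["is_plate"], dtype=bool),
            constricting=np.asarray(d["constricting"], dtype=bool),
            frozen=np.asarray(d["frozen"], dtype=bool),
            p0=np.asarray(d["p0"], dtype=float),
            k_p=float(d["k_p"]),
            grid_index=np.asarray(d["grid_index"], dtype=int),
            plate_spec=tuple(d["plate_spec"]),
            tissue_spec=tuple(d["tissue_spec"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Tissue2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ShapeTensorSummary:
    """Gyration-tensor description of a single cell's shape.

    ``tensor`` is the second-moment (gyration) tensor of the vertex
    positions about their mean.  ``kappa`` is the elongation
    (g1 - g2) / (g1 + g2) of the two leading eigenvalues (0 for an
    isotropic cell, approaching 1 for a needle), and ``theta_deg`` the
    angle between the leading eigenvector and the reference axis, folded
    to [0, 90] degrees (eigenvector sign is meaningless).  For an exactly
    isotropic cell the orientation is undefined and ``theta_deg`` is NaN.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    kappa: float
    theta_deg: float


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------

# Pointy-top hexagon corner offsets on the integer lattice (units of
# half-width, half-side), counterclockwise starting at 30 degrees.
_HEX_CORNERS_INT = ((1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1))


def build_hex_lattice(
    nx_tissue: int,
    ny_tissue: int,
    plate: tuple[int, int],
    p0: float = 3.7,
    k_p: float = 1.0,
) -> Tissue2D:
    """Build a regular honeycomb tissue with a centered plate region.

    Parameters
    ----------
    nx_tissue, ny_tissue : int
        Cells along the AP axis (x) and perpendicular to it (y).
    plate : (int, int)
        (N_x, N_y) extent of the centered plate region, in cell units.
    p0 : float
        Baseline target perimeter given to every cell (constriction is
        assigned later by the solver).
    k_p : float
        Perimeter elasticity modulus.

    The lattice is built from pointy-top hexagons of unit area; consecutive
    rows are offset by half a cell width.  Plate membership selects, in each
    of the centered ``N_y`` rows, the cells nearest the tissue midline;
    rows whose cell centers straddle the midline symmetrically keep both
    tied boundary cells, which yields the alternating extra cell that makes
    the plate symmetric about the AP axis.  The outermost ring of cells is
    frozen (fixed boundary conditions).
    """
    nx_p, ny_p = plate
    if nx_p <= 0 or ny_p <= 0:
        raise ValueError("plate dimensions must be positive")
    if nx_tissue < nx_p + 2 or ny_tissue < ny_p + 2:
        raise ValueError(
            f"plate {nx_p}x{ny_p} does not fit inside tissue "
            f"{nx_tissue}x{ny_tissue}: need at least a one-cell margin "
            "for the frozen boundary ring on every side"
        )

    s = HEX_SIDE
    half_w = 0.5 * np.sqrt(3.0) * s  # half cell width
    half_s = 0.5 * s

    vertex_key_to_id: dict[tuple[int, int], int] = {}
    cells = np.empty((nx_tissue * ny_tissue, 6), dtype=np.intp)
    grid = np.empty((nx_tissue * ny_tissue, 2), dtype=int)

    c = 0
    for j in range(ny_tissue):
        for i in range(nx_tissue):
            # cell center on the integer lattice
            cx = 2 * i + (j % 2)
            cy = 3 * j
            for k, (dx, dy) in enumerate(_HEX_CORNERS_INT):
                key = (cx + dx, cy + dy)
                vid = vertex_key_to_id.setdefault(key, len(vertex_key_to_id))
                cells[c, k] = vid
            grid[c] = (i, j)
            c += 1

    positions = np.empty((len(vertex_key_to_id), 2), dtype=float)
    for (kx, ky), vid in vertex_key_to_id.items():
        positions[vid, 0] = kx * half_w
        positions[vid, 1] = ky * half_s

    # plate membership: centered band of ny_p rows; per row, the cells whose
    # centers are nearest the tissue midline (ties at the boundary included)
    i_idx, j_idx = grid[:, 0], grid[:, 1]
    centers_x_units = i_idx + 0.5 * (j_idx % 2)  # in units of cell width
    x_mid = 0.5 * (centers_x_units.min() + centers_x_units.max())
    j_mid = 0.5 * (ny_tissue - 1)

    is_plate = np.zeros(len(cells), dtype=bool)
    row_ok = np.abs(j_idx - j_mid) <= 0.5 * (ny_p - 1) + 1e-9
    for j in np.unique(j_idx[row_ok]):
        row = np.where(row_ok & (j_idx == j))[0]
        d = np.abs(centers_x_units[row] - x_mid)
        cutoff = np.sort(d)[nx_p - 1] + 1e-9
        is_plate[row[d <= cutoff]] = True

    frozen = (
        (i_idx == 0)
        | (i_idx == nx_tissue - 1)
        | (j_idx == 0)
        | (j_idx == ny_tissue - 1)
    )

    return Tissue2D(
        positions=positions,
        cells=cells,
        is_plate=is_plate,
        constricting=np.zeros(len(cells), dtype=bool),
        frozen=frozen,
        p0=np.full(len(cells), float(p0)),
        k_p=float(k_p),
        grid_index=grid,
        plate_spec=(nx_p, ny_p),
        tissue_spec=(nx_tissue, ny_tissue),
    )


# ---------------------------------------------------------------------------
# Polygon measures
# ---------------------------------------------------------------------------

def polygon_measures(loop: np.ndarray) -> tuple[float, float]:
    """Shoelace area and Euclidean perimeter of a counterclockwise loop.

    Raises
    ------
    DegeneratePolygonError
        Fewer than 3 points.
    OrientationError
        Signed area is not positive (clockwise or degenerate loop).
    """
    loop = np.asarray(loop, dtype=float)
    if loop.ndim != 2 or loop.shape[0] < 3 or loop.shape[1] != 2:
        raise DegeneratePolygonError("polygon needs at least 3 planar points")
    nxt = np.roll(loop, -1, axis=0)
    signed = 0.5 * np.sum(loop[:, 0] * nxt[:, 1] - nxt[:, 0] * loop[:, 1])
    if signed <= 0:
        raise OrientationError(
            f"polygon loop must be counterclockwise (signed area {signed:g})"
        )
    perimeter = float(np.linalg.norm(nxt - loop, axis=1).sum())
    return float(signed), perimeter


def polygon_moments(loop: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and area-weighted central second moments of a polygon.

    The second-moment matrix is the covariance of the uniform distribution
    over the polygon interior (the continuous analogue of an image region's
    normalized second central moments), computed in closed form from the
    shoelace decomposition.  This is deliberately distinct from the
    vertex-based gyration tensor of :func:`shape_summary`.
    """
    area, _ = polygon_measures(loop)
    loop = np.asarray(loop, dtype=float)
    x, y = loop[:, 0], loop[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y1 - x1 * y
    cx = np.sum((x + x1) * cr) / (6.0 * area)
    cy = np.sum((y + y1) * cr) / (6.0 * area)
    exx = np.sum((x * x + x * x1 + x1 * x1) * cr) / (12.0 * area) - cx * cx
    eyy = np.sum((y * y + y * y1 + y1 * y1) * cr) / (12.0 * area) - cy * cy
    exy = (
        np.sum((x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y) * cr)
        / (24.0 * area)
        - cx * cy
    )
    cov = np.array([[exx, exy], [exy, eyy]])
    return area, np.array([cx, cy]), cov


# ---------------------------------------------------------------------------
# Gyration tensor
# ---------------------------------------------------------------------------

def fold_angle_deg(theta: float) -> float:
    """Fold an angle in degrees into [0, 90] (axis, not direction)."""
    t = np.mod(theta, 180.0)
    return float(min(t, 180.0 - t))


def shape_summary(
    points: np.ndarray, reference_axis: np.ndarray | None = None
) -> ShapeTensorSummary:
    """Gyration tensor, elongation and orientation of a point set.

    The tensor is the unweighted second moment of the points about their
    mean (vertex average, not the area centroid).  Works for 2D and 3D
    point sets; in 3D the elongation uses the two leading eigenvalues and
    the orientation is measured for the leading eigenvector.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegeneratePolygonError("need at least 2 points")
    dim = pts.shape[1]
    if reference_axis is None:
        reference_axis = np.zeros(dim)
        reference_axis[0] = 1.0
    axis = np.asarray(reference_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    centered = pts - pts.mean(axis=0)
    if not np.any(np.abs(centered) > 0):
        raise DegeneratePolygonError("all points coincide; shape undefined")
    S = centered.T @ centered / len(pts)
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    g1, g2 = eigvals[0], eigvals[1]
    kappa = float((g1 - g2) / (g1 + g2))
    if kappa < 1e-12:
        theta = float("nan")  # isotropic: orientation undefined
    else:
        cosang = np.clip(abs(float(eigvecs[:, 0] @ axis)), 0.0, 1.0)
        theta = float(np.degrees(np.arccos(cosang)))
    return ShapeTensorSummary(
        tensor=S, eigenvalues=eigvals, kappa=kappa, theta_deg=theta
    )


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def write_off(path: str | Path, vertices: np.ndarray, faces) -> None:
    """Write a polygon mesh as ASCII OFF (2D vertices padded with z=0)."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[1] == 2:
        vertices = np.c_[vertices, np.zeros(len(vertices))]
    lines = ["OFF", f"{len(vertices)} {len(faces)} 0"]
    lines += [f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}" for v in vertices]
    for f in faces:
        lines.append(str(len(f)) + " " + " ".join(str(int(i)) for i in f))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk(path: str | Path, vertices: np.ndarray, faces, name="tissue") -> None:
    """Write a polygon mesh as legacy ASCII VTK polydata."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[1] == 2:
        vertices = np.c_[vertices, np.zeros(len(vertices))]
    out = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} double",
    ]
    out += [f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}" for v in vertices]
    size = sum(len(f) + 1 for f in faces)
    out.append(f"POLYGONS {len(faces)} {size}")
    for f in faces:
        out.append(str(len(f)) + " " + " ".join(str(int(i)) for i in f))
    Path(path).write_text("\n".join(out) + "\n")
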