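"""3D vertex model of hinge furrowing in a prism-cell monolayer.

Cells are hexagonal prisms with distinct apical and basal polygon loops and
lateral quadrilaterals, with dimensionless energy

    e = sum_c [ alpha*a_a + beta*a_b + 1/2*a_l
                + k_p (p_a - p0)^2 + k_V (v - 1)^2 ],

where a_a, a_b, a_l are the apical, basal and lateral surface areas, p_a
the apical perimeter, v the cell volume, alpha and beta the apical and
basal surface tensions relative to the lateral one, and the 1/2 accounts
for each lateral face being shared by two cells.  Lengths are measured in
units of the cube root of the target cell volume.  With alpha = beta = 0.5
(a cuboidal tissue) the equilibrium apical perimeter of a hexagonal
honeycomb without perimeter elasticity is 2*6^(1/3)*(alpha+beta)^(-1/3);
that value is the target perimeter of non-constricting cells, and
constricting cells get 10% of it.

The patch is periodic along the AP axis (x); the outermost cell rows
perpendicular to AP are frozen.  Faces are fan-triangulated about their
vertex centroid and volumes are sums of signed origin tetrahedra over the
closed triangulated surface; the same decomposition is used for the energy
and its analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .vertex2d import CONSTRICTION_FACTOR, EDGE_EPS, Diagnostics

__all__ = [
    "Tissue3D",
    "build_prism_tissue",
    "target_apical_perimeter",
    "energy3d",
    "forces3d",
    "relax3d",
    "furrow_profile",
    "apical_shape_table",
]


class NegativeVolumeError(RuntimeError):
    """A prism cell has non-positive volume."""


# Fan-triangle areas enter the energy as sqrt(|n|^2 + AREA_EPS^2) (n the
# triangle cross product).  When a constricting cell's apical loop
# collapses, sliver triangles in the adjacent lateral-quad fans sit at a
# cone of the raw area (the normal direction flips), where forces cannot
# vanish; smoothing at this scale (area error ~5e-9 on intact faces)
# rounds the cone so the descent can converge.  Mirrors the 2D edge-length
# smoothing.
AREA_EPS = 1e-4


def target_apical_perimeter(alpha: float, beta: float) -> float:
    """Equilibrium apical perimeter of a honeycomb without perimeter elasticity."""
    return 2.0 * 6.0 ** (1.0 / 3.0) * (alpha + beta) ** (-1.0 / 3.0)


@dataclass
class Tissue3D:
    """Monolayer of hexagonal prism cells, periodic along AP (x).

    ``positions`` stacks the apical vertex block above the basal block.
    ``apical``/``basal`` are per-cell counterclockwise loops (seen from
    +z) into the global vertex array, with ``shift`` holding the periodic
    x-image (0 or 1 box length) applied when gathering each loop slot.
    """

    positions: np.ndarray  # (V, 3)
    apical: np.ndarray  # (N, 6)
    basal: np.ndarray  # (N, 6)
    shift: np.ndarray  # (N, 6) ints, x-image per loop slot
    constricting: np.ndarray
    frozen: np.ndarray
    p0: np.ndarray
    alpha: float
    beta: float
    k_p: float
    k_V: float
    box_length: float
    grid_index: np.ndarray
    hinge: np.ndarray  # per-cell: in the constriction-eligible band

    @property
    def n_cells(self) -> int:
        return len(self.apical)

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def free_vertex_mask(self) -> np.ndarray:
        free = np.ones(self.n_vertices, dtype=bool)
        fro = self.frozen
        free[self.apical[fro].ravel()] = False
        free[self.basal[fro].ravel()] = False
        return free

    def _gather(self, loops: np.ndarray, pos: np.ndarray | None = None):
        p = (self.positions if pos is None else pos)[loops]
        p = p.copy()
        p[..., 0] += self.shift * self.box_length
        return p

    def apical_coords(self, pos=None) -> np.ndarray:
        return self._gather(self.apical, pos)

    def basal_coords(self, pos=None) -> np.ndarray:
        return self._gather(self.basal, pos)

    def volumes(self) -> np.ndarray:
        _, vols, _ = _energy_grad3(self, self.positions, need_grad=False)
        return vols

    def copy(self) -> "Tissue3D":
        return Tissue3D(
            positions=self.positions.copy(),
            apical=self.apical,
            basal=self.basal,
            shift=self.shift,
            constricting=self.constricting.copy(),
            frozen=self.frozen.copy(),
            p0=self.p0.copy(),
            alpha=self.alpha,
            beta=self.beta,
            k_p=self.k_p,
            k_V=self.k_V,
            box_length=self.box_length,
            grid_index=self.grid_index,
            hinge=self.hinge.copy(),
        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

_HEX_CORNERS_INT = ((1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1))


def build_prism_tissue(
    n_ap: int = 20,
    n_perp: int = 40,
    hinge_width: int = 3,
    p_c: float = 0.5,
    seed: int = 0,
    alpha: float = 0.5,
    beta: float = 0.5,
    k_p: float = 1.0,
    k_V: float = 100.0,
) -> Tissue3D:
    """Flat honeycomb monolayer of unit-volume prisms with a hinge band.

    The in-plane hexagon side is the equilibrium side of the tension model
    at unit volume, so the flat lattice with the default target perimeter
    is a stationary state.  The hinge band is ``hinge_width`` cell rows
    centered in the perpendicular (y) direction; each hinge cell is
    flagged constricting with probability ``p_c``.  The outermost rows
    perpendicular to AP are frozen.
    """
    if hinge_width < 1 or hinge_width > n_perp - 4:
        raise ValueError("hinge band must fit inside the non-frozen interior")
    # equilibrium hexagon side: minimizes (alpha+beta)*A + 3*s/A at v=1
    s = (2.0 / (9.0 * (alpha + beta))) ** (1.0 / 3.0)
    area = 1.5 * np.sqrt(3.0) * s * s
    height = 1.0 / area
    half_w = 0.5 * np.sqrt(3.0) * s
    half_s = 0.5 * s
    box_length = n_ap * 2 * half_w

    key_to_id: dict[tuple[int, int], int] = {}
    n_cells = n_ap * n_perp
    loops = np.empty((n_cells, 6), dtype=np.intp)
    shifts = np.zeros((n_cells, 6), dtype=np.int8)
    grid = np.empty((n_cells, 2), dtype=int)
    kx_period = 2 * n_ap
    c = 0
    for j in range(n_perp):
        for i in range(n_ap):
            cx = 2 * i + (j % 2)
            cy = 3 * j
            for k, (dx, dy) in enumerate(_HEX_CORNERS_INT):
                kx_raw = cx + dx
                sh, kx = divmod(kx_raw, kx_period)
                key = (kx, cy + dy)
                vid = key_to_id.setdefault(key, len(key_to_id))
                loops[c, k] = vid
                shifts[c, k] = sh
            grid[c] = (i, j)
            c += 1

    n_v2 = len(key_to_id)
    plane = np.empty((n_v2, 2))
    for (kx, ky), vid in key_to_id.items():
        plane[vid] = (kx * half_w, ky * half_s)

    positions = np.empty((2 * n_v2, 3))
    positions[:n_v2, :2] = plane
    positions[:n_v2, 2] = height  # apical on top
    positions[n_v2:, :2] = plane
    positions[n_v2:, 2] = 0.0

    j_idx = grid[:, 1]
    frozen = (j_idx == 0) | (j_idx == n_perp - 1)
    j_mid = 0.5 * (n_perp - 1)
    all_rows = np.arange(n_perp)
    order = np.lexsort((all_rows, np.abs(all_rows - j_mid)))
    hinge_rows = set(all_rows[order[:hinge_width]])
    hinge = np.isin(j_idx, list(hinge_rows))
    if np.any(hinge & frozen):
        raise ValueError("hinge band overlaps the frozen boundary rows")

    p0_val = target_apical_perimeter(alpha, beta)
    rng = np.random.default_rng(seed)
    order = np.lexsort((grid[:, 0], grid[:, 1]))
    eligible = order[hinge[order]]
    constricting = np.zeros(n_cells, dtype=bool)
    constricting[eligible[rng.random(len(eligible)) < p_c]] = True
    p0 = np.full(n_cells, p0_val)
    p0[constricting] = CONSTRICTION_FACTOR * p0_val

    return Tissue3D(
        positions=positions,
        apical=loops,
        basal=loops + n_v2,
        shift=shifts,
        constricting=constricting,
        frozen=frozen,
        p0=p0,
        alpha=alpha,
        beta=beta,
        k_p=k_p,
        k_V=k_V,
        box_length=box_length,
        grid_index=grid,
        hinge=hinge,
    )


# ---------------------------------------------------------------------------
# Fan-decomposition primitives (areas, volumes and their gradients)
# ---------------------------------------------------------------------------

def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product on the last axis (faster than np.cross for small arrays)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def _fan_area(V: np.ndarray, need_grad: bool):
    """Total fan-triangulated area of loops V (..., n, 3) and its gradient.

    Triangle areas are smoothed at AREA_EPS; the gradient of
    sqrt(|n|^2 + eps^2)/2 is the raw cross-product gradient scaled by
    |n|/sqrt(|n|^2 + eps^2), i.e. n replaces nhat by n/l_eps.
    """
    cen = V.mean(axis=-2, keepdims=True)
    P = V - cen
    Q = np.roll(V, -1, axis=-2) - cen
    nvec = _cross(P, Q)
    nn2 = np.einsum("...k,...k->...", nvec, nvec)
    leps = np.sqrt(nn2 + AREA_EPS**2)
    area = 0.5 * leps.sum(axis=-1)
    if not need_grad:
        return area, None
    nhat = nvec / leps[..., None]
    gP = 0.5 * _cross(Q, nhat)
    gQ = 0.5 * _cross(nhat, P)
    gV = gP + np.roll(gQ, 1, axis=-2)
    gC = -(gP + gQ).sum(axis=-2, keepdims=True) / V.shape[-2]
    return area, gV + gC


def _fan_volume(V: np.ndarray, need_grad: bool):
    """Signed volume contribution of an outward-oriented loop fan (origin tets)."""
    cen = V.mean(axis=-2, keepdims=True)
    Vn = np.roll(V, -1, axis=-2)
    cross_vn = _cross(V, Vn)
    vol = np.einsum("...k,...ik->...i", cen[..., 0, :], cross_vn).sum(-1) / 6.0
    if not need_grad:
        return vol, None
    c = cen[..., 0, :]
    # d/dV_i: cross(V_{i+1}, c)/6 from term i, cross(c, V_{i-1})/6 from term i-1
    gV = (_cross(Vn, c[..., None, :]) +
          np.roll(_cross(c[..., None, :], V), 1, axis=-2)) / 6.0
    gC = cross_vn.sum(axis=-2) / 6.0 / V.shape[-2]
    return vol, gV + gC[..., None, :]


def _energy_grad3(tissue: Tissue3D, pos: np.ndarray, need_grad: bool = True):
    """Fused energy, per-cell volumes, and per-vertex gradient."""
    A = tissue.apical_coords(pos)  # (N, 6, 3)
    B = tissue.basal_coords(pos)
    N = len(A)

    a_a, gA_a = _fan_area(A, need_grad)
    a_b, gB_b = _fan_area(B, need_grad)

    # lateral quads: slots (A_i, A_{i+1}, B_{i+1}, B_i)
    An = np.roll(A, -1, axis=1)
    Bn = np.roll(B, -1, axis=1)
    quads = np.stack((A, An, Bn, B), axis=2)  # (N, 6, 4, 3)
    a_l_q, gQ = _fan_area(quads, need_grad)
    a_l = a_l_q.sum(axis=1)

    # apical perimeter (smoothed edge lengths, as in 2D)
    e_ap = An - A
    l_ap = np.sqrt(np.einsum("ijk,ijk->ij", e_ap, e_ap) + EDGE_EPS**2)
    p_a = l_ap.sum(axis=1)

    # volume: apical fan up (+z out), basal fan reversed, lateral outward
    v_api, gV_api = _fan_volume(A, need_grad)
    v_bas, gV_bas = _fan_volume(B[:, ::-1], need_grad)
    quads_out = quads[:, :, ::-1]  # (A_i, B_i, B_{i+1}, A_{i+1}): outward
    v_lat, gV_lat = _fan_volume(quads_out, need_grad)
    vols = v_api + v_bas + v_lat.sum(axis=1)

    al, be, kp, kV = tissue.alpha, tissue.beta, tissue.k_p, tissue.k_V
    energy = float(
        np.sum(
            al * a_a + be * a_b + 0.5 * a_l
            + kp * (p_a - tissue.p0) ** 2 + kV * (vols - 1.0) ** 2
        )
    )
    if not need_grad:
        return energy, vols, None

    dE_dp = 2.0 * kp * (p_a - tissue.p0)
    dE_dv = 2.0 * kV * (vols - 1.0)

    # accumulate per-slot gradients for the apical and basal loops
    gA = al * gA_a + dE_dv[:, None, None] * gV_api
    gB = be * gB_b + dE_dv[:, None, None] * gV_bas[:, ::-1]

    unit = e_ap / l_ap[..., None]
    gA += dE_dp[:, None, None] * (np.roll(unit, 1, axis=1) - unit)

    # lateral faces: area term and volume term, mapped back to loop slots
    gQl = 0.5 * gQ + dE_dv[:, None, None, None] * gV_lat[:, :, ::-1]
    # quad slots: 0 -> A_i, 1 -> A_{i+1}, 2 -> B_{i+1}, 3 -> B_i
    gA += gQl[:, :, 0]
    gA += np.roll(gQl[:, :, 1], 1, axis=1)
    gB += np.roll(gQl[:, :, 2], 1, axis=1)
    gB += gQl[:, :, 3]

    grad = np.zeros((len(pos), 3))
    flat_a = tissue.apical.ravel()
    flat_b = tissue.basal.ravel()
    for d in range(3):
        grad[:, d] += np.bincount(flat_a, weights=gA[..., d].ravel(),
                                  minlength=len(pos))
        grad[:, d] += np.bincount(flat_b, weights=gB[..., d].ravel(),
                                  minlength=len(pos))
    return energy, vols, grad


try:  # JIT path: the relaxations take 1e4-1e7 gradient evaluations
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _cell_loops_kernel(pos, apical, basal, shift, box_length, p0,
                           alpha, beta, k_p, k_V, vols, grad,
                           need_grad):  # pragma: no cover
        n_cells = apical.shape[0]
        energy = 0.0
        A = np.empty((6, 3))
        B = np.empty((6, 3))
        Q = np.empty((4, 3))
        gL = np.empty((6, 3))
        gQ = np.empty((4, 3))
        eps2 = EDGE_EPS * EDGE_EPS
        for c in range(n_cells):
            for k in range(6):
                ia = apical[c, k]
                ib = basal[c, k]
                sx = shift[c, k] * box_length
                A[k, 0] = pos[ia, 0] + sx
                A[k, 1] = pos[ia, 1]
                A[k, 2] = pos[ia, 2]
                B[k, 0] = pos[ib, 0] + sx
                B[k, 1] = pos[ib, 1]
                B[k, 2] = pos[ib, 2]

            vol = 0.0
            dv = 0.0  # filled after volume known; two passes over fans

            # --- apical perimeter (smoothed) ---
            p_a = 0.0
            for k in range(6):
                kn = (k + 1) % 6
                ex = A[kn, 0] - A[k, 0]
                ey = A[kn, 1] - A[k, 1]
                ez = A[kn, 2] - A[k, 2]
                p_a += np.sqrt(ex * ex + ey * ey + ez * ez + eps2)

            # --- areas and volume (first pass, scalars only) ---
            a_a = _fan_area_scalar(A, 6)
            a_b = _fan_area_scalar(B, 6)
            vol = _fan_volume_scalar(A, 6, 1.0)
            vol += _fan_volume_scalar(B, 6, -1.0)
            a_l = 0.0
            for k in range(6):
                kn = (k + 1) % 6
                for d in range(3):
                    Q[0, d] = A[k, d]
                    Q[1, d] = A[kn, d]
                    Q[2, d] = B[kn, d]
                    Q[3, d] = B[k, d]
                a_l += _fan_area_scalar(Q, 4)
                vol += _fan_volume_scalar(Q, 4, -1.0)

            vols[c] = vol
            dp = p_a - p0[c]
            dvol = vol - 1.0
            energy += (alpha * a_a + beta * a_b + 0.5 * a_l
                       + k_p * dp * dp + k_V * dvol * dvol)

            if not need_grad:
                continue

            cp = 2.0 * k_p * dp
            cv = 2.0 * k_V * dvol

            # apical loop: area (alpha), perimeter, volume (+1 orientation)
            _fan_area_grad(A, 6, alpha, gL)
            _fan_volume_grad(A, 6, cv, gL)
            for k in range(6):
                kn = (k + 1) % 6
                ex = A[kn, 0] - A[k, 0]
                ey = A[kn, 1] - A[k, 1]
                ez = A[kn, 2] - A[k, 2]
                ln = np.sqrt(ex * ex + ey * ey + ez * ez + eps2)
                gL[k, 0] -= cp * ex / ln
                gL[k, 1] -= cp * ey / ln
                gL[k, 2] -= cp * ez / ln
                gL[kn, 0] += cp * ex / ln
                gL[kn, 1] += cp * ey / ln
                gL[kn, 2] += cp * ez / ln
            for k in range(6):
                ia = apical[c, k]
                for d in range(3):
                    grad[ia, d] += gL[k, d]

            # basal loop: area (beta), volume (reversed orientation)
            _fan_area_grad(B, 6, beta, gL)
            _fan_volume_grad(B, 6, -cv, gL)
            for k in range(6):
                ib = basal[c, k]
                for d in range(3):
                    grad[ib, d] += gL[k, d]

            # lateral quads: area (1/2 each) and volume (reversed)
            for k in range(6):
                kn = (k + 1) % 6
                for d in range(3):
                    Q[0, d] = A[k, d]
                    Q[1, d] = A[kn, d]
                    Q[2, d] = B[kn, d]
                    Q[3, d] = B[k, d]
                _fan_area_grad(Q, 4, 0.5, gQ)
                _fan_volume_grad(Q, 4, -cv, gQ)
                i0 = apical[c, k]
                i1 = apical[c, kn]
                i2 = basal[c, kn]
                i3 = basal[c, k]
                for d in range(3):
                    grad[i0, d] += gQ[0, d]
                    grad[i1, d] += gQ[1, d]
                    grad[i2, d] += gQ[2, d]
                    grad[i3, d] += gQ[3, d]
        return energy

    @njit(cache=True, fastmath=True, inline="always")
    def _fan_area_scalar(V, n):  # pragma: no cover
        cx = cy = cz = 0.0
        for i in range(n):
            cx += V[i, 0]; cy += V[i, 1]; cz += V[i, 2]
        cx /= n; cy /= n; cz /= n
        area = 0.0
        eps2 = AREA_EPS * AREA_EPS
        for i in range(n):
            j = (i + 1) % n
            px = V[i, 0] - cx; py = V[i, 1] - cy; pz = V[i, 2] - cz
            qx = V[j, 0] - cx; qy = V[j, 1] - cy; qz = V[j, 2] - cz
            nx = py * qz - pz * qy
            ny = pz * qx - px * qz
            nz = px * qy - py * qx
            area += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz + eps2)
        return area

    @njit(cache=True, fastmath=True, inline="always")
    def _fan_volume_scalar(V, n, orient):  # pragma: no cover
        cx = cy = cz = 0.0
        for i in range(n):
            cx += V[i, 0]; cy += V[i, 1]; cz += V[i, 2]
        cx /= n; cy /= n; cz /= n
        vol = 0.0
        for i in range(n):
            j = (i + 1) % n
            ax, ay, az = V[i, 0], V[i, 1], V[i, 2]
            bx, by, bz = V[j, 0], V[j, 1], V[j, 2]
            vol += (cx * (ay * bz - az * by)
                    + cy * (az * bx - ax * bz)
                    + cz * (ax * by - ay * bx)) / 6.0
        return orient * vol

    @njit(cache=True, fastmath=True, inline="always")
    def _fan_area_grad(V, n, coef, gout):  # pragma: no cover
        cx = cy = cz = 0.0
        for i in range(n):
            cx += V[i, 0]; cy += V[i, 1]; cz += V[i, 2]
        cx /= n; cy /= n; cz /= n
        for i in range(n):
            for d in range(3):
                gout[i, d] = 0.0
        gcx = gcy = gcz = 0.0
        eps2 = AREA_EPS * AREA_EPS
        for i in range(n):
            j = (i + 1) % n
            px = V[i, 0] - cx; py = V[i, 1] - cy; pz = V[i, 2] - cz
            qx = V[j, 0] - cx; qy = V[j, 1] - cy; qz = V[j, 2] - cz
            nx = py * qz - pz * qy
            ny = pz * qx - px * qz
            nz = px * qy - py * qx
            nn = np.sqrt(nx * nx + ny * ny + nz * nz + eps2)
            hx = nx / nn; hy = ny / nn; hz = nz / nn
            gpx = 0.5 * (qy * hz - qz * hy)
            gpy = 0.5 * (qz * hx - qx * hz)
            gpz = 0.5 * (qx * hy - qy * hx)
            gqx = 0.5 * (hy * pz - hz * py)
            gqy = 0.5 * (hz * px - hx * pz)
            gqz = 0.5 * (hx * py - hy * px)
            gout[i, 0] += coef * gpx
            gout[i, 1] += coef * gpy
            gout[i, 2] += coef * gpz
            gout[j, 0] += coef * gqx
            gout[j, 1] += coef * gqy
            gout[j, 2] += coef * gqz
            gcx -= coef * (gpx + gqx)
            gcy -= coef * (gpy + gqy)
            gcz -= coef * (gpz + gqz)
        for i in range(n):
            gout[i, 0] += gcx / n
            gout[i, 1] += gcy / n
            gout[i, 2] += gcz / n

    @njit(cache=True, fastmath=True, inline="always")
    def _fan_volume_grad(V, n, coef, gout):  # pragma: no cover
        # gout is ACCUMULATED into (area grad already there)
        cx = cy = cz = 0.0
        for i in range(n):
            cx += V[i, 0]; cy += V[i, 1]; cz += V[i, 2]
        cx /= n; cy /= n; cz /= n
        gcx = gcy = gcz = 0.0
        for i in range(n):
            j = (i + 1) % n
            ax, ay, az = V[i, 0], V[i, 1], V[i, 2]
            bx, by, bz = V[j, 0], V[j, 1], V[j, 2]
            # d/da of c.(a x b) = b x c ; d/db = c x a ; d/dc = a x b
            gout[i, 0] += coef * (by * cz - bz * cy) / 6.0
            gout[i, 1] += coef * (bz * cx - bx * cz) / 6.0
            gout[i, 2] += coef * (bx * cy - by * cx) / 6.0
            gout[j, 0] += coef * (cy * az - cz * ay) / 6.0
            gout[j, 1] += coef * (cz * ax - cx * az) / 6.0
            gout[j, 2] += coef * (cx * ay - cy * ax) / 6.0
            gcx += coef * (ay * bz - az * by) / 6.0
            gcy += coef * (az * bx - ax * bz) / 6.0
            gcz += coef * (ax * by - ay * bx) / 6.0
        for i in range(n):
            gout[i, 0] += gcx / n
            gout[i, 1] += gcy / n
            gout[i, 2] += gcz / n

    _HAVE_NUMBA3D = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA3D = False


def _energy_grad3_fast(tissue: Tissue3D, pos: np.ndarray, need_grad: bool = True):
    """JIT-backed energy/volumes/gradient; falls back to the numpy path."""
    if not _HAVE_NUMBA3D:
        return _energy_grad3(tissue, pos, need_grad)
    vols = np.empty(tissue.n_cells)
    grad = np.zeros((len(pos), 3)) if need_grad else np.zeros((1, 3))
    e = _cell_loops_kernel(
        pos, tissue.apical, tissue.basal, tissue.shift, tissue.box_length,
        tissue.p0, tissue.alpha, tissue.beta, tissue.k_p, tissue.k_V,
        vols, grad, need_grad,
    )
    return e, vols, (grad if need_grad else None)


def _check_volumes(vols: np.ndarray) -> None:
    bad_mask = vols <= 0
    if np.any(bad_mask):
        bad = int(np.argmax(bad_mask))
        raise NegativeVolumeError(
            f"cell {bad} has non-positive volume {vols[bad]:g}"
        )


def energy3d(tissue: Tissue3D, positions: np.ndarray | None = None,
             validate: bool = True) -> float:
    """Dimensionless tissue energy (surface tensions, apical elasticity, volume)."""
    pos = tissue.positions if positions is None else positions
    e, vols, _ = _energy_grad3(tissue, pos, need_grad=False)
    if validate:
        _check_volumes(vols)
    return e


def forces3d(tissue: Tissue3D, positions: np.ndarray | None = None,
             validate: bool = True) -> np.ndarray:
    """Analytic force -grad e per vertex; frozen-cell vertices get 0."""
    pos = tissue.positions if positions is None else positions
    _, vols, grad = _energy_grad3(tissue, pos)
    if validate:
        _check_volumes(vols)
    force = -grad
    force[~tissue.free_vertex_mask()] = 0.0
    return force


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def relax3d(
    tissue: Tissue3D,
    dt: float = 1e-4,
    t_end: float = 5000.0,
    mode: str = "minimize",
    force_tol: float = 1e-3,
    stop_force: float | None = None,
):
    """Overdamped descent on the 3D energy; frozen vertices immobile.

    ``euler``: explicit Euler at ``dt`` until ``t_end`` (or ``stop_force``),
    with a non-increasing energy check.  ``minimize``: L-BFGS descent to
    max-force below ``force_tol``.  Returns ``(tissue, diagnostics)``.
    """
    out = tissue.copy()
    free = out.free_vertex_mask()
    if mode == "euler":
        n_steps = int(round(t_end / dt))
        check = min(max(1, n_steps // 200), 2000)
        e_prev, vols, grad = _energy_grad3_fast(out, out.positions)
        ts, es, fs = [0.0], [e_prev], [
            float(np.linalg.norm(grad[free], axis=1).max(initial=0.0))]
        step = 0
        while step < n_steps:
            n_sub = min(check, n_steps - step)
            for _ in range(n_sub):
                out.positions[free] -= dt * grad[free]
                e, vols, grad = _energy_grad3_fast(out, out.positions)
            step += n_sub
            _check_volumes(vols)
            mf = float(np.linalg.norm(grad[free], axis=1).max(initial=0.0))
            ts.append(step * dt); es.append(e); fs.append(mf)
            if e > e_prev + 1e-9 * n_sub:
                raise RuntimeError(
                    f"energy increased at t={step * dt:g}; reduce dt below {dt:g}"
                )
            e_prev = e
            if stop_force is not None and mf < stop_force:
                break
        return out, Diagnostics(np.array(ts), np.array(es), np.array(fs))

    if mode != "minimize":
        raise ValueError(f"unknown mode {mode!r}")

    free_idx = np.where(free)[0]
    pos_buf = out.positions.copy()

    def fun(x):
        pos_buf[free_idx] = x.reshape(-1, 3)
        e, _, grad = _energy_grad3_fast(out, pos_buf)
        return e, grad[free_idx].ravel()

    x = pos_buf[free_idx].ravel()
    trace_e, trace_f = [], []
    for attempt in range(16):
        res = minimize(
            fun, x, jac=True, method="L-BFGS-B",
            options={"maxiter": 8000, "maxfun": 16000,
                     "gtol": 0.05 * force_tol, "ftol": 0.0, "maxcor": 30},
        )
        x = res.x
        pos_buf[free_idx] = x.reshape(-1, 3)
        e, vols, grad = _energy_grad3_fast(out, pos_buf)
        mf = float(np.linalg.norm(grad[free_idx], axis=1).max(initial=0.0))
        trace_e.append(e); trace_f.append(mf)
        if mf < force_tol or res.nit == 0:
            break
    out.positions = pos_buf
    _check_volumes(vols)
    converged = trace_f[-1] < force_tol
    diag = Diagnostics(
        np.arange(len(trace_e), dtype=float), np.array(trace_e),
        np.array(trace_f), converged=converged,
        note="" if converged else
        f"max force {trace_f[-1]:.3g} above tolerance {force_tol:g}",
    )
    if not converged:
        raise RuntimeError(
            f"3D relaxation did not reach max-force < {force_tol:g} "
            f"(got {trace_f[-1]:.3g})"
        )
    return out, diag


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def furrow_profile(tissue: Tissue3D, far_rows: int = 5):
    """Furrow depth and AP-averaged apical cross-section profile.

    Depth is the mean apical z of cells far from the hinge (the ``far_rows``
    non-frozen rows nearest each frozen edge) minus the mean apical z of
    hinge-band cells, in units of the cube root of cell volume.  The
    profile table gives the mean apical z of each cell row against the
    row's mean y coordinate.  This depth metric is a convention of this
    package, chosen so a flat tissue scores ~0 and an apically dipping
    hinge scores positive.
    """
    api_z = tissue.apical_coords()[..., 2].mean(axis=1)
    y = tissue.apical_coords()[..., 1].mean(axis=1)
    j = tissue.grid_index[:, 1]
    n_perp = j.max() + 1
    rows = np.arange(n_perp)
    profile_z = np.array([api_z[j == r].mean() for r in rows])
    profile_y = np.array([y[j == r].mean() for r in rows])

    far = (~tissue.frozen) & (
        (j <= far_rows) | (j >= n_perp - 1 - far_rows)
    ) & (~tissue.hinge)
    depth = float(api_z[far].mean() - api_z[tissue.hinge].mean())
    import pandas as pd

    profile = pd.DataFrame(
        {"row": rows, "y": profile_y, "mean_apical_z": profile_z}
    )
    return depth, profile


def apical_shape_table(tissue: Tissue3D):
    """Elongation and AP-orientation of each cell's apical loop."""
    from .geometry import shape_summary
    import pandas as pd

    A = tissue.apical_coords()
    rows = []
    for c in range(tissue.n_cells):
        ss = shape_summary(A[c], (1.0, 0.0, 0.0))
        rows.append(
            {
                "cell_id": c,
                "hinge": bool(tissue.hinge[c]),
                "constricting": bool(tissue.constricting[c]),
                "frozen": bool(tissue.frozen[c]),
                "kappa": ss.kappa,
                "theta_deg": ss.theta_deg,
            }
        )
    return pd.DataFrame(rows)
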