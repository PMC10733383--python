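"""2D vertex model of the neural plate with a dispersed constricting subpopulation.

Each cell is a polygon with the dimensionless area-and-perimeter elasticity
energy

    e = sum_c [ (a_c - 1)^2 + k_p (p_c - p0_c)^2 ],

where a_c and p_c are the cell's area and perimeter and p0_c its target
perimeter.  The baseline target perimeter is p0 = 3.7, just below the
perimeter of the unit-area regular hexagon (3.72242); apically constricting
cells carry p0 reduced to 10% of baseline.  Vertices follow overdamped
gradient dynamics r' = -grad e with the outermost ring of cells frozen.
Neighbor relations never change (no T1 transitions).

Two relaxation routes are provided: the explicit-Euler integration of the
equations of motion, and a quasi-Newton (L-BFGS) descent to the same energy
minimum, which reaches the fixed point orders of magnitude faster and is
the default for large tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .geometry import Tissue2D, shape_summary

__all__ = [
    "SimConfig2D",
    "PlateDimensions",
    "Diagnostics",
    "assign_constriction",
    "energy2d",
    "forces2d",
    "relax2d",
    "plate_dimensions",
    "plate_cell_stats",
    "CONSTRICTION_FACTOR",
]

# Constricting cells get a target perimeter of 10% of baseline.
CONSTRICTION_FACTOR = 0.10

# Edge lengths enter the energy as sqrt(l^2 + EDGE_EPS^2).  Clusters of
# adjacent constricting cells can collapse to a point (no T1s, no excluded
# volume), where the raw perimeter energy has a cone singularity and vertex
# forces never vanish; smoothing at this scale (far below any physical cell
# size, perimeter error ~5e-8 on intact unit cells) replaces the cone by a
# smooth stationary configuration so descent can converge to tight force
# tolerances.  The perimeter of an intact unit cell shifts by ~5e-8 and its
# energy by ~2e-9; smaller eps makes the collapse landscape too stiff for
# the descent to converge.
EDGE_EPS = 1e-4


class InvertedCellError(RuntimeError):
    """A cell polygon has non-positive signed area."""


class EulerInstabilityError(RuntimeError):
    """Energy increased during explicit-Euler relaxation."""


@dataclass(frozen=True)
class SimConfig2D:
    """Configuration of a single 2D relaxation run.

    ``scheme`` selects how constriction probabilities are laid out over the
    plate: ``"uniform"`` flags every plate cell independently with
    probability ``p_c``; ``"hinge"`` places two ``hinge_width``-cell-wide
    bands (probability ``p_h``) separated by ``hinge_separation`` rows, with
    probability ``p_c_between`` in between and zero outside the block.
    """

    p0: float = 3.7
    k_p: float = 1.0
    constriction_factor: float = CONSTRICTION_FACTOR
    scheme: str = "uniform"  # "uniform" | "hinge"
    p_c: float = 0.5
    p_h: float = 0.5
    p_c_between: float = 0.2
    hinge_width: int = 3
    hinge_separation: int = 14
    dt: float = 1e-4
    t_end: float = 2000.0
    seed: int = 0
    mode: str = "euler"  # "euler" | "minimize"
    stop_force: float | None = None  # early stop for euler when max|f| drops below
    force_tol: float = 1e-6  # minimize-mode convergence target

    def __post_init__(self):
        if not (0.0 <= self.p_c <= 1.0 and 0.0 <= self.p_h <= 1.0):
            raise ValueError("constriction probabilities must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.constriction_factor <= 1.0):
            raise ValueError("constriction factor must lie in (0, 1]")
        if self.scheme not in ("uniform", "hinge"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.mode not in ("euler", "minimize"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PlateDimensions:
    """Central plate length (along AP) and width, normalized by a reference."""

    length: float
    width: float


@dataclass
class Diagnostics:
    """Relaxation trace: times, energies and max force magnitudes."""

    t: np.ndarray
    energy: np.ndarray
    max_force: np.ndarray
    converged: bool = True
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "energy": self.energy, "max_force": self.max_force}
        )


# ---------------------------------------------------------------------------
# Constriction assignment
# ---------------------------------------------------------------------------

def hinge_zones(tissue: Tissue2D, width: int = 3, separation: int = 14) -> np.ndarray:
    """Per-cell zone labels for the hinge layout.

    Returns an array of ``"hinge"``, ``"between"``, ``"outside"`` or
    ``"exterior"``.  The two hinge bands (``width`` rows each, separated by
    ``separation`` rows) are centered on the plate's row span.
    """
    zones = np.full(tissue.n_cells, "exterior", dtype=object)
    plate_rows = np.unique(tissue.grid_index[tissue.is_plate, 1])
    block = 2 * width + separation
    if block > len(plate_rows):
        raise ValueError(
            f"hinge layout needs {block} plate rows, plate has {len(plate_rows)}"
        )
    start = (len(plate_rows) - block) // 2
    band1 = set(plate_rows[start : start + width])
    band2 = set(plate_rows[start + width + separation : start + block])
    between = set(plate_rows[start + width : start + width + separation])
    rows = tissue.grid_index[:, 1]
    for i in np.where(tissue.is_plate)[0]:
        if rows[i] in band1 or rows[i] in band2:
            zones[i] = "hinge"
        elif rows[i] in between:
            zones[i] = "between"
        else:
            zones[i] = "outside"
    return zones


def assign_constriction(
    tissue: Tissue2D, config: SimConfig2D, seed: int | None = None
) -> Tissue2D:
    """Flag plate cells as constricting and reduce their target perimeter.

    Each eligible cell is flagged independently with its scheme probability
    (sampled in row-major order over plate cells, so a fixed seed fully
    determines the pattern).  Flagged cells get p0 multiplied by the
    constriction factor (default 0.10); exterior cells are never flagged.
    """
    if not tissue.is_plate.any():
        raise ValueError("tissue has no plate region")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    out = tissue.copy()
    out.k_p = config.k_p
    out.p0 = np.full(out.n_cells, config.p0)

    # row-major order over plate cells
    plate_idx = np.where(out.is_plate)[0]
    order = np.lexsort(
        (out.grid_index[plate_idx, 0], out.grid_index[plate_idx, 1])
    )
    plate_idx = plate_idx[order]

    if config.scheme == "uniform":
        prob = np.full(len(plate_idx), config.p_c)
    else:
        zones = hinge_zones(out, config.hinge_width, config.hinge_separation)
        zmap = {"hinge": config.p_h, "between": config.p_c_between}
        prob = np.array([zmap.get(zones[i], 0.0) for i in plate_idx])

    draw = rng.random(len(plate_idx))
    flagged = plate_idx[draw < prob]
    out.constricting[:] = False
    out.constricting[flagged] = True
    out.p0[flagged] = config.p0 * config.constriction_factor
    return out


# ---------------------------------------------------------------------------
# Energy and forces
# ---------------------------------------------------------------------------

def _energy_grad(tissue: Tissue2D, pos: np.ndarray, need_grad: bool = True):
    """Fused energy and per-vertex energy gradient (one geometry pass).

    The shoelace-area gradient at loop slot i is
    0.5 * (y_{i+1} - y_{i-1}, x_{i-1} - x_{i+1}); the perimeter gradient is
    the sum of the unit vectors of the two incident edges pointing away
    from their far ends.  Shared vertices accumulate contributions from all
    incident cells.  Edge lengths are smoothed at EDGE_EPS.
    """
    P = pos[tissue.cells]  # (N, 6, 2)
    nxt = np.roll(P, -1, axis=1)
    areas = 0.5 * np.sum(P[..., 0] * nxt[..., 1] - nxt[..., 0] * P[..., 1], axis=1)
    edges = nxt - P
    lengths = np.sqrt(np.einsum("ijk,ijk->ij", edges, edges) + EDGE_EPS**2)
    perims = lengths.sum(axis=1)
    energy = float(
        np.sum((areas - 1.0) ** 2 + tissue.k_p * (perims - tissue.p0) ** 2)
    )
    if not need_grad:
        return energy, areas, None

    dE_da = 2.0 * (areas - 1.0)  # (N,)
    dE_dp = 2.0 * tissue.k_p * (perims - tissue.p0)

    prv = np.roll(P, 1, axis=1)
    dA = 0.5 * np.stack(
        (nxt[..., 1] - prv[..., 1], prv[..., 0] - nxt[..., 0]), axis=2
    )  # (N, 6, 2)
    unit = edges / lengths[..., None]
    # dp/dr_i = (r_i - r_{i-1})/l + (r_i - r_{i+1})/l
    dP = np.roll(unit, 1, axis=1) - unit

    grad_slots = dE_da[:, None, None] * dA + dE_dp[:, None, None] * dP
    flat = tissue.cells.ravel()
    gx = np.bincount(flat, weights=grad_slots[..., 0].ravel(),
                     minlength=len(pos))
    gy = np.bincount(flat, weights=grad_slots[..., 1].ravel(),
                     minlength=len(pos))
    return energy, areas, np.stack((gx, gy), axis=1)


def _check_areas(areas: np.ndarray) -> None:
    # collapsed constricting clusters legitimately reach area 0 (to rounding);
    # anything clearly negative is an inverted polygon
    bad_mask = areas < -1e-9
    if np.any(bad_mask):
        bad = int(np.argmax(bad_mask))
        raise InvertedCellError(f"cell {bad} has negative area {areas[bad]:g}")


def energy2d(
    tissue: Tissue2D, positions: np.ndarray | None = None, validate: bool = True
) -> float:
    """Dimensionless tissue energy, summed over all cells (frozen included).

    With ``validate`` (the default) an inverted cell raises; the smooth
    signed-area form (``validate=False``) is what the relaxation descends,
    so a line-search step passing through a degenerate configuration stays
    differentiable.
    """
    pos = tissue.positions if positions is None else positions
    energy, areas, _ = _energy_grad(tissue, pos, need_grad=False)
    if validate:
        _check_areas(areas)
    return energy


def forces2d(
    tissue: Tissue2D, positions: np.ndarray | None = None, validate: bool = True
) -> np.ndarray:
    """Analytic force -grad e on every vertex; frozen-cell vertices get 0."""
    pos = tissue.positions if positions is None else positions
    _, areas, grad = _energy_grad(tissue, pos)
    if validate:
        _check_areas(areas)
    force = -grad
    force[~tissue.free_vertex_mask()] = 0.0
    return force


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def _area_hessian_block() -> np.ndarray:
    """Constant 12x12 second derivative of the shoelace area of a hexagon."""
    H = np.zeros((12, 12))
    for i in range(6):
        nxt, prv = (i + 1) % 6, (i - 1) % 6
        H[2 * i, 2 * nxt + 1] += 0.5
        H[2 * nxt + 1, 2 * i] += 0.5
        H[2 * i, 2 * prv + 1] -= 0.5
        H[2 * prv + 1, 2 * i] -= 0.5
    return H


_H_AREA = _area_hessian_block()


def hessian2d(tissue: Tissue2D, positions: np.ndarray | None = None) -> sp.csr_matrix:
    """Analytic sparse Hessian of the tissue energy (all vertices, 2V x 2V).

    Per cell: 2 dA(x)dA + 2(a-1) H_A + 2 k_p dP(x)dP + 2 k_p (p-p0) H_P,
    where H_A is the constant shoelace block and H_P is assembled from the
    per-edge blocks (I/l - u(x)u/l^3) of the smoothed edge lengths.
    Used by the Newton polish of the quasi-Newton relaxation.
    """
    pos = tissue.positions if positions is None else positions
    cells = tissue.cells
    P = pos[cells]
    nxt = np.roll(P, -1, axis=1)
    areas = 0.5 * np.sum(P[..., 0] * nxt[..., 1] - nxt[..., 0] * P[..., 1], axis=1)
    edges = nxt - P
    lengths = np.sqrt(np.einsum("ijk,ijk->ij", edges, edges) + EDGE_EPS**2)
    perims = lengths.sum(axis=1)

    prv = np.roll(P, 1, axis=1)
    dA = 0.5 * np.stack(
        (nxt[..., 1] - prv[..., 1], prv[..., 0] - nxt[..., 0]), axis=2
    ).reshape(len(cells), 12)
    unit = edges / lengths[..., None]
    dP = (np.roll(unit, 1, axis=1) - unit).reshape(len(cells), 12)

    k = tissue.k_p
    blocks = 2.0 * np.einsum("ni,nj->nij", dA, dA)
    blocks += 2.0 * k * np.einsum("ni,nj->nij", dP, dP)
    blocks += (2.0 * (areas - 1.0))[:, None, None] * _H_AREA

    # per-edge blocks M = I/l - u u^T / l^3 for the perimeter curvature
    M = (
        np.eye(2) / lengths[..., None, None]
        - np.einsum("nia,nib->niab", edges, edges) / lengths[..., None, None] ** 3
    )  # (N, 6, 2, 2)
    coef = (2.0 * k * (perims - tissue.p0))[:, None, None, None]
    Mc = coef * M
    for i in range(6):
        j = (i + 1) % 6
        si, sj = slice(2 * i, 2 * i + 2), slice(2 * j, 2 * j + 2)
        blocks[:, si, si] += Mc[:, i]
        blocks[:, sj, sj] += Mc[:, i]
        blocks[:, si, sj] -= Mc[:, i]
        blocks[:, sj, si] -= Mc[:, i]

    dof = np.empty((len(cells), 12), dtype=np.intp)
    dof[:, 0::2] = 2 * cells
    dof[:, 1::2] = 2 * cells + 1
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 2 * len(pos)
    H = sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=(n, n))
    return H.tocsr()


def _newton_polish(tissue, pos_buf, free_dofs, force_tol, max_iter=30):
    """Damped Newton iterations on the gradient from a near-converged state.

    The energy is too large (~1e3) for an energy-based line search to
    resolve steps that shrink the force below ~1e-4 in double precision,
    so the final decade is handled as a root-finding problem for the
    gradient, accepting steps that reduce the force norm and damping the
    Hessian when they do not.
    """
    lam = 0.0
    _, _, grad = _energy_grad(tissue, pos_buf)
    mf = float(np.linalg.norm(grad.ravel()[free_dofs].reshape(-1, 2), axis=1).max())
    for _ in range(max_iter):
        if mf < force_tol:
            break
        H = hessian2d(tissue, pos_buf)[free_dofs][:, free_dofs].tocsc()
        g = grad.ravel()[free_dofs]
        accepted = False
        for _trial in range(8):
            A = H + lam * sp.identity(H.shape[0], format="csc") if lam else H
            try:
                step = spla.spsolve(A, -g)
            except RuntimeError:
                lam = max(10 * lam, 1e-8)
                continue
            trial = pos_buf.copy()
            trial.ravel()[free_dofs] += step
            _, _, tgrad = _energy_grad(tissue, trial)
            tmf = float(
                np.linalg.norm(tgrad.ravel()[free_dofs].reshape(-1, 2), axis=1).max()
            )
            if np.isfinite(tmf) and tmf < mf:
                pos_buf[...] = trial
                grad, mf = tgrad, tmf
                lam = 0.1 * lam if lam > 1e-12 else 0.0
                accepted = True
                break
            lam = max(10 * lam, 1e-8)
        if not accepted:
            break
    return pos_buf, mf


def _max_force(tissue: Tissue2D, grad: np.ndarray, free: np.ndarray) -> float:
    return float(np.linalg.norm(grad[free], axis=1).max(initial=0.0))


def _euler_steps_numpy(pos, cells, p0, k_p, free, dt, n_steps):
    for _ in range(n_steps):
        P = pos[cells]
        nxt = np.roll(P, -1, axis=1)
        areas = 0.5 * np.sum(
            P[..., 0] * nxt[..., 1] - nxt[..., 0] * P[..., 1], axis=1
        )
        edges = nxt - P
        lengths = np.sqrt(np.einsum("ijk,ijk->ij", edges, edges) + EDGE_EPS**2)
        perims = lengths.sum(axis=1)
        dE_da = 2.0 * (areas - 1.0)
        dE_dp = 2.0 * k_p * (perims - p0)
        prv = np.roll(P, 1, axis=1)
        dA = 0.5 * np.stack(
            (nxt[..., 1] - prv[..., 1], prv[..., 0] - nxt[..., 0]), axis=2
        )
        unit = edges / lengths[..., None]
        dP = np.roll(unit, 1, axis=1) - unit
        g = dE_da[:, None, None] * dA + dE_dp[:, None, None] * dP
        flat = cells.ravel()
        gx = np.bincount(flat, weights=g[..., 0].ravel(), minlength=len(pos))
        gy = np.bincount(flat, weights=g[..., 1].ravel(), minlength=len(pos))
        pos[free, 0] -= dt * gx[free]
        pos[free, 1] -= dt * gy[free]


try:  # JIT inner loop: the explicit Euler scheme takes 1e6-1e7 steps
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _euler_steps_jit(pos, cells, p0, k_p, free, dt, n_steps):  # pragma: no cover
        n_cells = cells.shape[0]
        n_v = pos.shape[0]
        grad = np.empty((n_v, 2))
        eps2 = EDGE_EPS * EDGE_EPS
        for _ in range(n_steps):
            grad[:] = 0.0
            for c in range(n_cells):
                area = 0.0
                perim = 0.0
                for k in range(6):
                    i0 = cells[c, k]
                    i1 = cells[c, (k + 1) % 6]
                    area += pos[i0, 0] * pos[i1, 1] - pos[i1, 0] * pos[i0, 1]
                    dx = pos[i1, 0] - pos[i0, 0]
                    dy = pos[i1, 1] - pos[i0, 1]
                    perim += np.sqrt(dx * dx + dy * dy + eps2)
                area *= 0.5
                da = 2.0 * (area - 1.0)
                dp = 2.0 * k_p * (perim - p0[c])
                for k in range(6):
                    i0 = cells[c, k]
                    i1 = cells[c, (k + 1) % 6]
                    ip = cells[c, (k + 5) % 6]
                    gx = 0.5 * da * (pos[i1, 1] - pos[ip, 1])
                    gy = 0.5 * da * (pos[ip, 0] - pos[i1, 0])
                    ex = pos[i1, 0] - pos[i0, 0]
                    ey = pos[i1, 1] - pos[i0, 1]
                    ln = np.sqrt(ex * ex + ey * ey + eps2)
                    px = pos[ip, 0] - pos[i0, 0]
                    py = pos[ip, 1] - pos[i0, 1]
                    lp = np.sqrt(px * px + py * py + eps2)
                    gx += dp * (-ex / ln - px / lp)
                    gy += dp * (-ey / ln - py / lp)
                    grad[i0, 0] += gx
                    grad[i0, 1] += gy
            for v in range(n_v):
                if free[v]:
                    pos[v, 0] -= dt * grad[v, 0]
                    pos[v, 1] -= dt * grad[v, 1]

    _euler_steps = _euler_steps_jit
except ImportError:  # pragma: no cover
    _euler_steps = _euler_steps_numpy


def _relax_euler(tissue: Tissue2D, config: SimConfig2D):
    out = tissue.copy()
    free = out.free_vertex_mask()
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    check_every = min(max(1, n_steps // 400), 20000) if n_steps else 1
    e_prev, _, grad = _energy_grad(out, out.positions)
    ts = [0.0]
    energies = [e_prev]
    maxfs = [_max_force(out, grad, free)]
    t_now = 0.0
    p0 = np.ascontiguousarray(out.p0)
    halvings = 0
    note = ""
    while t_now < config.t_end - 1e-12:
        n_sub = min(check_every, max(1, int(round((config.t_end - t_now) / dt))))
        _euler_steps(out.positions, out.cells, p0, out.k_p, free, dt, n_sub)
        t_now += n_sub * dt
        e, areas, grad = _energy_grad(out, out.positions)
        _check_areas(areas)
        mf = _max_force(out, grad, free)
        ts.append(t_now); energies.append(e); maxfs.append(mf)
        if e > e_prev + 1e-9 * n_sub:  # tolerance of 1e-9 per Euler step
            raise EulerInstabilityError(
                f"energy increased by {e - e_prev:.3g} at t={t_now:g}; "
                f"reduce dt below {dt:g}"
            )
        stalled = (e_prev - e) < 1e-12 * max(1.0, abs(e))
        e_prev = e
        if config.stop_force is not None:
            if mf < config.stop_force:
                break
            if stalled:
                # near collapsed constricting clusters the time step can sit
                # at the oscillatory stability margin: refine it so the
                # integration settles into the stiff equilibrium
                if halvings >= 10:
                    note = (
                        f"max force stalled at {mf:.3g} "
                        f"after {halvings} step halvings"
                    )
                    break
                dt *= 0.5
                halvings += 1
    diag = Diagnostics(np.array(ts), np.array(energies), np.array(maxfs), note=note)
    if config.stop_force is not None:
        diag.converged = maxfs[-1] < config.stop_force
    if halvings and not note:
        diag.note = f"dt refined to {dt:g} near the energy minimum"
    return out, diag


def _relax_minimize(tissue: Tissue2D, config: SimConfig2D):
    out = tissue.copy()
    free = out.free_vertex_mask()
    free_idx = np.where(free)[0]
    pos_buf = out.positions.copy()

    def fun(x):
        pos_buf[free_idx] = x.reshape(-1, 2)
        e, _, grad = _energy_grad(out, pos_buf)
        return e, grad[free_idx].ravel()

    x = pos_buf[free_idx].ravel()
    free_dofs = np.stack((2 * free_idx, 2 * free_idx + 1), axis=1).ravel()
    trace_e, trace_f = [], []
    for attempt in range(12):
        res = minimize(
            fun, x, jac=True, method="L-BFGS-B",
            options={
                "maxiter": 4000, "maxfun": 8000,
                "gtol": 0.05 * config.force_tol, "ftol": 0.0, "maxcor": 30,
            },
        )
        x = res.x
        pos_buf[free_idx] = x.reshape(-1, 2)
        e, _, grad = _energy_grad(out, pos_buf)
        mf = _max_force(out, grad, free)
        trace_e.append(e); trace_f.append(mf)
        if mf < config.force_tol:
            break
        if mf < 0.5 or res.nit < 100:
            # near the minimum (or at the resolution floor of the
            # energy-based line search): try the Newton polish; fall back to
            # more quasi-Newton rounds if it cannot make progress yet
            pos_buf, mf = _newton_polish(out, pos_buf, free_dofs, config.force_tol)
            x = pos_buf[free_idx].ravel()
            e, _, grad = _energy_grad(out, pos_buf)
            mf = _max_force(out, grad, free)
            trace_e.append(e); trace_f.append(mf)
            if mf < config.force_tol:
                break
    out.positions = pos_buf
    energy2d(out)  # validate: the converged state must have no inverted cell
    converged = trace_f[-1] < config.force_tol
    diag = Diagnostics(
        np.arange(len(trace_e), dtype=float),
        np.array(trace_e),
        np.array(trace_f),
        converged=converged,
        note="" if converged else
        f"max force {trace_f[-1]:.3g} above tolerance {config.force_tol:g}",
    )
    if not converged:
        raise RuntimeError(
            f"quasi-Newton relaxation did not reach max-force "
            f"< {config.force_tol:g} (got {trace_f[-1]:.3g})"
        )
    return out, diag


def relax2d(tissue: Tissue2D, config: SimConfig2D):
    """Relax the tissue to (or toward) its energy minimum.

    ``euler`` mode integrates r' = f with the explicit Euler scheme at
    ``config.dt`` until ``t_end`` (or until the maximum force drops below
    ``config.stop_force`` if set); the energy trace is checked to be
    non-increasing and an instability raises with advice to reduce dt.
    ``minimize`` mode runs L-BFGS descent on the same energy with frozen
    vertices fixed until the maximum force is below ``config.force_tol``.

    Returns ``(relaxed_tissue, diagnostics)``.
    """
    if config.mode == "euler":
        try:
            return _relax_euler(tissue, config)
        except EulerInstabilityError:
            # stiff constriction transient: retry once at half the step
            halved = replace(config, dt=0.5 * config.dt)
            out, diag = _relax_euler(tissue, halved)
            diag.note = f"dt halved to {halved.dt:g} after instability"
            return out, diag
    return _relax_minimize(tissue, config)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def _edge_groups(tissue: Tissue2D, group_size: int = 5):
    """Indices of the centrally located plate cells on each plate edge.

    For the left/right edges: in each of the ``group_size`` rows nearest
    the plate's central row, the plate cell with the smallest/largest
    column index.  Top/bottom analogously with columns and rows swapped.
    Groups are defined on lattice topology, so they identify the same
    cells before and after relaxation.
    """
    plate = np.where(tissue.is_plate)[0]
    gi = tissue.grid_index
    rows = np.unique(gi[plate, 1])
    cols = np.unique(gi[plate, 0])
    mid_row = 0.5 * (rows.min() + rows.max())
    mid_col = 0.5 * (cols.min() + cols.max())

    central_rows = rows[np.argsort(np.abs(rows - mid_row), kind="stable")[:group_size]]
    central_cols = cols[np.argsort(np.abs(cols - mid_col), kind="stable")[:group_size]]

    left, right, bottom, top = [], [], [], []
    for r in central_rows:
        in_row = plate[gi[plate, 1] == r]
        left.append(in_row[np.argmin(gi[in_row, 0])])
        right.append(in_row[np.argmax(gi[in_row, 0])])
    for cc in central_cols:
        in_col = plate[gi[plate, 0] == cc]
        if len(in_col) == 0:  # offset rows: column may be absent
            continue
        bottom.append(in_col[np.argmin(gi[in_col, 1])])
        top.append(in_col[np.argmax(gi[in_col, 1])])
    return map(np.asarray, (left, right, bottom, top))


def _raw_plate_dimensions(tissue: Tissue2D, group_size: int = 5):
    left, right, bottom, top = _edge_groups(tissue, group_size)
    centers = tissue.centers()
    length = float(np.linalg.norm(centers[right].mean(0) - centers[left].mean(0)))
    width = float(np.linalg.norm(centers[top].mean(0) - centers[bottom].mean(0)))
    return length, width


def plate_dimensions(
    after: Tissue2D, reference: Tissue2D, group_size: int = 5
) -> PlateDimensions:
    """Central plate length and width of ``after``, normalized by ``reference``.

    Both tissues must share the same lattice topology (the reference is
    the relaxed tissue with zero constricting cells).  Each dimension is
    the distance between the mean centers of small groups of centrally
    located cells on opposite plate edges.
    """
    if after.cells.shape != reference.cells.shape or not np.array_equal(
        after.cells, reference.cells
    ):
        raise ValueError("tissues do not share lattice topology")
    length, width = _raw_plate_dimensions(after, group_size)
    ref_length, ref_width = _raw_plate_dimensions(reference, group_size)
    return PlateDimensions(length=length / ref_length, width=width / ref_width)


def plate_cell_stats(
    tissue: Tissue2D, reference_axis=(1.0, 0.0), n_bins: int = 9
):
    """Per-cell shape table plus the angle histogram of Fig.-style summaries.

    Returns ``(table, histogram, summary)`` where ``table`` has one row per
    cell (area, perimeter, elongation kappa, orientation theta_deg vs the
    AP axis), ``histogram`` is a DataFrame of angle bins over the
    non-constricting plate cells (cells with undefined orientation, i.e.
    exactly isotropic, are excluded), and ``summary`` holds their mean
    angle and between-cell standard deviation and mean elongation.
    """
    polys = tissue.cell_polygons()
    nxt = np.roll(polys, -1, axis=1)
    areas = 0.5 * np.sum(
        polys[..., 0] * nxt[..., 1] - nxt[..., 0] * polys[..., 1], axis=1
    )
    perims = np.linalg.norm(nxt - polys, axis=2).sum(axis=1)
    kappas = np.empty(tissue.n_cells)
    thetas = np.empty(tissue.n_cells)
    for c in range(tissue.n_cells):
        ss = shape_summary(polys[c], reference_axis)
        kappas[c] = ss.kappa
        thetas[c] = ss.theta_deg
    table = pd.DataFrame(
        {
            "cell_id": np.arange(tissue.n_cells),
            "region": np.where(tissue.is_plate, "plate", "exterior"),
            "constricting": tissue.constricting,
            "frozen": tissue.frozen,
            "area": areas,
            "perimeter": perims,
            "kappa": kappas,
            "theta_deg": thetas,
        }
    )
    sel = tissue.is_plate & ~tissue.constricting & np.isfinite(thetas)
    ang = thetas[sel]
    counts, edges_ = np.histogram(ang, bins=n_bins, range=(0.0, 90.0))
    histogram = pd.DataFrame(
        {"bin_start_deg": edges_[:-1], "bin_end_deg": edges_[1:], "count": counts}
    )
    nc_plate = tissue.is_plate & ~tissue.constricting
    summary = {
        "n_cells": int(sel.sum()),
        "mean_angle_deg": float(ang.mean()) if len(ang) else float("nan"),
        "sd_angle_deg": float(ang.std(ddof=1)) if len(ang) > 1 else float("nan"),
        "mean_kappa": float(kappas[nc_plate].mean()) if nc_plate.any()
        else float("nan"),
    }
    return table, histogram, summary
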