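"""Synthetic neural-plate-like tissues and apical-area tracks with ground truth.

The tissue generator emulates the segmented-epithelium phenotype the
morphometrics stage is built for: a fraction of cells with small apical
domains interspersed among larger cells that are elongated along a
preferred axis, an optional hinge band with boosted area heterogeneity,
and a junctional intensity channel in which shorter junctions are
brighter.  Cells are the cells of a power (Laguerre) diagram of a jittered
anisotropic lattice: lattice stretch sets the elongation bias and negative
site weights shrink the "constricted" subpopulation.  The exact polygons
are the ground truth; the label image is rasterized from the same power
metric, so polygon ids and pixel labels agree by construction.

The track generator emulates families of apical-domain time series in
which set fractions of cells shrink (AC) or expand (AE) by a target
relative change, with multiplicative log-normal noise per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon, box

from .geometry import fold_angle_deg, polygon_moments
from .morphometrics import ApicalAreaTrack, LabelImage

__all__ = [
    "TissueGenParams",
    "TrackGenParams",
    "TissueSample",
    "generate_polygonal_tissue",
    "render_label_image",
    "generate_area_tracks",
]


@dataclass(frozen=True)
class TissueGenParams:
    """Parameters of the synthetic tissue generator.

    ``area_ratio`` is the target mean small/large apical-area ratio;
    ``aspect_target`` and ``orientation_deg`` bias the non-constricted
    cells' shapes; ``hinge_rows`` marks a horizontal band of lattice rows
    (fraction of height, centered) whose site weights get extra spread
    ``hinge_weight_sd`` (relative to mean cell area), raising the local
    area CV.  ``intensity_base``/``intensity_slope``/``intensity_noise``
    parameterize the junction channel intensity = base - slope*length + N.
    """

    n_cells: int = 400
    f_c: float = 0.5
    area_ratio: float = 0.2
    aspect_target: float = 1.6
    orientation_deg: float = 0.0
    hinge_rows: float = 0.0  # fraction of frame height, 0 disables
    hinge_weight_sd: float = 0.0
    intensity_base: float = 200.0
    intensity_slope: float = 2.0
    intensity_noise: float = 5.0
    cytoplasm_level: float = 60.0
    image_shape: tuple[int, int] = (512, 512)
    jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_c <= 1.0:
            raise ValueError("f_c must lie in [0, 1]")
        if self.area_ratio <= 0 or self.aspect_target < 1:
            raise ValueError("area_ratio must be > 0 and aspect_target >= 1")
        h, w = self.image_shape
        if h * w < 200 * self.n_cells:
            raise ValueError(
                f"raster {h}x{w} too small for {self.n_cells} cells "
                "(need >= 200 px per cell)"
            )


@dataclass(frozen=True)
class TrackGenParams:
    """Parameters of the apical-area track generator."""

    n_cells: int = 50
    f_ac: float = 0.3
    f_ae: float = 0.3
    change_ac: float = -0.5
    change_ae: float = 0.4
    change_none: float = 0.0
    noise_sd: float = 0.05
    n_timepoints: int = 20
    mean_area: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.f_ac + self.f_ae > 1 + 1e-12:
            raise ValueError("f_ac + f_ae must not exceed 1")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")


@dataclass
class TissueSample:
    """Generated tissue: sites, exact polygons and per-cell ground truth."""

    sites: np.ndarray  # (M, 2) all sites incl. guards, pixel coords (x, y)
    sites_transformed: np.ndarray  # sites in the isotropic metric frame
    transform: np.ndarray  # world = transform @ metric-frame + offset
    offset: np.ndarray
    weights: np.ndarray
    cell_site: np.ndarray  # site index of each cell id (1-based ids)
    polygons: list[Polygon]
    truth: pd.DataFrame
    adjacency: set[tuple[int, int]]
    params: TissueGenParams


# ---------------------------------------------------------------------------
# Power diagram
# ---------------------------------------------------------------------------

def _power_cells(sites: np.ndarray, weights: np.ndarray):
    """Power-diagram cells via the convex-hull lifting construction.

    Sites are lifted to (x, y, x^2+y^2-w); the lower hull's simplices are
    the regular triangulation, and each simplex's power center is a
    diagram vertex.  Returns (vertices of each complete fan as a dict
    site -> polygon ndarray, neighbor pair set).
    """
    lifted = np.c_[sites, (sites**2).sum(axis=1) - weights]
    hull = ConvexHull(lifted)
    lower = hull.equations[:, 2] < -1e-12
    simplices = hull.simplices[lower]

    # power center of each lower simplex
    centers = np.empty((len(simplices), 2))
    for t, (i, j, k) in enumerate(simplices):
        si, sj, sk = sites[i], sites[j], sites[k]
        pi = (si**2).sum() - weights[i]
        pj = (sj**2).sum() - weights[j]
        pk = (sk**2).sum() - weights[k]
        A = 2.0 * np.array([sj - si, sk - si])
        b = np.array([pj - pi, pk - pi])
        centers[t] = np.linalg.solve(A, b)

    fans: dict[int, list[int]] = {}
    for t, tri in enumerate(simplices):
        for i in tri:
            fans.setdefault(int(i), []).append(t)

    neighbors: set[tuple[int, int]] = set()
    for tri in simplices:
        a, b_, c = (int(v) for v in np.sort(tri))
        neighbors |= {(a, b_), (a, c), (b_, c)}

    polys: dict[int, np.ndarray] = {}
    hull_sites = set()
    for tri, eq in zip(simplices, hull.equations[lower]):
        pass
    # sites on the triangulation's outer boundary have incomplete fans;
    # detect them via boundary edges (edges in exactly one simplex)
    edge_count: dict[tuple[int, int], int] = {}
    for tri in simplices:
        for a, b_ in ((0, 1), (0, 2), (1, 2)):
            e = tuple(sorted((int(tri[a]), int(tri[b_]))))
            edge_count[e] = edge_count.get(e, 0) + 1
    open_sites = {v for e, n in edge_count.items() if n == 1 for v in e}

    for i, tris in fans.items():
        if i in open_sites:
            continue
        pts = centers[tris]
        ref = pts.mean(axis=0)
        ang = np.arctan2(pts[:, 1] - ref[1], pts[:, 0] - ref[0])
        polys[i] = pts[np.argsort(ang)]
    return polys, neighbors


def _polygon_shape_truth(poly: Polygon):
    """Area, area-weighted aspect ratio, orientation and centroid of a polygon."""
    loop = np.asarray(poly.exterior.coords)[:-1]
    if poly.exterior.is_ccw is False:
        loop = loop[::-1]
    area, cen, cov = polygon_moments(loop)
    evals, evecs = np.linalg.eigh(cov)
    aspect = float(np.sqrt(evals[1] / max(evals[0], 1e-12)))
    v = evecs[:, 1]
    orient = fold_angle_deg(float(np.degrees(np.arctan2(v[1], v[0]))))
    return area, aspect, orient, cen


def generate_polygonal_tissue(params: TissueGenParams) -> TissueSample:
    """Tessellate the frame into cells with recorded ground truth.

    The elongation bias is an anisotropic metric: the diagram is built in
    coordinates compressed by sqrt(aspect_target) along ``orientation_deg``
    (where the jittered hexagonal site lattice is isotropic) and mapped
    back, so non-constricted cells come out elongated along the preferred
    axis.  The constricted fraction of sites gets a negative power weight
    sized to the target area ratio.  Ground-truth area, aspect ratio
    (area-weighted second moments) and orientation are measured on the
    exact polygons.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    mean_area = h * w / params.n_cells
    q = np.sqrt(params.aspect_target)
    theta = np.radians(params.orientation_deg)
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    # world = R @ diag(q, 1/q) @ transformed (unit determinant)
    M = R @ np.diag([q, 1.0 / q])
    Minv = np.linalg.inv(M)

    # isotropic hex lattice in transformed space, area-preserving map
    L = np.sqrt(mean_area / (np.sqrt(3.0) / 2.0))
    ry = L * np.sqrt(3.0) / 2.0
    half_diag = 0.5 * np.hypot(h, w) * max(q, 1.0 / q)
    nx = int(np.ceil(2 * (half_diag + 3 * L) / L))
    ny = int(np.ceil(2 * (half_diag + 3 * ry) / ry))
    xs = (np.arange(nx) - nx / 2) * L
    ys = (np.arange(ny) - ny / 2) * ry
    X, Y = np.meshgrid(xs, ys)
    X[::2] += L / 2  # offset alternate rows
    pts_t = np.c_[X.ravel(), Y.ravel()]
    pts_t += rng.normal(0.0, params.jitter * L, pts_t.shape)
    pts = pts_t @ M.T + np.array([w / 2.0, h / 2.0])

    inside = (
        (pts[:, 0] > 0) & (pts[:, 0] < w) & (pts[:, 1] > 0) & (pts[:, 1] < h)
    )
    margin = 3 * L * max(q, 1.0 / q)
    near = (
        (pts[:, 0] > -margin) & (pts[:, 0] < w + margin)
        & (pts[:, 1] > -margin) & (pts[:, 1] < h + margin)
    )
    sites = pts[near]
    sites_t = pts_t[near]
    inside = inside[near]

    weights = np.zeros(len(sites))
    n_in = int(inside.sum())
    constricted = np.zeros(len(sites), dtype=bool)
    in_idx = np.where(inside)[0]
    n_small = int(round(params.f_c * n_in))
    small = rng.choice(in_idx, size=n_small, replace=False)
    constricted[small] = True
    weights[small] = -(1.0 - np.sqrt(params.area_ratio)) * mean_area

    hinge_ids: set[int] = set()
    if params.hinge_rows > 0:
        band = params.hinge_rows * h / 2.0
        in_band = inside & (np.abs(sites[:, 1] - h / 2.0) < band)
        weights[in_band] += rng.normal(
            0.0, params.hinge_weight_sd * mean_area, int(in_band.sum())
        )
        hinge_ids = set(np.where(in_band)[0])

    polys_t, neighbors = _power_cells(sites_t, weights)
    offset = np.array([w / 2.0, h / 2.0])

    frame = box(0.0, 0.0, float(w), float(h))
    cell_site = []
    shapely_polys = []
    truth_rows = []
    site_to_cell = {}
    for i in in_idx:
        if i not in polys_t:
            continue
        loop_world = polys_t[i] @ M.T + offset
        poly = Polygon(loop_world)
        if not poly.is_valid:
            poly = poly.buffer(0)
        try:
            poly = poly.intersection(frame)
        except Exception:
            continue
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area < 1.0:
            continue
        clipped = Polygon(loop_world).area - poly.area > 1e-6
        cid = len(cell_site) + 1
        site_to_cell[int(i)] = cid
        cell_site.append(int(i))
        shapely_polys.append(poly)
        area, aspect, orient, cen = _polygon_shape_truth(poly)
        # the rasterized cell is the polygon minus the shared 1-px
        # boundary, i.e. the half-pixel-eroded polygon: record its shape
        # too as the continuous analogue of the rendered region
        rendered = poly.buffer(-0.5)
        if rendered.is_empty or rendered.geom_type != "Polygon":
            r_area = r_aspect = r_orient = float("nan")
        else:
            r_area, r_aspect, r_orient, _ = _polygon_shape_truth(rendered)
        truth_rows.append(
            {
                "cell_id": cid,
                "constricted": bool(constricted[i]),
                "hinge": int(i) in hinge_ids,
                "clipped": bool(clipped),
                "area": area,
                "aspect_ratio": aspect,
                "orientation_deg": orient,
                "centroid_x": cen[0],
                "centroid_y": cen[1],
                "area_rendered": r_area,
                "aspect_ratio_rendered": r_aspect,
                "orientation_deg_rendered": r_orient,
            }
        )

    adjacency = {
        (site_to_cell[a], site_to_cell[b])
        for a, b in neighbors
        if a in site_to_cell and b in site_to_cell
    }
    return TissueSample(
        sites=sites,
        sites_transformed=sites_t,
        transform=M,
        offset=offset,
        weights=weights,
        cell_site=np.asarray(cell_site),
        polygons=shapely_polys,
        truth=pd.DataFrame(truth_rows),
        adjacency=adjacency,
        params=params,
    )


def render_label_image(sample: TissueSample) -> LabelImage:
    """Rasterize a tissue sample into a label mask plus intensity channel.

    Pixels are assigned by the same power metric that defined the
    polygons, boundaries between different labels are carved out 1 px
    wide and painted with the junction model
    intensity = base - slope * (junction pixel length) + Gaussian noise
    (clipped at zero); cell interiors get the cytoplasm level with the
    same per-pixel noise.
    """
    params = sample.params
    h, w = params.image_shape
    total = sum(p.area for p in sample.polygons)
    if total > h * w * 1.001:
        raise ValueError("polygons overlap: total area exceeds the frame")
    rng = np.random.default_rng(params.seed + 1)

    site_label = np.zeros(len(sample.sites), dtype=np.int32)
    site_label[sample.cell_site] = np.arange(1, len(sample.cell_site) + 1)

    # assign pixels by power distance in the metric frame among the k
    # nearest sites (the weights are small relative to the squared
    # spacing, so the winner is among them; the polygon round-trip tests
    # guard this)
    from scipy.spatial import cKDTree

    Minv = np.linalg.inv(sample.transform)
    tree = cKDTree(sample.sites_transformed)
    xx, yy = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    pix = (np.c_[xx.ravel(), yy.ravel()] - sample.offset) @ Minv.T
    k = min(16, len(sample.sites_transformed))
    dist, idx = tree.query(pix, k=k)
    power = dist**2 - sample.weights[idx]
    winner = idx[np.arange(len(pix)), np.argmin(power, axis=1)]
    labels = site_label[winner].reshape(h, w).astype(np.int32)

    # carve 1-px boundaries where the label changes rightward/downward
    bmask = np.zeros_like(labels, dtype=bool)
    bmask[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    bmask[:-1, :] |= labels[:-1, :] != labels[1:, :]
    lab = labels.copy()
    lab[bmask] = 0

    intensity = np.full((h, w), params.cytoplasm_level)
    from .morphometrics import _boundary_adjacency

    boundary, neigh = _boundary_adjacency(lab)

    def _distinct(stack):
        nsort = np.sort(stack, axis=0)
        distinct = (nsort > 0) & (np.diff(nsort, axis=0, prepend=0) > 0)
        return nsort, distinct.sum(axis=0)

    nsort4, n_ids4 = _distinct(neigh[:4])
    _, n_ids8 = _distinct(neigh)
    big = np.iinfo(lab.dtype).max
    lo = np.where(nsort4 > 0, nsort4, big).min(axis=0)
    hi = nsort4[-1]

    edge_px = boundary & (n_ids4 == 2) & (n_ids8 < 3)
    base = np.int64(lab.max()) + 1
    ers, ecs = np.nonzero(edge_px)
    keys = lo[ers, ecs].astype(np.int64) * base + hi[ers, ecs]
    order = np.argsort(keys, kind="stable")
    ers, ecs, keys = ers[order], ecs[order], keys[order]
    starts = np.r_[0, np.nonzero(np.diff(keys))[0] + 1, len(keys)]
    for s0, s1 in zip(starts[:-1], starts[1:]):
        n_px = s1 - s0
        value = params.intensity_base - params.intensity_slope * n_px
        if params.intensity_noise:
            value += rng.normal(0.0, params.intensity_noise)
        intensity[ers[s0:s1], ecs[s0:s1]] = max(value, 0.0)
    intensity[boundary & ~edge_px] = params.intensity_base
    if params.intensity_noise:
        intensity += rng.normal(0.0, params.intensity_noise * 0.2, (h, w))
        np.clip(intensity, 0.0, None, out=intensity)

    regions = {}
    for _, row in sample.truth.iterrows():
        regions[int(row["cell_id"])] = "hinge" if row["hinge"] else "non-hinge"
    return LabelImage(labels=lab, intensity=intensity, regions=regions)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def generate_area_tracks(params: TrackGenParams) -> list[ApicalAreaTrack]:
    """Per-class geometric drift to the target relative change, with noise.

    Each cell's noiseless trajectory is A0 * (1+change)^(t/T); every
    timepoint after the first is additionally multiplied by log-normal
    noise exp(N(0, noise_sd)).  Ground-truth classes are stored on the
    tracks (threshold convention: |change| > 0.2 splits AC/AE from
    no-change).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    n_ac = int(round(params.f_ac * n))
    n_ae = int(round(params.f_ae * n))
    classes = ["AC"] * n_ac + ["AE"] * n_ae + ["no-change"] * (n - n_ac - n_ae)
    rng.shuffle(classes)
    changes = {
        "AC": params.change_ac,
        "AE": params.change_ae,
        "no-change": params.change_none,
    }
    T = params.n_timepoints
    t = np.arange(T, dtype=float)
    tracks = []
    for cid, cls in enumerate(classes, start=1):
        a0 = params.mean_area * rng.lognormal(0.0, 0.2)
        drift = a0 * (1.0 + changes[cls]) ** (t / (T - 1))
        noise = np.ones(T)
        if params.noise_sd:
            noise[1:] = np.exp(rng.normal(0.0, params.noise_sd, T - 1))
        tracks.append(
            ApicalAreaTrack(cell_id=cid, t=t, area=drift * noise,
                            true_label=cls)
        )
    return tracks
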