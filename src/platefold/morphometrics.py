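"""Label-image and track morphometrics for apical-domain quantification.

This stage runs downstream of segmentation/tracking: it consumes 2D integer
label masks (0 = boundary/background) with optional registered intensity
channels, and per-cell apical-area time series.  It reports the per-cell
shape descriptors used for epithelial sheets (area, second-central-moment
aspect ratio and orientation, solidity), descriptive dispersion statistics
(sample s.d. and coefficient of variation), the apical-constriction /
apical-expansion classification of tracked cells (>20% decrease/increase
over the recording), and junction / cytoplasm intensity measurements on
dilated boundary and eroded interior masks.

Note the deliberate difference from the solvers' gyration tensor: image
regions are characterized by area-weighted (pixel) second central moments,
i.e. the ellipse with the same normalized second moments as the region,
not by unweighted polygon-vertex moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops_table

__all__ = [
    "LabelImage",
    "ApicalAreaTrack",
    "region_shape_metrics",
    "classify_apical_dynamics",
    "dispersion_stats",
    "junction_intensities",
    "read_label_image",
    "read_tracks_csv",
    "write_tracks_csv",
]

MIN_REGION_PIXELS = 4  # below this, aspect ratio / orientation are degenerate


@dataclass
class LabelImage:
    """2D integer segmentation mask with optional intensity channel.

    ``labels``: 0 marks boundary/background, k >= 1 a cell id.
    ``intensity``: registered channel of identical shape (optional).
    ``pixel_size``: micrometres per pixel (optional; areas/lengths are
    reported in pixel units when absent).
    ``regions``: cell id -> annotation ("hinge" | "non-hinge" | ...).
    """

    labels: np.ndarray
    intensity: np.ndarray | None = None
    pixel_size: float | None = None
    regions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 2D integer array")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.labels.shape:
                raise ValueError("intensity channel shape mismatch")

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class ApicalAreaTrack:
    """Apical domain size of one tracked cell over time."""

    cell_id: int
    t: np.ndarray
    area: np.ndarray
    label: str | None = None  # assigned AC/AE/no-change class
    true_label: str | None = None  # generator ground truth, if synthetic

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if len(self.area) < 2:
            raise ValueError(f"track {self.cell_id}: need >= 2 timepoints")
        if np.any(self.area <= 0):
            raise ValueError(f"track {self.cell_id}: areas must be positive")


# ---------------------------------------------------------------------------
# Region shape metrics
# ---------------------------------------------------------------------------

def region_shape_metrics(
    image: LabelImage, reference_axis=(1.0, 0.0)
) -> pd.DataFrame:
    """Per-cell area, perimeter, aspect ratio, orientation, solidity, centroid.

    Aspect ratio is the long/short axis ratio of the ellipse with the same
    normalized second central moments as the region; orientation is the
    angle between the long axis and ``reference_axis`` (default the image
    x axis, read as AP), folded to [0, 90] degrees.  Regions smaller than
    4 pixels are flagged degenerate and get NaN aspect/orientation.
    Areas and lengths are scaled by ``pixel_size`` when provided.
    """
    labels = image.labels
    if not np.any(labels > 0):
        raise ValueError("label image contains no cells")
    props = regionprops_table(
        labels,
        properties=(
            "label", "area", "perimeter", "solidity", "centroid",
            "moments_central",
        ),
    )
    df = pd.DataFrame(props).rename(
        columns={
            "label": "cell_id",
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
        }
    )
    # normalized second central moments; skimage indexes moments (row, col),
    # so over (x, y) = (col, row): cov_xx = mu02/mu00, cov_yy = mu20/mu00
    mu00 = df["moments_central-0-0"].to_numpy()
    cov_xx = df["moments_central-0-2"].to_numpy() / mu00
    cov_yy = df["moments_central-2-0"].to_numpy() / mu00
    cov_xy = df["moments_central-1-1"].to_numpy() / mu00
    df = df.drop(columns=[c for c in df.columns if c.startswith("moments_")])

    axis = np.asarray(reference_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    aspect = np.full(len(df), np.nan)
    theta = np.full(len(df), np.nan)
    degenerate = df["area"].to_numpy() < MIN_REGION_PIXELS
    for i in range(len(df)):
        if degenerate[i]:
            continue
        C = np.array([[cov_xx[i], cov_xy[i]], [cov_xy[i], cov_yy[i]]])
        evals, evecs = np.linalg.eigh(C)
        lo, hi = evals[0], evals[1]
        if hi <= 0 or lo < 0:
            degenerate[i] = True
            continue
        if lo == 0:
            degenerate[i] = True
            continue
        aspect[i] = float(np.sqrt(hi / lo))
        v = evecs[:, 1]
        theta[i] = float(np.degrees(np.arccos(np.clip(abs(v @ axis), 0, 1))))

    df["aspect_ratio"] = aspect
    df["orientation_deg"] = theta
    df["degenerate"] = degenerate
    df["centroid_x"] = df["centroid_col"]
    df["centroid_y"] = df["centroid_row"]
    df["area_px"] = df["area"]
    if image.pixel_size is not None:
        df["area"] = df["area"] * image.pixel_size**2
        df["perimeter"] = df["perimeter"] * image.pixel_size
    if image.regions:
        df["region"] = df["cell_id"].map(image.regions).fillna("none")
    return df.drop(columns=["centroid_row", "centroid_col"])


# ---------------------------------------------------------------------------
# Apical dynamics classification
# ---------------------------------------------------------------------------

def classify_apical_dynamics(
    tracks: list[ApicalAreaTrack],
    threshold: float = 0.20,
    baseline: str = "endpoints",
):
    """Score tracks as AC / AE / no-change by relative apical-area change.

    Relative change is (final - initial) / initial with the default
    ``endpoints`` baseline; the ``extrema`` option scores against the
    min/max over the whole track instead.  A track is AC (apical
    constriction) below -threshold, AE (apical expansion) above
    +threshold, else no-change.  Returns the tracks (labels filled in)
    and a frequency table.
    """
    if baseline not in ("endpoints", "extrema"):
        raise ValueError(f"unknown baseline {baseline!r}")
    counts = {"AC": 0, "AE": 0, "no-change": 0}
    for tr in tracks:
        a0 = tr.area[0]
        if a0 <= 0:
            raise ValueError(f"track {tr.cell_id}: non-positive initial area")
        if baseline == "endpoints":
            change = (tr.area[-1] - a0) / a0
        else:
            down = (tr.area.min() - a0) / a0
            up = (tr.area.max() - a0) / a0
            change = down if abs(down) >= abs(up) else up
        if change < -threshold:
            tr.label = "AC"
        elif change > threshold:
            tr.label = "AE"
        else:
            tr.label = "no-change"
        counts[tr.label] += 1
    n = len(tracks)
    freq = pd.DataFrame(
        {
            "class": list(counts),
            "count": list(counts.values()),
            "frequency": [c / n if n else np.nan for c in counts.values()],
        }
    )
    return tracks, freq


def dispersion_stats(values) -> tuple[float, float, float]:
    """Mean, sample standard deviation (n-1) and coefficient of variation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for dispersion statistics")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return mean, sd, sd / mean


# ---------------------------------------------------------------------------
# Junction and cytoplasm intensities
# ---------------------------------------------------------------------------

_N8 = [(-1, 0), (1, 0), (0, -1), (0, 1),
       (-1, -1), (-1, 1), (1, -1), (1, 1)]


def _boundary_adjacency(labels: np.ndarray):
    """For each boundary (0) pixel, the adjacent cell ids (8-connectivity)."""
    h, w = labels.shape
    padded = np.zeros((h + 2, w + 2), dtype=labels.dtype)
    padded[1:-1, 1:-1] = labels
    stacks = [padded[1 + dr:h + 1 + dr, 1 + dc:w + 1 + dc] for dr, dc in _N8]
    neigh = np.stack(stacks)  # (8, h, w)
    boundary = labels == 0
    return boundary, neigh


def junction_intensities(
    image: LabelImage, dilation_radius: int = 1, erosion_radius: int = 1
):
    """Junction and cytoplasm intensity tables from a labeled intensity image.

    A junction is a connected run of boundary pixels adjacent (4-conn) to
    exactly the same pair of cell ids; pixels adjacent to three or more
    cells are junction vertices and are tabulated separately.  Mean
    intensities are measured over the junction mask dilated by
    ``dilation_radius`` pixels; per-cell cytoplasmic intensity over the
    cell mask eroded by ``erosion_radius``.  Junction length is the
    boundary pixel count (times pixel size if provided).

    Returns ``(junctions, vertices, cytoplasm)`` DataFrames.
    """
    if image.intensity is None:
        raise ValueError("junction intensities need an intensity channel")
    labels = image.labels
    inten = image.intensity
    boundary, neigh = _boundary_adjacency(labels)

    h, w = labels.shape
    pair_rows: list[dict] = []
    vertex_rows: list[dict] = []

    # classify each boundary pixel by its adjacent cell ids (vectorized):
    # pair membership uses the 4-connected neighbors (tight junction
    # lengths); vertex detection uses all 8 (a triple point's center pixel
    # may touch its third cell only diagonally) and takes precedence
    def _distinct(stack):
        nsort = np.sort(stack, axis=0)
        distinct = (nsort > 0) & (np.diff(nsort, axis=0, prepend=0) > 0)
        return nsort, distinct.sum(axis=0)

    nsort4, n_ids4 = _distinct(neigh[:4])
    _, n_ids8 = _distinct(neigh)
    big = np.iinfo(labels.dtype).max
    lo = np.where(nsort4 > 0, nsort4, big).min(axis=0)
    hi = nsort4[-1]

    vertex_mask = boundary & (n_ids8 >= 3)
    edge_px = boundary & (n_ids4 == 2) & ~vertex_mask

    def _measure_run(run_mask, rs, cs):
        r0, r1 = rs.min(), rs.max()
        c0, c1 = cs.min(), cs.max()
        pad = dilation_radius + 1
        r0, r1 = max(0, r0 - pad), min(h, r1 + pad + 1)
        c0, c1 = max(0, c0 - pad), min(w, c1 + pad + 1)
        crop = run_mask[r0:r1, c0:c1]
        dil = ndimage.binary_dilation(crop, iterations=dilation_radius) \
            if dilation_radius else crop
        return float(inten[r0:r1, c0:c1][dil].mean())

    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity for runs
    px = image.pixel_size if image.pixel_size is not None else 1.0
    if edge_px.any():
        base = np.int64(labels.max()) + 1
        ers, ecs = np.nonzero(edge_px)
        keys = lo[ers, ecs].astype(np.int64) * base + hi[ers, ecs]
        order = np.argsort(keys, kind="stable")
        ers, ecs, keys = ers[order], ecs[order], keys[order]
        starts = np.r_[0, np.nonzero(np.diff(keys))[0] + 1, len(keys)]
        for s0, s1 in zip(starts[:-1], starts[1:]):
            rs, cs = ers[s0:s1], ecs[s0:s1]
            a = int(keys[s0] // base)
            b = int(keys[s0] % base)
            r0, r1 = rs.min(), rs.max() + 1
            c0, c1 = cs.min(), cs.max() + 1
            crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            crop[rs - r0, cs - c0] = True
            lab_runs, n_runs = ndimage.label(crop, structure=structure)
            for run in range(1, n_runs + 1):
                rr, cc = np.nonzero(lab_runs == run)
                run_mask = np.zeros_like(boundary)
                run_mask[rr + r0, cc + c0] = True
                pair_rows.append(
                    {
                        "cell_a": a,
                        "cell_b": b,
                        "length_px": len(rr),
                        "length": len(rr) * px,
                        "mean_intensity": _measure_run(
                            run_mask, rr + r0, cc + c0
                        ),
                    }
                )
    if vertex_mask.any():
        lab_runs, n_runs = ndimage.label(vertex_mask, structure=structure)
        for run in range(1, n_runs + 1):
            run_mask = lab_runs == run
            rs, cs = np.nonzero(run_mask)
            ids: set[int] = set()
            for r, c in zip(rs, cs):
                ids |= set(int(v) for v in neigh[:, r, c] if v > 0)
            vertex_rows.append(
                {
                    "cells": ",".join(str(i) for i in sorted(ids)),
                    "n_px": len(rs),
                    "mean_intensity": _measure_run(run_mask, rs, cs),
                }
            )

    cyto_rows = []
    for cid in image.cell_ids():
        m = labels == cid
        ero = ndimage.binary_erosion(m, iterations=erosion_radius) \
            if erosion_radius else m
        if not ero.any():
            ero = m
        cyto_rows.append(
            {"cell_id": int(cid), "mean_intensity": float(inten[ero].mean())}
        )

    junctions = pd.DataFrame(
        pair_rows,
        columns=["cell_a", "cell_b", "length_px", "length", "mean_intensity"],
    )
    vertices = pd.DataFrame(
        vertex_rows, columns=["cells", "n_px", "mean_intensity"]
    )
    cytoplasm = pd.DataFrame(cyto_rows, columns=["cell_id", "mean_intensity"])
    return junctions, vertices, cytoplasm


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_label_image(
    label_path: str | Path,
    intensity_path: str | Path | None = None,
    pixel_size: float | None = None,
) -> LabelImage:
    """Read a label mask (16-bit TIFF/PNG) and optional intensity channel."""
    import tifffile
    from skimage.io import imread

    def _read(p):
        p = Path(p)
        if p.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(p)
        return imread(p)

    labels = np.asarray(_read(label_path))
    if not np.issubdtype(labels.dtype, np.integer):
        labels = labels.astype(np.int32)
    intensity = _read(intensity_path) if intensity_path else None
    return LabelImage(labels=labels, intensity=intensity, pixel_size=pixel_size)


def read_tracks_csv(path: str | Path) -> list[ApicalAreaTrack]:
    """Read tracks from CSV with columns cell_id, t, area[, true_label]."""
    df = pd.read_csv(path)
    tracks = []
    for cid, g in df.groupby("cell_id"):
        g = g.sort_values("t")
        true_label = None
        if "true_label" in g.columns:
            true_label = str(g["true_label"].iloc[0])
        tracks.append(
            ApicalAreaTrack(
                cell_id=int(cid),
                t=g["t"].to_numpy(),
                area=g["area"].to_numpy(),
                true_label=true_label,
            )
        )
    return tracks


def write_tracks_csv(tracks: list[ApicalAreaTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, a in zip(tr.t, tr.area):
            row = {"cell_id": tr.cell_id, "t": t, "area": a}
            if tr.true_label is not None:
                row["true_label"] = tr.true_label
            if tr.label is not None:
                row["label"] = tr.label
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
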