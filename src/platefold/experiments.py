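"""Named end-to-end reproductions of the in-silico experiments.

Each registry entry runs a configured simulation study — the relaxation of
the plate with dispersed constricting cells, the constriction-probability
and aspect-ratio sweeps, the exterior-geometry and hinge-layout variants,
and the 3D furrow — and writes a result bundle (config + summary JSON and
the tables underlying the figures) to disk.  Two tiers are provided:
``smoke`` runs every experiment on a reduced lattice in minutes, ``full``
uses the study-size lattices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Tissue2D, build_hex_lattice
from .vertex2d import (
    SimConfig2D,
    assign_constriction,
    hinge_zones,
    plate_cell_stats,
    plate_dimensions,
    relax2d,
)
from .vertex3d import build_prism_tissue, furrow_profile, relax3d, apical_shape_table

__all__ = [
    "ExperimentSpec",
    "EXPERIMENTS",
    "run_experiment",
    "relax_plate",
    "pc_sweep",
    "alpha_sweep",
    "alpha_pairs",
    "hinge_run",
    "furrow_run",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """A named, seeded, tiered experiment run."""

    name: str
    tier: str = "smoke"  # "smoke" | "full"
    seeds: tuple[int, ...] = (1, 2, 3)
    out_dir: str | Path | None = None
    overrides: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reusable drivers
# ---------------------------------------------------------------------------

def relax_plate(
    tissue_shape: tuple[int, int],
    plate_shape: tuple[int, int],
    config: SimConfig2D,
    seeds=(1,),
    group_size: int = 5,
):
    """Relax one 2D geometry over seeds, against the no-constriction reference.

    Returns ``(per_seed, reference_tissue)`` where ``per_seed`` is a list
    of dicts holding the relaxed tissue, its per-cell shape table, summary
    statistics and normalized plate dimensions.
    """
    base = build_hex_lattice(*tissue_shape, plate_shape,
                             p0=config.p0, k_p=config.k_p)
    ref_cfg = replace(config, scheme="uniform", p_c=0.0)
    ref = assign_constriction(base, ref_cfg, seed=0)
    ref_relaxed, _ = relax2d(ref, ref_cfg)

    results = []
    for seed in seeds:
        t = assign_constriction(base, config, seed=seed)
        relaxed, diag = relax2d(t, config)
        table, hist, summary = plate_cell_stats(relaxed)
        dims = plate_dimensions(relaxed, ref_relaxed, group_size)
        initial_areas = t.areas()
        sel = t.is_plate & ~t.constricting
        area_ratio = (
            float(relaxed.areas()[sel].mean() / initial_areas[sel].mean())
            if sel.any() else float("nan")
        )
        results.append(
            {
                "seed": seed,
                "tissue": relaxed,
                "initial": t,
                "table": table,
                "histogram": hist,
                "summary": summary,
                "length": dims.length,
                "width": dims.width,
                "area_ratio_nonconstricting": area_ratio,
                "n_constricting": int(t.constricting.sum()),
                "final_energy": float(diag.energy[-1]),
                "max_force": float(diag.max_force[-1]),
            }
        )
    return results, ref_relaxed


def pc_sweep(tissue_shape, plate_shape, p_c_values, seeds, config=None):
    """Normalized plate length/width across constriction probabilities."""
    config = config or SimConfig2D(mode="minimize")
    rows = []
    for p_c in p_c_values:
        cfg = replace(config, p_c=float(p_c))
        per_seed, _ = relax_plate(tissue_shape, plate_shape, cfg, seeds)
        for r in per_seed:
            rows.append(
                {
                    "p_c": float(p_c),
                    "seed": r["seed"],
                    "length": r["length"],
                    "width": r["width"],
                    "mean_angle_deg": r["summary"]["mean_angle_deg"],
                    "area_ratio_nonconstricting":
                        r["area_ratio_nonconstricting"],
                }
            )
    df = pd.DataFrame(rows)
    pooled = df.groupby("p_c", as_index=False)[["length", "width"]].mean()
    return df, pooled


def alpha_pairs(n_pairs=16, target_cells=1200, lo=1 / 3, hi=3.0):
    """(N_x, N_y) pairs with aspect ratio alpha = N_y/N_x log-spaced."""
    alphas = np.exp(np.linspace(np.log(lo), np.log(hi), n_pairs))
    pairs = []
    for a in alphas:
        nx = max(4, int(round(np.sqrt(target_cells / a))))
        ny = max(4, int(round(a * nx)))
        pairs.append((nx, ny))
    return pairs


def alpha_sweep(pairs, margin=40, seeds=(1,), config=None):
    """Mean angle and elongation of non-constricting plate cells vs alpha."""
    config = config or SimConfig2D(mode="minimize", p_c=0.5)
    rows = []
    for nx, ny in pairs:
        shape = (nx + margin, ny + margin)
        per_seed, _ = relax_plate(shape, (nx, ny), config, seeds)
        for r in per_seed:
            rows.append(
                {
                    "n_x": nx,
                    "n_y": ny,
                    "alpha": ny / nx,
                    "seed": r["seed"],
                    "n_cells": r["summary"]["n_cells"],
                    "mean_angle_deg": r["summary"]["mean_angle_deg"],
                    "sd_angle_deg": r["summary"]["sd_angle_deg"],
                    "mean_kappa": r["summary"]["mean_kappa"],
                }
            )
    return pd.DataFrame(rows)


def hinge_run(tissue_shape, plate_shape, config=None, seeds=(1,)):
    """Hinge-layout relaxation; per-zone angle statistics."""
    config = config or SimConfig2D(mode="minimize", scheme="hinge")
    per_seed, _ = relax_plate(tissue_shape, plate_shape, config, seeds)
    rows = []
    for r in per_seed:
        zones = hinge_zones(r["tissue"], config.hinge_width,
                            config.hinge_separation)
        table = r["table"]
        for zone in ("hinge", "between"):
            sel = (
                (zones == zone)
                & ~table["constricting"].to_numpy()
                & np.isfinite(table["theta_deg"].to_numpy())
            )
            ang = table.loc[sel, "theta_deg"]
            rows.append(
                {
                    "seed": r["seed"],
                    "zone": zone,
                    "n_cells": int(sel.sum()),
                    "mean_angle_deg": float(ang.mean()),
                    "sd_angle_deg": float(ang.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows), per_seed


def furrow_run(p_c_values=(0.0, 0.5, 1.0), seed=1, n_ap=20, n_perp=40,
               hinge_width=3, force_tol=1e-3):
    """3D furrow formation across constriction probabilities."""
    rows = []
    bundles = []
    for p_c in p_c_values:
        t = build_prism_tissue(n_ap=n_ap, n_perp=n_perp,
                               hinge_width=hinge_width, p_c=p_c, seed=seed)
        relaxed, diag = relax3d(t, mode="minimize", force_tol=force_tol)
        depth, profile = furrow_profile(relaxed)
        rows.append(
            {
                "p_c": float(p_c),
                "seed": seed,
                "depth": depth,
                "n_constricting": int(t.constricting.sum()),
                "max_force": float(diag.max_force[-1]),
            }
        )
        bundles.append({"tissue": relaxed, "profile": profile})
    return pd.DataFrame(rows), bundles


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_SMOKE_2D = {"tissue": (50, 30), "plate": (30, 10)}
_FULL_2D = {"tissue": (100, 60), "plate": (60, 20)}


def _geom(tier):
    return _SMOKE_2D if tier == "smoke" else _FULL_2D


def _exp_fig3b_relax(spec: ExperimentSpec):
    g = _geom(spec.tier)
    cfg = SimConfig2D(mode="minimize", p_c=0.5, **spec.overrides)
    per_seed, _ = relax_plate(g["tissue"], g["plate"], cfg, spec.seeds)
    summary = {
        "area_ratio_nonconstricting": [
            r["area_ratio_nonconstricting"] for r in per_seed
        ],
        "mean_angle_deg": [r["summary"]["mean_angle_deg"] for r in per_seed],
        "length": [r["length"] for r in per_seed],
        "width": [r["width"] for r in per_seed],
    }
    tables = {f"cells_seed{r['seed']}": r["table"] for r in per_seed}
    return summary, tables


def _exp_fig3c_angles(spec: ExperimentSpec):
    g = _geom(spec.tier)
    cfg = SimConfig2D(mode="minimize", p_c=0.5, **spec.overrides)
    per_seed, _ = relax_plate(g["tissue"], g["plate"], cfg, spec.seeds)
    summary = {
        "mean_angle_deg": [r["summary"]["mean_angle_deg"] for r in per_seed],
        "sd_angle_deg": [r["summary"]["sd_angle_deg"] for r in per_seed],
    }
    tables = {f"angle_histogram_seed{r['seed']}": r["histogram"]
              for r in per_seed}
    return summary, tables


def _exp_fig3d_pc_sweep(spec: ExperimentSpec):
    g = _geom(spec.tier)
    pcs = spec.overrides.get("p_c_values", (0.0, 0.25, 0.5, 0.75, 1.0))
    df, pooled = pc_sweep(g["tissue"], g["plate"], pcs, spec.seeds)
    summary = {
        "p_c": pooled["p_c"].tolist(),
        "length": pooled["length"].tolist(),
        "width": pooled["width"].tolist(),
    }
    return summary, {"pc_sweep": df, "pc_sweep_pooled": pooled}


def _exp_fig3ef_alpha_sweep(spec: ExperimentSpec):
    if spec.tier == "smoke":
        pairs = alpha_pairs(n_pairs=5, target_cells=300)
        margin = 20
    else:
        pairs = alpha_pairs(n_pairs=16, target_cells=1200)
        margin = 40
    df = alpha_sweep(pairs, margin=margin, seeds=spec.seeds[:1])
    summary = {
        "alpha": df["alpha"].tolist(),
        "mean_angle_deg": df["mean_angle_deg"].tolist(),
        "mean_kappa": df["mean_kappa"].tolist(),
    }
    return summary, {"alpha_sweep": df}


def _exp_supp_geometry(spec: ExperimentSpec):
    if spec.tier == "smoke":
        variants = {"matched_aspect": ((50, 17), (30, 10)),
                    "square": ((50, 50), (30, 10))}
    else:
        variants = {"matched_aspect": ((100, 34), (60, 20)),
                    "square": ((100, 100), (60, 20))}
    cfg = SimConfig2D(mode="minimize", p_c=0.5, **spec.overrides)
    summary, tables = {}, {}
    for name, (tissue_shape, plate_shape) in variants.items():
        per_seed, _ = relax_plate(tissue_shape, plate_shape, cfg, spec.seeds)
        summary[name] = {
            "mean_angle_deg": [r["summary"]["mean_angle_deg"]
                               for r in per_seed],
        }
        tables[f"cells_{name}"] = per_seed[0]["table"]
    return summary, tables


def _exp_supp_hinges(spec: ExperimentSpec):
    if spec.tier == "smoke":
        tissue_shape, plate_shape = (50, 40), (30, 20)
    else:
        tissue_shape, plate_shape = (100, 60), (60, 20)
    cfg = SimConfig2D(mode="minimize", scheme="hinge", **spec.overrides)
    df, per_seed = hinge_run(tissue_shape, plate_shape, cfg, spec.seeds)
    pooled = df.groupby("zone", as_index=False)["mean_angle_deg"].mean()
    summary = {
        row["zone"]: row["mean_angle_deg"] for _, row in pooled.iterrows()
    }
    return summary, {"hinge_zones": df}


def _exp_fig3hij_3d(spec: ExperimentSpec):
    if spec.tier == "smoke":
        kw = {"n_ap": 10, "n_perp": 20}
    else:
        kw = {"n_ap": 20, "n_perp": 40}
    kw.update(spec.overrides)
    df, bundles = furrow_run(seed=spec.seeds[0], **kw)
    summary = {
        "p_c": df["p_c"].tolist(),
        "depth": df["depth"].tolist(),
    }
    tables = {"furrow_depths": df}
    for row, b in zip(df.itertuples(), bundles):
        tables[f"profile_pc{row.p_c:g}"] = b["profile"]
    return summary, tables


EXPERIMENTS = {
    "fig3b_relax": _exp_fig3b_relax,
    "fig3c_angles": _exp_fig3c_angles,
    "fig3d_pc_sweep": _exp_fig3d_pc_sweep,
    "fig3ef_alpha_sweep": _exp_fig3ef_alpha_sweep,
    "supp_geometry": _exp_supp_geometry,
    "supp_hinges": _exp_supp_hinges,
    "fig3hij_3d": _exp_fig3hij_3d,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run a registry experiment and (optionally) write its bundle to disk.

    The bundle contains ``config.json`` (spec, config hash, package
    version, scaled-down provenance note), ``summary.json`` and one CSV
    per result table.  Output is deterministic given the seeds.
    """
    if spec.name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {spec.name!r}; registry: "
            + ", ".join(sorted(EXPERIMENTS))
        )
    summary, tables = EXPERIMENTS[spec.name](spec)

    record = {
        "name": spec.name,
        "tier": spec.tier,
        "seeds": list(spec.seeds),
        "overrides": dict(spec.overrides),
        "version": __version__,
        "scaled_down": spec.tier == "smoke",
        "note": (
            "reduced lattice (smoke tier)" if spec.tier == "smoke"
            else "study-size lattice"
        ),
    }
    record["config_hash"] = hashlib.sha256(
        json.dumps(record, sort_keys=True).encode()
    ).hexdigest()[:16]

    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(record, indent=2,
                                                    sort_keys=True))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return {"config": record, "summary": summary, "tables": tables}
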