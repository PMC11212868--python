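"""Mechanical scenarios: wild type, softened lamina, LINC disruption.

The wild-type parameter set is calibrated (not measured) so that the model's
probe stresses land in the physiologically reported ranges: myofibril
diastolic tension 2-3 kPa and microtubule axial compression 1-1.8 kPa.
Lamina softening (mutant lamin A/C) reduces the NE+lamina modulus to
10 kPa; LINC-complex disruption scales both the cage compressive stress and
the cage modulus down (the perinuclear cage is lost together with the
kinesin motors that load it).  Microtubule enrichment maps linearly onto
(sigma_MT, cage modulus) relative to the wild-type enrichment.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import yaml

from ..errors import ConfigError, SolverError
from .mesh import MechGeometry
from .model import ActiveState, MechMaterials, build_model, solve_ramp

#: wild-type perinuclear MT enrichment used as the reference point of the
#: enrichment -> (cage stress, cage stiffness) mapping
WT_ENRICHMENT = 2.2

#: fraction of cage stress and stiffness remaining after LINC disruption
LINC_CAGE_FRACTION = 0.3

#: lamina modulus (kPa) for the mutant-lamin scenarios
MUTANT_LAMINA_MODULUS = 10.0

SCENARIOS = ("WT", "LMNA_mut", "csDNKASH", "LMNA_mut_csDNKASH")


def scenario_parameters(name: str, config: dict | None = None):
    """Resolve (geometry, materials, active) for a named scenario."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}")
    cfg = config or {}
    geometry = cfg.get("geometry") or MechGeometry()
    materials = cfg.get("materials") or MechMaterials()
    active = cfg.get("active") or ActiveState()
    materials = MechMaterials(moduli=dict(materials.moduli),
                              poisson=dict(materials.poisson))
    if "LMNA_mut" in name:
        materials.moduli["lamina"] = cfg.get("mutant_lamina_modulus",
                                             MUTANT_LAMINA_MODULUS)
    if "csDNKASH" in name:
        frac = cfg.get("linc_cage_fraction", LINC_CAGE_FRACTION)
        materials.moduli["cage"] = materials.moduli["cage"] * frac
        active = replace(active, sigma_mt=active.sigma_mt * frac)
    return geometry, materials, active


def run_scenario(name: str, config: dict | None = None, refine: float = 1.0,
                 n_steps: int | None = None):
    """Solve one scenario to its physiologically stressed configuration."""
    geometry, materials, active = scenario_parameters(name, config)
    model = build_model(geometry, materials, active, refine=refine)
    return solve_ramp(model, n_steps=n_steps)


def _scaled_state(base_active: ActiveState, base_materials: MechMaterials,
                  enrichment: float, wt_enrichment: float = WT_ENRICHMENT):
    """Linear enrichment mapping: scale cage stress and modulus together."""
    scale = enrichment / wt_enrichment
    mats = MechMaterials(moduli=dict(base_materials.moduli),
                         poisson=dict(base_materials.poisson))
    mats.moduli["cage"] = base_materials.moduli["cage"] * scale
    act = replace(base_active, sigma_mt=base_active.sigma_mt * scale)
    return mats, act


def sweep_enrichment(base_scenario: str = "WT", enrichment_grid=None,
                     config: dict | None = None, refine: float = 1.0,
                     instability_threshold: float = 0.8) -> pd.DataFrame:
    """Nuclear aspect ratio across a grid of MT-cage enrichment values.

    Each grid point rescales the cage compressive stress and stiffness
    linearly in enrichment (wild-type enrichment = reference).  Solver
    failures flag the point and the sweep continues.
    """
    if enrichment_grid is None:
        enrichment_grid = np.linspace(0.5, 3.0, 9)
    geometry, materials, active = scenario_parameters(base_scenario, config)
    rows = []
    for e in np.asarray(enrichment_grid, dtype=float):
        mats, act = _scaled_state(active, materials, e)
        try:
            model = build_model(geometry, mats, act, refine=refine)
            sol = solve_ramp(model)
            s_loc, _ = sol.lamina_max_principal_location()
            rows.append({"enrichment": float(e),
                         "aspect_ratio": sol.nuclear_aspect_ratio,
                         "volume_change_pct": sol.nuclear_volume_change,
                         "stress_location": s_loc,
                         "instability": bool(s_loc > instability_threshold),
                         "failed": False})
        except SolverError:
            rows.append({"enrichment": float(e), "aspect_ratio": np.nan,
                         "volume_change_pct": np.nan, "stress_location": np.nan,
                         "instability": False, "failed": True})
    return pd.DataFrame(rows)


def detect_tip_instability(sigma_levels, lamina_modulus: float,
                           config: dict | None = None, refine: float = 1.0,
                           threshold: float = 0.8):
    """Find the critical cage stress at which tension jumps to the tips.

    Solves the model over increasing sigma_MT at fixed lamina modulus and
    flags the first load level where the maximum-principal-stress location
    on the lamina crosses ``threshold`` (normalized arc: 0 equator, 1 tip).
    The critical value is interpolated between the bracketing levels.
    Returns a dict with the per-level trace; a non-monotone location trace
    is reported with a warning flag and no critical value.
    """
    sigma_levels = np.asarray(sigma_levels, dtype=float)
    if len(sigma_levels) < 5:
        raise ValueError("need >= 5 load levels to bracket the instability")
    cfg = dict(config or {})
    geometry = cfg.get("geometry") or MechGeometry()
    materials = cfg.get("materials") or MechMaterials()
    materials = MechMaterials(moduli=dict(materials.moduli),
                              poisson=dict(materials.poisson))
    materials.moduli["lamina"] = lamina_modulus
    base_active = cfg.get("active") or ActiveState()

    locations, ars = [], []
    for s_mt in sigma_levels:
        act = replace(base_active, sigma_mt=float(s_mt))
        model = build_model(geometry, materials, act, refine=refine)
        try:
            sol = solve_ramp(model)
        except SolverError:
            # unreachable load level: record a gap and keep scanning
            locations.append(np.nan)
            ars.append(np.nan)
            continue
        loc, _ = sol.lamina_max_principal_location()
        locations.append(loc)
        ars.append(sol.nuclear_aspect_ratio)
    locations = np.array(locations)
    ars = np.array(ars)

    finite = np.isfinite(locations)
    above = finite & (locations > threshold)
    result = {"sigma_levels": sigma_levels, "locations": locations,
              "aspect_ratios": ars, "instability": bool(above.any()),
              "critical_sigma_mt": None,
              "warning": "solver failed at some load levels"
              if not finite.all() else None}
    if above.any():
        k = int(np.argmax(above))
        if k == 0 or not finite[k - 1]:
            result["critical_sigma_mt"] = float(sigma_levels[k])
        else:
            s0, s1 = sigma_levels[k - 1], sigma_levels[k]
            l0, l1 = locations[k - 1], locations[k]
            frac = (threshold - l0) / (l1 - l0) if l1 != l0 else 0.5
            result["critical_sigma_mt"] = float(s0 + frac * (s1 - s0))
        # once unstable, the location should stay at the tip
        tail = locations[k:][np.isfinite(locations[k:])]
        if not np.all(tail > threshold):
            result["warning"] = "non-monotone stress-location trace"
            result["critical_sigma_mt"] = None
    return result


# ---------------------------------------------------------------------------
# YAML scenario configs
# ---------------------------------------------------------------------------

def config_from_yaml(path) -> dict:
    """Load a scenario config: geometry / materials / active blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {}
    if "geometry" in raw:
        cfg["geometry"] = MechGeometry(**raw["geometry"])
    if "materials" in raw:
        m = raw["materials"]
        cfg["materials"] = MechMaterials(
            moduli=m.get("moduli", MechMaterials().moduli),
            poisson=m.get("poisson", MechMaterials().poisson))
    if "active" in raw:
        cfg["active"] = ActiveState(**raw["active"])
    for key in ("mutant_lamina_modulus", "linc_cage_fraction"):
        if key in raw:
            cfg[key] = raw[key]
    return cfg


def export_vtk(solution, path):
    """Legacy-ASCII VTK unstructured grid of the deformed mesh + stresses."""
    m = solution.model.mesh
    u = solution.U.reshape(-1, 2)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncardionuc axisymmetric solution\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {m.n_nodes} float\n")
        for (r, z), (ur, uz) in zip(m.nodes, u):
            fh.write(f"{r + ur:.6g} {z + uz:.6g} 0\n")
        fh.write(f"CELLS {m.n_elements} {4 * m.n_elements}\n")
        for tri in m.elements:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {m.n_elements}\n")
        fh.write("5\n" * m.n_elements)
        fh.write(f"CELL_DATA {m.n_elements}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        for r in m.region:
            fh.write(f"{r}\n")
        for i, name in enumerate(("sigma_rr", "sigma_zz", "sigma_tt", "sigma_rz")):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in solution.sigma[:, i]:
                fh.write(f"{v:.6g}\n")


def element_table(solution) -> pd.DataFrame:
    """Per-element CSV-ready table: centroid, region, stresses."""
    m = solution.model.mesh
    cent = m.nodes[m.elements].mean(axis=1)
    from .mesh import REGION_NAMES
    return pd.DataFrame({
        "r": cent[:, 0], "z": cent[:, 1],
        "region": [REGION_NAMES[i] for i in m.region],
        "sigma_rr": solution.sigma[:, 0], "sigma_zz": solution.sigma[:, 1],
        "sigma_tt": solution.sigma[:, 2], "sigma_rz": solution.sigma[:, 3],
    })
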