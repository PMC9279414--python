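"""End-to-end comparison experiment: geometry -> mesh -> BCs -> solve ->
WSS -> report, behind a validated run configuration.

The experiment solves the same diastolic flow problem on a control root
and on a variant whose left coronary ostium is displaced toward the
sinotubular junction, everything else held fixed, and reports the percent
change in area-averaged ostial wall shear stress together with the
diagnostics needed to audit the run (boundary-condition summary, Womersley
number, shear-rate quantiles, convergence histories, provenance hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as ofio
from .boundary_conditions import HemodynamicsConfig, assemble_bcs
from .errors import ConfigurationError
from .flow_solver import SolverOptions, outlet_flux, solve_steady
from .geometry import (GeometryConfig, LCA_OUTLET, RCA_OUTLET,
                       build_root_geometry, displace_lco, mesh_geometry,
                       validate_mesh)
from .rheology import CarreauParams, NewtonianParams
from .synthetic_data import MUTANT_AXIAL_SHIFT, MUTANT_AZIMUTH_SHIFT_DEG
from .units import MM_TO_M, pa_to_mmhg
from .wss_postprocess import (ComparisonReport, ostial_region,
                              percent_reduction, regional_mean_wss,
                              wall_shear_stress, womersley_number)

__all__ = ["RunConfig", "run_comparison", "default_config_dict"]

log = logging.getLogger("ostiaflow")

_GEOM_KEYS_MM = ("aortic_diameter_mm", "root_length_mm", "sinus_height_mm",
                 "coronary_diameter_mm", "coronary_stub_length_mm")
_GEOM_REQUIRED = ("aortic_diameter_mm",)
_HEMO_REQUIRED = ("aortic_outlet_pressure_mmHg", "R_eq_mmHg_s_per_mL")


@dataclass
class RunConfig:
    """Validated configuration of one comparison run."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    mutant_axial_shift: float = MUTANT_AXIAL_SHIFT
    mutant_azimuth_shift_deg: float = MUTANT_AZIMUTH_SHIFT_DEG
    hemodynamics: HemodynamicsConfig = field(default_factory=HemodynamicsConfig)
    rheology: object = field(default_factory=CarreauParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    output_dir: Path = Path("ostiaflow_out")
    seed: int = 17
    mesh_edge_length: float = 4.8e-5   # m; < coronary_diameter / 3

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a hierarchical config mapping, validating every
        section and naming the failing key on error."""
        known = {"geometry", "hemodynamics", "rheology", "solver", "run"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config sections {sorted(unknown)}")

        gsec = dict(data.get("geometry", {}))
        for key in _GEOM_REQUIRED:
            if key not in gsec:
                raise ConfigurationError(f"config missing key 'geometry.{key}'")
        gkw = {}
        for key, val in gsec.items():
            if key in _GEOM_KEYS_MM:
                gkw[key[:-3]] = float(val) * MM_TO_M
            elif key in ("lco_axial_fraction", "lco_azimuth_deg",
                         "rco_axial_fraction", "rco_azimuth_deg",
                         "sinus_bulge_ratio", "sinus_lobes"):
                gkw[key] = val
            else:
                raise ConfigurationError(f"unknown key 'geometry.{key}'")
        geometry = GeometryConfig(**gkw)

        hsec = dict(data.get("hemodynamics", {}))
        for key in _HEMO_REQUIRED:
            if key not in hsec:
                raise ConfigurationError(f"config missing key 'hemodynamics.{key}'")
        hfields = {f.name for f in dataclasses.fields(HemodynamicsConfig)}
        for key in hsec:
            if key not in hfields:
                raise ConfigurationError(f"unknown key 'hemodynamics.{key}'")
        hemodynamics = HemodynamicsConfig(**hsec)

        rsec = dict(data.get("rheology", {"model": "carreau"}))
        model = rsec.pop("model", "carreau")
        if model == "carreau":
            rheology = CarreauParams(**rsec)
        elif model == "newtonian":
            rheology = NewtonianParams(**rsec)
        else:
            raise ConfigurationError(f"unknown rheology.model {model!r}")

        ssec = dict(data.get("solver", {}))
        sfields = {f.name for f in dataclasses.fields(SolverOptions)}
        for key in ssec:
            if key not in sfields:
                raise ConfigurationError(f"unknown key 'solver.{key}'")
        solver = SolverOptions(**ssec)

        run = dict(data.get("run", {}))
        cfg = cls(geometry=geometry, hemodynamics=hemodynamics,
                  rheology=rheology, solver=solver)
        if "mutant_axial_shift" in run:
            cfg.mutant_axial_shift = float(run.pop("mutant_axial_shift"))
        if "mutant_azimuth_shift_deg" in run:
            cfg.mutant_azimuth_shift_deg = float(run.pop("mutant_azimuth_shift_deg"))
        if "mesh_edge_length_mm" in run:
            cfg.mesh_edge_length = float(run.pop("mesh_edge_length_mm")) * MM_TO_M
        if "output_dir" in run:
            cfg.output_dir = Path(run.pop("output_dir"))
        if "seed" in run:
            cfg.seed = int(run.pop("seed"))
        if run:
            raise ConfigurationError(f"unknown key 'run.{sorted(run)[0]}'")
        return cfg

    def to_dict(self) -> dict:
        g = self.geometry
        rheo = dataclasses.asdict(self.rheology)
        rheo["model"] = ("newtonian" if isinstance(self.rheology, NewtonianParams)
                         else "carreau")
        return {
            "geometry": {
                "aortic_diameter_mm": g.aortic_diameter / MM_TO_M,
                "root_length_mm": g.root_length / MM_TO_M,
                "sinus_height_mm": g.sinus_height / MM_TO_M,
                "coronary_diameter_mm": g.coronary_diameter / MM_TO_M,
                "coronary_stub_length_mm": g.coronary_stub_length / MM_TO_M,
                "sinus_bulge_ratio": g.sinus_bulge_ratio,
                "sinus_lobes": g.sinus_lobes,
                "lco_axial_fraction": g.lco_axial_fraction,
                "lco_azimuth_deg": g.lco_azimuth_deg,
                "rco_axial_fraction": g.rco_axial_fraction,
                "rco_azimuth_deg": g.rco_azimuth_deg,
            },
            "hemodynamics": dataclasses.asdict(self.hemodynamics),
            "rheology": rheo,
            "solver": dataclasses.asdict(self.solver),
            "run": {
                "mutant_axial_shift": self.mutant_axial_shift,
                "mutant_azimuth_shift_deg": self.mutant_azimuth_shift_deg,
                "mesh_edge_length_mm": self.mesh_edge_length / MM_TO_M,
                "output_dir": str(self.output_dir),
                "seed": self.seed,
            },
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_config_dict() -> dict:
    return RunConfig().to_dict()


def _run_scenario(label, geom_config, config: RunConfig, outdir: Path | None):
    """Mesh, solve and post-process one scenario; returns a result dict."""
    geom = build_root_geometry(geom_config)
    mesh = mesh_geometry(geom, config.mesh_edge_length)
    quality = validate_mesh(mesh)
    bcs = assemble_bcs(mesh, config.hemodynamics, geom_config)
    log.info("%s: %d tets; wall speed %.3g mm/s; outlet pressure %.3g mmHg; "
             "R = %s mmHg.s/mL", label, mesh.n_tets,
             bcs.wall_normal_speed * 1e3,
             pa_to_mmhg(bcs.descriptors[2].pressure),
             {pid: f"{spec.resistance / 1.33322e8:.3g}"
              for pid, spec in bcs.resistance_patches().items()})
    if outdir is not None:
        ofio.write_mesh(mesh, outdir / f"{label}_mesh.vtu")
        ofio.write_mesh(mesh, outdir / f"{label}_mesh.msh")

    sol = solve_steady(mesh, bcs, config.rheology, config.solver,
                       density=config.hemodynamics.density)
    result = {
        "label": label,
        "n_tets": mesh.n_tets,
        "n_nodes": mesh.n_nodes,
        "watertight": bool(quality.watertight),
        "converged": bool(sol.convergence.converged),
        "iterations": sol.convergence.iterations,
        "residual_history": [float(v) for v in sol.convergence.residual_history],
        "geometry": geom_config.to_dict(),
    }
    if not sol.convergence.converged:
        if outdir is not None:        # persist partial artifacts for audit
            ofio.write_solution(sol, outdir / f"{label}_solution.vtu")
        return result, None

    wss = wall_shear_stress(sol)
    region = ostial_region(geom, "LCA")
    ostial = regional_mean_wss(wss, region)
    gdot = sol.shear_rates()
    net, gross = sol.mass_balance()
    patch_stats = {}
    for pid in mesh.patch_ids():
        f = wall_shear_stress(sol, patch_label=pid) if pid != wss.patch_label else wss
        w = f.areas
        patch_stats[mesh.patch_names.get(pid, str(pid))] = {
            "mean": float(np.sum(w * f.wss_cgs) / np.sum(w)),
            "max": float(f.wss_cgs.max()),
        }
    result.update({
        "ostial_wss_cgs": float(ostial),
        "ostial_region": {"center_m": [float(v) for v in region.center],
                          "radius_m": float(region.radius)},
        "patch_wss_cgs": patch_stats,
        "outlet_flow_mm3_per_s": {
            "LCA": outlet_flux(sol, LCA_OUTLET) * 1e9,
            "RCA": outlet_flux(sol, RCA_OUTLET) * 1e9,
        },
        "mass_balance": {"net_over_gross": abs(net) / max(gross, 1e-300)},
        "shear_rate_quantiles_per_s": {
            q: float(np.quantile(gdot, float(q))) for q in ("0.1", "0.5", "0.9", "0.99")
        },
    })
    if outdir is not None:
        ofio.write_solution(sol, outdir / f"{label}_solution.vtu",
                            wss_fields=[wss])
    return result, float(ostial)


def run_comparison(config: RunConfig, write_artifacts: bool = True) -> ComparisonReport:
    """Execute the control and displaced-LCO scenarios and compare ostial WSS.

    Both scenarios use identical settings except the LCO placement. Writes
    meshes, solution VTUs, and the JSON+CSV report into
    ``config.output_dir``; on non-convergence the report is flagged and has
    no reduction value, but partial artifacts persist.
    """
    outdir = None
    if write_artifacts:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    control_cfg = config.geometry
    mutant_cfg = displace_lco(control_cfg, config.mutant_axial_shift,
                              config.mutant_azimuth_shift_deg)

    scenarios, ostial = {}, {}
    for label, gcfg in (("control", control_cfg), ("mutant", mutant_cfg)):
        result, mean_wss = _run_scenario(label, gcfg, config, outdir)
        scenarios[label] = result
        ostial[label] = mean_wss

    reduction = None
    if ostial["control"] is not None and ostial["mutant"] is not None:
        reduction = percent_reduction(ostial["control"], ostial["mutant"])

    hemo = config.hemodynamics
    mu_ref = (config.rheology.mu if isinstance(config.rheology, NewtonianParams)
              else config.rheology.mu0)
    report = ComparisonReport(
        scenarios=scenarios,
        ostial_regions={k: v.get("ostial_region") for k, v in scenarios.items()},
        percent_reduction=reduction,
        diagnostics={
            "womersley_number": womersley_number(
                control_cfg.aortic_diameter / 2.0, hemo.heart_rate_bpm,
                hemo.density, mu_ref),
            "wall_speed_mm_per_s": 1e3 * _wall_speed(config),
            "all_converged": all(s["converged"] for s in scenarios.values()),
        },
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "mesh_edge_length_m": config.mesh_edge_length,
            "package": "ostiaflow",
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    if outdir is not None:
        ofio.write_report(report, outdir / "comparison_report.json",
                          outdir / "comparison_report.csv")
        ofio.save_config_file(config.to_dict(), outdir / "run_config.yaml")
    return report


def _wall_speed(config: RunConfig) -> float:
    from .boundary_conditions import wall_inward_velocity
    h = config.hemodynamics
    return wall_inward_velocity(h.contraction_fraction, h.diastole_fraction,
                                h.heart_rate_bpm, config.geometry.aortic_diameter)
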