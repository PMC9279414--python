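"""Diastolic boundary conditions for the idealized aortic root.

Three BC families drive the quasi-steady diastolic flow:

* the aortic wall moves inward (Dirichlet velocity ``u = -s n``) at a speed
  derived from a fractional wall contraction over the diastolic part of the
  cardiac cycle;
* the aortic outlet carries a constant pressure (normal traction);
* each coronary outlet carries a lumped resistance, ``p = R Q + p_distal``,
  with the resistances distributed over outlets by Murray's law
  (R_i proportional to A_i^-1.5) so that their parallel combination equals a
  prescribed equivalent resistance R_eq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .errors import ConfigurationError, ValidationError
from .units import mmhg_to_pa, resistance_to_si

__all__ = [
    "HemodynamicsConfig",
    "OutletSpec",
    "WallMotion",
    "PressureOutlet",
    "ResistanceOutlet",
    "BoundaryConditionSet",
    "wall_inward_velocity",
    "murray_resistances",
    "assemble_bcs",
]


@dataclass(frozen=True)
class HemodynamicsConfig:
    """Hemodynamic constants of the diastolic scenario.

    Units are carried in the field names where they are not SI. The default
    values describe the E16.5 mouse embryo: density 1060 kg/m^3, heart rate
    240 bpm, a diastole occupying 30% of the cycle with a 10% wall
    contraction, 9 mmHg aortic diastolic pressure, and an equivalent
    coronary vascular resistance of 5.6e3 mmHg.s/mL.
    """

    density: float = 1060.0                      # kg/m^3
    heart_rate_bpm: float = 240.0
    diastole_fraction: float = 0.30
    contraction_fraction: float = 0.10
    aortic_outlet_pressure_mmHg: float = 9.0
    R_eq_mmHg_s_per_mL: float = 5.6e3
    distal_pressure_mmHg: float = 0.0

    def __post_init__(self):
        for name in ("density", "heart_rate_bpm", "aortic_outlet_pressure_mmHg",
                     "R_eq_mmHg_s_per_mL"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("diastole_fraction", "contraction_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.distal_pressure_mmHg < 0:
            raise ValidationError("distal_pressure_mmHg must be >= 0")


@dataclass(frozen=True)
class OutletSpec:
    """Resistance-outlet descriptor: meshed area (m^2), resistance
    (Pa.s/m^3) and distal reference pressure (Pa)."""

    patch_label: int
    area: float
    resistance: float
    distal_pressure: float = 0.0

    def __post_init__(self):
        if self.area <= 0:
            raise ValidationError("outlet area must be > 0")
        if self.resistance <= 0:
            raise ValidationError("outlet resistance must be > 0")


@dataclass(frozen=True)
class WallMotion:
    """Dirichlet wall velocity u = -speed * n (inward normal motion)."""

    speed: float  # m/s, positive = inward


@dataclass(frozen=True)
class PressureOutlet:
    """Constant-pressure outlet imposed as normal traction -p n (Pa)."""

    pressure: float


@dataclass(frozen=True)
class ResistanceOutlet:
    """Lumped resistance outlet: traction -(R Q + p_distal) n."""

    spec: OutletSpec


@dataclass
class BoundaryConditionSet:
    """Per-patch BC descriptors plus the Murray-split bookkeeping."""

    descriptors: dict            # patch_id -> descriptor
    wall_normal_speed: float     # m/s
    murray_constant: float       # C in R_i = C A_i^-1.5 (SI)
    R_eq: float                  # Pa.s/m^3

    def patch_descriptor(self, patch_id):
        return self.descriptors[patch_id]

    def resistance_patches(self):
        return {pid: d.spec for pid, d in self.descriptors.items()
                if isinstance(d, ResistanceOutlet)}

    def validate_against(self, mesh: geo.VolumeMesh):
        mesh_patches = set(mesh.patch_ids())
        missing = mesh_patches - set(self.descriptors)
        if missing:
            names = [mesh.patch_names.get(p, str(p)) for p in sorted(missing)]
            raise ConfigurationError(f"no boundary condition for patches {names}")


def wall_inward_velocity(contraction_fraction: float, diastole_fraction: float,
                         heart_rate_bpm: float, aortic_diameter: float) -> float:
    """Inward wall-normal speed (m/s) of the contracting aortic wall.

    A fractional contraction of the lumen over the diastolic interval
    ``diastole_fraction * (60 / heart_rate_bpm)`` displaces the wall radially
    by ``contraction_fraction * aortic_diameter / 2``; the speed is the
    ratio. (A diameter- or radius-based reading of "contraction" gives the
    same displacement; the ambiguity is immaterial.)
    """
    if contraction_fraction < 0:
        raise ValidationError("contraction_fraction must be >= 0")
    for name, v in (("diastole_fraction", diastole_fraction),
                    ("heart_rate_bpm", heart_rate_bpm),
                    ("aortic_diameter", aortic_diameter)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0, got {v}")
    if diastole_fraction >= 1.0:
        raise ValidationError("diastole_fraction must be < 1")
    radial_displacement = contraction_fraction * aortic_diameter / 2.0
    diastole_duration = diastole_fraction * 60.0 / heart_rate_bpm
    return radial_displacement / diastole_duration


def murray_resistances(outlet_areas, R_eq: float):
    """Murray's-law resistance split: R_i = C A_i^-1.5 with the constant C
    chosen so the parallel sum of the R_i equals R_eq.

    Since R_i^-1 = A_i^1.5 / C, the constraint gives C = R_eq * sum A_j^1.5.
    Returns ``(C, resistances)``.
    """
    areas = np.asarray(list(outlet_areas), dtype=float)
    if areas.size == 0:
        raise ValidationError("need at least one outlet area")
    if np.any(areas <= 0) or R_eq <= 0:
        raise ValidationError("areas and R_eq must be > 0")
    C = R_eq * float(np.sum(areas**1.5))
    resistances = C * areas**-1.5
    return C, resistances


def assemble_bcs(mesh: geo.VolumeMesh, hemo: HemodynamicsConfig,
                 geom_config: geo.GeometryConfig) -> BoundaryConditionSet:
    """Build the full diastolic BC set for a labeled root mesh.

    Coronary outlet areas are taken from the meshed patches (not the nominal
    config) so the Murray split is consistent with the discrete geometry.
    """
    present = set(mesh.patch_ids())
    required = {geo.WALL, geo.AORTIC_OUTLET, geo.LCA_OUTLET, geo.RCA_OUTLET}
    missing = required - present
    if missing:
        names = [geo.PATCH_NAMES[p] for p in sorted(missing)]
        raise ConfigurationError(f"mesh is missing required patches {names}")

    speed = wall_inward_velocity(
        hemo.contraction_fraction, hemo.diastole_fraction,
        hemo.heart_rate_bpm, geom_config.aortic_diameter,
    )
    R_eq_si = resistance_to_si(hemo.R_eq_mmHg_s_per_mL)
    p_distal = mmhg_to_pa(hemo.distal_pressure_mmHg)
    coronary = [geo.LCA_OUTLET, geo.RCA_OUTLET]
    areas = [mesh.patch_area(p) for p in coronary]
    C, resistances = murray_resistances(areas, R_eq_si)

    descriptors = {
        geo.WALL: WallMotion(speed=speed),
        geo.AORTIC_OUTLET: PressureOutlet(
            pressure=mmhg_to_pa(hemo.aortic_outlet_pressure_mmHg)),
    }
    for pid, A, R in zip(coronary, areas, resistances):
        descriptors[pid] = ResistanceOutlet(OutletSpec(
            patch_label=pid, area=A, resistance=float(R),
            distal_pressure=p_distal))

    bcs = BoundaryConditionSet(
        descriptors=descriptors, wall_normal_speed=speed,
        murray_constant=C, R_eq=R_eq_si,
    )
    # parallel-sum identity must hold to near machine precision
    inv_sum = sum(1.0 / d.spec.resistance for d in descriptors.values()
                  if isinstance(d, ResistanceOutlet))
    if abs(inv_sum * R_eq_si - 1.0) > 1e-12:
        raise ConfigurationError("Murray split failed the parallel-sum identity")
    return bcs
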