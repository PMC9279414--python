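"""Generators for every input the pipeline needs, with no downloads.

Three kinds of inputs are emulated:

* viscometry tables drawn from a known Carreau law with multiplicative
  Gaussian noise (viscometer error scales with the reading), standing in
  distributionally for adult-mouse viscometry data;
* the control / displaced-LCO geometry configuration pair of the
  comparison experiment (the mutant differs from the control only in the
  left-coronary-ostium placement: +0.4 of sinus height toward the
  sinotubular junction and +30 degrees posterior);
* closed-form Hagen-Poiseuille benchmark records used as verification
  oracles for the flow solver.

All generators are pure functions of their arguments: the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import GeometryConfig, displace_lco
from .rheology import CarreauParams, ViscositySample, carreau_viscosity

__all__ = [
    "SyntheticSpec",
    "PoiseuilleBenchmark",
    "MUTANT_AXIAL_SHIFT",
    "MUTANT_AZIMUTH_SHIFT_DEG",
    "generate_viscosity_samples",
    "generate_geometry_pair",
    "poiseuille_fixture",
]

#: Default displaced-LCO scenario: the axial/azimuthal shift applied to the
#: control ostium. The displacement magnitude is a stated scenario
#: parameter (the in vivo shift is quantified only relative to the valve
#: base), not a measured reproduction.
MUTANT_AXIAL_SHIFT = 0.4
MUTANT_AZIMUTH_SHIFT_DEG = 30.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Controls for the synthetic generators."""

    seed: int = 17
    noise_sd: float = 0.05            # relative (multiplicative) noise
    n_samples: int = 50
    shear_rate_range: tuple = (0.1, 1.0e3)   # 1/s, log-spaced
    scenario: str = "default"
    geometry_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        lo, hi = self.shear_rate_range
        if not 0 < lo < hi:
            raise ValidationError("shear_rate_range must satisfy 0 < min < max")


def generate_viscosity_samples(params: CarreauParams,
                               spec: SyntheticSpec) -> list[ViscositySample]:
    """Noisy viscometry table from a known Carreau law.

    Shear rates are log-spaced over ``spec.shear_rate_range``; viscosities
    are mu_model(gdot) * (1 + eps) with eps ~ N(0, noise_sd), seeded.
    """
    lo, hi = spec.shear_rate_range
    gdot = np.logspace(np.log10(lo), np.log10(hi), spec.n_samples)
    mu = np.asarray(carreau_viscosity(gdot, params), dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mu = mu * (1.0 + spec.noise_sd * rng.standard_normal(spec.n_samples))
        mu = np.maximum(mu, 1e-9)     # viscometers do not report <= 0
    return [ViscositySample(float(g), float(m)) for g, m in zip(gdot, mu)]


def generate_geometry_pair(spec: SyntheticSpec | None = None):
    """(control, mutant) GeometryConfig pair of the comparison experiment.

    The control uses the default E16.5 idealized-root dimensions (aortic
    diameter 0.5 mm) with any ``geometry_overrides`` applied; the mutant is
    the control with the LCO displaced by (MUTANT_AXIAL_SHIFT,
    MUTANT_AZIMUTH_SHIFT_DEG). The pair differs only in LCO placement.
    """
    spec = spec or SyntheticSpec()
    control = GeometryConfig(**spec.geometry_overrides)
    mutant = displace_lco(control, MUTANT_AXIAL_SHIFT, MUTANT_AZIMUTH_SHIFT_DEG)
    return control, mutant


@dataclass(frozen=True)
class PoiseuilleBenchmark:
    """Closed-form laminar pipe flow driven by an end-to-end pressure drop."""

    radius: float
    length: float
    delta_p: float
    mu: float
    u_max: float
    Q: float
    wall_wss: float

    def profile(self, r):
        """Axial velocity u(r) = u_max (1 - (r/R)^2)."""
        r = np.asarray(r, dtype=float)
        return self.u_max * (1.0 - (r / self.radius) ** 2)


def poiseuille_fixture(radius: float, length: float, delta_p: float,
                       mu: float) -> PoiseuilleBenchmark:
    """Analytic Hagen-Poiseuille record:

    u_max = dp R^2 / (4 mu L),  Q = pi dp R^4 / (8 mu L),
    wall WSS = dp R / (2 L).
    """
    if radius <= 0 or length <= 0 or mu <= 0:
        raise ValidationError("radius, length and mu must be > 0")
    if delta_p < 0:
        raise ValidationError("delta_p must be >= 0")
    return PoiseuilleBenchmark(
        radius=radius, length=length, delta_p=delta_p, mu=mu,
        u_max=delta_p * radius**2 / (4.0 * mu * length),
        Q=np.pi * delta_p * radius**4 / (8.0 * mu * length),
        wall_wss=delta_p * radius / (2.0 * length),
    )
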