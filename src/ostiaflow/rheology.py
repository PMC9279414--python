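"""Blood rheology: the Carreau shear-thinning law, scalar shear rate, and
least-squares fitting of the law to viscometry tables.

The effective viscosity follows the Carreau model

    mu_eff(gamma_dot) = mu_inf + (mu0 - mu_inf) * (1 + (lam*gamma_dot)**a)**((n-1)/a)

which interpolates between a zero-shear asymptote ``mu0`` and an
infinite-shear asymptote ``mu_inf`` with power-law behaviour in between.
The scalar shear rate is defined from the strain-rate tensor E (symmetric
part of the velocity gradient) as

    gamma_dot = sqrt(E:E)

Note this is a factor sqrt(2) smaller than the sqrt(2 E:E) convention common
elsewhere in the hemodynamics literature; an opt-in flag selects the latter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ParameterError, ValidationError

__all__ = [
    "CarreauParams",
    "NewtonianParams",
    "ViscositySample",
    "shear_rate",
    "carreau_viscosity",
    "effective_viscosity",
    "fit_carreau",
]

#: Default constants paired with the adult-mouse asymptotic viscosities.
#: mu0 and mu_inf come from a least-squares fit to adult-mouse viscometry;
#: lam, n and a are standard blood-Carreau constants (the relaxation time and
#: power-law exponent of human-blood fits), exposed for override.
DEFAULT_MU0 = 1.38e-2
DEFAULT_MU_INF = 3.03e-3
DEFAULT_LAM = 3.313
DEFAULT_N = 0.3568
DEFAULT_A = 2.0

#: Constant viscosity of the Newtonian comparison mode (Pa.s).
NEWTONIAN_MU = 4.0e-3


@dataclass(frozen=True)
class CarreauParams:
    """Carreau-law constants.

    mu0
        zero-shear viscosity asymptote (Pa.s).
    mu_inf
        infinite-shear viscosity asymptote (Pa.s).
    lam
        relaxation time lambda (s); sets the shear rate where thinning begins.
    n
        power-law exponent (dimensionless, n < 1 is shear-thinning).
    a
        smoothing parameter controlling the sharpness of the transition.
    """

    mu0: float = DEFAULT_MU0
    mu_inf: float = DEFAULT_MU_INF
    lam: float = DEFAULT_LAM
    n: float = DEFAULT_N
    a: float = DEFAULT_A

    def __post_init__(self):
        if not (self.mu_inf > 0 and self.mu0 >= self.mu_inf):
            raise ParameterError(
                f"require mu0 >= mu_inf > 0, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if self.lam < 0:
            raise ParameterError(f"relaxation time lam must be >= 0, got {self.lam}")
        if self.a <= 0:
            raise ParameterError(f"smoothing parameter a must be > 0, got {self.a}")

    def viscosity(self, gamma_dot):
        return carreau_viscosity(gamma_dot, self)


@dataclass(frozen=True)
class NewtonianParams:
    """Constant-viscosity model used for the Newtonian comparison runs."""

    mu: float = NEWTONIAN_MU

    def __post_init__(self):
        if self.mu <= 0:
            raise ParameterError(f"viscosity must be > 0, got {self.mu}")

    def viscosity(self, gamma_dot):
        return np.broadcast_arrays(np.asarray(gamma_dot, dtype=float), self.mu)[1].copy()


@dataclass(frozen=True)
class ViscositySample:
    """One viscometry measurement: shear rate (1/s) and viscosity (Pa.s)."""

    shear_rate: float
    viscosity: float

    def __post_init__(self):
        if self.shear_rate < 0:
            raise ValidationError(f"shear_rate must be >= 0, got {self.shear_rate}")
        if self.viscosity <= 0:
            raise ValidationError(f"viscosity must be > 0, got {self.viscosity}")


def shear_rate(velocity_gradient, *, convention: str = "frobenius"):
    """Scalar shear rate from a 3x3 velocity-gradient tensor G (or a stack).

    With E = (G + G^T)/2, returns sqrt(E:E) (``convention="frobenius"``, the
    default) or sqrt(2 E:E) (``convention="doubled"``).
    """
    G = np.asarray(velocity_gradient, dtype=float)
    if G.shape[-2:] != (3, 3):
        raise ValidationError(f"velocity gradient must be (...,3,3), got {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValidationError("velocity gradient contains non-finite entries")
    E = 0.5 * (G + np.swapaxes(G, -1, -2))
    ee = np.einsum("...ij,...ij->...", E, E)
    if convention == "frobenius":
        return np.sqrt(ee)
    if convention == "doubled":
        return np.sqrt(2.0 * ee)
    raise ValidationError(f"unknown shear-rate convention {convention!r}")


def carreau_viscosity(gamma_dot, params: CarreauParams):
    """Evaluate the Carreau law at shear rate(s) ``gamma_dot`` (1/s)."""
    if not isinstance(params, CarreauParams):
        raise ParameterError("params must be a CarreauParams instance")
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValidationError("shear rate must be >= 0")
    x = (params.lam * g) ** params.a
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (1.0 + x) ** (
        (params.n - 1.0) / params.a
    )
    return mu if mu.ndim else float(mu)


def effective_viscosity(gamma_dot, model):
    """Dispatch on the rheology model (CarreauParams or NewtonianParams)."""
    return model.viscosity(gamma_dot)


_FIT_FIELDS = ("mu0", "mu_inf", "lam", "n", "a")
_FIT_BOUNDS = {
    "mu0": (1e-6, 1.0),
    "mu_inf": (1e-6, 1.0),
    "lam": (1e-6, 1e3),
    "n": (1e-3, 1.5),
    "a": (1e-2, 10.0),
}


def fit_carreau(
    samples: Sequence[ViscositySample],
    init: CarreauParams | None = None,
    fixed: Iterable[str] = (),
):
    """Fit Carreau constants to viscometry samples by least squares.

    The residual is taken in log-viscosity space because samples typically
    span several decades of shear rate and relative (not absolute) error is
    what viscometry controls. Parameters named in ``fixed`` are held at their
    ``init`` values. Returns ``(params, residual_sum_of_squares)`` where the
    residual is in the (linear) viscosity variable.
    """
    samples = list(samples)
    if len(samples) < 5:
        raise ValidationError(f"need >= 5 samples for a Carreau fit, got {len(samples)}")
    g = np.array([s.shear_rate for s in samples], dtype=float)
    mu = np.array([s.viscosity for s in samples], dtype=float)
    pos = g[g > 0]
    if pos.size and np.log10(pos.max() / pos.min()) < 2.0:
        import warnings

        warnings.warn(
            "viscosity samples span < 2 decades of shear rate; "
            "the Carreau fit may be ill-posed",
            stacklevel=2,
        )
    init = init or CarreauParams()
    fixed = set(fixed)
    unknown = fixed - set(_FIT_FIELDS)
    if unknown:
        raise ValidationError(f"unknown parameter names in 'fixed': {sorted(unknown)}")
    free = [f for f in _FIT_FIELDS if f not in fixed]
    if not free:
        raise ValidationError("all parameters fixed; nothing to fit")

    def unpack(theta):
        vals = {f: getattr(init, f) for f in _FIT_FIELDS}
        vals.update(dict(zip(free, theta)))
        return vals

    def resid(theta):
        v = unpack(theta)
        x = (v["lam"] * g) ** v["a"]
        model = v["mu_inf"] + (v["mu0"] - v["mu_inf"]) * (1.0 + x) ** (
            (v["n"] - 1.0) / v["a"]
        )
        return np.log(np.maximum(model, 1e-300)) - np.log(mu)

    theta0 = np.array([getattr(init, f) for f in free])
    lo = np.array([_FIT_BOUNDS[f][0] for f in free])
    hi = np.array([_FIT_BOUNDS[f][1] for f in free])
    theta0 = np.clip(theta0, lo, hi)
    sol = least_squares(resid, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(
            f"Carreau fit did not converge: {sol.message}",
            residual=float(np.sum(sol.fun**2)),
            params=unpack(sol.x),
        )
    vals = unpack(sol.x)
    # mu0 >= mu_inf is a CarreauParams invariant; a degenerate (Newtonian)
    # table can land epsilon on the wrong side of it.
    if vals["mu0"] < vals["mu_inf"]:
        vals["mu0"], vals["mu_inf"] = vals["mu_inf"], vals["mu0"]
    fitted = CarreauParams(**vals)
    rss = float(np.sum((carreau_viscosity(g, fitted) - mu) ** 2))
    return fitted, rss
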