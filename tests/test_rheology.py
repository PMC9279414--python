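"""Carreau law, scalar shear rate, and viscometry fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ostiaflow.errors import ParameterError, ValidationError
from ostiaflow.rheology import (CarreauParams, NewtonianParams,
                                ViscositySample, carreau_viscosity,
                                fit_carreau, shear_rate)
from ostiaflow.synthetic_data import SyntheticSpec, generate_viscosity_samples

# Carreau law with the default (adult-mouse asymptote) constants at
# gamma_dot = 10 1/s, evaluated with arbitrary-precision arithmetic.
CARREAU_AT_10 = 4.1631361209520057e-3


class TestShearRate:
    def test_uniform_flow_has_zero_shear(self):
        assert shear_rate(np.zeros((3, 3))) == 0.0

    def test_rigid_rotation_has_zero_shear(self):
        # antisymmetric gradient: strain-rate tensor vanishes
        W = np.array([[0.0, 2.0, -1.0], [-2.0, 0.0, 0.5], [1.0, -0.5, 0.0]])
        assert shear_rate(W) == pytest.approx(0.0, abs=1e-15)

    def test_simple_shear_frobenius_convention(self):
        # u = (gamma*y, 0, 0), gamma = 1: sqrt(E:E) = 1/sqrt(2)
        G = np.zeros((3, 3))
        G[0, 1] = 1.0
        assert shear_rate(G) == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-14)
        assert shear_rate(G, convention="doubled") == pytest.approx(1.0, rel=1e-14)

    def test_non_finite_entries_rejected(self):
        G = np.full((3, 3), np.nan)
        with pytest.raises(ValidationError):
            shear_rate(G)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=9, max_size=9))
    def test_nonnegative_and_transpose_invariant(self, entries):
        G = np.array(entries).reshape(3, 3)
        gd = shear_rate(G)
        assert gd >= 0.0
        assert gd == pytest.approx(shear_rate(G.T), rel=1e-12, abs=1e-12)


class TestCarreauViscosity:
    def test_zero_shear_gives_mu0_exactly(self):
        p = CarreauParams()
        assert carreau_viscosity(0.0, p) == p.mu0

    def test_zero_relaxation_time_is_constant(self):
        p = CarreauParams(lam=0.0)
        g = np.logspace(-2, 6, 30)
        assert np.allclose(carreau_viscosity(g, p), p.mu0, rtol=1e-14)

    def test_printed_asymptotes_at_gamma_10(self):
        p = CarreauParams(mu0=1.38e-2, mu_inf=3.03e-3, lam=3.313, n=0.3568, a=2.0)
        assert carreau_viscosity(10.0, p) == pytest.approx(CARREAU_AT_10, rel=1e-12)

    def test_monotone_nonincreasing_for_thinning_exponent(self):
        p = CarreauParams()
        mu = carreau_viscosity(np.logspace(-3, 7, 200), p)
        assert np.all(np.diff(mu) <= 1e-18)

    def test_bounds_and_infinite_shear_limit(self):
        p = CarreauParams()
        mu = carreau_viscosity(np.logspace(-3, 9, 100), p)
        assert np.all(mu <= p.mu0) and np.all(mu >= p.mu_inf)
        # residual gap above mu_inf at 1e9 1/s is 2.6e-6 relative for the
        # default constants
        assert carreau_viscosity(1e9, p) == pytest.approx(p.mu_inf, rel=5e-6)

    @pytest.mark.parametrize("bad", [
        dict(mu0=1e-3, mu_inf=2e-3),      # mu0 < mu_inf
        dict(mu_inf=-1e-3),
        dict(lam=-1.0),
        dict(a=0.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            CarreauParams(**bad)

    def test_newtonian_model_is_constant(self):
        m = NewtonianParams(4e-3)
        assert np.allclose(m.viscosity(np.logspace(-2, 5, 20)), 4e-3)


class TestFitCarreau:
    INIT = CarreauParams(mu0=1.9e-2, mu_inf=2.2e-3, lam=5.0, n=0.5, a=2.0)

    def test_noiseless_recovery_and_residual(self):
        truth = CarreauParams()
        samples = generate_viscosity_samples(
            truth, SyntheticSpec(noise_sd=0.0, n_samples=50))
        fitted, rss = fit_carreau(samples, self.INIT, fixed=("a",))
        for name in ("mu0", "mu_inf", "lam", "n"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(truth, name), rel=1e-3), name
        mu = np.array([s.viscosity for s in samples])
        assert rss / np.sum(mu**2) < 1e-12

    def test_newtonian_degenerate_table(self):
        g = np.logspace(-1, 3, 40)
        samples = [ViscositySample(float(x), 4e-3) for x in g]
        fitted, _ = fit_carreau(samples, self.INIT, fixed=("a",))
        assert fitted.mu0 == pytest.approx(4e-3, rel=1e-2)
        assert fitted.mu_inf == pytest.approx(4e-3, rel=1e-2)

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_recovery_of_mu0(self, seed):
        truth = CarreauParams()
        samples = generate_viscosity_samples(
            truth, SyntheticSpec(seed=seed, noise_sd=0.05, n_samples=500))
        fitted, _ = fit_carreau(samples, self.INIT, fixed=("a",))
        assert fitted.mu0 == pytest.approx(truth.mu0, rel=0.05)

    def test_too_few_samples_rejected(self):
        samples = [ViscositySample(1.0, 4e-3)] * 4
        with pytest.raises(ValidationError):
            fit_carreau(samples)

    def test_narrow_span_warns(self):
        g = np.linspace(10.0, 20.0, 10)
        truth = CarreauParams()
        samples = [ViscositySample(float(x), float(carreau_viscosity(x, truth)))
                   for x in g]
        from ostiaflow.errors import FitError
        with pytest.warns(UserWarning, match="decades"):
            try:
                fit_carreau(samples, self.INIT, fixed=("a",))
            except FitError:
                pass      # narrow span may legitimately fail to converge
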