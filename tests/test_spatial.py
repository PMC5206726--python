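"""EGF point-source fields and the ring-reduced reaction-diffusion model."""

import math

import numpy as np
import pytest

from mapkosc import StimulationProtocol, simulate
from mapkosc.spatial import (
    EGFField,
    EGFSourceEvent,
    SpatialConfig,
    point_source_concentration,
    sample_sources,
    simulate_spatial,
)


class TestGreensFunction:
    D, GAMMA, A = 600.0, 0.06, 1000.0     # um^2/min, 1/min, molecules/min

    def test_long_time_limit_is_screened_coulomb(self):
        """t -> inf gives the steady diffusion-degradation profile."""
        r = np.array([2.0, 5.0, 20.0, 50.0])
        lam = math.sqrt(self.GAMMA / self.D)
        expected = self.A * np.exp(-lam * r) / (4 * math.pi * self.D * r)
        got = point_source_concentration(r, 1e9, self.D, self.GAMMA, self.A)
        assert np.allclose(got, expected, rtol=1e-10)

    def test_zero_degradation_limit(self):
        from scipy.special import erfc
        r, t = np.array([1.0, 10.0, 30.0]), 7.0
        expected = (self.A / (4 * math.pi * self.D * r)
                    * erfc(r / math.sqrt(4 * self.D * t)))
        got = point_source_concentration(r, t, self.D, 0.0, self.A)
        assert np.allclose(got, expected, rtol=1e-12)

    def test_before_onset_and_singular_origin(self):
        assert point_source_concentration(5.0, -1.0, self.D, self.GAMMA,
                                          self.A) == 0.0
        with pytest.raises(ValueError, match="singular"):
            point_source_concentration(0.0, 1.0, self.D, self.GAMMA, self.A)

    def test_matches_radial_finite_difference_solution(self):
        """Brute-force FV solution of dc/dt = D lap(c) - g c, point source."""
        dr, r_max = 0.25, 150.0
        r = (np.arange(int(r_max / dr)) + 0.5) * dr
        faces = np.arange(int(r_max / dr) + 1) * dr
        vol = 4.0 / 3.0 * math.pi * (faces[1:] ** 3 - faces[:-1] ** 3)
        area = 4.0 * math.pi * faces**2
        c = np.zeros_like(r)
        dt = 0.2 * dr * dr / self.D
        t_probe = 5.0
        n_steps = int(round(t_probe / dt))
        dt = t_probe / n_steps
        for _ in range(n_steps):
            flux = np.zeros_like(faces)
            flux[1:-1] = -self.D * (c[1:] - c[:-1]) / dr * area[1:-1]
            dc = (-np.diff(flux)) / vol - self.GAMMA * c
            dc[0] += self.A / vol[0]
            c = c + dt * dc
        mask = (r > 1.0) & (r < 50.0)
        exact = point_source_concentration(r[mask], t_probe, self.D,
                                           self.GAMMA, self.A)
        rel = np.abs(c[mask] - exact) / exact.max()
        assert rel.max() < 0.01

    def test_finite_duration_source_switches_off(self):
        ev = EGFSourceEvent((0.0, 0.0, 12.0), t_start=1.0, duration=3.0,
                            intensity=self.A)
        field = EGFField(events=[ev], D=self.D, gamma=self.GAMMA)
        x = (0.0, 0.0, 2.0)
        during = field.concentration(x, 3.5)
        after = field.concentration(x, 60.0)
        assert during > 0
        assert after < 0.05 * during

    def test_field_additivity(self):
        e1 = EGFSourceEvent((0.0, 0.0, 15.0), 0.0, 10.0, self.A)
        e2 = EGFSourceEvent((12.0, 0.0, 0.0), 2.0, 5.0, 2 * self.A)
        both = EGFField(events=[e1, e2], D=self.D, gamma=self.GAMMA)
        f1 = EGFField(events=[e1], D=self.D, gamma=self.GAMMA)
        f2 = EGFField(events=[e2], D=self.D, gamma=self.GAMMA)
        x, t = (3.0, 4.0, 5.0), 6.0
        assert both.concentration(x, t) == pytest.approx(
            f1.concentration(x, t) + f2.concentration(x, t), rel=1e-12)


class TestSampleSources:
    def test_positions_inside_shell_and_seeded(self):
        events = sample_sources(0.2, 0.1, 1000.0, 0.5, r_cell=10.0,
                                r_shell_out=50.0, t_end=500.0, seed=5)
        again = sample_sources(0.2, 0.1, 1000.0, 0.5, r_cell=10.0,
                               r_shell_out=50.0, t_end=500.0, seed=5)
        assert [e.position for e in events] == [e.position for e in again]
        for e in events:
            assert 10.0 < np.linalg.norm(e.position) <= 50.0

    def test_poisson_event_count(self):
        rate, t_end = 0.5, 2000.0
        events = sample_sources(rate, 0.1, 1000.0, 0.5, 10.0, 50.0,
                                t_end, seed=11)
        n_expected = rate * t_end
        assert abs(len(events) - n_expected) < 3 * math.sqrt(n_expected)

    def test_lognormal_intensity_mean(self):
        events = sample_sources(5.0, 0.1, 2000.0, 0.5, 10.0, 50.0,
                                2000.0, seed=2)
        intensities = np.array([e.intensity for e in events])
        assert len(intensities) > 5000
        assert abs(intensities.mean() / 2000.0 - 1.0) < 0.05


class TestRingModel:
    def test_homogeneous_reduction_matches_ode(self, params):
        """Uniform field + uniform start: every node tracks the ODE."""
        cfg = SpatialConfig(n_nodes=12)
        dose = 20.0
        t_end = 30.0
        st = simulate_spatial(params, cfg, uniform_dose=dose, t_end=t_end,
                              dt_out=5.0)
        ode = simulate(params, StimulationProtocol.sustained(dose),
                       t_end=t_end, t_grid=st.t, rtol=1e-10, atol=1e-12)
        # nodes stay identical to each other...
        spread = np.max(st.y.max(axis=2) - st.y.min(axis=2))
        assert spread < 1e-12
        # ...and equal to the well-mixed solution
        err = np.max(np.abs(st.y[:, :, 0] - ode.y))
        assert err < 1e-6

    def test_diffusion_conserves_angular_totals(self, params):
        """Random initial field, no reactions: node sums are invariant."""
        from mapkosc import build_network
        from mapkosc.network import ReactionNetwork

        net = build_network(params)
        empty = ReactionNetwork(params=params, species=net.species,
                                reactions=[])
        cfg = SpatialConfig(n_nodes=16)
        rng = np.random.default_rng(0)
        x0 = rng.uniform(0.0, 1.0, (net.n_species, cfg.n_nodes))
        st = simulate_spatial(params, cfg, uniform_dose=0.0, t_end=2.0,
                              x0=x0, network=empty, dt_out=1.0)
        totals = st.y.sum(axis=2)
        assert np.allclose(totals, totals[0], rtol=1e-9, atol=1e-12)

    def test_grid_refinement_converges(self, params):
        """Halving the spacing barely moves the homogeneous solution."""
        sols = []
        for n in (8, 16):
            cfg = SpatialConfig(n_nodes=n)
            st = simulate_spatial(params, cfg, uniform_dose=50.0,
                                  t_end=20.0, dt_out=10.0)
            sols.append(st.active_erk_fraction[:, 0])
        assert np.max(np.abs(sols[0] - sols[1])) < 1e-8
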