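"""Exact SSA, bursty EGFR expression, hybrid populations."""

import math

import numpy as np
import pytest

from mapkosc import StimulationProtocol, build_network, simulate
from mapkosc.network import conserved_totals
from mapkosc.stochastic import (
    CellConfig,
    SSAOptions,
    draw_cell,
    hybrid_simulate,
    sample_burst_path,
    sample_population,
    ssa_simulate,
    telegraph_mean_egfr,
)


def _telegraph_master_equation_moments(cell: CellConfig, omega: float,
                                       n_max: int):
    """Independent oracle: stationary moments of the telegraph
    birth-death process from the truncated master equation."""
    lam_on, lam_off = cell.lam_interburst, cell.lam_burst
    birth = cell.a_burst * cell.alpha_cell * omega
    delta = math.log(2.0) / cell.tau_egfr
    n_states = 2 * (n_max + 1)

    def idx(b, n):
        return b * (n_max + 1) + n

    Q = np.zeros((n_states, n_states))
    for b in (0, 1):
        for n in range(n_max + 1):
            i = idx(b, n)
            sw = lam_on if b == 0 else lam_off
            Q[idx(1 - b, n), i] += sw
            Q[i, i] -= sw
            if b == 1 and n < n_max:
                Q[idx(b, n + 1), i] += birth
                Q[i, i] -= birth
            if n > 0:
                Q[idx(b, n - 1), i] += delta * n
                Q[i, i] -= delta * n
    # stationary distribution: null vector of Q
    w, v = np.linalg.eig(Q)
    pi = np.real(v[:, np.argmin(np.abs(w))])
    pi = np.abs(pi) / np.abs(pi).sum()
    ns = np.tile(np.arange(n_max + 1), 2)
    mean = float(pi @ ns)
    var = float(pi @ ns**2 - mean**2)
    return mean, var


@pytest.fixture(scope="module")
def quiet_params(params):
    """Dose 0 keeps the signaling network silent; only the EGFR
    expression processes fire."""
    return params


class TestFullSSA:
    def test_same_seed_bit_identical(self, quiet_params):
        cell = CellConfig(seed=3)
        opts = SSAOptions(omega=50.0, mode="full", seed=9, dt_out=10.0)
        a = ssa_simulate(quiet_params, cell, dose=0.0, t_end=200.0,
                         opts=opts)
        b = ssa_simulate(quiet_params, cell, dose=0.0, t_end=200.0,
                         opts=opts)
        assert np.array_equal(a.y, b.y)

    def test_no_synthesis_egfr_never_increases(self, quiet_params):
        cell = CellConfig(a_burst=0.0, seed=1)
        opts = SSAOptions(omega=100.0, mode="full", seed=4, dt_out=5.0)
        traj = ssa_simulate(quiet_params, cell, dose=0.0, t_end=600.0,
                            opts=opts)
        egfr = traj.species("EGFR")
        assert np.all(np.diff(egfr) <= 0)

    def test_non_receptor_groups_conserved_exactly(self, quiet_params):
        cell = CellConfig(seed=2)
        opts = SSAOptions(omega=100.0, mode="full", seed=5, dt_out=20.0)
        traj = ssa_simulate(quiet_params, cell, dose=5.0, t_end=300.0,
                            opts=opts)
        totals = conserved_totals(traj.network, traj.y)
        for group, series in totals.items():
            if group == "EGFR":
                continue
            assert np.all(series == series[0]), group

    def test_bursty_egfr_matches_master_equation_moments(self, quiet_params):
        """Long-run SSA occupation statistics vs the truncated
        master-equation stationary distribution."""
        omega = 30.0
        cell = CellConfig(lam_interburst=1 / 60.0, lam_burst=1 / 20.0,
                          a_burst=0.02, tau_egfr=120.0, seed=0)
        mean_th, var_th = _telegraph_master_equation_moments(
            cell, omega, n_max=150)
        # analytic mean of the birth-death-telegraph process as cross-check
        assert telegraph_mean_egfr(cell) * omega == pytest.approx(
            mean_th, rel=0.01)
        opts = SSAOptions(omega=omega, mode="full", seed=12, dt_out=2.0)
        traj = ssa_simulate(quiet_params, cell, dose=0.0, t_end=30000.0,
                            opts=opts)
        egfr = traj.species("EGFR")[traj.t > 2000.0]
        # ~75 correlation times (tau_corr ~ 1/delta ~ 175 min)
        n_eff = len(egfr) * 2.0 / 175.0
        se_mean = math.sqrt(var_th / n_eff)
        assert abs(egfr.mean() - mean_th) < 4 * se_mean
        assert abs(egfr.var() - var_th) / var_th < 0.25

    def test_large_omega_tracks_ode(self, quiet_params):
        """Thermodynamic limit: one SSA path at omega = 10^4 with a fixed
        receptor pool follows the deterministic trajectory."""
        dose = 50.0
        omega = 1e5   # ignition-front timing jitter dominates below this
        opts = SSAOptions(omega=omega, mode="full", seed=21, dt_out=1.0)
        traj = ssa_simulate(quiet_params, None, dose=dose, t_end=60.0,
                            opts=opts)
        ode = simulate(quiet_params, StimulationProtocol.sustained(dose),
                       t_end=60.0, t_grid=traj.t)
        frac_ssa = traj.species("ERK_pp") / (quiet_params.ERK_tot * omega)
        err = np.max(np.abs(frac_ssa - ode.active_erk_fraction))
        assert err < 0.05


class TestHybrid:
    def test_receptor_path_is_dose_independent(self, params):
        cell = CellConfig(seed=8)
        rng = np.random.default_rng(55)
        path = sample_burst_path(cell, 400.0, rng)
        net = build_network(params)
        ix = [net.index[s] for s in ("EGFR", "EGFR_a", "C0", "CD", "CT")]
        totals = []
        for dose in (2.0, 50.0):
            traj = hybrid_simulate(params, cell, dose, 400.0,
                                   burst_path=path, network=net)
            totals.append(traj.y[:, ix].sum(axis=1))
        assert np.max(np.abs(totals[0] - totals[1])) < 1e-4

    def test_freezing_receptor_path_suppresses_variance(self, params):
        """Hybrid mode is deterministic given the burst path: replicate
        runs with identical paths coincide."""
        cell = CellConfig(seed=4)
        rng = np.random.default_rng(7)
        path = sample_burst_path(cell, 300.0, rng)
        a = hybrid_simulate(params, cell, 10.0, 300.0, burst_path=path)
        b = hybrid_simulate(params, cell, 10.0, 300.0, burst_path=path)
        assert np.array_equal(a.y, b.y)


class TestPopulation:
    def test_seeded_population_reproducible(self, params):
        kw = dict(n_cells=2, doses=[2.0], t_end=200.0, seed=13)
        a = sample_population(params, **kw)
        b = sample_population(params, **kw)
        assert np.array_equal(a.activity, b.activity)
        assert [c.alpha_cell for c in a.cells] == \
               [c.alpha_cell for c in b.cells]

    def test_alpha_lognormal_mean_one(self):
        rng = np.random.default_rng(3)
        alphas = [draw_cell(rng).alpha_cell for _ in range(4000)]
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.02)

    def test_activity_increases_with_dose(self, params):
        """Mean ERK-active time fraction rises across the dose panel."""
        pop = sample_population(params, n_cells=6,
                                doses=[2.0, 10.0, 200.0],
                                t_end=900.0, seed=17)
        frac = pop.active_fraction_of_time().mean(axis=1)
        assert frac[0] <= frac[1] <= frac[2]
        assert frac[2] > frac[0]

    def test_subthreshold_dose_gives_intermittent_bursts(self, params):
        """Below the deterministic onset some cells still fire, driven by
        receptor-abundance fluctuations, but activity stays intermittent."""
        pop = sample_population(params, n_cells=8, doses=[2.0],
                                t_end=1200.0, seed=29,
                                cell_kwargs={})
        frac = pop.active_fraction_of_time()[0]
        assert frac.max() > 0.0         # somebody fires
        assert frac.mean() < 0.5        # but the population is mostly off
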