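"""Steady-state location, folds, clamped-complex analysis, regimes."""

import numpy as np
import pytest

from mapkosc import StimulationProtocol, simulate
from mapkosc.bifurcation import (
    clamp_complex_variant,
    classify_regime,
    find_folds,
    find_steady_states,
    hysteresis_scan,
    regime_map_2d,
    scan_steady_states,
    site_count_scan,
)
from mapkosc.network import resting_state


class TestFindSteadyStates:
    def test_no_input_gives_unique_resting_state(self, params):
        ss = find_steady_states(params, dose=0.0, n_starts=10, seed=0)
        assert len(ss) == 1
        assert ss.states[0].stable
        x_rest = resting_state(ss.network)
        assert np.max(np.abs(ss.states[0].state - x_rest)) < 1e-8

    # a clamped complex level inside the bistable window (in SOS_tot units)
    BISTABLE_LEVEL = 0.09

    def test_states_satisfy_rhs_tolerance(self, nf_free_params):
        clamped = clamp_complex_variant(
            nf_free_params, self.BISTABLE_LEVEL * nf_free_params.SOS_tot)
        ss = find_steady_states(clamped=clamped, n_starts=12, seed=1)
        assert len(ss) == 3 and ss.n_stable == 2
        for s in ss.states:
            resid = clamped.network.rhs(s.state, 0.0)
            assert np.linalg.norm(resid, ord=np.inf) < 1e-9

    def test_stable_states_attract_unstable_repel(self, nf_free_params):
        clamped = clamp_complex_variant(
            nf_free_params, self.BISTABLE_LEVEL * nf_free_params.SOS_tot)
        ss = find_steady_states(clamped=clamped, n_starts=12, seed=2)
        for s in ss.states:
            x0 = s.state * 1.0002 + 1e-7
            traj = simulate(nf_free_params, StimulationProtocol.sustained(0),
                            t_end=800.0, x0=x0, network=clamped.network,
                            check=False)
            drift = np.max(np.abs(traj.y[-1] - s.state))
            if s.stable:
                assert drift < 2e-3     # stays on the perturbed manifold
            else:
                assert drift > 0.05     # saddle: leaves along the unstable mode

    def test_too_few_starts_rejected(self, params):
        with pytest.raises(ValueError):
            find_steady_states(params, dose=0.0, n_starts=1)


class TestClampedComplex:
    def test_zero_level_is_resting(self, nf_free_params):
        clamped = clamp_complex_variant(nf_free_params, 0.0)
        ss = find_steady_states(clamped=clamped, n_starts=8, seed=0)
        assert len(ss) == 1
        assert ss.erk_fractions()[0] < 1e-6

    def test_level_above_sos_total_rejected(self, nf_free_params):
        with pytest.raises(ValueError):
            clamp_complex_variant(nf_free_params,
                                  1.1 * nf_free_params.SOS_tot)

    def test_requires_feedback_free_configuration(self, params):
        with pytest.raises(ValueError, match="f_nf1"):
            clamp_complex_variant(params, 0.01)

    def test_s_shaped_branch_with_two_folds(self, nf_free_params):
        """Scanning the clamped complex level shows bistability between
        two saddle-node points (the relaxation oscillator's backbone)."""
        sos = nf_free_params.SOS_tot
        levels = np.geomspace(1e-3 * sos, 0.9 * sos, 21)
        diagram = scan_steady_states(nf_free_params, "complex", levels,
                                     n_starts=14, seed=3)
        assert diagram.counts.max() == 3
        inside = diagram.counts == 3
        assert np.all(diagram.stable_counts[inside] == 2)
        assert np.all(diagram.counts[~inside] == 1)
        folds = find_folds(diagram, nf_free_params, n_starts=14)
        assert len(folds) == 2
        sn1, sn2 = folds
        assert 0 < sn1 < sn2 < sos

    def test_gef_symmetry_destroys_folds(self, nf_free_params):
        """With k2C = k2B = k2A (no REM-occupancy asymmetry) the branch
        is single-valued: no saddle-nodes."""
        p = nf_free_params.replace(k2B=nf_free_params.k2A,
                                   k2C=nf_free_params.k2A)
        sos = p.SOS_tot
        levels = np.geomspace(1e-3 * sos, 0.9 * sos, 13)
        diagram = scan_steady_states(p, "complex", levels, n_starts=10,
                                     seed=4)
        assert diagram.counts.max() == 1
        assert find_folds(diagram, p, n_starts=10) == ()

    def test_weaker_gap_saturation_narrows_then_kills_window(
            self, nf_free_params):
        """Raising the product-release rate u3 makes RasGAP less
        saturable: the fold ratio SN2/SN1 shrinks and bistability is
        eventually lost."""
        sos = nf_free_params.SOS_tot
        levels = np.geomspace(2e-3 * sos, 0.9 * sos, 13)

        def fold_ratio(p):
            d = scan_steady_states(p, "complex", levels, n_starts=8, seed=5)
            folds = find_folds(d, p, n_starts=8, rel_tol=0.01)
            return folds[-1] / folds[0] if len(folds) >= 2 else 1.0

        r_default = fold_ratio(nf_free_params)
        r_weak = fold_ratio(nf_free_params.replace(
            u3=4 * nf_free_params.u3))
        r_gone = fold_ratio(nf_free_params.replace(
            u3=16 * nf_free_params.u3))
        assert r_default > r_weak > r_gone == 1.0


class TestHysteresis:
    def test_up_down_scan_disagrees_inside_window(self, nf_free_params):
        lo, hi = 0.2, 50.0
        doses = np.geomspace(lo, hi, 12)
        up, down = hysteresis_scan(nf_free_params, doses)
        assert np.max(np.abs(up - down)) > 0.3   # bistable window crossed
        # end points agree: monostable on both ends
        assert abs(up[-1] - down[-1]) < 0.02


class TestClassifyRegime:
    def test_no_input_is_monostable_off(self, params):
        assert classify_regime(params, 0.0, t_end=1200.0,
                               transient_discard=300.0) == "monostable-off"

    def test_oscillatory_at_reference_dose(self, params):
        assert classify_regime(params, 10.0) == "oscillatory"

    def test_no_sos_feedback_means_no_oscillations(self, params):
        """With the ERK-to-SOS loop cut, only bistable switching remains."""
        p = params.replace(f_nf1=0.0)
        for dose in (1.0, 5.0, 25.0, 250.0):
            label = classify_regime(p, dose)
            assert label != "oscillatory", dose

    def test_regime_map_consistent_with_1d(self, params):
        doses = [0.5, 10.0]
        rm = regime_map_2d(params, doses, "f_nf1", [1.0], t_end=1500.0)
        for j, d in enumerate(doses):
            assert rm.labels[0, j] == classify_regime(params, d,
                                                      t_end=1500.0)


class TestSiteCount:
    def test_flags_and_q1_held_per_site(self, params):
        doses = [5.0, 10.0, 40.0]
        flags = site_count_scan(params, site_counts=(1, 4), doses=doses)
        assert flags[4] is True
        assert flags[1] is False
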