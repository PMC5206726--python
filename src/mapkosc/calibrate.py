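"""Staged calibration of the default parameter set.

The network's structural constraints (zero GEF activity with an empty
REM site, ten-fold lower activity with RAS-GDP than with RAS-GTP bound,
four phosphorylatable SOS sites) are fixed a priori; the remaining
degrees of freedom were selected to produce target qualitative
behaviors, mirroring how the model's behavior decomposes:

1. positive-feedback stage: the RAS/SOS/RasGAP module must be bistable
   over a window of clamped receptor-complex levels;
2. cascade-timing stage: RAF/MEK/ERK rates give full ERK activation
   within ~5-10 minutes of threshold crossing;
3. negative-feedback stage: the ERK-to-SOS rates (q1, d1) give a limit
   cycle with a period above one hour and an oscillatory dose range of
   roughly two decades;
4. input-gain stage: ``egf_gain`` is rescaled so the sustained-
   stimulation critical dose equals the anchor (2.5 pg/ml).

Stages 1-3 verify (and, for stage 4, adjust) the shipped defaults;
the procedure is deterministic given the constraint list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bifurcation import (
    find_folds,
    oscillatory_dose_range,
    scan_steady_states,
)
from .deterministic import critical_dose, detect_pulse, oscillation_metrics, simulate
from .params import ParameterSet
from .protocols import StimulationProtocol

__all__ = ["CalibrationConstraints", "CalibrationError", "calibrate_defaults"]


@dataclass(frozen=True)
class CalibrationConstraints:
    critical_dose_anchor: float = 2.5      # pg/ml, sustained stimulation
    min_period: float = 60.0               # minutes, at the reference dose
    reference_dose_factor: float = 4.0     # reference dose = factor * anchor
    range_ratio_bounds: tuple[float, float] = (50.0, 200.0)
    activation_time_bounds: tuple[float, float] = (1.0, 15.0)  # minutes
    check_range: bool = True


class CalibrationError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"calibration stage {stage!r} failed: {message}")
        self.stage = stage


def _stage1_bistable(params: ParameterSet) -> None:
    pnf = params.without_negative_feedback()
    levels = np.geomspace(1e-4 * params.SOS_tot, 0.9 * params.SOS_tot, 15)
    diagram = scan_steady_states(pnf, "complex", levels, n_starts=8, seed=0)
    if diagram.counts.max() < 3:
        raise CalibrationError(
            "1:positive-feedback",
            "no clamped-complex level with three steady states; "
            "RasGAP saturation (b3, u3, RasGAP_tot) too weak")
    folds = find_folds(diagram, pnf, n_starts=8, rel_tol=0.01)
    if len(folds) < 2:
        raise CalibrationError(
            "1:positive-feedback", "fewer than two folds located")


def _stage2_cascade_timing(params: ParameterSet,
                           c: CalibrationConstraints) -> float:
    # step the dose well above threshold; time for ERK to reach half-max
    traj = simulate(params.without_negative_feedback(),
                    StimulationProtocol.sustained(
                        100.0 * c.critical_dose_anchor),
                    t_end=120.0)
    fired, t_half = detect_pulse(traj, theta=0.5)
    if not fired:
        raise CalibrationError(
            "2:cascade-timing", "saturating dose does not activate ERK")
    lo, hi = c.activation_time_bounds
    if not (lo <= t_half <= hi):
        raise CalibrationError(
            "2:cascade-timing",
            f"ERK half-activation at {t_half:.1f} min outside [{lo}, {hi}]")
    return t_half


def _stage3_oscillation(params: ParameterSet,
                        c: CalibrationConstraints,
                        d_crit: float) -> None:
    ref = c.reference_dose_factor * d_crit
    traj = simulate(params, StimulationProtocol.sustained(ref), t_end=3000.0)
    m = oscillation_metrics(traj)
    if not m.is_oscillatory:
        raise CalibrationError(
            "3:negative-feedback", f"no limit cycle at {ref:.2g} pg/ml")
    if m.period < c.min_period:
        raise CalibrationError(
            "3:negative-feedback",
            f"period {m.period:.0f} min below {c.min_period:.0f} min; "
            "slow SOS dephosphorylation (d1) further")
    if c.check_range:
        lo, hi = oscillatory_dose_range(params)
        ratio = hi / lo
        rlo, rhi = c.range_ratio_bounds
        if not (rlo <= ratio <= rhi):
            raise CalibrationError(
                "3:negative-feedback",
                f"oscillatory dose range {ratio:.0f}-fold outside "
                f"[{rlo:.0f}, {rhi:.0f}]; adjust q1 against d1")


def calibrate_defaults(
    params: ParameterSet | None = None,
    constraints: CalibrationConstraints | None = None,
    verbose: bool = False,
) -> ParameterSet:
    """Verify the staged behavioral constraints and anchor the input gain.

    Returns a parameter set whose sustained-stimulation critical dose
    equals the anchor exactly (to bisection tolerance); raises
    :class:`CalibrationError` naming the first stage whose constraint
    the candidate set cannot satisfy.
    """
    p = params if params is not None else ParameterSet()
    c = constraints if constraints is not None else CalibrationConstraints()
    if p.k2A <= 0 or abs(p.k2B / p.k2A - 0.1) > 1e-12:
        raise CalibrationError("0:structure", "requires k2B = 0.1 * k2A")
    if p.k2C != 0:
        raise CalibrationError("0:structure", "requires k2C = 0")

    _stage1_bistable(p)
    if verbose:
        print("stage 1 (positive feedback): bistable window located")
    t_half = _stage2_cascade_timing(p, c)
    if verbose:
        print(f"stage 2 (cascade timing): ERK half-activation {t_half:.1f} min")

    # stage 4 first pass: the critical dose scales exactly as 1/egf_gain,
    # so a single measurement fixes the gain
    d0 = critical_dose(p)
    if not math.isfinite(d0):
        raise CalibrationError("4:input-gain", "no sustained dose activates")
    p_anchored = p.replace(egf_gain=p.egf_gain * d0 / c.critical_dose_anchor)
    d_check = critical_dose(p_anchored)
    if abs(d_check - c.critical_dose_anchor) / c.critical_dose_anchor > 0.02:
        raise CalibrationError(
            "4:input-gain",
            f"anchored critical dose {d_check:.3g} != "
            f"{c.critical_dose_anchor}")
    if verbose:
        print(f"stage 4 (input gain): egf_gain -> {p_anchored.egf_gain:.4g}")

    _stage3_oscillation(p_anchored, c, c.critical_dose_anchor)
    if verbose:
        print("stage 3 (negative feedback): period and dose range verified")
    return p_anchored
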