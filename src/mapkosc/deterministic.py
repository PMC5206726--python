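"""Deterministic (well-mixed ODE) simulation and pulse/oscillation analysis.

The ODE system is stiff near the relaxation switches, so integration
uses LSODA with tight tolerances; the dose is piecewise constant and the
integrator is restarted at every protocol breakpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .network import ReactionNetwork, build_network, conserved_totals, resting_state
from .params import ParameterSet
from .protocols import StimulationProtocol

__all__ = [
    "Trajectory",
    "OscillationMetrics",
    "SimulationError",
    "simulate",
    "detect_pulse",
    "oscillation_metrics",
    "critical_dose",
    "critical_duration",
]

RTOL = 1e-8
ATOL = 1e-10
#: default threshold on the active-ERK fraction defining "high ERK activity"
PULSE_THRESHOLD = 0.5
#: transient discarded before oscillation metrics (minutes)
TRANSIENT_DISCARD = 600.0
#: horizon used when classifying long-term behavior (minutes)
CLASSIFY_T_END = 3000.0


class SimulationError(RuntimeError):
    """Integrator failure; carries the last time reached."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid time {t_last:g} min)")
        self.t_last = t_last


@dataclass
class Trajectory:
    """Time grid + state matrix + derived observables."""

    t: np.ndarray                  # (n_t,) minutes, strictly increasing
    y: np.ndarray                  # (n_t, n_species)
    network: ReactionNetwork
    protocol: Optional[StimulationProtocol] = None
    #: copy-number scale; 1.0 for concentration semantics, the SSA's
    #: system size when ``y`` holds integer counts
    omega: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def params(self) -> ParameterSet:
        return self.network.params

    def species(self, name: str) -> np.ndarray:
        return self.y[:, self.network.index[name]]

    @property
    def active_erk_fraction(self) -> np.ndarray:
        return self.species("ERK_pp") / (self.params.ERK_tot * self.omega)

    @property
    def complex_total(self) -> np.ndarray:
        """Level of activated-receptor-SOS complexes (all REM states)."""
        return self.species("C0") + self.species("CD") + self.species("CT")

    def reporter_fraction(self, rep: str) -> np.ndarray:
        return self.species(f"REP_{rep}_p") / (
            self.params.reporters[rep].total * self.omega)

    def conserved_totals(self):
        return conserved_totals(self.network, self.y)

    def check_conservation(self, rtol: float = 1e-8) -> None:
        targets = self.network.group_totals()
        for g, series in self.conserved_totals().items():
            ref = targets[g] * self.omega
            err = np.max(np.abs(series - ref)) / max(ref, 1e-300)
            if err > rtol:
                raise AssertionError(
                    f"conservation violated for {g}: rel err {err:.2e}")


@dataclass(frozen=True)
class OscillationMetrics:
    is_oscillatory: bool
    period: float                  # minutes; nan when not oscillatory
    amplitude: float               # peak-to-trough active-ERK fraction
    pulse_width: float             # minutes above threshold, per period
    duty_cycle: float
    n_peaks: int = 0
    period_cv: float = float("nan")


def simulate(
    params: ParameterSet,
    protocol: StimulationProtocol,
    t_end: float,
    t_grid: Optional[np.ndarray] = None,
    x0: Optional[np.ndarray] = None,
    network: Optional[ReactionNetwork] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    check: bool = True,
) -> Trajectory:
    """Integrate the network from rest (or ``x0``) under a protocol.

    The state is clipped to zero at the output stage (entries may
    undershoot by no more than the absolute tolerance); conservation is
    asserted on the result unless ``check=False``.
    """
    net = network if network is not None else build_network(params)
    f = net.compile_rhs()
    if t_grid is None:
        t_grid = np.linspace(0.0, t_end, max(int(t_end * 2), 200) + 1)
    t_grid = np.asarray(t_grid, dtype=float)
    x = np.array(resting_state(net) if x0 is None else x0, dtype=float)

    pieces_t: list[np.ndarray] = []
    pieces_y: list[np.ndarray] = []
    bps = protocol.breakpoints(t_end)
    for a, b in zip(bps[:-1], bps[1:]):
        dose = protocol.dose_at(a)
        mask = (t_grid >= a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([[a], t_grid[mask], [b]]))
        sol = solve_ivp(
            f, (a, b), x, t_eval=t_eval, args=(dose,),
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(sol.message, sol.t[-1] if sol.t.size else a)
        keep = mask & (t_grid < b) if b < t_end else mask
        sel = np.searchsorted(sol.t, t_grid[keep])
        pieces_t.append(t_grid[keep])
        pieces_y.append(sol.y[:, sel].T)
        x = sol.y[:, -1]

    t = np.concatenate(pieces_t)
    y = np.concatenate(pieces_y, axis=0)
    if y.min() < -1e-9:
        raise SimulationError(
            f"state went negative ({y.min():.2e})", float(t[-1]))
    y = np.clip(y, 0.0, None)
    traj = Trajectory(t=t, y=y, network=net, protocol=protocol)
    if check:
        traj.check_conservation(rtol=max(rtol * 100, 1e-8) * 10)
    return traj


def detect_pulse(
    traj: Trajectory, theta: float = PULSE_THRESHOLD
) -> tuple[bool, float]:
    """First upward crossing of the active-ERK fraction through ``theta``.

    Returns ``(fired, t_cross)`` with ``t_cross = nan`` when no pulse.
    """
    a = traj.active_erk_fraction
    above = a >= theta
    if not above.any():
        return False, float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return True, float(traj.t[0])
    # linear interpolation of the crossing time
    t0, t1 = traj.t[i - 1], traj.t[i]
    a0, a1 = a[i - 1], a[i]
    t_cross = t0 + (theta - a0) / (a1 - a0) * (t1 - t0)
    return True, float(t_cross)


def oscillation_metrics(
    traj: Trajectory,
    transient_discard: float = TRANSIENT_DISCARD,
    theta: float = PULSE_THRESHOLD,
    min_amplitude: float = 0.1,
    max_period_cv: float = 0.05,
) -> OscillationMetrics:
    """Period/amplitude/pulse-width of the post-transient active-ERK series.

    A trajectory counts as oscillatory when at least four peaks give at
    least three inter-peak intervals with coefficient of variation below
    5% and the peak-to-trough amplitude exceeds ``min_amplitude``.
    """
    mask = traj.t >= transient_discard
    if mask.sum() < 16:
        raise ValueError("trajectory too short after transient discard")
    t = traj.t[mask]
    a = traj.active_erk_fraction[mask]
    amp = float(a.max() - a.min())
    not_osc = OscillationMetrics(False, float("nan"), amp, 0.0, 0.0)
    if amp <= min_amplitude:
        return not_osc

    height = a.min() + theta * amp
    peaks, _ = find_peaks(a, height=height, prominence=0.25 * amp)
    if len(peaks) < 4:
        return not_osc
    periods = np.diff(t[peaks])
    cv = float(periods.std() / periods.mean())
    if cv >= max_period_cv:
        return OscillationMetrics(False, float("nan"), amp, 0.0, 0.0,
                                  n_peaks=len(peaks), period_cv=cv)
    period = float(periods.mean())
    # width above the absolute threshold, averaged per period
    above = a >= theta
    dt = np.diff(t, prepend=t[0])
    span = t[peaks[-1]] - t[peaks[0]]
    inner = (t >= t[peaks[0]]) & (t <= t[peaks[-1]])
    time_above = float(dt[inner & above].sum())
    width = time_above / max(len(peaks) - 1, 1)
    duty = min(max(time_above / span, 0.0), 1.0) if span > 0 else 0.0
    return OscillationMetrics(True, period, amp, width, duty,
                              n_peaks=len(peaks), period_cv=cv)


def _pulse_fires(
    params: ParameterSet,
    dose: float,
    duration: float,
    theta: float,
    t_end: float,
    network: Optional[ReactionNetwork] = None,
) -> bool:
    if math.isinf(duration):
        proto = StimulationProtocol.sustained(dose)
    else:
        proto = StimulationProtocol.pulse(dose, duration)
    traj = simulate(params, proto, t_end=t_end, network=network, check=False)
    return detect_pulse(traj, theta)[0]


def critical_dose(
    params: ParameterSet,
    duration: float = math.inf,
    theta: float = PULSE_THRESHOLD,
    rel_tol: float = 0.01,
    dose_lo: float = 0.1,
    dose_hi_cap: float = 1e5,
    t_end: Optional[float] = None,
) -> float:
    """Minimal EGF dose eliciting a full ERK pulse, by bisection.

    ``duration=inf`` probes sustained stimulation (simulated for 50 h);
    finite durations use a pulse-plus-washout protocol (5 h horizon).
    Returns ``inf`` if even ``dose_hi_cap`` does not trigger.
    """
    if t_end is None:
        t_end = CLASSIFY_T_END if math.isinf(duration) else 300.0
    net = build_network(params)

    def fires(d: float) -> bool:
        return _pulse_fires(params, d, duration, theta, t_end, net)

    lo = dose_lo
    while fires(lo):           # ensure lo is genuinely sub-threshold
        lo /= 4.0
        if lo < 1e-6:
            return lo
    hi = lo * 4.0
    while not fires(hi):
        lo = hi
        hi *= 4.0
        if hi > dose_hi_cap:
            return math.inf
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def critical_duration(
    params: ParameterSet,
    dose: float,
    theta: float = PULSE_THRESHOLD,
    tol: float = 1.0 / 60.0,
    duration_cap: float = 240.0,
    t_end: float = 300.0,
) -> float:
    """Minimal pulse duration (minutes) triggering a full ERK pulse.

    Bisection to ``tol`` (default 1 s); ``inf`` when no duration up to
    ``duration_cap`` triggers.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    net = build_network(params)

    def fires(dur: float) -> bool:
        return _pulse_fires(params, dose, dur, theta,
                            max(t_end, dur + 120.0), net)

    if not fires(duration_cap):
        return math.inf
    lo, hi = 0.0, duration_cap
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
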