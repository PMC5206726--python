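"""Steady states, folds, limit cycles and dynamical-regime classification.

Continuation is deliberately replaced by dense scans plus bisection:
steady-state branches are located by multi-start damped root finding on
the conservation manifold, saddle-node (fold) points by bisection on the
change in steady-state count, and oscillatory regions by simulation with
the limit-cycle detector.  Hopf points appear as oscillatory/monostable
boundary points without normal-form classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import least_squares, root

from .deterministic import (
    CLASSIFY_T_END,
    TRANSIENT_DISCARD,
    oscillation_metrics,
    simulate,
)
from .network import ReactionNetwork, build_network, resting_state
from .params import ParameterSet
from .protocols import StimulationProtocol

__all__ = [
    "SteadyState",
    "SteadyStateSet",
    "BifurcationDiagram",
    "RegimeMap",
    "ClampedSystem",
    "clamp_complex_variant",
    "find_steady_states",
    "scan_steady_states",
    "find_folds",
    "classify_regime",
    "regime_map_2d",
    "site_count_scan",
    "oscillatory_dose_range",
    "hysteresis_scan",
]

DEDUPE_TOL = 1e-6          # infinity-norm in normalized concentration
RESIDUAL_TOL = 1e-10
STABILITY_TOL = 1e-7


@dataclass(frozen=True)
class SteadyState:
    state: np.ndarray
    stable: bool
    leading_eig: float      # largest real part on the conservation manifold

    @property
    def erk_fraction(self) -> float:
        raise AttributeError("use SteadyStateSet.erk_fraction")


@dataclass
class SteadyStateSet:
    network: ReactionNetwork
    states: list[SteadyState]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_stable(self) -> int:
        return sum(s.stable for s in self.states)

    def erk_fractions(self) -> np.ndarray:
        i = self.network.index["ERK_pp"]
        tot = self.network.params.ERK_tot
        return np.array(sorted(s.state[i] / tot for s in self.states))


# ---------------------------------------------------------------------
# clamped-complex variant (receptor layer frozen)
# ---------------------------------------------------------------------

@dataclass
class ClampedSystem:
    """Network with the receptor-SOS binding layer frozen.

    The total level of activated-receptor-SOS complexes (all REM
    occupancy states) is a conserved quantity of the reduced reaction
    set and serves as the bifurcation parameter; REM-site exchange with
    the free RAS pools still equilibrates dynamically.
    """

    network: ReactionNetwork
    level: float

    _FROZEN = frozenset({"egfr_act", "egfr_deact", "c0_bind", "c0_unbind"})

    def initial_state(self, active: bool = False) -> np.ndarray:
        net = self.network
        p = net.params
        x = resting_state(net)
        ix = net.index
        x[ix["SOS_u"]] = p.SOS_tot - self.level
        x[ix["C0"]] = self.level
        if active:
            x[ix["RAS_GDP"]] = 0.1 * p.RAS_tot
            x[ix["RAS_GTP"]] = 0.9 * p.RAS_tot
            for a, b in (("RAF", "RAF_a"), ("MEK", "MEK_pp"), ("ERK", "ERK_pp")):
                x[ix[b]] = x[ix[a]]
                x[ix[a]] = 0.0
        return x


def clamp_complex_variant(params: ParameterSet, level: float) -> ClampedSystem:
    """Freeze receptor binding at a fixed total complex level.

    Requires the negative-feedback-free configuration (otherwise SOS
    phosphorylation would drain the clamped pool).
    """
    if level < 0 or level > params.SOS_tot:
        raise ValueError("clamped complex level must lie in [0, SOS_tot]")
    if params.f_nf1 != 0:
        raise ValueError(
            "clamped-complex analysis requires f_nf1 = 0 "
            "(the ERK-to-SOS feedback would unclamp the complex pool)")
    full = build_network(params)
    rxns = [r for r in full.reactions if r.name not in ClampedSystem._FROZEN]
    net = ReactionNetwork(params=params, species=full.species, reactions=rxns)
    return ClampedSystem(network=net, level=level)


# ---------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------

def _stoichiometric_invariants(net: ReactionNetwork) -> np.ndarray:
    """Complete basis of linear conservation laws, from the left null
    space of the stoichiometry matrix.

    For the full network this spans exactly the protein-group totals;
    for reduced variants (e.g. the clamped-complex system) it also
    captures the additional invariants created by freezing reactions,
    which the hardcoded groups would miss.
    """
    return null_space(net.stoich.T.astype(float)).T


def _pivot_rows(C: np.ndarray) -> np.ndarray:
    """One well-conditioned species row to replace per invariant."""
    from scipy.linalg import qr

    _, _, piv = qr(C, pivoting=True)
    return piv[: C.shape[0]]


def _reduced_jacobian(
    net: ReactionNetwork, x: np.ndarray, dose: float, C: np.ndarray
) -> np.ndarray:
    n = net.n_species
    f = net.compile_rhs()
    J = np.empty((n, n))
    h0 = 1e-7
    f0 = f(0.0, x, dose)
    for j in range(n):
        h = h0 * max(abs(x[j]), 1e-3)
        xp = x.copy()
        xp[j] += h
        J[:, j] = (f(0.0, xp, dose) - f0) / h
    N = null_space(C)
    return N.T @ J @ N


def find_steady_states(
    params: Optional[ParameterSet] = None,
    dose: float = 0.0,
    clamped: Optional[ClampedSystem] = None,
    n_starts: int = 24,
    seed: int = 0,
    network: Optional[ReactionNetwork] = None,
    x_ref: Optional[np.ndarray] = None,
) -> SteadyStateSet:
    """Multi-start root finding on the conservation manifold.

    Starting points are Latin-hypercube-like Dirichlet draws of each
    conservation group over its members; converged roots are deduped at
    ``DEDUPE_TOL`` and classified by the eigenvalues of the Jacobian
    restricted to the manifold (spurious zero modes along conservation
    directions are projected out).
    """
    if n_starts < 2:
        raise ValueError("n_starts must be at least 2")
    if clamped is not None:
        net = clamped.network
        x0_ref = clamped.initial_state()
    else:
        net = network if network is not None else build_network(params)
        x0_ref = resting_state(net)
    if x_ref is not None:
        x0_ref = x_ref
    C = _stoichiometric_invariants(net)
    totals = C @ x0_ref
    groups = list(net.conservation_groups().values())
    f = net.compile_rhs()
    n = net.n_species

    # replace one redundant rate equation per independent invariant
    fixed_rows = _pivot_rows(C)

    def F(x: np.ndarray) -> np.ndarray:
        r = f(0.0, x, dose)
        r[fixed_rows] = C @ x - totals
        return r

    rng = np.random.default_rng(seed)
    group_totals = [x0_ref[m].sum() for m in groups]
    structured = [x0_ref]
    if clamped is not None:
        x_act = clamped.initial_state(active=True)
        structured += [x_act, 0.5 * (x0_ref + x_act)]
    random_starts = []
    for _ in range(n_starts - len(structured)):
        x = np.zeros(n)
        for members, tot in zip(groups, group_totals):
            x[members] = rng.dirichlet(np.ones(len(members))) * tot
        random_starts.append(x)

    def polish(x0: np.ndarray, thorough: bool) -> Optional[np.ndarray]:
        sol = root(F, x0, method="hybr", tol=1e-12)
        x = sol.x
        if not (sol.success and x.min() > -1e-8):
            if not thorough:
                return None
            # mass-action roots with negative entries are legal solutions
            # of the equations but not of the model: retry with bounds
            ls = least_squares(F, np.clip(x0, 1e-12, None),
                               bounds=(0.0, np.inf), method="trf",
                               xtol=1e-15, ftol=1e-15, gtol=1e-15)
            x = ls.x
        x = np.clip(x, 0.0, None)
        if np.linalg.norm(F(x), ord=np.inf) > RESIDUAL_TOL:
            return None
        return x

    roots: list[np.ndarray] = []
    for thorough, x0 in ([(True, s) for s in structured]
                         + [(False, s) for s in random_starts]):
        x = polish(x0, thorough)
        if x is None:
            continue
        if np.linalg.norm(net.rhs(x, dose), ord=np.inf) > RESIDUAL_TOL * 10:
            continue
        if all(np.max(np.abs(x - r)) > DEDUPE_TOL for r in roots):
            roots.append(x)
    if not roots:
        raise RuntimeError("no steady state converged; increase n_starts")

    states = []
    for x in roots:
        Jr = _reduced_jacobian(net, x, dose, C)
        lead = float(np.max(np.linalg.eigvals(Jr).real))
        states.append(SteadyState(state=x, stable=lead < STABILITY_TOL,
                                  leading_eig=lead))
    return SteadyStateSet(network=net, states=states)


# ---------------------------------------------------------------------
# 1-D scans and folds
# ---------------------------------------------------------------------

@dataclass
class BifurcationDiagram:
    axis_name: str              # "dose" or "complex"
    axis: np.ndarray
    counts: np.ndarray          # steady states per scan point
    stable_counts: np.ndarray
    erk_branches: list[np.ndarray]   # sorted ERK_pp fractions per point
    folds: tuple[float, ...] = ()


def _states_at(params: ParameterSet, axis_name: str, value: float,
               n_starts: int, seed: int) -> SteadyStateSet:
    if axis_name == "dose":
        return find_steady_states(params, dose=value, n_starts=n_starts,
                                  seed=seed)
    elif axis_name == "complex":
        return find_steady_states(
            clamped=clamp_complex_variant(params, value),
            n_starts=n_starts, seed=seed)
    raise ValueError(f"unknown scan axis {axis_name!r}")


def scan_steady_states(
    params: ParameterSet,
    axis_name: str,
    values: Sequence[float],
    n_starts: int = 24,
    seed: int = 0,
) -> BifurcationDiagram:
    counts, stables, branches = [], [], []
    for v in values:
        ss = _states_at(params, axis_name, v, n_starts, seed)
        counts.append(len(ss))
        stables.append(ss.n_stable)
        branches.append(ss.erk_fractions())
    return BifurcationDiagram(
        axis_name=axis_name, axis=np.asarray(values, float),
        counts=np.asarray(counts), stable_counts=np.asarray(stables),
        erk_branches=branches)


def find_folds(
    diagram: BifurcationDiagram,
    params: ParameterSet,
    n_starts: int = 24,
    seed: int = 0,
    rel_tol: float = 1e-3,
) -> tuple[float, ...]:
    """Locate fold (saddle-node) points by bisection on state count.

    Returns axis locations where the steady-state count changes,
    refined to ``rel_tol`` of the scan span; empty when the scan is
    monostable everywhere.
    """
    ax, counts = diagram.axis, diagram.counts
    span = ax[-1] - ax[0]
    folds = []
    cache: dict[float, int] = {
        float(v): int(c) for v, c in zip(ax, counts)}

    def count_at(v: float) -> int:
        v = float(v)
        if v not in cache:
            cache[v] = len(_states_at(params, diagram.axis_name, v,
                                      n_starts, seed))
        return cache[v]

    for a, b in zip(ax[:-1], ax[1:]):
        ca, cb = count_at(a), count_at(b)
        if ca == cb:
            continue
        lo, hi = float(a), float(b)
        while hi - lo > rel_tol * span:
            mid = 0.5 * (lo + hi)
            if count_at(mid) == ca:
                lo = mid
            else:
                hi = mid
        folds.append(0.5 * (lo + hi))
    folds.sort()
    diagram.folds = tuple(folds)
    return tuple(folds)


# ---------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------

def _active_initial_state(net: ReactionNetwork) -> np.ndarray:
    p = net.params
    x = resting_state(net)
    ix = net.index
    x[ix["RAS_GDP"]] = 0.2 * p.RAS_tot
    x[ix["RAS_GTP"]] = 0.8 * p.RAS_tot
    for a, b in (("RAF", "RAF_a"), ("MEK", "MEK_pp"), ("ERK", "ERK_pp")):
        x[ix[b]] = x[ix[a]]
        x[ix[a]] = 0.0
    return x


def classify_regime(
    params: ParameterSet,
    dose: float,
    t_end: float = CLASSIFY_T_END,
    transient_discard: float = TRANSIENT_DISCARD,
    network: Optional[ReactionNetwork] = None,
    on_threshold: float = 0.3,
) -> str:
    """Label the long-term behavior at a sustained dose.

    Simulates from both the resting and a fully-active initial
    condition.  Labels: ``oscillatory``, ``bistable``, ``monostable-on``,
    ``monostable-off``; coexistence of a limit cycle and a stable
    steady state yields the compound label ``oscillatory+steady``.
    """
    net = network if network is not None else build_network(params)
    proto = StimulationProtocol.sustained(dose)
    ends = []
    osc = []
    for active in (False, True):
        x0 = _active_initial_state(net) if active else None
        traj = simulate(params, proto, t_end=t_end, x0=x0, network=net,
                        check=False)
        m = oscillation_metrics(traj, transient_discard=transient_discard)
        osc.append(m.is_oscillatory)
        a = traj.active_erk_fraction
        tail = a[traj.t >= traj.t[-1] - 0.1 * (traj.t[-1] - traj.t[0])]
        ends.append((float(tail.mean()), float(tail.max() - tail.min())))
    if any(osc):
        if all(osc):
            return "oscillatory"
        # one initial condition found a cycle, the other a steady state
        settled = [e for e, o in zip(ends, osc) if not o]
        if settled and settled[0][1] < 0.02:
            return "oscillatory+steady"
        return "oscillatory"
    means = [e[0] for e in ends]
    settled = all(e[1] < 0.02 for e in ends)
    if settled and abs(means[0] - means[1]) > 0.1:
        return "bistable"
    return "monostable-on" if max(means) > on_threshold else "monostable-off"


@dataclass
class RegimeMap:
    doses: np.ndarray
    axis_name: str
    axis_values: np.ndarray
    labels: np.ndarray            # (n_axis, n_dose) object array
    boundaries: list[tuple[float, float, float, float]] = field(
        default_factory=list)     # (dose_mid, axis_mid, dose_span, axis_span)


def regime_map_2d(
    params: ParameterSet,
    doses: Sequence[float],
    axis_name: str,
    axis_values: Sequence[float],
    t_end: float = CLASSIFY_T_END,
) -> RegimeMap:
    """Per-cell regime classification over (dose, feedback-strength).

    ``axis_name`` is ``f_nf1`` or ``f_nf23`` (the latter sets the
    ERK-to-RAF and ERK-to-MEK strengths jointly, as they are taken to
    be equal).  Cell boundaries are reported as midpoints of edges
    between cells with different labels.
    """
    doses = np.asarray(doses, float)
    axis_values = np.asarray(axis_values, float)
    labels = np.empty((len(axis_values), len(doses)), dtype=object)
    for i, v in enumerate(axis_values):
        if axis_name == "f_nf1":
            pv = params.replace(f_nf1=float(v))
        elif axis_name == "f_nf23":
            pv = params.replace(f_nf2=float(v), f_nf3=float(v))
        else:
            raise ValueError(f"unknown feedback axis {axis_name!r}")
        net = build_network(pv)
        for j, d in enumerate(doses):
            labels[i, j] = classify_regime(pv, float(d), t_end=t_end,
                                           network=net)
    bounds = []
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1] - 1):
            if labels[i, j] != labels[i, j + 1]:
                bounds.append((math.sqrt(doses[j] * doses[j + 1]),
                               axis_values[i], doses[j + 1] - doses[j], 0.0))
    for i in range(labels.shape[0] - 1):
        for j in range(labels.shape[1]):
            if labels[i, j] != labels[i + 1, j]:
                bounds.append((doses[j],
                               0.5 * (axis_values[i] + axis_values[i + 1]),
                               0.0, axis_values[i + 1] - axis_values[i]))
    return RegimeMap(doses=doses, axis_name=axis_name,
                     axis_values=axis_values, labels=labels,
                     boundaries=bounds)


# ---------------------------------------------------------------------
# oscillatory dose range and SOS-site scan
# ---------------------------------------------------------------------

def _is_oscillatory(params: ParameterSet, dose: float, t_end: float,
                    network: Optional[ReactionNetwork] = None) -> bool:
    traj = simulate(params, StimulationProtocol.sustained(dose),
                    t_end=t_end, network=network, check=False)
    return oscillation_metrics(traj).is_oscillatory


def oscillatory_dose_range(
    params: ParameterSet,
    dose_lo: float = 0.1,
    dose_hi: float = 1e4,
    n_scan: int = 40,
    t_end: float = CLASSIFY_T_END,
    refine_rel: float = 0.05,
) -> tuple[float, float]:
    """Lower and upper dose boundaries of the oscillatory regime.

    Log-spaced scan followed by bisection refinement of the two
    boundaries; returns ``(nan, nan)`` when no scanned dose oscillates.
    """
    net = build_network(params)
    doses = np.geomspace(dose_lo, dose_hi, n_scan)
    flags = [_is_oscillatory(params, float(d), t_end, net) for d in doses]
    idx = [i for i, fl in enumerate(flags) if fl]
    if not idx:
        return float("nan"), float("nan")
    i0, i1 = idx[0], idx[-1]

    def refine(a: float, b: float, osc_side_low: bool) -> float:
        # invariant: exactly one of (a, b) is oscillatory
        while b / a > 1.0 + refine_rel:
            m = math.sqrt(a * b)
            if _is_oscillatory(params, m, t_end, net) == osc_side_low:
                b = m
            else:
                a = m
        return math.sqrt(a * b)

    lo = doses[i0] if i0 == 0 else refine(doses[i0 - 1], doses[i0], True)
    hi = doses[i1] if i1 == len(doses) - 1 else refine(
        doses[i1], doses[i1 + 1], False)
    return float(lo), float(hi)


def site_count_scan(
    params: ParameterSet,
    site_counts: Iterable[int] = (1, 2, 3, 4, 5, 6),
    doses: Optional[Sequence[float]] = None,
    t_end: float = CLASSIFY_T_END,
) -> dict[int, bool]:
    """Oscillatory flag per SOS phospho-site count.

    The per-site phosphorylation rate ``q1`` is held fixed (each residue
    is an independent ERK substrate); each site count is probed over a
    log-spaced dose grid and flagged when any dose oscillates.
    """
    if doses is None:
        doses = np.geomspace(0.5, 2048, 13)
    out = {}
    for n in site_counts:
        pn = params.replace(n_sos_sites=int(n)) if n > 0 else params.replace(
            n_sos_sites=0, f_nf1=0.0)
        net = build_network(pn)
        out[int(n)] = any(
            _is_oscillatory(pn, float(d), t_end, net) for d in doses)
    return out


def nf_free_dose_window(
    params: ParameterSet,
    dose_lo: float = 0.05,
    dose_hi: float = 200.0,
    rel_tol: float = 0.05,
    t_settle: float = 1500.0,
) -> tuple[float, float]:
    """Dose-axis bistable window of the feedback-free system.

    Returns ``(d_off, d_on)``: the dose below which the active branch is
    lost (SN1-equivalent) and the dose above which the resting branch
    ignites (SN2-equivalent), located by bisection on quasi-static
    simulations.  Raises if the system is not hysteretic over the
    bracket.
    """
    p = params.without_negative_feedback()
    net = build_network(p)
    x_rest = resting_state(net)

    def settles_on(dose: float, x0: np.ndarray) -> tuple[bool, np.ndarray]:
        traj = simulate(p, StimulationProtocol.sustained(dose),
                        t_end=t_settle, x0=x0, network=net, check=False)
        frac = traj.active_erk_fraction[-1]
        return frac > 0.3, traj.y[-1]

    on_lo, _ = settles_on(dose_lo, x_rest)
    on_hi, x_on = settles_on(dose_hi, x_rest)
    if on_lo or not on_hi:
        raise RuntimeError("no ignition threshold inside the dose bracket")
    a, b = dose_lo, dose_hi
    while b / a > 1.0 + rel_tol:
        m = math.sqrt(a * b)
        if settles_on(m, x_rest)[0]:
            b = m
        else:
            a = m
    d_on = math.sqrt(a * b)

    # walk the active branch down from dose_hi
    still_on, _ = settles_on(dose_lo, x_on)
    if still_on:
        raise RuntimeError("active branch persists at the lower bracket")
    a, b = dose_lo, dose_hi
    while b / a > 1.0 + rel_tol:
        m = math.sqrt(a * b)
        if settles_on(m, x_on)[0]:
            b = m
        else:
            a = m
    d_off = math.sqrt(a * b)
    if not d_off < d_on:
        raise RuntimeError("no hysteresis: branch thresholds coincide")
    return d_off, d_on


def hysteresis_scan(
    params: ParameterSet,
    doses: Sequence[float],
    t_settle: float = 1500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-static up-then-down dose scan of the steady active-ERK level.

    Returns (up_scan, down_scan) ERK_pp fractions; differing values
    inside a dose window indicate hysteresis (bistability).
    """
    net = build_network(params)
    x = resting_state(net)
    up, down = [], []
    for d in doses:
        traj = simulate(params, StimulationProtocol.sustained(float(d)),
                        t_end=t_settle, x0=x, network=net, check=False)
        x = traj.y[-1]
        up.append(float(traj.active_erk_fraction[-1]))
    for d in reversed(doses):
        traj = simulate(params, StimulationProtocol.sustained(float(d)),
                        t_end=t_settle, x0=x, network=net, check=False)
        x = traj.y[-1]
        down.append(float(traj.active_erk_fraction[-1]))
    return np.asarray(up), np.asarray(down)[::-1]
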