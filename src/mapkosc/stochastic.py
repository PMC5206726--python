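"""Stochastic extension: exact SSA plus bursty EGFR surface expression.

Extrinsic noise enters through cell-specific, time-varying EGFR surface
abundance: synthesis occurs in bursts governed by a two-state telegraph
process (OFF -> ON at ``lam_interburst``, ON -> OFF at ``lam_burst``),
produces receptors at ``A_burst * alpha_cell`` while ON, and every
EGFR-containing species decays with half-life ``tau_egfr``.  Decay of a
receptor-SOS complex releases the bound SOS (and any REM-site RAS) back
to the free pools, so all non-receptor conservation laws still hold
exactly.

Two simulation modes are provided: a statistically exact direct-method
SSA of the full network (all species as integer copy numbers), and a
hybrid mode where only the burst telegraph process is stochastic and
the network (with piecewise-deterministic synthesis/decay) is
integrated as ODEs.  The hybrid mode is the default for population
figures, since the population phenomenology is driven by the extrinsic
receptor noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .deterministic import SimulationError, Trajectory
from .network import ReactionNetwork, build_network, resting_state
from .params import ParameterSet

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "CellConfig",
    "SSAOptions",
    "draw_cell",
    "telegraph_mean_egfr",
    "ssa_simulate",
    "hybrid_simulate",
    "sample_population",
    "PopulationSample",
]

#: default log-normal sigma for the cell-specific burst factor
ALPHA_SIGMA = 0.3


@dataclass(frozen=True)
class CellConfig:
    """Cell-specific EGFR surface-expression dynamics.

    Defaults make EGFR abundance fluctuate on a time scale of hours:
    bursts arrive on average every 2 h, last on average 30 min, and the
    receptor half-life is 6 h.  ``a_burst`` is in normalized
    concentration per minute and is scaled so that the population-mean
    receptor level equals the deterministic total.
    """

    alpha_cell: float = 1.0
    lam_interburst: float = 1.0 / 120.0   # 1/min: burst arrival
    lam_burst: float = 1.0 / 30.0         # 1/min: burst termination
    a_burst: float = 0.009625             # conc/min while bursting
    tau_egfr: float = 360.0               # min, half-life
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("alpha_cell", "lam_interburst", "lam_burst",
                  "a_burst", "tau_egfr"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")

    @property
    def p_on(self) -> float:
        return self.lam_interburst / (self.lam_interburst + self.lam_burst)


def draw_cell(rng: np.random.Generator, sigma: float = ALPHA_SIGMA,
              seed: int = 0, **kwargs) -> CellConfig:
    """Draw a cell with a log-normal burst factor of mean exactly 1."""
    alpha = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    return CellConfig(alpha_cell=alpha, seed=seed, **kwargs)


def telegraph_mean_egfr(cell: CellConfig) -> float:
    """Stationary mean receptor level of the burst/decay process alone."""
    delta = math.log(2.0) / cell.tau_egfr
    return cell.a_burst * cell.alpha_cell * cell.p_on / delta


@dataclass(frozen=True)
class SSAOptions:
    omega: float = 1000.0      # copy numbers = round(omega * concentration)
    mode: str = "hybrid"       # "full" or "hybrid"
    seed: int = 0
    dt_out: float = 1.0        # minutes between recorded samples

    def __post_init__(self) -> None:
        if self.omega < 10:
            raise ValueError("omega must be at least 10")
        if self.mode not in ("full", "hybrid"):
            raise ValueError("mode must be 'full' or 'hybrid'")


# ---------------------------------------------------------------------
# full SSA (direct method)
# ---------------------------------------------------------------------

@njit(cache=True)
def _ssa_core(S, k, fac, t_grid, x0, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n_rxn = S.shape[1]
    n_sp = S.shape[0]
    nt = t_grid.shape[0]
    out = np.zeros((nt, n_sp), dtype=np.int64)
    x = x0.copy()
    t = t_grid[0]
    it = 0
    a = np.zeros(n_rxn)
    while it < nt:
        total = 0.0
        for j in range(n_rxn):
            aj = k[j]
            for m in range(fac.shape[1]):
                i = fac[j, m]
                if i >= 0:
                    aj *= x[i]
            a[j] = aj
            total += aj
        if total <= 0.0:
            for it2 in range(it, nt):
                out[it2] = x
            return out
        t += -math.log(np.random.random()) / total
        while it < nt and t_grid[it] < t:
            out[it] = x
            it += 1
        r = np.random.random() * total
        acc = 0.0
        jsel = n_rxn - 1
        for j in range(n_rxn):
            acc += a[j]
            if acc >= r:
                jsel = j
                break
        for i in range(n_sp):
            x[i] += S[i, jsel]
            if x[i] < 0:
                raise ValueError("negative copy number")
    return out


def _egfr_process_reactions(net: ReactionNetwork, cell: CellConfig,
                            omega: float):
    """Stoichiometry columns + count-unit rates for the EGFR processes.

    Species layout: network species + [B_off, B_on] appended.
    """
    n = net.n_species
    ix = net.index
    cols = []
    rates = []
    facs = []
    b_off, b_on = n, n + 1

    def add(stoich: dict[int, int], rate: float, factors: tuple[int, ...]):
        col = np.zeros(n + 2, dtype=np.int64)
        for i, v in stoich.items():
            col[i] = v
        cols.append(col)
        rates.append(rate)
        facs.append(factors)

    add({b_off: -1, b_on: +1}, cell.lam_interburst, (b_off,))
    add({b_on: -1, b_off: +1}, cell.lam_burst, (b_on,))
    # synthesis: propensity A*alpha*omega while ON (molecules/min)
    add({ix["EGFR"]: +1}, cell.a_burst * cell.alpha_cell * omega, (b_on,))
    delta = math.log(2.0) / cell.tau_egfr
    add({ix["EGFR"]: -1}, delta, (ix["EGFR"],))
    add({ix["EGFR_a"]: -1}, delta, (ix["EGFR_a"],))
    add({ix["C0"]: -1, ix["SOS_u"]: +1}, delta, (ix["C0"],))
    add({ix["CD"]: -1, ix["SOS_u"]: +1, ix["RAS_GDP"]: +1}, delta,
        (ix["CD"],))
    add({ix["CT"]: -1, ix["SOS_u"]: +1, ix["RAS_GTP"]: +1}, delta,
        (ix["CT"],))
    return np.array(cols).T, np.array(rates), facs


def _ssa_arrays(net: ReactionNetwork, cell: Optional[CellConfig],
                dose: float, omega: float):
    S, k_conc, fac, orders, dose_order = net.ssa_arrays()
    # concentration-rate -> count-rate: k_count = k_conc * omega^(1-order)
    k = k_conc * omega ** (1.0 - orders) * np.where(
        dose_order > 0, dose ** dose_order, 1.0)
    n = net.n_species
    S2 = np.vstack([S, np.zeros((2, S.shape[1]), dtype=np.int64)])
    if cell is not None:
        Se, ke, face = _egfr_process_reactions(net, cell, omega)
        S2 = np.hstack([S2, Se])
        k = np.concatenate([k, ke])
        width = max(fac.shape[1], max(len(f) for f in face))
        fac2 = -np.ones((S2.shape[1], width), dtype=np.int64)
        fac2[: fac.shape[0], : fac.shape[1]] = fac
        for j, f in enumerate(face):
            for m, i in enumerate(f):
                fac2[fac.shape[0] + j, m] = i
        fac = fac2
    return S2, k, fac


def ssa_simulate(
    params: ParameterSet,
    cell: Optional[CellConfig],
    dose: float,
    t_end: float,
    opts: SSAOptions = SSAOptions(mode="full"),
    x0_counts: Optional[np.ndarray] = None,
    network: Optional[ReactionNetwork] = None,
) -> Trajectory:
    """Exact direct-method SSA; returns integer copy numbers.

    ``cell=None`` disables the EGFR expression processes (fixed receptor
    pool).  The returned trajectory carries ``omega`` so fraction-valued
    observables are on the same scale as deterministic runs.
    """
    net = network if network is not None else build_network(params)
    S, k, fac = _ssa_arrays(net, cell, dose, opts.omega)
    if x0_counts is None:
        x0 = np.round(resting_state(net) * opts.omega).astype(np.int64)
    else:
        x0 = np.asarray(x0_counts, dtype=np.int64).copy()
    x0 = np.concatenate([x0, [1, 0]])       # burst telegraph starts OFF
    t_grid = np.arange(0.0, t_end + 0.5 * opts.dt_out, opts.dt_out)
    seed = (int(opts.seed) + (cell.seed if cell is not None else 0)) % (2**31)
    try:
        out = _ssa_core(S, k, fac, t_grid, x0, seed)
    except ValueError as e:  # pragma: no cover - defensive
        raise SimulationError(str(e), float("nan"))
    return Trajectory(t=t_grid, y=out[:, : net.n_species].astype(float),
                      network=net, omega=opts.omega)


# ---------------------------------------------------------------------
# hybrid mode: stochastic telegraph bursts + deterministic network
# ---------------------------------------------------------------------

def sample_burst_path(cell: CellConfig, t_end: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Telegraph switch times; returns array of (t_switch, new_state)."""
    t, state = 0.0, 0
    events = []
    while t < t_end:
        rate = cell.lam_interburst if state == 0 else cell.lam_burst
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        state = 1 - state
        if t < t_end:
            events.append((t, state))
    return np.array(events).reshape(-1, 2)


def hybrid_simulate(
    params: ParameterSet,
    cell: CellConfig,
    dose: float,
    t_end: float,
    burst_path: Optional[np.ndarray] = None,
    seed: int = 0,
    dt_out: float = 1.0,
    network: Optional[ReactionNetwork] = None,
    x0: Optional[np.ndarray] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Piecewise-deterministic simulation driven by stochastic bursts.

    The telegraph process is sampled exactly; between switches the
    network ODEs are integrated with receptor synthesis (while ON) and
    first-order receptor decay added.  Because synthesis and decay act
    only on receptor totals, the receptor-abundance path is identical
    across doses for a fixed burst path.
    """
    net = network if network is not None else build_network(params)
    if burst_path is None:
        rng = np.random.default_rng((seed + cell.seed) % (2**31))
        burst_path = sample_burst_path(cell, t_end, rng)
    f = net.compile_rhs()
    ix = net.index
    delta = math.log(2.0) / cell.tau_egfr
    decay = np.zeros((net.n_species, net.n_species))
    for sp, released in (("EGFR", ()), ("EGFR_a", ()),
                         ("C0", ("SOS_u",)),
                         ("CD", ("SOS_u", "RAS_GDP")),
                         ("CT", ("SOS_u", "RAS_GTP"))):
        i = ix[sp]
        decay[i, i] -= delta
        for r in released:
            decay[ix[r], i] += delta
    e_egfr = np.zeros(net.n_species)
    e_egfr[ix["EGFR"]] = 1.0
    syn_rate = cell.a_burst * cell.alpha_cell

    def rhs(t, x, s):
        return f(t, x, dose) + decay @ x + s * e_egfr

    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    x = np.array(resting_state(net) if x0 is None else x0, float)
    times = np.concatenate([[0.0], burst_path[:, 0], [t_end]])
    states = np.concatenate([[0], burst_path[:, 1]])
    pieces_t, pieces_y = [], []
    for a, b, st in zip(times[:-1], times[1:], states):
        if b <= a:
            continue
        mask = (t_grid >= a) & (t_grid < b)
        t_eval = np.unique(np.concatenate([[a], t_grid[mask], [b]]))
        sol = solve_ivp(rhs, (a, b), x, t_eval=t_eval,
                        args=(syn_rate if st else 0.0,),
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(sol.message, sol.t[-1] if sol.t.size else a)
        sel = np.searchsorted(sol.t, t_grid[mask])
        pieces_t.append(t_grid[mask])
        pieces_y.append(sol.y[:, sel].T)
        x = sol.y[:, -1]
    t = np.concatenate(pieces_t + [[t_end]])
    y = np.vstack(pieces_y + [x[None, :]])
    keep = np.concatenate([np.diff(t) > 0, [True]])
    traj = Trajectory(t=t[keep], y=np.clip(y[keep], 0.0, None), network=net)
    traj.burst_path = burst_path
    return traj


# ---------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------

@dataclass
class PopulationSample:
    doses: list[float]
    cells: list[CellConfig]
    t: np.ndarray
    #: active-ERK fraction, shape (n_doses, n_cells, n_t)
    activity: np.ndarray
    egfr_total: np.ndarray    # (n_cells, n_t), dose-independent path

    def active_fraction_of_time(self, theta: float = 0.5) -> np.ndarray:
        """Mean fraction of time each cell spends ERK-active, per dose."""
        return (self.activity > theta).mean(axis=2)


def sample_population(
    params: ParameterSet,
    n_cells: int,
    doses: Sequence[float],
    t_end: float = 1500.0,
    shared_profile: bool = True,
    seed: int = 0,
    sigma: float = ALPHA_SIGMA,
    dt_out: float = 3.0,
    cell_kwargs: Optional[dict] = None,
) -> PopulationSample:
    """Hybrid-mode population run over a dose panel.

    With ``shared_profile`` the burst path (hence the receptor
    expression profile) of each cell is generated once and reused for
    every dose, isolating the dose effect from the extrinsic noise.
    Deterministic given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    net = build_network(params)
    rng = np.random.default_rng(seed % (2**31))
    cells = [draw_cell(rng, sigma=sigma, seed=i, **(cell_kwargs or {}))
             for i in range(n_cells)]
    paths = []
    for cell in cells:
        cell_rng = np.random.default_rng((seed + 7919 * (cell.seed + 1))
                                         % (2**31))
        paths.append(sample_burst_path(cell, t_end, cell_rng))
    t_ref = None
    act = []
    egfr = []
    ix = [net.index[s] for s in ("EGFR", "EGFR_a", "C0", "CD", "CT")]
    for d_i, dose in enumerate(doses):
        per_cell = []
        for c_i, cell in enumerate(cells):
            path = paths[c_i] if shared_profile else sample_burst_path(
                cell, t_end,
                np.random.default_rng((seed + 104729 * (d_i + 1)
                                       + 7919 * (c_i + 1)) % (2**31)))
            traj = hybrid_simulate(params, cell, float(dose), t_end,
                                   burst_path=path, dt_out=dt_out,
                                   network=net)
            if t_ref is None:
                t_ref = traj.t
            per_cell.append(traj.active_erk_fraction)
            if d_i == 0:
                egfr.append(traj.y[:, ix].sum(axis=1))
        act.append(per_cell)
    return PopulationSample(
        doses=[float(d) for d in doses], cells=cells, t=t_ref,
        activity=np.asarray(act), egfr_total=np.asarray(egfr))
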