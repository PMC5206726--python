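"""Species registry, mass-action reaction network and ODE right-hand side.

The network couples one positive feedback (RAS-GTP boosting SOS GEF
activity via the allosteric REM site) with three ERK-driven negative
feedbacks: ERK-to-SOS (NF1, via multi-site phosphorylation of free SOS),
ERK-to-RAF (NF2) and ERK-to-MEK (NF3).  Every reaction is elementary
mass action; the model is closed (no synthesis or degradation), so each
protein pool obeys an exact conservation law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .params import ParameterSet

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "species_names",
    "build_network",
    "resting_state",
    "conserved_totals",
]


def species_names(params: ParameterSet) -> list[str]:
    """Ordered species list for a given parameter set."""
    names = ["EGFR", "EGFR_a", "C0", "CD", "CT", "SOS_u"]
    names += [f"SOS_p{i}" for i in range(1, params.n_sos_sites + 1)]
    names += ["RAS_GDP", "RAS_GTP", "GAPC", "RasGAP"]
    names += ["RAF", "RAF_a", "RAF_i"]
    names += ["MEK", "MEK_p", "MEK_pp", "MEK_i"]
    names += ["ERK", "ERK_p", "ERK_pp"]
    for rep in params.reporters:
        names += [f"REP_{rep}_u", f"REP_{rep}_p"]
    return names


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants`` are consumed, ``modifiers`` enter the rate law but are
    not consumed (catalysts).  The propensity is
    ``rate_constant * dose**dose_order * prod(conc[reactants + modifiers])``.
    """

    name: str
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_constant: float
    modifiers: tuple[int, ...] = ()
    dose_order: int = 0

    @property
    def order(self) -> int:
        return len(self.reactants) + len(self.modifiers)


@dataclass
class ReactionNetwork:
    """Stoichiometry + rate laws, shared by the ODE, SSA and PDE layers."""

    params: ParameterSet
    species: list[str]
    reactions: list[Reaction]
    index: dict[str, int] = field(init=False)
    stoich: np.ndarray = field(init=False)        # (n_species, n_reactions)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.species)}
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                S[i, j] -= 1
            for i in rxn.products:
                S[i, j] += 1
        self.stoich = S

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- rate evaluation --------------------------------------------

    def propensities(self, x: np.ndarray, dose: float) -> np.ndarray:
        """Mass-action rates for state ``x`` (concentration semantics)."""
        w = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            r = rxn.rate_constant
            if rxn.dose_order:
                r *= dose ** rxn.dose_order
            for i in rxn.reactants:
                r *= x[i]
            for i in rxn.modifiers:
                r *= x[i]
            w[j] = r
        return w

    def rhs(self, x: np.ndarray, dose: float) -> np.ndarray:
        """Time derivative of every species under mass-action kinetics."""
        if np.any(np.asarray(x) < 0):
            raise ValueError("negative state entries")
        return self.stoich @ self.propensities(np.asarray(x, float), dose)

    def compile_rhs(self) -> Callable[[float, np.ndarray, float], np.ndarray]:
        """Return a fast ``f(t, x, dose)`` closure for ODE integrators.

        Precomputes index arrays so the hot loop is pure numpy; no
        nonnegativity guard (integrators may probe slightly negative
        states during error control).
        """
        n_rxn = len(self.reactions)
        k = np.array([r.rate_constant for r in self.reactions])
        dose_order = np.array([r.dose_order for r in self.reactions])
        # pad factor index lists to a rectangle; index -1 multiplies by 1.0
        max_ord = max((r.order for r in self.reactions), default=0)
        fac = -np.ones((n_rxn, max_ord), dtype=np.intp)
        for j, rxn in enumerate(self.reactions):
            for m, i in enumerate(rxn.reactants + rxn.modifiers):
                fac[j, m] = i
        S = self.stoich.astype(float)

        def f(t: float, x: np.ndarray, dose: float) -> np.ndarray:
            xe = np.append(x, 1.0)          # index -1 -> 1.0
            w = k * np.prod(xe[fac], axis=1)
            if dose != 1.0:
                w = w * dose ** dose_order
            return S @ w

        return f

    def compile_rhs_multi(self):
        """Vectorized ``f(x, dose)`` over node columns.

        ``x`` has shape (n_species, n_nodes) and ``dose`` is a per-node
        vector; returns the per-node mass-action derivative.  Used by
        the reaction-diffusion layer.
        """
        n_rxn = len(self.reactions)
        k = np.array([r.rate_constant for r in self.reactions])
        dose_order = np.array([r.dose_order for r in self.reactions])
        max_ord = max((r.order for r in self.reactions), default=0)
        fac = -np.ones((n_rxn, max_ord), dtype=np.intp)
        for j, rxn in enumerate(self.reactions):
            for m, i in enumerate(rxn.reactants + rxn.modifiers):
                fac[j, m] = i
        S = self.stoich.astype(float)
        dosed = dose_order > 0

        def f(x: np.ndarray, dose: np.ndarray) -> np.ndarray:
            xe = np.vstack([x, np.ones((1, x.shape[1]))])
            w = k[:, None] * np.prod(xe[fac, :], axis=1)
            if np.any(dosed):
                w[dosed] *= dose[None, :] ** dose_order[dosed, None]
            return S @ w

        return f

    def ssa_arrays(self):
        """(stoich, rate_constants, factor_index, dose_order) for the SSA."""
        n_rxn = len(self.reactions)
        max_ord = max((r.order for r in self.reactions), default=1)
        fac = -np.ones((n_rxn, max_ord), dtype=np.int64)
        orders = np.zeros(n_rxn, dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            facs = rxn.reactants + rxn.modifiers
            orders[j] = len(facs)
            for m, i in enumerate(facs):
                fac[j, m] = i
        k = np.array([r.rate_constant for r in self.reactions])
        dose_order = np.array([r.dose_order for r in self.reactions])
        return self.stoich.copy(), k, fac, orders, dose_order

    # -- conservation ------------------------------------------------

    def conservation_groups(self) -> dict[str, list[int]]:
        ix = self.index
        p = self.params
        groups = {
            "EGFR": ["EGFR", "EGFR_a", "C0", "CD", "CT"],
            "SOS": ["C0", "CD", "CT", "SOS_u"]
            + [f"SOS_p{i}" for i in range(1, p.n_sos_sites + 1)],
            "RAS": ["RAS_GDP", "RAS_GTP", "GAPC", "CD", "CT"],
            "RasGAP": ["RasGAP", "GAPC"],
            "RAF": ["RAF", "RAF_a", "RAF_i"],
            "MEK": ["MEK", "MEK_p", "MEK_pp", "MEK_i"],
            "ERK": ["ERK", "ERK_p", "ERK_pp"],
        }
        for rep in p.reporters:
            groups[f"REP_{rep}"] = [f"REP_{rep}_u", f"REP_{rep}_p"]
        return {g: [ix[s] for s in members] for g, members in groups.items()}

    def conservation_matrix(self) -> np.ndarray:
        groups = self.conservation_groups()
        C = np.zeros((len(groups), self.n_species))
        for row, members in enumerate(groups.values()):
            C[row, members] = 1.0
        return C

    def group_totals(self) -> dict[str, float]:
        p = self.params
        totals = {
            "EGFR": p.EGFR_tot, "SOS": p.SOS_tot, "RAS": p.RAS_tot,
            "RasGAP": p.RasGAP_tot, "RAF": p.RAF_tot, "MEK": p.MEK_tot,
            "ERK": p.ERK_tot,
        }
        for rep, rp in p.reporters.items():
            totals[f"REP_{rep}"] = rp.total
        return totals


def build_network(params: ParameterSet) -> ReactionNetwork:
    """Assemble the full mass-action reaction list.

    Structural rules: only unphosphorylated free SOS binds activated
    EGFR; SOS is phosphorylated/dephosphorylated only when free (never
    in a receptor complex); a single phosphorylated SOS site abolishes
    receptor binding; the GEF step converts free RAS-GDP at a rate set
    by the REM-site occupancy of the receptor-bound SOS complex.
    """
    params.validate()
    p = params
    species = species_names(p)
    ix = {s: i for i, s in enumerate(species)}
    rxns: list[Reaction] = []

    def add(name, reactants, products, k, modifiers=(), dose_order=0):
        if k < 0:
            raise ValueError(f"negative rate for {name}")
        rxns.append(Reaction(
            name=name,
            reactants=tuple(ix[s] for s in reactants),
            products=tuple(ix[s] for s in products),
            rate_constant=k,
            modifiers=tuple(ix[s] for s in modifiers),
            dose_order=dose_order,
        ))

    # (1) receptor activation / deactivation
    add("egfr_act", ["EGFR"], ["EGFR_a"], p.egf_gain, dose_order=1)
    add("egfr_deact", ["EGFR_a"], ["EGFR"], p.k_egfr_deact)
    # (2) complex formation with free unphosphorylated SOS
    add("c0_bind", ["EGFR_a", "SOS_u"], ["C0"], p.b1)
    add("c0_unbind", ["C0"], ["EGFR_a", "SOS_u"], p.u1)
    # (3) REM-site RAS binding
    add("rem_gdp_bind", ["C0", "RAS_GDP"], ["CD"], p.bG)
    add("rem_gdp_unbind", ["CD"], ["C0", "RAS_GDP"], p.uG)
    add("rem_gtp_bind", ["C0", "RAS_GTP"], ["CT"], p.bT)
    add("rem_gtp_unbind", ["CT"], ["C0", "RAS_GTP"], p.uT)
    # (4) GEF catalysis on free RAS-GDP, REM-occupancy dependent
    if p.k2A > 0:
        add("gef_ct", ["RAS_GDP"], ["RAS_GTP"], p.k2A, modifiers=["CT"])
    if p.k2B > 0:
        add("gef_cd", ["RAS_GDP"], ["RAS_GTP"], p.k2B, modifiers=["CD"])
    if p.k2C > 0:
        add("gef_c0", ["RAS_GDP"], ["RAS_GTP"], p.k2C, modifiers=["C0"])
    # (5) RasGAP two-step catalysis
    add("gap_bind", ["RasGAP", "RAS_GTP"], ["GAPC"], p.b3)
    add("gap_convert", ["GAPC"], ["RasGAP", "RAS_GDP"], p.u3)
    # (6) RAF activation by RAS-GTP; NF2 inhibitory phosphorylation
    add("raf_act", ["RAF"], ["RAF_a"], p.k_raf_act, modifiers=["RAS_GTP"])
    add("raf_deact", ["RAF_a"], ["RAF"], p.k_raf_deact)
    if p.f_nf2 * p.q2 > 0:
        add("nf2_raf", ["RAF"], ["RAF_i"], p.f_nf2 * p.q2,
            modifiers=["ERK_pp"])
        if p.nf2_targets_active:
            add("nf2_raf_a", ["RAF_a"], ["RAF_i"], p.f_nf2 * p.q2,
                modifiers=["ERK_pp"])
    add("nf2_release", ["RAF_i"], ["RAF"], p.d2)
    # (7) distributive MEK phosphorylation; NF3
    add("mek_ph1", ["MEK"], ["MEK_p"], p.k_mek_ph, modifiers=["RAF_a"])
    add("mek_ph2", ["MEK_p"], ["MEK_pp"], p.k_mek_ph, modifiers=["RAF_a"])
    add("mek_deph2", ["MEK_pp"], ["MEK_p"], p.k_mek_deph)
    add("mek_deph1", ["MEK_p"], ["MEK"], p.k_mek_deph)
    if p.f_nf3 * p.q3 > 0:
        add("nf3_mek", ["MEK"], ["MEK_i"], p.f_nf3 * p.q3,
            modifiers=["ERK_pp"])
    add("nf3_release", ["MEK_i"], ["MEK"], p.d3)
    # (8) distributive ERK phosphorylation
    add("erk_ph1", ["ERK"], ["ERK_p"], p.k_erk_ph, modifiers=["MEK_pp"])
    add("erk_ph2", ["ERK_p"], ["ERK_pp"], p.k_erk_ph, modifiers=["MEK_pp"])
    add("erk_deph2", ["ERK_pp"], ["ERK_p"], p.k_erk_deph)
    add("erk_deph1", ["ERK_p"], ["ERK"], p.k_erk_deph)
    # (9) NF1: sequential multi-site phosphorylation of free SOS
    if p.f_nf1 * p.q1 > 0:
        chain = ["SOS_u"] + [f"SOS_p{i}" for i in range(1, p.n_sos_sites + 1)]
        for a, b in zip(chain[:-1], chain[1:]):
            add(f"nf1_{a}_to_{b}", [a], [b], p.f_nf1 * p.q1,
                modifiers=["ERK_pp"])
        for a, b in zip(chain[1:], chain[:-1]):
            add(f"sos_deph_{a}_to_{b}", [a], [b], p.d1)
    elif p.n_sos_sites > 0 and p.d1 > 0:
        chain = ["SOS_u"] + [f"SOS_p{i}" for i in range(1, p.n_sos_sites + 1)]
        for a, b in zip(chain[1:], chain[:-1]):
            add(f"sos_deph_{a}_to_{b}", [a], [b], p.d1)
    # (10) reporters
    for rep, rp in p.reporters.items():
        add(f"rep_{rep}_ph", [f"REP_{rep}_u"], [f"REP_{rep}_p"],
            rp.k_ph, modifiers=["ERK_pp"])
        add(f"rep_{rep}_deph", [f"REP_{rep}_p"], [f"REP_{rep}_u"], rp.k_deph)

    return ReactionNetwork(params=p, species=species, reactions=rxns)


def resting_state(net: ReactionNetwork) -> np.ndarray:
    """All-inactive state: every pool in its basal species."""
    p = net.params
    x = np.zeros(net.n_species)
    ix = net.index
    x[ix["EGFR"]] = p.EGFR_tot
    x[ix["SOS_u"]] = p.SOS_tot
    x[ix["RAS_GDP"]] = p.RAS_tot
    x[ix["RasGAP"]] = p.RasGAP_tot
    x[ix["RAF"]] = p.RAF_tot
    x[ix["MEK"]] = p.MEK_tot
    x[ix["ERK"]] = p.ERK_tot
    for rep, rp in p.reporters.items():
        x[ix[f"REP_{rep}_u"]] = rp.total
    return x


def conserved_totals(net: ReactionNetwork, state: np.ndarray):
    """Per-group totals of ``state`` (runtime conservation check).

    ``state`` may be a single state vector or a (n_t, n_species)
    trajectory matrix; totals are summed over the last axis.
    """
    state = np.asarray(state)
    out = {}
    for g, members in net.conservation_groups().items():
        tot = state[..., members].sum(axis=-1)
        out[g] = float(tot) if state.ndim == 1 else tot
    return out
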