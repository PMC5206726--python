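"""Model parameters for the MAPK/ERK relaxation-oscillator network.

All concentrations are normalized so that the total ERK pool equals 1;
time is measured in minutes; the EGF dose is expressed in pg/ml and
enters the equations only through ``egf_gain``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["ReporterParams", "ParameterSet", "default_params"]

MAX_SOS_SITES = 8


@dataclass(frozen=True)
class ReporterParams:
    """First-order kinetics of an ERK-activity reporter.

    ``k_ph`` is the ERK_pp-catalyzed phosphorylation rate constant
    (per unit active ERK per minute), ``k_deph`` the constitutive
    dephosphorylation rate (1/min); ``total`` is the reporter pool.
    """

    k_ph: float
    k_deph: float
    total: float = 0.01

    def validate(self, name: str) -> None:
        for f in ("k_ph", "k_deph", "total"):
            if getattr(self, f) < 0:
                raise ValueError(f"reporter {name!r}: {f} must be nonnegative")


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants, protein totals and feedback strengths.

    The single source of truth for the reaction network.  Defaults are
    the package's calibrated reference set (see :func:`default_params`).
    """

    # receptor layer
    egf_gain: float = 0.015423562818497275       # per (pg/ml) per min: EGFR -> EGFR_a
    k_egfr_deact: float = 0.5      # 1/min

    # EGFR_a + SOS_u association
    b1: float = 1.0
    u1: float = 1.0

    # REM (allosteric) site on SOS: RAS-GDP / RAS-GTP binding
    bG: float = 2.0
    uG: float = 1.0
    bT: float = 20.0
    uT: float = 1.0

    # GEF catalysis of the EGFR_a-SOS complex, by REM occupancy
    k2A: float = 60.0              # REM holds RAS-GTP
    k2B: float = 6.0               # REM holds RAS-GDP (default 0.1*k2A)
    k2C: float = 0.0               # REM empty

    # RasGAP two-step catalysis
    b3: float = 1600.0
    u3: float = 1.0

    # RAF layer
    k_raf_act: float = 2.0         # per RAS_GTP per min
    k_raf_deact: float = 0.5

    # distributive MEK / ERK (de)phosphorylation, per site
    k_mek_ph: float = 4.0
    k_mek_deph: float = 0.5
    k_erk_ph: float = 4.0
    k_erk_deph: float = 0.5

    # negative feedbacks (ERK_pp-catalyzed)
    q1: float = 0.465                # NF1: SOS phosphorylation per site
    d1: float = 0.1               # SOS dephosphorylation per site
    q2: float = 0.05               # NF2: inhibitory RAF phosphorylation
    d2: float = 0.05
    q3: float = 0.05               # NF3: inhibitory MEK phosphorylation
    d3: float = 0.05
    f_nf1: float = 1.0
    f_nf2: float = 1.0
    f_nf3: float = 1.0
    nf2_targets_active: bool = True   # NF2 also hits RAF_a (not only RAF)

    n_sos_sites: int = 4

    # totals (normalized concentration units; ERK_tot defines the scale)
    EGFR_tot: float = 1.0
    SOS_tot: float = 0.05
    RAS_tot: float = 1.0
    RasGAP_tot: float = 0.05
    RAF_tot: float = 1.0
    MEK_tot: float = 1.0
    ERK_tot: float = 1.0

    reporters: Mapping[str, ReporterParams] = field(
        default_factory=lambda: {
            "EKAR3": ReporterParams(k_ph=0.5, k_deph=0.15),
            "ERKTR": ReporterParams(k_ph=5.0, k_deph=1.5),
        }
    )

    _RATE_FIELDS = (
        "egf_gain", "k_egfr_deact", "b1", "u1", "bG", "uG", "bT", "uT",
        "k2A", "k2B", "k2C", "b3", "u3", "k_raf_act", "k_raf_deact",
        "k_mek_ph", "k_mek_deph", "k_erk_ph", "k_erk_deph",
        "q1", "d1", "q2", "d2", "q3", "d3",
    )
    _TOTAL_FIELDS = (
        "EGFR_tot", "SOS_tot", "RAS_tot", "RasGAP_tot",
        "RAF_tot", "MEK_tot", "ERK_tot",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in self._RATE_FIELDS + self._TOTAL_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        for f in ("f_nf1", "f_nf2", "f_nf3"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if not (self.k2C <= self.k2B <= self.k2A):
            raise ValueError("GEF rates must satisfy k2C <= k2B <= k2A")
        if not isinstance(self.n_sos_sites, int) or not (
            0 <= self.n_sos_sites <= MAX_SOS_SITES
        ):
            raise ValueError(
                f"n_sos_sites must be an integer in [0, {MAX_SOS_SITES}]"
            )
        if self.n_sos_sites == 0 and self.f_nf1 > 0:
            raise ValueError(
                "f_nf1 > 0 requires at least one phosphorylatable SOS site"
            )
        for name, rep in self.reporters.items():
            rep.validate(name)

    # -- convenience -------------------------------------------------

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def without_negative_feedback(self) -> "ParameterSet":
        """Copy with all three ERK-driven negative feedbacks switched off."""
        return self.replace(f_nf1=0.0, f_nf2=0.0, f_nf3=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reporters"] = {
            k: dataclasses.asdict(v) for k, v in self.reporters.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if "reporters" in d:
            d["reporters"] = {
                k: ReporterParams(**v) if not isinstance(v, ReporterParams) else v
                for k, v in d["reporters"].items()
            }
        return cls(**d)

    def digest(self) -> str:
        """Short stable hash of the parameter values (for output metadata)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_params() -> ParameterSet:
    """The calibrated default parameter set.

    Produced by the staged calibration in :mod:`mapkosc.calibrate`:
    the positive-feedback (RAS/SOS) module is placed in its bistable
    region, cascade rates give ERK activation within ~5-10 min of
    threshold crossing, the ERK-to-SOS feedback gives a period above
    one hour and an oscillatory dose range of roughly two decades, and
    ``egf_gain`` anchors the sustained-stimulation critical dose at
    2.5 pg/ml.
    """
    return ParameterSet()
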