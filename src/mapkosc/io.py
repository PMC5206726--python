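"""Configuration files, trajectory serialization and SBML export.

Parameter sets and stimulation protocols round-trip through YAML or
JSON (chosen by file extension).  Trajectories are written as CSV with
a commented metadata header (parameter digest, seed, package version,
and the full parameter set as JSON) or as a single JSON document;
numeric round-trips are lossless to double precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .deterministic import Trajectory
from .network import ReactionNetwork, build_network
from .params import ParameterSet
from .protocols import StimulationProtocol

__all__ = [
    "load_params", "save_params", "load_protocol", "save_protocol",
    "RunConfig", "load_config", "save_config",
    "write_trajectory", "read_trajectory",
    "export_sbml",
]


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def _dump_structured(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r}")


def load_params(path: str | Path) -> ParameterSet:
    return ParameterSet.from_dict(_load_structured(path))


def save_params(params: ParameterSet, path: str | Path) -> None:
    _dump_structured(params.to_dict(), path)


def load_protocol(path: str | Path) -> StimulationProtocol:
    return StimulationProtocol.from_dict(_load_structured(path))


def save_protocol(protocol: StimulationProtocol, path: str | Path) -> None:
    d = protocol.to_dict()
    for seg in d["segments"]:
        if math.isinf(seg["t_end"]):
            seg["t_end"] = "inf"
    _dump_structured(d, path)


@dataclasses.dataclass
class RunConfig:
    """Validated top-level run description for the CLI."""

    params: ParameterSet
    protocol: StimulationProtocol
    t_end: float = 3000.0
    seed: int = 0
    output: Optional[str] = None

    _KEYS = {"params", "protocol", "t_end", "seed", "output"}


def load_config(path: str | Path) -> RunConfig:
    data = _load_structured(path)
    unknown = set(data) - RunConfig._KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = ParameterSet.from_dict(data.get("params", {}))
    protocol = (StimulationProtocol.from_dict(data["protocol"])
                if "protocol" in data else StimulationProtocol.sustained(0.0))
    return RunConfig(
        params=params, protocol=protocol,
        t_end=float(data.get("t_end", 3000.0)),
        seed=int(data.get("seed", 0)),
        output=data.get("output"),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d: dict[str, Any] = {
        "params": cfg.params.to_dict(),
        "protocol": cfg.protocol.to_dict(),
        "t_end": cfg.t_end,
        "seed": cfg.seed,
    }
    for seg in d["protocol"]["segments"]:
        if math.isinf(seg["t_end"]):
            seg["t_end"] = "inf"
    if cfg.output is not None:
        d["output"] = cfg.output
    _dump_structured(d, path)


# ---------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------

def _derived_columns(traj: Trajectory) -> dict[str, np.ndarray]:
    cols = {
        "active_erk_fraction": traj.active_erk_fraction,
        "complex_total": traj.complex_total,
    }
    for rep in traj.params.reporters:
        cols[f"reporter_{rep}_fraction"] = traj.reporter_fraction(rep)
    return cols


def write_trajectory(traj: Trajectory, path: str | Path,
                     fmt: str = "csv", seed: Optional[int] = None) -> None:
    """Serialize a trajectory with its metadata header.

    CSV columns: time, every species, then the derived observables.
    """
    path = Path(path)
    meta = {
        "version": __version__,
        "params_digest": traj.params.digest(),
        "seed": seed,
        "params": traj.params.to_dict(),
    }
    derived = _derived_columns(traj)
    if fmt == "csv":
        lines = [f"# {json.dumps(meta)}"]
        header = ["time"] + traj.network.species + list(derived)
        lines.append(",".join(header))
        mat = np.column_stack([traj.t, traj.y] + list(derived.values()))
        for row in mat:
            lines.append(",".join(f"{v:.17g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        doc = {
            "meta": meta,
            "species": traj.network.species,
            "time": traj.t.tolist(),
            "state": traj.y.tolist(),
            "derived": {k: v.tolist() for k, v in derived.items()},
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path: str | Path) -> Trajectory:
    """Rebuild a trajectory (and its network) from a serialized file."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        params = ParameterSet.from_dict(doc["meta"]["params"])
        net = build_network(params)
        if doc["species"] != net.species:
            raise ValueError("species list does not match parameters")
        return Trajectory(t=np.asarray(doc["time"], float),
                          y=np.asarray(doc["state"], float), network=net)
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# "):
        raise ValueError(f"{path}: missing metadata header")
    meta = json.loads(lines[0][2:])
    params = ParameterSet.from_dict(meta["params"])
    net = build_network(params)
    header = lines[1].split(",")
    n_species = len(net.species)
    if header[1:1 + n_species] != net.species:
        raise ValueError("species columns do not match parameters")
    data = np.array([[float(v) for v in ln.split(",")]
                     for ln in lines[2:] if ln.strip()])
    if data.size == 0:
        raise ValueError(f"{path}: trajectory contains no samples")
    return Trajectory(t=data[:, 0], y=data[:, 1:1 + n_species], network=net)


# ---------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def export_sbml(params: ParameterSet,
                network: Optional[ReactionNetwork] = None) -> str:
    """SBML Level 3 Version 2 document with mass-action kinetic laws.

    One compartment; species initialized at the resting state; each
    reaction's kinetic law is rate_constant x reactants x modifiers
    (the EGF dose enters as a global parameter ``egf_dose``).  Intended
    for cross-validation of the network in external simulators.
    """
    from xml.etree import ElementTree as ET

    from .network import resting_state

    net = network if network is not None else build_network(params)
    x0 = resting_state(net)

    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml",
                      attrib={"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model",
                          attrib={"id": "mapk_erk_network",
                                  "name": "MAPK/ERK feedback network"})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment",
                  attrib={"id": "cell", "size": "1", "constant": "true",
                          "spatialDimensions": "3"})
    sp_list = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for name, init in zip(net.species, x0):
        ET.SubElement(sp_list, f"{{{_SBML_NS}}}species", attrib={
            "id": name, "compartment": "cell",
            "initialConcentration": f"{init:.17g}",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false", "constant": "false"})
    par_list = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    ET.SubElement(par_list, f"{{{_SBML_NS}}}parameter",
                  attrib={"id": "egf_dose", "value": "0", "constant": "true"})
    for rxn in net.reactions:
        ET.SubElement(par_list, f"{{{_SBML_NS}}}parameter", attrib={
            "id": f"k_{rxn.name}", "value": f"{rxn.rate_constant:.17g}",
            "constant": "true"})
    rx_list = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for rxn in net.reactions:
        rx = ET.SubElement(rx_list, f"{{{_SBML_NS}}}reaction",
                           attrib={"id": f"r_{rxn.name}",
                                   "reversible": "false"})
        if rxn.reactants:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for i in rxn.reactants:
                ET.SubElement(lo, f"{{{_SBML_NS}}}speciesReference",
                              attrib={"species": net.species[i],
                                      "stoichiometry": "1",
                                      "constant": "true"})
        if rxn.products:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for i in rxn.products:
                ET.SubElement(lo, f"{{{_SBML_NS}}}speciesReference",
                              attrib={"species": net.species[i],
                                      "stoichiometry": "1",
                                      "constant": "true"})
        if rxn.modifiers:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
            for i in rxn.modifiers:
                ET.SubElement(lo, f"{{{_SBML_NS}}}modifierSpeciesReference",
                              attrib={"species": net.species[i]})
        law = ET.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(law, f"{{{_MATHML_NS}}}math")
        apply_el = ET.SubElement(math_el, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{_MATHML_NS}}}times")
        factors = [f"k_{rxn.name}"]
        factors += ["egf_dose"] * rxn.dose_order
        factors += [net.species[i] for i in rxn.reactants + rxn.modifiers]
        for name in factors:
            ci = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}ci")
            ci.text = name
    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)
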