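"""Structure/trajectory readers, the analysis configuration, and result writers.

All coordinates are stored in nm, times in ps, masses in amu, energies in
kcal/mol.  PDB files (natively in Angstrom) are converted on read; mdtraj
handles the format plumbing underneath, the containers here are plain
dataclasses that the rest of the library consumes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import mdtraj as md
import mdtraj.core.element
import numpy as np
import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the molecular system.

    ``residue_number`` keeps the author numbering of the input file
    (antibody constant regions conventionally use EU numbering); PDB
    insertion codes are appended to it as a string key when present.
    """

    atom_index: int
    atom_name: str
    element: str
    mass: float
    chain_id: str
    residue_number: int
    residue_name: str
    insertion_code: str = ""

    @property
    def residue_key(self) -> str:
        """Residue number with insertion code, unique within a chain."""
        return f"{self.residue_number}{self.insertion_code}"

    @property
    def key(self) -> tuple[str, str, str]:
        """(chain, residue+icode, atom name): unique within a Topology."""
        return (self.chain_id, self.residue_key, self.atom_name)


@dataclass
class Topology:
    """Ordered atom table defining the molecular system."""

    atoms: list[AtomRecord]
    chains: list[str]

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise ValueError(
                    f"atom_index values must be 0..N-1 without gaps; "
                    f"atom {i} carries index {a.atom_index}"
                )
            if not a.mass > 0:
                raise ValueError(f"atom {i} ({a.atom_name}) has non-positive mass")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom identity {k} in topology")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def select(self, chain_id: str, residue_start: int, residue_end: int) -> np.ndarray:
        """Atom indices with the given chain whose residue number lies in
        the inclusive range [residue_start, residue_end]."""
        return np.array(
            [
                a.atom_index
                for a in self.atoms
                if a.chain_id == chain_id
                and residue_start <= a.residue_number <= residue_end
            ],
            dtype=int,
        )


@dataclass
class TrajectoryFrames:
    """F x N x 3 coordinates in nm with per-frame times in ps."""

    coordinates: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, N, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# mdtraj interop


def _to_mdtraj_topology(topology: Topology) -> md.Topology:
    mtop = md.Topology()
    chain_map: dict[str, object] = {}
    res_map: dict[tuple[str, str], object] = {}
    for a in topology.atoms:
        if a.chain_id not in chain_map:
            chain_map[a.chain_id] = mtop.add_chain(chain_id=a.chain_id)
        rkey = (a.chain_id, a.residue_key)
        if rkey not in res_map:
            res_map[rkey] = mtop.add_residue(
                a.residue_name, chain_map[a.chain_id], resSeq=a.residue_number
            )
        elem = md.core.element.Element.getBySymbol(a.element)
        mtop.add_atom(a.atom_name, elem, res_map[rkey])
    return mtop


def _from_mdtraj_topology(mtop: md.Topology) -> Topology:
    atoms: list[AtomRecord] = []
    chains: list[str] = []
    for atom in mtop.atoms:
        if atom.element is None or atom.element.symbol == "VS":
            raise ValueError(
                f"atom {atom.name} in residue {atom.residue.name}"
                f"{atom.residue.resSeq} has unknown element; cannot assign mass"
            )
        chain_id = atom.residue.chain.chain_id or chr(ord("A") + atom.residue.chain.index)
        if chain_id not in chains:
            chains.append(chain_id)
        icode = getattr(atom.residue, "insertion_code", "") or ""
        atoms.append(
            AtomRecord(
                atom_index=atom.index,
                atom_name=atom.name,
                element=atom.element.symbol,
                mass=float(atom.element.mass),
                chain_id=chain_id,
                residue_number=int(atom.residue.resSeq),
                residue_name=atom.residue.name,
                insertion_code=icode.strip(),
            )
        )
    return Topology(atoms=atoms, chains=chains)


# ---------------------------------------------------------------------------
# readers


def read_structure(path: str | os.PathLike) -> tuple[Topology, TrajectoryFrames]:
    """Read a PDB structure into a Topology plus a single-frame trajectory.

    Coordinates are converted from the PDB's Angstrom to nm.  Hydrogens
    are retained if present; masses come from the element of each atom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    traj = md.load_pdb(str(path), standard_names=False)
    if traj.n_atoms == 0:
        raise ValueError(f"no ATOM records found in {path}")
    topology = _from_mdtraj_topology(traj.topology)
    times = traj.time if traj.time is not None else np.zeros(traj.n_frames)
    frames = TrajectoryFrames(
        coordinates=traj.xyz[:1].astype(float),  # mdtraj already stores nm
        times=np.asarray(times[:1], dtype=float),
        topology=topology,
    )
    return topology, frames


def read_trajectory(path: str | os.PathLike, topology: Topology) -> TrajectoryFrames:
    """Read a DCD or XTC trajectory against a previously read Topology."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    mtop = _to_mdtraj_topology(topology)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        traj = md.load_dcd(str(path), top=mtop)
    elif suffix == ".xtc":
        traj = md.load_xtc(str(path), top=mtop)
    else:
        raise ValueError(f"unsupported trajectory format: {suffix} (use .dcd or .xtc)")
    if traj.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count {traj.n_atoms} does not match topology "
            f"atom count {topology.n_atoms}"
        )
    return TrajectoryFrames(
        coordinates=traj.xyz.astype(float),
        times=np.asarray(traj.time, dtype=float),
        topology=topology,
    )


def write_structure(path: str | os.PathLike, topology: Topology, frame: np.ndarray) -> None:
    """Write one frame (N x 3, nm) to a PDB file (emitted in Angstrom)."""
    mtop = _to_mdtraj_topology(topology)
    traj = md.Trajectory(np.asarray(frame, dtype=float)[None], mtop)
    traj.save_pdb(str(path))


def write_trajectory(path: str | os.PathLike, frames: TrajectoryFrames) -> None:
    """Write frames to DCD or XTC, chosen by file extension."""
    path = Path(path)
    mtop = _to_mdtraj_topology(frames.topology)
    traj = md.Trajectory(
        frames.coordinates.astype(np.float32), mtop, time=frames.times
    )
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        traj.save_dcd(str(path))
    elif suffix == ".xtc":
        traj.save_xtc(str(path))
    else:
        raise ValueError(f"unsupported trajectory format: {suffix} (use .dcd or .xtc)")


# ---------------------------------------------------------------------------
# configuration

#: analysis parameters and their defaults (hydrogen-bond geometric cutoffs,
#: occupancy/persistence thresholds, per-atom pulling force magnitude)
DEFAULT_PARAMETERS: dict[str, float | int] = {
    "hbond_distance_cutoff_nm": 0.25,
    "hbond_angle_cutoff_deg": 120.0,
    "occupancy_threshold": 0.80,
    "min_replicates": 2,
    "pulling_force_kcal_mol_nm": 0.01,
}

_KNOWN_TOP_KEYS = {"beads", "fragments", "parameters", "mode", "measures"}


@dataclass
class AnalysisConfig:
    """Validated configuration: bead definitions, extra fragment selections
    for atoms outside any bead (hinge, glycan, planted H-bond residues),
    measure specs and scalar parameters."""

    beads: list  # list[DomainDefinition]; typed loosely to avoid circular import
    fragments: dict[str, list[tuple[str, int, int]]]
    parameters: dict[str, float | int]
    measures: list | None = None
    mode: str = "antibody"


def read_config(path: str | os.PathLike) -> AnalysisConfig:
    """Read and validate the YAML analysis configuration.

    In antibody mode exactly six beads must be declared, each with one or
    more (chain, residue range) selections; selections may not overlap
    between beads.  Omitted parameters fall back to the standard cutoffs
    (H-A distance < 0.25 nm, D-H-A angle > 120 deg, occupancy > 0.80,
    per-atom pulling force 0.01 kcal/mol/nm).
    """
    from igdyn.domain_model import DomainDefinition, BEAD_LABELS
    from igdyn.geometry import MeasureSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    mode = raw.get("mode", "antibody")
    if mode not in ("antibody", "generic"):
        raise ValueError(f"mode must be 'antibody' or 'generic', got {mode!r}")

    beads_raw = raw.get("beads")
    if not beads_raw:
        raise ValueError("config must declare beads")
    beads = []
    for entry in beads_raw:
        unknown_b = set(entry) - {"id", "label", "selections"}
        if unknown_b:
            raise ValueError(f"unknown bead keys: {sorted(unknown_b)}")
        sels = [
            (str(s["chain"]), int(s["start"]), int(s["end"]))
            for s in entry["selections"]
        ]
        beads.append(
            DomainDefinition(
                bead_id=int(entry["id"]),
                label=str(entry.get("label", f"bead_{entry['id']}")),
                selections=sels,
            )
        )
    if mode == "antibody":
        ids = sorted(b.bead_id for b in beads)
        if ids != [1, 2, 3, 4, 5, 6]:
            raise ValueError(
                f"antibody mode requires beads with ids exactly 1..6, got {ids}"
            )
        labels = {b.label for b in beads}
        missing = set(BEAD_LABELS.values()) - labels
        if missing:
            raise ValueError(f"antibody mode is missing bead labels {sorted(missing)}")
    # pairwise range-overlap check per chain (atom-level disjointness is
    # re-validated against the topology in assign_beads)
    for i, a in enumerate(beads):
        for b in beads[i + 1 :]:
            for ca, sa, ea in a.selections:
                for cb, sb, eb in b.selections:
                    if ca == cb and sa <= eb and sb <= ea:
                        raise ValueError(
                            f"beads {a.bead_id} and {b.bead_id} both select "
                            f"chain {ca} residues [{max(sa, sb)}, {min(ea, eb)}]"
                        )
    for b in beads:
        if not b.selections:
            raise ValueError(f"bead {b.bead_id} has an empty selection")

    fragments_raw = raw.get("fragments", {}) or {}
    fragments = {
        str(label): [(str(s["chain"]), int(s["start"]), int(s["end"])) for s in sels]
        for label, sels in fragments_raw.items()
    }

    params = dict(DEFAULT_PARAMETERS)
    for k, v in (raw.get("parameters") or {}).items():
        if k not in DEFAULT_PARAMETERS:
            raise ValueError(f"unknown parameter {k!r}")
        params[k] = type(DEFAULT_PARAMETERS[k])(v)

    measures = None
    if raw.get("measures"):
        measures = [
            MeasureSpec(
                kind=m["kind"], bead_indices=tuple(m["beads"]), label=m["label"]
            )
            for m in raw["measures"]
        ]

    return AnalysisConfig(
        beads=beads, fragments=fragments, parameters=params, measures=measures, mode=mode
    )


# ---------------------------------------------------------------------------
# result writers


def write_results(
    tables: Mapping[str, "pd.DataFrame | dict"],
    out_dir: str | os.PathLike,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write analysis outputs: DataFrames to CSV, dicts to JSON, plus a
    run manifest recording parameters and seeds.  Column order and file
    contents are deterministic for identical inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            table.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(table, fh, indent=2, sort_keys=True, default=_json_default)
        written[name] = p
    if manifest is not None:
        p = out_dir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=_json_default)
        written["manifest"] = p
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
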