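"""Mapping atoms to the six antibody domain beads and the three fragments.

Bead numbering follows the Y-shaped coarse-graining of the antibody:
1: Fc CH3, 2: Fc CH2, 3: Fab1 CH1+CL, 4: Fab1 VH+VL, 5: Fab2 CH1+CL,
6: Fab2 VH+VL.  Fragments group beads: Fc = 1+2, Fab1 = 3+4, Fab2 = 5+6;
hinge and glycan atoms belong to no bead but carry a fragment label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from igdyn.trajectory_io import Topology, TrajectoryFrames

#: canonical bead labels in antibody mode
BEAD_LABELS: dict[int, str] = {
    1: "Fc_CH3",
    2: "Fc_CH2",
    3: "Fab1_CH1_CL",
    4: "Fab1_VH_VL",
    5: "Fab2_CH1_CL",
    6: "Fab2_VH_VL",
}

#: fragment each bead belongs to
BEAD_FRAGMENT: dict[int, str] = {1: "Fc", 2: "Fc", 3: "Fab1", 4: "Fab1", 5: "Fab2", 6: "Fab2"}

FRAGMENT_LABELS = ("Fc", "Fab1", "Fab2", "hinge", "other")

#: the 20 standard amino-acid residue names; glycan and other hetero
#: residues are never auto-assigned to beads
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class DomainDefinition:
    """One bead: an id, a label and inclusive (chain, start, end) residue
    ranges whose atoms constitute the bead."""

    bead_id: int
    label: str
    selections: list[tuple[str, int, int]]


@dataclass
class FragmentAssignment:
    """Per-atom fragment labels (Fc / Fab1 / Fab2 / hinge / other)."""

    labels: np.ndarray  # dtype=object strings, one per atom

    def atoms_of(self, fragment: str) -> np.ndarray:
        if fragment not in FRAGMENT_LABELS:
            raise ValueError(f"unknown fragment label {fragment!r}")
        return np.nonzero(self.labels == fragment)[0]


@dataclass
class BeadTrajectory:
    """Per-frame mass-weighted bead centers, F x B x 3 in nm."""

    centers: np.ndarray
    bead_ids: list[int]
    bead_masses: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("bead centers contain non-finite values")

    def series(self, bead_id: int) -> np.ndarray:
        """F x 3 center positions of one bead."""
        return self.centers[:, self.bead_ids.index(bead_id), :]


def assign_beads(
    topology: Topology,
    definitions: list[DomainDefinition],
    extra_fragments: dict[str, list[tuple[str, int, int]]] | None = None,
    mode: str = "antibody",
) -> tuple[dict[int, np.ndarray], FragmentAssignment]:
    """Resolve bead definitions against a topology.

    Returns the atom-index array per bead and a per-atom fragment
    assignment.  Atoms outside every bead get their fragment from
    ``extra_fragments`` selections (e.g. hinge residues, planted H-bond
    residues) or the label "other".  Glycan/hetero residues are skipped
    inside bead selections unless a bead selects only hetero atoms
    explicitly -- bead atoms must be amino-acid residues.
    """
    if mode == "antibody":
        ids = sorted(d.bead_id for d in definitions)
        if ids != [1, 2, 3, 4, 5, 6]:
            raise ValueError(f"antibody mode requires bead ids exactly 1..6, got {ids}")

    bead_map: dict[int, np.ndarray] = {}
    owner = np.full(topology.n_atoms, -1, dtype=int)
    for d in definitions:
        idx: list[int] = []
        for chain, start, end in d.selections:
            sel = topology.select(chain, start, end)
            sel = [i for i in sel if topology.atoms[i].residue_name in AMINO_ACIDS]
            idx.extend(sel)
        if not idx:
            raise ValueError(
                f"bead {d.bead_id} ({d.label}): selection matches zero atoms"
            )
        idx_arr = np.array(sorted(idx), dtype=int)
        clash = idx_arr[owner[idx_arr] >= 0]
        if clash.size:
            other = owner[clash[0]]
            raise ValueError(
                f"atom {clash[0]} is claimed by beads {other} and {d.bead_id}"
            )
        owner[idx_arr] = d.bead_id
        bead_map[d.bead_id] = idx_arr

    labels = np.array(["other"] * topology.n_atoms, dtype=object)
    for bead_id, idx in bead_map.items():
        labels[idx] = BEAD_FRAGMENT.get(bead_id, "other")
    for frag_label, sels in (extra_fragments or {}).items():
        if frag_label not in FRAGMENT_LABELS:
            raise ValueError(f"unknown fragment label {frag_label!r} in config")
        for chain, start, end in sels:
            for i in topology.select(chain, start, end):
                if owner[i] < 0:  # bead membership wins over extra selections
                    labels[i] = frag_label
    return bead_map, FragmentAssignment(labels=labels)


def center_of_mass(
    coordinates: np.ndarray, atom_subset: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Mass-weighted mean position of a subset of atoms in one frame (nm)."""
    atom_subset = np.asarray(atom_subset, dtype=int)
    if atom_subset.size == 0:
        raise ValueError("cannot compute center of mass of an empty atom subset")
    m = np.asarray(masses, dtype=float)[atom_subset]
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    x = np.asarray(coordinates, dtype=float)[atom_subset]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def compute_bead_trajectory(
    traj: TrajectoryFrames,
    bead_map: dict[int, np.ndarray],
    mass_weighted: bool = True,
) -> BeadTrajectory:
    """Per-frame centers of every bead.

    Centers are mass-weighted by default (the beads represent domain
    centers of mass); ``mass_weighted=False`` switches to geometric
    centers.
    """
    bead_ids = sorted(bead_map)
    masses = traj.topology.masses
    F = traj.n_frames
    centers = np.empty((F, len(bead_ids), 3))
    bead_masses = np.empty(len(bead_ids))
    for b, bead_id in enumerate(bead_ids):
        idx = np.asarray(bead_map[bead_id], dtype=int)
        if idx.size == 0:
            raise ValueError(f"bead {bead_id} has no atoms")
        m = masses[idx] if mass_weighted else np.ones(idx.size)
        w = m / m.sum()
        centers[:, b, :] = np.einsum("fak,a->fk", traj.coordinates[:, idx, :], w)
        bead_masses[b] = masses[idx].sum()
    return BeadTrajectory(centers=centers, bead_ids=bead_ids, bead_masses=bead_masses)


def fragment_com_series(
    traj: TrajectoryFrames, assignment: FragmentAssignment, fragment: str
) -> np.ndarray:
    """F x 3 mass-weighted center of one whole fragment over frames."""
    idx = assignment.atoms_of(fragment)
    if idx.size == 0:
        raise ValueError(f"fragment {fragment!r} has no atoms")
    m = traj.topology.masses[idx]
    w = m / m.sum()
    return np.einsum("fak,a->fk", traj.coordinates[:, idx, :], w)
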