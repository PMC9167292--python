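"""Constant-force pulling assay: force specification, rupture detection,
and external-work bookkeeping.

The assay applies a constant per-atom force +f*r_hat to every Fab2 atom
and -f*r_hat to every Fc atom, where r_hat is the unit vector from the
Fc center of mass to the Fab2 center of mass in the initial frame.  The
external work between two structures is endpoint-based:

    W = sum_i f_Fab2 (R_i . r_hat) - sum_j f_Fc (R_j . r_hat)

with R_i the raw displacement of atom i between the end and start frames
(no superposition is applied, so W is frame-of-reference sensitive; this
is recorded in the run manifest).  Per-atom force magnitudes are equal by
default, so net group forces are unbalanced when atom counts differ; the
resulting center-of-mass drift is accepted, not corrected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from igdyn.domain_model import FragmentAssignment, center_of_mass, fragment_com_series
from igdyn.trajectory_io import Topology, TrajectoryFrames


@dataclass
class PullingSpec:
    group_fc: np.ndarray      # atom indices
    group_fab2: np.ndarray
    f_fc: float               # per-atom magnitudes, kcal/mol/nm
    f_fab2: float
    r_hat: np.ndarray         # unit vector COM(Fc) -> COM(Fab2), initial frame

    def __post_init__(self) -> None:
        self.group_fc = np.asarray(self.group_fc, dtype=int)
        self.group_fab2 = np.asarray(self.group_fab2, dtype=int)
        self.r_hat = np.asarray(self.r_hat, dtype=float)
        if self.f_fc < 0 or self.f_fab2 < 0:
            raise ValueError("force magnitudes must be >= 0")
        if np.intersect1d(self.group_fc, self.group_fab2).size:
            raise ValueError("Fc and Fab2 atom groups must be disjoint")
        if not np.isclose(np.linalg.norm(self.r_hat), 1.0, atol=1e-9):
            raise ValueError("r_hat must be a unit vector")


@dataclass
class WorkResult:
    W: float                  # kcal/mol
    fab2_term: float
    fc_term: float
    frame_start: int
    frame_end: int


def build_pulling_spec(
    topology: Topology,
    fragment_assignment: FragmentAssignment,
    initial_frame: np.ndarray,
    f: float = 0.01,
) -> PullingSpec:
    """Pulling specification from the fragment assignment and the initial
    structure: r_hat from the mass-weighted Fc COM to the Fab2 COM."""
    fc = fragment_assignment.atoms_of("Fc")
    fab2 = fragment_assignment.atoms_of("Fab2")
    if fc.size == 0 or fab2.size == 0:
        raise ValueError("both Fc and Fab2 fragments must be non-empty")
    masses = topology.masses
    com_fc = center_of_mass(initial_frame, fc, masses)
    com_fab2 = center_of_mass(initial_frame, fab2, masses)
    r = com_fab2 - com_fc
    norm = np.linalg.norm(r)
    if norm < 1e-12:
        raise ValueError("Fc and Fab2 centers of mass coincide; r_hat undefined")
    return PullingSpec(
        group_fc=fc, group_fab2=fab2, f_fc=f, f_fab2=f, r_hat=r / norm
    )


def export_force_table(spec: PullingSpec) -> pd.DataFrame:
    """Per-atom constant force vectors (kcal/mol/nm) for an external MD
    engine; atoms outside both groups are absent."""
    rows = []
    for i in spec.group_fab2:
        fv = spec.f_fab2 * spec.r_hat
        rows.append((int(i), fv[0], fv[1], fv[2]))
    for j in spec.group_fc:
        fv = -spec.f_fc * spec.r_hat
        rows.append((int(j), fv[0], fv[1], fv[2]))
    df = pd.DataFrame(rows, columns=["atom_index", "fx", "fy", "fz"])
    return df.sort_values("atom_index").reset_index(drop=True)


def read_force_table(source: str | io.IOBase) -> pd.DataFrame:
    df = pd.read_csv(source)
    expected = ["atom_index", "fx", "fy", "fz"]
    if list(df.columns) != expected:
        raise ValueError(f"force table must have columns {expected}")
    return df


def compute_work(
    frame_start: np.ndarray,
    frame_end: np.ndarray,
    spec: PullingSpec,
    frame_start_index: int = 0,
    frame_end_index: int = -1,
) -> WorkResult:
    """Endpoint external work between two frames of the same topology."""
    frame_start = np.asarray(frame_start, dtype=float)
    frame_end = np.asarray(frame_end, dtype=float)
    if frame_start.shape != frame_end.shape:
        raise ValueError("start and end frames have mismatched atom counts")
    disp = frame_end - frame_start
    fab2_term = float(spec.f_fab2 * (disp[spec.group_fab2] @ spec.r_hat).sum())
    fc_term = float(spec.f_fc * (disp[spec.group_fc] @ spec.r_hat).sum())
    return WorkResult(
        W=fab2_term - fc_term,
        fab2_term=fab2_term,
        fc_term=fc_term,
        frame_start=frame_start_index,
        frame_end=frame_end_index,
    )


def path_integrated_work(
    traj_coordinates: np.ndarray, spec: PullingSpec
) -> float:
    """Sum of endpoint work over successive frames.  For a constant force
    field this telescopes to the endpoint value; provided for dense toy
    trajectories where intermediate bookkeeping is wanted."""
    X = np.asarray(traj_coordinates, dtype=float)
    total = 0.0
    for f in range(X.shape[0] - 1):
        w = compute_work(X[f], X[f + 1], spec, f, f + 1)
        total += w.W
    return total


def per_atom_work_table(
    frame_start: np.ndarray, frame_end: np.ndarray, spec: PullingSpec
) -> pd.DataFrame:
    """Per-atom contributions to W (kcal/mol), for the pull-work export."""
    disp = np.asarray(frame_end, dtype=float) - np.asarray(frame_start, dtype=float)
    rows = []
    for i in spec.group_fab2:
        rows.append((int(i), "Fab2", float(spec.f_fab2 * (disp[i] @ spec.r_hat))))
    for j in spec.group_fc:
        rows.append((int(j), "Fc", float(-spec.f_fc * (disp[j] @ spec.r_hat))))
    return pd.DataFrame(rows, columns=["atom_index", "group", "work_kcal_mol"])


def detect_rupture(
    bond_count_series: np.ndarray, sustain_frames: int = 1
) -> int | None:
    """First frame f where the bound-bond count stays zero for
    ``sustain_frames`` consecutive frames; None if never.  Transient
    rebinding shorter than the sustain window postpones rupture."""
    if sustain_frames < 1:
        raise ValueError("sustain_frames must be >= 1")
    counts = np.asarray(bond_count_series)
    F = counts.shape[0]
    zero = counts == 0
    f = 0
    while f < F:
        if zero[f]:
            g = f
            while g < F and zero[g]:
                g += 1
            if g - f >= sustain_frames:
                return f
            f = g
        else:
            f += 1
    return None


def com_separation_series(
    traj: TrajectoryFrames,
    fragment_assignment: FragmentAssignment,
    fragment_a: str = "Fc",
    fragment_b: str = "Fab2",
) -> np.ndarray:
    """Per-frame distance (nm) between two whole-fragment mass-weighted
    centers (not bead centers)."""
    ca = fragment_com_series(traj, fragment_assignment, fragment_a)
    cb = fragment_com_series(traj, fragment_assignment, fragment_b)
    return np.linalg.norm(cb - ca, axis=1)
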