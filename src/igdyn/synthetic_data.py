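"""Ground-truth synthetic antibody systems for testing the pipeline.

Three generators:

* an antibody-like topology: six rigid domains (one chain per fragment,
  one CA pseudo-atom per residue), hinge linker atoms, and optional
  donor-H-acceptor triads for hydrogen-bond tests;
* a rigid-motion trajectory built from per-frame internal coordinates
  (the nine bead measures) sampled from configurable normals and
  realized *exactly* by z-matrix construction, so the planted values are
  the ground truth, not approximate targets;
* an overdamped Langevin toy bead system with harmonic springs, a
  breakable truncated-harmonic attraction, and either a constant
  external force (the pulling assay) or a moving stiff harmonic trap on
  an inter-bead distance (for work/free-energy comparisons), with a
  per-step work ledger.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from igdyn.domain_model import DomainDefinition, BEAD_LABELS
from igdyn.trajectory_io import AnalysisConfig, AtomRecord, Topology, TrajectoryFrames, DEFAULT_PARAMETERS

#: 1 kcal/mol expressed in amu nm^2 / ps^2 (the MD-internal energy unit)
KCAL_PER_MOL = 4.184

_ELEMENT_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008}

#: chain hosting each fragment in the synthetic layout
FRAGMENT_CHAIN = {"Fc": "A", "Fab1": "B", "Fab2": "C"}

#: default fluctuation model: (mean, sd) per measure.  Scales mirror an
#: asymmetric IgG1: Fab1 measures broad (R_23 ~ 5-7 nm, theta_123 sd 10
#: deg), Fab2 tightly constrained (R_25 ~ 3.5 nm, theta_125 sd 3 deg).
DEFAULT_FLUCTUATIONS: dict[str, tuple[float, float]] = {
    "R_12": (2.5, 0.05),
    "R_23": (6.0, 0.5),
    "R_25": (3.5, 0.08),
    "theta_123": (120.0, 10.0),
    "theta_125": (60.0, 3.0),
    "Theta_1234": (90.0, 15.0),
    "Theta_1256": (90.0, 4.0),
    "R_34": (3.0, 0.1),
    "R_56": (3.0, 0.1),
}

#: fixed auxiliary internal angles (deg) closing the z-matrix
_ANGLE_234 = 150.0
_ANGLE_256 = 150.0


@dataclass
class HBondTriadSpec:
    """One planted donor(N)-H ... acceptor(O) triad between fragments."""

    donor_fragment: str = "Fab2"
    acceptor_fragment: str = "Fc"


@dataclass
class SyntheticAntibodySpec:
    seed: int
    atoms_per_domain: int = 10
    n_frames: int = 1000
    fluctuations: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FLUCTUATIONS)
    )
    hbond_triads: list[HBondTriadSpec] = field(default_factory=list)
    hinge_atoms: int = 3
    domain_radius: float = 0.4  # nm, half-extent of the rigid atom cloud

    def __post_init__(self) -> None:
        if self.atoms_per_domain < 3:
            raise ValueError("atoms_per_domain must be >= 3")
        if self.atoms_per_domain > 100:
            raise ValueError("atoms_per_domain must be <= 100 (residue layout)")
        for label, (_, sd) in self.fluctuations.items():
            if sd < 0:
                raise ValueError(f"negative sd for measure {label}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class SyntheticAntibody:
    """Built topology plus everything needed to generate trajectories."""

    spec: SyntheticAntibodySpec
    topology: Topology
    frame0: np.ndarray                     # N x 3 nm
    config: AnalysisConfig
    domain_atoms: dict[int, np.ndarray]    # bead id -> atom indices
    domain_clouds: dict[int, np.ndarray]   # bead id -> local offsets (COM 0)
    hinge_atoms: np.ndarray
    triads: list[tuple[int, int, int]]     # (N, H, O) atom indices
    triad_bases: np.ndarray                # T x 3 donor base positions
    template_centers: np.ndarray           # 6 x 3 bead rest positions


# ---------------------------------------------------------------------------
# z-matrix construction of the six bead centers


def _place_nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place point d given chain a-b-c, |c-d|, angle(b,c,d), dihedral(a,b,c,d)
    under the right-hand-rule sign convention."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("degenerate z-matrix chain (collinear a, b, c)")
    n = n / nn
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bead_centers_from_measures(measures: dict[str, float]) -> np.ndarray:
    """Exact 6 x 3 bead centers realizing the nine measure values.

    Construction: bead 1 at the origin, bead 2 along +z at R_12; bead 3
    in the xz-plane at (R_23, theta_123) from bead 2; bead 5 mirrored on
    the -x side at (R_25, theta_125); beads 4 and 6 by z-matrix placement
    with fixed auxiliary angles and the planted dihedrals Theta_1234,
    Theta_1256.  Raises for angles outside (0, 180).
    """
    for lab in ("theta_123", "theta_125"):
        if not 0.0 < measures[lab] < 180.0:
            raise ValueError(
                f"unsatisfiable geometry: {lab} = {measures[lab]:.2f} deg "
                "outside (0, 180)"
            )
    for lab in ("R_12", "R_23", "R_25", "R_34", "R_56"):
        if measures[lab] <= 0:
            raise ValueError(f"unsatisfiable geometry: {lab} <= 0")
    p1 = np.zeros(3)
    p2 = np.array([0.0, 0.0, measures["R_12"]])
    u = (p1 - p2) / measures["R_12"]  # unit vector bead2 -> bead1
    t123 = np.radians(measures["theta_123"])
    t125 = np.radians(measures["theta_125"])
    x_hat = np.array([1.0, 0.0, 0.0])
    p3 = p2 + measures["R_23"] * (np.cos(t123) * u + np.sin(t123) * x_hat)
    p5 = p2 + measures["R_25"] * (np.cos(t125) * u + np.sin(t125) * (-x_hat))
    p4 = _place_nerf(p1, p2, p3, measures["R_34"], _ANGLE_234, measures["Theta_1234"])
    p6 = _place_nerf(p1, p2, p5, measures["R_56"], _ANGLE_256, measures["Theta_1256"])
    return np.stack([p1, p2, p3, p4, p5, p6])


# ---------------------------------------------------------------------------
# topology construction


def build_synthetic_topology(
    spec: SyntheticAntibodySpec,
) -> SyntheticAntibody:
    """Six labeled rigid domains on three chains (A: Fc, B: Fab1, C:
    Fab2), hinge linker atoms, and the requested H-bond triads with the
    hydrogen placed 0.10 nm from its donor.

    Each domain holds ``atoms_per_domain`` CA pseudo-atoms (one per
    residue) in a rigid cloud whose centroid coincides exactly with the
    template bead center, so frame-0 bead centers of mass equal the rest
    positions by construction.
    """
    rng = np.random.default_rng(spec.seed)
    means = {k: v[0] for k, v in spec.fluctuations.items()}
    for k, v in DEFAULT_FLUCTUATIONS.items():
        means.setdefault(k, v[0])
    template = bead_centers_from_measures(means)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    domain_atoms: dict[int, list[int]] = {b: [] for b in range(1, 7)}
    domain_clouds: dict[int, np.ndarray] = {}
    hinge_idx: list[int] = []
    triads: list[tuple[int, int, int]] = []

    def add_atom(name, element, chain, resnum, resname, xyz) -> int:
        i = len(atoms)
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element=element,
                mass=_ELEMENT_MASS[element],
                chain_id=chain,
                residue_number=resnum,
                residue_name=resname,
            )
        )
        coords.append(np.asarray(xyz, dtype=float))
        return i

    # bead id -> (chain, residue offset): residues 1..n and 101..100+n
    layout = {1: ("A", 0), 2: ("A", 100), 3: ("B", 0), 4: ("B", 100),
              5: ("C", 0), 6: ("C", 100)}
    chain_order = {"A": [1, 2], "B": [3, 4], "C": [5, 6]}

    # triad base positions: grid with 1.2 nm spacing, displaced well away
    # from the domain region so planted geometries never collide
    n_triads = len(spec.hbond_triads)
    side = max(int(np.ceil(n_triads ** (1.0 / 3.0))), 1)
    grid = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                grid.append(np.array([30.0 + 1.2 * ix, 1.2 * iy, 1.2 * iz]))
    triad_bases = np.array(grid[:n_triads]) if n_triads else np.zeros((0, 3))

    triads_by_chain: dict[str, list[tuple[int, HBondTriadSpec]]] = {
        "A": [], "B": [], "C": []
    }
    for t, tr in enumerate(spec.hbond_triads):
        triads_by_chain[FRAGMENT_CHAIN[tr.donor_fragment]].append((t, tr))
    triad_atoms: dict[int, dict[str, int]] = {t: {} for t in range(n_triads)}

    for chain in ("A", "B", "C"):
        for bead in chain_order[chain]:
            _, offset = layout[bead]
            cloud = rng.uniform(
                -spec.domain_radius, spec.domain_radius, size=(spec.atoms_per_domain, 3)
            )
            cloud -= cloud.mean(axis=0)  # exact zero centroid (equal masses)
            domain_clouds[bead] = cloud
            for r in range(spec.atoms_per_domain):
                i = add_atom(
                    "CA", "C", chain, offset + r + 1, "GLY",
                    template[bead - 1] + cloud[r],
                )
                domain_atoms[bead].append(i)
        if chain == "A":
            # hinge linker atoms sit between the Fc CH2 bead and the Fab
            # attachment points; rigidly tied to bead 2
            for h in range(spec.hinge_atoms):
                i = add_atom(
                    "CA", "C", "A", 500 + h, "GLY",
                    template[1] + np.array([0.3 * (h + 1), 0.0, 0.5]),
                )
                hinge_idx.append(i)
        # donor residues (N + H) for triads whose donor lives on this chain
        for t, tr in triads_by_chain[chain]:
            base = triad_bases[t]
            n_i = add_atom("N", "N", chain, 2001 + t, "ARG", base)
            h_i = add_atom("H", "H", chain, 2001 + t, "ARG",
                           base + np.array([0.10, 0.0, 0.0]))
            triad_atoms[t]["N"] = n_i
            triad_atoms[t]["H"] = h_i
        # acceptor residues (O) for triads whose acceptor lives here
        for t, tr in enumerate(spec.hbond_triads):
            if FRAGMENT_CHAIN[tr.acceptor_fragment] != chain:
                continue
            # bound-state geometry at frame 0 (H-A 0.20 nm, D-H-A 160 deg)
            o_pos = _acceptor_position(triad_bases[t], 0.20)
            o_i = add_atom("O", "O", chain, 3001 + t, "GLU", o_pos)
            triad_atoms[t]["O"] = o_i

    triads = [
        (triad_atoms[t]["N"], triad_atoms[t]["H"], triad_atoms[t]["O"])
        for t in range(n_triads)
    ]

    topology = Topology(atoms=atoms, chains=["A", "B", "C"])
    frame0 = np.array(coords)

    bead_defs = [
        DomainDefinition(
            bead_id=b,
            label=BEAD_LABELS[b],
            selections=[(layout[b][0], layout[b][1] + 1, layout[b][1] + 100)],
        )
        for b in range(1, 7)
    ]
    fragments = {
        "hinge": [("A", 500, 599)],
        "Fc": [("A", 2001, 3999)],
        "Fab1": [("B", 2001, 3999)],
        "Fab2": [("C", 2001, 3999)],
    }
    config = AnalysisConfig(
        beads=bead_defs,
        fragments=fragments,
        parameters=dict(DEFAULT_PARAMETERS),
        mode="antibody",
    )
    return SyntheticAntibody(
        spec=spec,
        topology=topology,
        frame0=frame0,
        config=config,
        domain_atoms={b: np.array(v, dtype=int) for b, v in domain_atoms.items()},
        domain_clouds=domain_clouds,
        hinge_atoms=np.array(hinge_idx, dtype=int),
        triads=triads,
        triad_bases=triad_bases,
        template_centers=template,
    )


def _acceptor_position(base: np.ndarray, ha_distance: float) -> np.ndarray:
    """Acceptor position giving D-H-A = 160 deg for a donor at ``base``
    with its hydrogen at base + 0.10 x_hat."""
    h = base + np.array([0.10, 0.0, 0.0])
    ang = np.radians(160.0)
    # direction from H with angle 160 deg to the H->N direction (-x)
    u = np.cos(ang) * np.array([-1.0, 0.0, 0.0]) + np.sin(ang) * np.array([0.0, 1.0, 0.0])
    return h + ha_distance * u


# ---------------------------------------------------------------------------
# rigid-motion trajectory


def generate_rigid_motion_trajectory(
    antibody: SyntheticAntibody,
    n_frames: int | None = None,
    seed: int | None = None,
    schedules: np.ndarray | None = None,
) -> tuple[TrajectoryFrames, pd.DataFrame]:
    """Trajectory with per-frame measures drawn from the fluctuation
    model and realized exactly; returns the frames plus the ground-truth
    measure table.

    ``schedules`` (T x F boolean) optionally plants the bound/unbound
    state of every triad per frame.  Domains move as rigid bodies
    (translation of the fixed cloud to the sampled bead center); hinge
    atoms follow bead 2.
    """
    spec = antibody.spec
    F = spec.n_frames if n_frames is None else n_frames
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = list(DEFAULT_FLUCTUATIONS)
    fluct = {k: spec.fluctuations.get(k, DEFAULT_FLUCTUATIONS[k]) for k in labels}
    sampled = {
        k: rng.normal(fluct[k][0], fluct[k][1], size=F) if fluct[k][1] > 0
        else np.full(F, fluct[k][0])
        for k in labels
    }
    N = antibody.topology.n_atoms
    X = np.empty((F, N, 3))
    # static atoms default to their frame-0 positions
    X[:] = antibody.frame0[None]
    for f in range(F):
        centers = bead_centers_from_measures({k: sampled[k][f] for k in labels})
        for b in range(1, 7):
            idx = antibody.domain_atoms[b]
            X[f, idx] = centers[b - 1] + antibody.domain_clouds[b]
        if antibody.hinge_atoms.size:
            shift = centers[1] - antibody.template_centers[1]
            X[f, antibody.hinge_atoms] = antibody.frame0[antibody.hinge_atoms] + shift
    traj = TrajectoryFrames(
        coordinates=X, times=np.arange(F, dtype=float), topology=antibody.topology
    )
    if schedules is not None:
        schedules = np.asarray(schedules, dtype=bool)
        if schedules.shape != (len(antibody.triads), F):
            raise ValueError("schedules must have shape (n_triads, n_frames)")
        for t, triad in enumerate(antibody.triads):
            plant_hbond_schedule(
                traj, triad, schedules[t], base=antibody.triad_bases[t]
            )
    truth = pd.DataFrame({"frame": np.arange(F), **sampled})
    return traj, truth


def plant_hbond_schedule(
    traj: TrajectoryFrames,
    triad: tuple[int, int, int],
    schedule: np.ndarray,
    base: np.ndarray | None = None,
) -> TrajectoryFrames:
    """Overwrite one triad's geometry per frame: bound frames get
    H-A = 0.20 nm with D-H-A = 160 deg, unbound frames H-A = 0.40 nm;
    all other atoms are untouched.  Modifies ``traj`` in place and
    returns it."""
    n_i, h_i, o_i = triad
    for idx in triad:
        if not 0 <= idx < traj.n_atoms:
            raise ValueError(f"triad atom index {idx} outside topology")
    schedule = np.asarray(schedule, dtype=bool)
    if schedule.shape[0] != traj.n_frames:
        raise ValueError(
            f"schedule length {schedule.shape[0]} != n_frames {traj.n_frames}"
        )
    if base is None:
        base = traj.coordinates[0, n_i]
    base = np.asarray(base, dtype=float)
    h_pos = base + np.array([0.10, 0.0, 0.0])
    bound_o = _acceptor_position(base, 0.20)
    unbound_o = _acceptor_position(base, 0.40)
    traj.coordinates[:, n_i] = base
    traj.coordinates[:, h_i] = h_pos
    traj.coordinates[schedule, o_i] = bound_o
    traj.coordinates[~schedule, o_i] = unbound_o
    return traj


def make_schedule(
    n_frames: int,
    occupancy: float,
    rng: np.random.Generator | None = None,
    style: str = "prefix",
) -> np.ndarray:
    """Boolean schedule with exactly round(occupancy * n_frames) bound
    frames, either as a leading block ("prefix") or randomly placed."""
    k = int(round(occupancy * n_frames))
    k = min(max(k, 0), n_frames)
    sched = np.zeros(n_frames, dtype=bool)
    if style == "prefix":
        sched[:k] = True
    elif style == "random":
        if rng is None:
            raise ValueError("random style requires an rng")
        sched[rng.choice(n_frames, size=k, replace=False)] = True
    else:
        raise ValueError(f"unknown schedule style {style!r}")
    return sched


# ---------------------------------------------------------------------------
# overdamped Langevin toy system


@dataclass
class BreakableWell:
    """Truncated shifted harmonic attraction between beads i and j:
    U(r) = -eps * (1 - ((r - r0)/width)^2) for |r - r0| <= width, else 0.
    Continuous at the cutoff; maximum restoring force 2*eps/width."""

    i: int
    j: int
    epsilon: float  # kcal/mol
    r0: float       # nm
    width: float    # nm

    def energy(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        x = (r - self.r0) / self.width
        return np.where(np.abs(x) <= 1.0, -self.epsilon * (1.0 - x**2), 0.0)

    def dU_dr(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        x = (r - self.r0) / self.width
        return np.where(
            np.abs(x) <= 1.0, 2.0 * self.epsilon * x / self.width, 0.0
        )

    @property
    def max_restoring_force(self) -> float:
        return 2.0 * self.epsilon / self.width


@dataclass
class TrapProtocol:
    """Stiff harmonic trap k/2 (r_ij - lambda(t))^2 whose center moves
    linearly from lam0 to lam1 over the run (constant-velocity pulling)."""

    i: int
    j: int
    k: float     # kcal/mol/nm^2
    lam0: float  # nm
    lam1: float  # nm


@dataclass
class ToyLangevinSpec:
    masses: np.ndarray            # amu
    friction: float               # 1/ps
    kT: float                     # kcal/mol
    timestep: float               # ps
    n_steps: int
    initial_positions: np.ndarray  # n_beads x dim, nm
    springs: list[tuple[int, int, float, float]] = field(default_factory=list)
    tethers: list[tuple[int, float, np.ndarray]] = field(default_factory=list)
    well: BreakableWell | None = None
    external_forces: np.ndarray | None = None  # n_beads x dim, kcal/mol/nm
    trap: TrapProtocol | None = None
    divergence_bound: float = 1e3  # nm

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.initial_positions = np.asarray(self.initial_positions, dtype=float)
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")
        if self.kT < 0:
            raise ValueError("kT must be >= 0")


@dataclass
class LangevinResult:
    positions: np.ndarray     # n_replicas x n_recorded x n_beads x dim
    times: np.ndarray         # ps
    work_external: np.ndarray  # n_replicas: sum F_ext . dx ledger
    work_protocol: np.ndarray  # n_replicas: trap (Jarzynski) work


def run_langevin(
    spec: ToyLangevinSpec,
    seed: int,
    n_replicas: int = 1,
    record_stride: int = 1,
) -> LangevinResult:
    """Overdamped (inertialess) Langevin integration, vectorized over
    independent replicas.

    Update: x += mu F dt + sqrt(2 mu kT dt) eta, with per-bead mobility
    mu = 1/(friction * mass).  Forces are evaluated in kcal/mol/nm and
    converted internally to amu nm/ps^2.  The ledger accumulates
    sum F_ext . dx for the constant external force and the protocol work
    sum [V(x, lam_new) - V(x, lam_old)] for the moving trap.
    """
    rng = np.random.default_rng(seed)
    n_beads, dim = spec.initial_positions.shape
    mu = 1.0 / (spec.friction * spec.masses)  # ps/amu, per bead
    dt = spec.timestep
    x = np.broadcast_to(
        spec.initial_positions, (n_replicas, n_beads, dim)
    ).astype(float).copy()
    noise_scale = np.sqrt(2.0 * mu * spec.kT * KCAL_PER_MOL * dt)  # per bead, nm

    lam_step = None
    lam = None
    if spec.trap is not None:
        lam = spec.trap.lam0
        lam_step = (spec.trap.lam1 - spec.trap.lam0) / spec.n_steps

    n_rec = spec.n_steps // record_stride + 1
    out = np.empty((n_replicas, n_rec, n_beads, dim))
    out[:, 0] = x
    times = np.empty(n_rec)
    times[0] = 0.0
    w_ext = np.zeros(n_replicas)
    w_prot = np.zeros(n_replicas)
    rec = 1

    f_ext = None
    if spec.external_forces is not None:
        f_ext = np.asarray(spec.external_forces, dtype=float)

    for step in range(spec.n_steps):
        if spec.trap is not None:
            # move the trap first and book the protocol work at fixed x
            r = _pair_distance(x, spec.trap.i, spec.trap.j)
            lam_new = lam + lam_step
            w_prot += 0.5 * spec.trap.k * ((r - lam_new) ** 2 - (r - lam) ** 2)
            lam = lam_new
        F = _forces(x, spec, lam)
        if f_ext is not None:
            F = F + f_ext[None]
        drift = mu[None, :, None] * (F * KCAL_PER_MOL) * dt
        kick = noise_scale[None, :, None] * rng.standard_normal(x.shape) \
            if spec.kT > 0 else 0.0
        dx = drift + kick
        x = x + dx
        if np.any(np.abs(x) > spec.divergence_bound):
            raise RuntimeError(f"trajectory diverged at step {step}")
        if f_ext is not None:
            w_ext += np.einsum("rbd,bd->r", dx, f_ext)
        if (step + 1) % record_stride == 0:
            out[:, rec] = x
            times[rec] = (step + 1) * dt
            rec += 1
    return LangevinResult(
        positions=out[:, :rec],
        times=times[:rec],
        work_external=w_ext,
        work_protocol=w_prot,
    )


def _pair_distance(x: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(x[:, j] - x[:, i], axis=-1)


def _forces(x: np.ndarray, spec: ToyLangevinSpec, lam: float | None) -> np.ndarray:
    """Total conservative force (kcal/mol/nm) on every bead, batched over
    replicas."""
    F = np.zeros_like(x)
    for i, j, k, r0 in spec.springs:
        rij = x[:, j] - x[:, i]
        r = np.linalg.norm(rij, axis=-1, keepdims=True)
        r = np.maximum(r, 1e-12)
        f = k * (r - r0) * (rij / r)  # pulls i toward j when stretched
        F[:, i] += f
        F[:, j] -= f
    for i, k, point in spec.tethers:
        d = x[:, i] - np.asarray(point, dtype=float)[None]
        F[:, i] -= k * d
    if spec.well is not None:
        i, j = spec.well.i, spec.well.j
        rij = x[:, j] - x[:, i]
        r = np.maximum(np.linalg.norm(rij, axis=-1, keepdims=True), 1e-12)
        mag = spec.well.dU_dr(r)  # dU/dr > 0 outside r0: attraction
        f = mag * (rij / r)
        F[:, i] += f
        F[:, j] -= f
    if spec.trap is not None and lam is not None:
        i, j = spec.trap.i, spec.trap.j
        rij = x[:, j] - x[:, i]
        r = np.maximum(np.linalg.norm(rij, axis=-1, keepdims=True), 1e-12)
        f = spec.trap.k * (r - lam) * (rij / r)
        F[:, i] += f
        F[:, j] -= f
    return F


# ---------------------------------------------------------------------------
# analytic free energy of the toy pulling coordinate


@dataclass
class ToyFreeEnergy:
    delta_f: float  # kcal/mol
    f_start: float
    f_end: float


def trap_free_energy(
    well: BreakableWell | None,
    kT: float,
    trap_k: float,
    lam: float,
    dim: int = 1,
    r_max: float = 50.0,
) -> float:
    """F(lambda) = -kT ln Z(lambda) of the pulling coordinate r > 0 under
    well + trap, by quadrature.  ``dim`` sets the Jacobian r^(dim-1) of
    the relative coordinate (1 for a collinear toy, 3 for free 3-D
    beads)."""
    if kT <= 0:
        raise ValueError("quadrature requires kT > 0")
    beta = 1.0 / kT

    def integrand(r: float) -> float:
        u = 0.5 * trap_k * (r - lam) ** 2
        if well is not None:
            u += float(well.energy(r))
        return r ** (dim - 1) * np.exp(-beta * u)

    # the integrand is concentrated near the trap center (width
    # sqrt(kT/k)) and possibly inside the well; integrate over a window
    # covering both, with breakpoints at the well edges
    sigma = np.sqrt(kT / trap_k)
    lo, hi = lam - 12 * sigma, lam + 12 * sigma
    points = []
    if well is not None:
        lo = min(lo, well.r0 - well.width - 12 * sigma)
        hi = max(hi, well.r0 + well.width + 12 * sigma)
        points = [well.r0 - well.width, well.r0, well.r0 + well.width]
    lo = max(lo, 0.0)
    hi = min(hi, r_max)
    points = [p for p in points if lo < p < hi]
    z, err = integrate.quad(integrand, lo, hi, limit=400, points=points or None)
    if not np.isfinite(z) or z <= 0 or err > 1e-6 * z:
        raise RuntimeError("non-convergent partition-function quadrature")
    return -kT * np.log(z)


def analytic_delta_f(
    well: BreakableWell | None,
    kT: float,
    trap_k: float,
    lam0: float,
    lam1: float,
    dim: int = 1,
) -> ToyFreeEnergy:
    """Free-energy difference of the trapped pulling coordinate between
    the bound (trap at lam0, inside the well) and released (trap at lam1,
    beyond the cutoff) states: Delta F = -kT ln(Z(lam1)/Z(lam0)).

    For eps = 0 the trap integral is translation invariant (dim = 1) and
    Delta F = 0; for a deep well and kT -> 0, Delta F -> eps.
    """
    f0 = trap_free_energy(well, kT, trap_k, lam0, dim=dim)
    f1 = trap_free_energy(well, kT, trap_k, lam1, dim=dim)
    return ToyFreeEnergy(delta_f=f1 - f0, f_start=f0, f_end=f1)
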