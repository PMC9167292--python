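"""Hydrogen-bond detection, occupancy, and persistence filtering.

A hydrogen bond is identified by its full donor-hydrogen-acceptor triple
(a donor with two hydrogens yields two distinct bonds).  The bound state
of a bond in a frame uses the geometric criterion: hydrogen-acceptor
distance strictly below the cutoff (default 0.25 nm) AND
donor-hydrogen-acceptor angle strictly above the cutoff (default 120
degrees); frames exactly at a cutoff are unbound.  Occupancy is the
bound-frame fraction; a bond is *persistent* when its occupancy strictly
exceeds the threshold (default 0.80) in a replicate, and *stable* when it
is persistent in at least ``min_replicates`` replicates.

Salt bridges are not detected separately: where their geometry satisfies
the criterion they appear as ordinary hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from igdyn.domain_model import FragmentAssignment, FRAGMENT_LABELS
from igdyn.geometry import angle
from igdyn.trajectory_io import Topology, TrajectoryFrames

#: covalent D-H bond inference cutoff in frame 0 (nm)
COVALENT_DH_CUTOFF = 0.12

#: elements that can act as hydrogen-bond donors (heavy atom) or acceptors
DONOR_ELEMENTS = {"N", "O"}
ACCEPTOR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class HBondDefinition:
    """One candidate bond: donor heavy atom, its covalent hydrogen, and
    the acceptor, as atom indices, plus fragment labels of both ends."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_fragment: str
    acceptor_fragment: str

    def key(self, topology: Topology) -> tuple:
        """Identity usable across replicates sharing the topology."""
        return (
            topology.atoms[self.donor_index].key,
            topology.atoms[self.hydrogen_index].key,
            topology.atoms[self.acceptor_index].key,
        )


@dataclass
class HBondStateSeries:
    bond: HBondDefinition
    bound: np.ndarray  # bool per frame

    @property
    def occupancy(self) -> float:
        return float(np.count_nonzero(self.bound)) / self.bound.shape[0]


@dataclass
class PersistenceReport:
    """Occupancy per bond per replicate, the per-replicate persistent
    sets, and the multi-replicate stable set."""

    occupancy: pd.DataFrame  # index = bond key string, columns = replicate
    persistent: dict[str, set[str]]  # replicate -> persistent bond keys
    stable: set[str]
    occupancy_threshold: float
    min_replicates: int


def find_candidate_bonds(
    topology: Topology,
    frame0: np.ndarray,
    fragment_assignment: FragmentAssignment,
    max_ha_distance: float | None = None,
) -> list[HBondDefinition]:
    """Enumerate donor-hydrogen ... acceptor candidate triples.

    Donors are N-H and O-H groups (hydrogen within 0.12 nm of the heavy
    atom in frame 0, or sharing its residue when closest); acceptors are
    all N/O atoms.  Intra-residue pairs are excluded.  ``max_ha_distance``
    optionally pre-filters candidates by the frame-0 hydrogen-acceptor
    distance; by default all combinations are returned.
    """
    elements = np.array([a.element for a in topology.atoms])
    h_idx = np.nonzero(elements == "H")[0]
    if h_idx.size == 0:
        raise ValueError(
            "topology contains no hydrogens: the geometric hydrogen-bond "
            "criterion needs explicit hydrogens (re-run with a protonated model)"
        )
    frame0 = np.asarray(frame0, dtype=float)
    heavy_idx = np.nonzero(np.isin(elements, sorted(DONOR_ELEMENTS)))[0]
    acceptor_idx = np.nonzero(np.isin(elements, sorted(ACCEPTOR_ELEMENTS)))[0]

    # donor pairs: each hydrogen bonded to the nearest N/O within cutoff
    pairs: list[tuple[int, int]] = []  # (donor_heavy, hydrogen)
    if heavy_idx.size:
        d2 = np.linalg.norm(
            frame0[h_idx][:, None, :] - frame0[heavy_idx][None, :, :], axis=-1
        )
        nearest = np.argmin(d2, axis=1)
        for hi, ni in zip(range(h_idx.size), nearest):
            if d2[hi, ni] < COVALENT_DH_CUTOFF:
                pairs.append((int(heavy_idx[ni]), int(h_idx[hi])))

    labels = fragment_assignment.labels
    res_of = [(a.chain_id, a.residue_key) for a in topology.atoms]
    out: list[HBondDefinition] = []
    for d, h in pairs:
        for a in acceptor_idx:
            a = int(a)
            if res_of[a] == res_of[d]:
                continue  # same-residue pairs excluded
            if max_ha_distance is not None:
                if np.linalg.norm(frame0[h] - frame0[a]) >= max_ha_distance:
                    continue
            out.append(
                HBondDefinition(
                    donor_index=d,
                    hydrogen_index=h,
                    acceptor_index=a,
                    donor_fragment=str(labels[d]),
                    acceptor_fragment=str(labels[a]),
                )
            )
    return out


def evaluate_bound_states(
    traj: TrajectoryFrames,
    bonds: list[HBondDefinition],
    dist_cutoff: float = 0.25,
    angle_cutoff: float = 120.0,
) -> list[HBondStateSeries]:
    """Per-frame bound state of each candidate bond (strict inequalities
    at both cutoffs)."""
    if dist_cutoff <= 0 or angle_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    if not bonds:
        return []
    X = traj.coordinates
    d_i = np.array([b.donor_index for b in bonds])
    h_i = np.array([b.hydrogen_index for b in bonds])
    a_i = np.array([b.acceptor_index for b in bonds])
    ha = np.linalg.norm(X[:, h_i, :] - X[:, a_i, :], axis=-1)  # F x B
    u = X[:, d_i, :] - X[:, h_i, :]
    v = X[:, a_i, :] - X[:, h_i, :]
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    dha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bound = (ha < dist_cutoff) & (dha > angle_cutoff)
    return [HBondStateSeries(bond=b, bound=bound[:, j]) for j, b in enumerate(bonds)]


def filter_interfragment(
    series: list[HBondStateSeries],
    fragment_a: str = "Fab2",
    fragment_b: str = "Fc",
) -> list[HBondStateSeries]:
    """Keep bonds whose donor/acceptor fragments are {a, b} in either
    orientation."""
    for f in (fragment_a, fragment_b):
        if f not in FRAGMENT_LABELS:
            raise ValueError(f"unknown fragment label {f!r}")
    want = {fragment_a, fragment_b}
    return [
        s
        for s in series
        if {s.bond.donor_fragment, s.bond.acceptor_fragment} == want
    ]


def unique_bond_counts(
    series: list[HBondStateSeries], topology: Topology
) -> dict[str, int]:
    """Number of unique bonds counted two ways: by full D-H-A triple and
    by donor-acceptor residue pair."""
    triples = {s.bond.key(topology) for s in series}
    pairs = set()
    for s in series:
        d = topology.atoms[s.bond.donor_index]
        a = topology.atoms[s.bond.acceptor_index]
        pairs.add(((d.chain_id, d.residue_key), (a.chain_id, a.residue_key)))
    return {"dha_triples": len(triples), "donor_acceptor_pairs": len(pairs)}


def persistence_filter(
    replicate_series: dict[str, list[HBondStateSeries]],
    topology: Topology,
    occupancy_threshold: float = 0.80,
    min_replicates: int = 2,
) -> PersistenceReport:
    """Cross-replicate occupancy table, persistent sets and stable set.

    Replicates may observe different candidate sets: bonds are aligned by
    the union of their D-H-A keys, with missing bonds treated as
    occupancy 0.  Persistence is strict (> threshold).
    """
    if not replicate_series:
        raise ValueError("at least one replicate is required")
    keys: list[str] = []
    tables: dict[str, dict[str, float]] = {}
    for rep, series in replicate_series.items():
        col = {}
        for s in series:
            k = _key_str(s.bond.key(topology))
            col[k] = s.occupancy
            if k not in keys:
                keys.append(k)
        tables[rep] = col
    reps = list(replicate_series)
    occ = pd.DataFrame(
        {rep: [tables[rep].get(k, 0.0) for k in keys] for rep in reps}, index=keys
    )
    persistent = {
        rep: set(occ.index[occ[rep] > occupancy_threshold]) for rep in reps
    }
    counts: dict[str, int] = {}
    for rep in reps:
        for k in persistent[rep]:
            counts[k] = counts.get(k, 0) + 1
    stable = {k for k, c in counts.items() if c >= min_replicates}
    return PersistenceReport(
        occupancy=occ,
        persistent=persistent,
        stable=stable,
        occupancy_threshold=occupancy_threshold,
        min_replicates=min_replicates,
    )


def bond_count_series(series: list[HBondStateSeries]) -> np.ndarray:
    """Per-frame number of bound bonds (the left axis of a pulling-assay
    time series)."""
    if not series:
        return np.zeros(0, dtype=int)
    F = series[0].bound.shape[0]
    for s in series:
        if s.bound.shape[0] != F:
            raise ValueError("bond state series are not frame-aligned")
    return np.sum([s.bound for s in series], axis=0).astype(int)


def bound_state_matrix(
    series: list[HBondStateSeries], topology: Topology
) -> pd.DataFrame:
    """Frames x bonds boolean matrix (heat-map style export)."""
    data = {
        _key_str(s.bond.key(topology)): s.bound.astype(int) for s in series
    }
    return pd.DataFrame(data)


def _key_str(key: tuple) -> str:
    (dc, dr, dn), (hc, hr, hn), (ac, ar, an) = key
    return f"{dc}:{dr}:{dn}--{hc}:{hr}:{hn}..{ac}:{ar}:{an}"
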