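"""Shared fixtures: small synthetic antibody systems built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from igdyn.domain_model import assign_beads
from igdyn.synthetic_data import (
    HBondTriadSpec,
    SyntheticAntibodySpec,
    build_synthetic_topology,
    generate_rigid_motion_trajectory,
)


@pytest.fixture(scope="session")
def small_antibody():
    """Six domains of 6 atoms, 3 hinge atoms, no triads."""
    spec = SyntheticAntibodySpec(seed=101, atoms_per_domain=6, n_frames=60)
    return build_synthetic_topology(spec)


@pytest.fixture(scope="session")
def small_trajectory(small_antibody):
    traj, truth = generate_rigid_motion_trajectory(small_antibody)
    return traj, truth


@pytest.fixture(scope="session")
def small_assignment(small_antibody):
    ab = small_antibody
    bead_map, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
    return bead_map, frag


@pytest.fixture(scope="session")
def triad_antibody():
    """Antibody with three planted triads (two Fab2-Fc, one Fab1-Fc)."""
    spec = SyntheticAntibodySpec(
        seed=202,
        atoms_per_domain=5,
        n_frames=40,
        hbond_triads=[
            HBondTriadSpec("Fab2", "Fc"),
            HBondTriadSpec("Fab2", "Fc"),
            HBondTriadSpec("Fab1", "Fc"),
        ],
    )
    return build_synthetic_topology(spec)


# -- independent oracles (deliberately naive, scalar implementations) --------


def oracle_distance(p, q):
    return sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5


def oracle_angle(p, v, q):
    """Cross-product formulation: atan2(|u x w|, u . w)."""
    u = np.asarray(p, dtype=float) - np.asarray(v, dtype=float)
    w = np.asarray(q, dtype=float) - np.asarray(v, dtype=float)
    return np.degrees(np.arctan2(np.linalg.norm(np.cross(u, w)), np.dot(u, w)))

def oracle_dihedral(a, b, c, d):
    """Signed torsion from plane normals; sign by the right-hand rule
    about b->c: positive when (n1 x n2) points along b->c."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return 180.0 if np.isclose(ang, -180.0) else ang


def random_rotation(rng):
    """Uniform proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
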