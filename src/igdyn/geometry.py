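"""Inter-bead geometric measures: distances R_ij, angles theta_ijk and
dihedrals Theta_ijkl evaluated per trajectory frame.

Conventions: distances in nm; angles in degrees within [0, 180] with the
vertex at the middle bead; dihedrals signed in (-180, 180] following the
right-hand rule about the j->k axis (IUPAC), so a mirror reflection flips
the dihedral sign while leaving distances and angles unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from igdyn.domain_model import BeadTrajectory

_DEGENERACY_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when an angle or dihedral is undefined (zero-length arm or
    collinear points)."""


@dataclass(frozen=True)
class MeasureSpec:
    kind: str  # "distance" | "angle" | "dihedral"
    bead_indices: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        expected = {"distance": 2, "angle": 3, "dihedral": 4}
        if self.kind not in expected:
            raise ValueError(f"unknown measure kind {self.kind!r}")
        if len(self.bead_indices) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} needs {expected[self.kind]} beads, "
                f"got {len(self.bead_indices)}"
            )
        if len(set(self.bead_indices)) != len(self.bead_indices):
            raise ValueError("bead indices must be distinct")


@dataclass
class GeometricSeries:
    label: str
    kind: str
    values: np.ndarray  # per-frame; NaN at frames excluded as degenerate
    degenerate_frames: list[int] = field(default_factory=list)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


#: the default antibody measure set: Fab-Fc displacements (R_23, R_25),
#: Fab-Fc orientations (theta_123, theta_125), Fc-Fab dihedrals
#: (Theta_1234, Theta_1256), intra-Fab (R_34, R_56) and intra-Fc (R_12)
DEFAULT_MEASURES: list[MeasureSpec] = [
    MeasureSpec("distance", (2, 3), "R_23"),
    MeasureSpec("distance", (2, 5), "R_25"),
    MeasureSpec("angle", (1, 2, 3), "theta_123"),
    MeasureSpec("angle", (1, 2, 5), "theta_125"),
    MeasureSpec("dihedral", (1, 2, 3, 4), "Theta_1234"),
    MeasureSpec("dihedral", (1, 2, 5, 6), "Theta_1256"),
    MeasureSpec("distance", (3, 4), "R_34"),
    MeasureSpec("distance", (5, 6), "R_56"),
    MeasureSpec("distance", (1, 2), "R_12"),
]


def distance(p_i: np.ndarray, p_j: np.ndarray) -> float | np.ndarray:
    """Euclidean distance between two points (or batches of points)."""
    return np.linalg.norm(np.asarray(p_j, dtype=float) - np.asarray(p_i, dtype=float), axis=-1)


def angle(p_i: np.ndarray, p_j: np.ndarray, p_k: np.ndarray) -> float | np.ndarray:
    """Angle in degrees subtended at vertex p_j by p_i and p_k."""
    u = np.asarray(p_i, dtype=float) - np.asarray(p_j, dtype=float)
    v = np.asarray(p_k, dtype=float) - np.asarray(p_j, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < _DEGENERACY_EPS) or np.any(nv < _DEGENERACY_EPS):
        raise DegenerateGeometryError("zero-length arm in angle computation")
    c = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral(
    p_i: np.ndarray, p_j: np.ndarray, p_k: np.ndarray, p_l: np.ndarray
) -> float | np.ndarray:
    """Signed torsion angle in degrees, range (-180, 180].

    The sign follows the right-hand rule about the j->k axis: looking
    down j->k, a positive angle rotates the i-side plane counter-clockwise
    onto the l-side plane.  Undefined (raises) when i,j,k or j,k,l are
    collinear.
    """
    p_i, p_j = np.asarray(p_i, dtype=float), np.asarray(p_j, dtype=float)
    p_k, p_l = np.asarray(p_k, dtype=float), np.asarray(p_l, dtype=float)
    b1 = p_j - p_i
    b2 = p_k - p_j
    b3 = p_l - p_k
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    if np.any(nb2 < _DEGENERACY_EPS):
        raise DegenerateGeometryError("zero-length central axis in dihedral")
    if np.any(np.linalg.norm(n1, axis=-1) < _DEGENERACY_EPS) or np.any(
        np.linalg.norm(n2, axis=-1) < _DEGENERACY_EPS
    ):
        raise DegenerateGeometryError("collinear points: dihedral plane undefined")
    b2_hat = b2 / (nb2[..., None] if np.ndim(nb2) else nb2)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2_hat, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang) if np.ndim(ang) else (
        180.0 if np.isclose(ang, -180.0) else float(ang)
    )


def evaluate_measures(
    beads: BeadTrajectory, specs: list[MeasureSpec] | None = None
) -> list[GeometricSeries]:
    """Evaluate measures on every frame of a bead trajectory.

    Frames where an angle/dihedral is degenerate are recorded in
    ``degenerate_frames`` and carry NaN in the series (excluded from
    downstream distributions) rather than being silently dropped.
    """
    if specs is None:
        specs = DEFAULT_MEASURES
    out: list[GeometricSeries] = []
    for spec in specs:
        for b in spec.bead_indices:
            if b not in beads.bead_ids:
                raise ValueError(f"measure {spec.label}: bead {b} not in trajectory")
        pts = [beads.series(b) for b in spec.bead_indices]
        F = pts[0].shape[0]
        values = np.full(F, np.nan)
        degenerate: list[int] = []
        if spec.kind == "distance":
            values = np.asarray(distance(pts[0], pts[1]), dtype=float)
        else:
            fn = angle if spec.kind == "angle" else dihedral
            try:
                values = np.asarray(fn(*pts), dtype=float)
            except DegenerateGeometryError:
                for f in range(F):  # vectorized path failed: find the frames
                    try:
                        values[f] = fn(*(p[f] for p in pts))
                    except DegenerateGeometryError:
                        degenerate.append(f)
        out.append(
            GeometricSeries(
                label=spec.label, kind=spec.kind, values=values,
                degenerate_frames=degenerate,
            )
        )
    return out
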