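"""Fc-aligned essential dynamics: PCA of C-alpha coordinate covariance.

Every frame is first superposed onto the Fc C-alpha atoms of a reference
frame with the Kabsch least-squares rotation (always a proper rotation).
The covariance of the mean-centered 3M-dimensional C-alpha coordinate
vectors is then diagonalized; eigenvalues (nm^2, descending) quantify the
variance carried by each collective mode, and the per-atom 3-subvectors
of each eigenvector attribute the mode to regions of the protein
(porcupine-style).  Fragment attribution uses partial projections: the
PC score restricted to a subset of atoms, which sums to the full score
over disjoint covering subsets.

Covariance uses the population (1/F) normalization; eigenvector signs
are fixed by making the largest-magnitude entry positive so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from igdyn.domain_model import AMINO_ACIDS
from igdyn.trajectory_io import Topology, TrajectoryFrames


@dataclass
class EssentialDynamicsResult:
    atom_indices: np.ndarray          # topology indices of the M analyzed atoms
    mean_coordinates: np.ndarray      # M x 3 nm
    eigenvalues: np.ndarray           # nm^2, descending
    eigenvectors: np.ndarray          # K x 3M, rows are unit vectors
    projections: np.ndarray           # F x K PC scores

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]

    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def select_calpha(topology: Topology) -> np.ndarray:
    """Indices of CA atoms in amino-acid residues, file order.  Glycan
    and other hetero residues are never selected."""
    idx = np.array(
        [
            a.atom_index
            for a in topology.atoms
            if a.atom_name == "CA" and a.residue_name in AMINO_ACIDS
        ],
        dtype=int,
    )
    if idx.size == 0:
        raise ValueError("topology contains no C-alpha atoms")
    return idx


def kabsch_transform(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (R, t) with R a proper rotation (det +1, reflections
    corrected by flipping the smallest singular direction) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need matching point sets with at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:  # rank < 2: points collinear, rotation underdetermined
        raise ValueError("alignment subset is degenerate (collinear points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def align_frames(
    traj: TrajectoryFrames,
    alignment_subset: np.ndarray,
    reference_frame: int = 0,
) -> TrajectoryFrames:
    """Superpose every frame onto ``alignment_subset`` of the reference
    frame (all atoms are transformed; the fit uses only the subset,
    unweighted)."""
    subset = np.asarray(alignment_subset, dtype=int)
    ref = traj.coordinates[reference_frame][subset]
    aligned = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        R, t = kabsch_transform(traj.coordinates[f][subset], ref)
        aligned[f] = traj.coordinates[f] @ R.T + t
    return TrajectoryFrames(
        coordinates=aligned, times=traj.times.copy(), topology=traj.topology
    )


def fit_pca(
    traj: TrajectoryFrames,
    atom_indices: np.ndarray,
    n_components: int | None = None,
) -> EssentialDynamicsResult:
    """Eigen-decomposition of the coordinate covariance of a subset of
    atoms over frames (frames should already be aligned).

    Implemented by SVD of the mean-centered F x 3M data matrix;
    eigenvalues are singular values squared over F (population
    covariance), and their sum equals the total coordinate variance.
    """
    atom_indices = np.asarray(atom_indices, dtype=int)
    F = traj.n_frames
    if F < 2:
        raise ValueError("PCA requires at least 2 frames")
    X = traj.coordinates[:, atom_indices, :].reshape(F, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = S**2 / F
    k = min(F, Xc.shape[1]) if n_components is None else n_components
    eigenvalues = eigenvalues[:k]
    eigenvectors = Vt[:k]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for i in range(eigenvectors.shape[0]):
        j = np.argmax(np.abs(eigenvectors[i]))
        if eigenvectors[i, j] < 0:
            eigenvectors[i] *= -1.0
    projections = Xc @ eigenvectors.T
    return EssentialDynamicsResult(
        atom_indices=atom_indices,
        mean_coordinates=mean.reshape(-1, 3),
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        projections=projections,
    )


def project(
    traj: TrajectoryFrames,
    result: EssentialDynamicsResult,
    component: int,
    atom_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame (partial) projection onto one principal component.

    With ``atom_subset=None`` (all analyzed atoms) this is the standard
    PC score.  With a subset, only those atoms' displacement terms enter
    the sum, so partial projections over disjoint covering subsets add up
    to the full score frame by frame.  ``atom_subset`` is given in
    topology atom indices and is intersected with the analyzed atoms.
    """
    if component >= result.n_components:
        raise ValueError(f"component {component} not available")
    X = traj.coordinates[:, result.atom_indices, :].reshape(traj.n_frames, -1)
    Xc = X - result.mean_coordinates.reshape(-1)
    v = result.eigenvectors[component]
    if atom_subset is None:
        return Xc @ v
    subset = np.asarray(atom_subset, dtype=int)
    pos = {int(a): m for m, a in enumerate(result.atom_indices)}
    local = [pos[int(a)] for a in subset if int(a) in pos]
    if not local:
        raise ValueError("atom subset contains none of the analyzed atoms")
    mask = np.zeros(result.atom_indices.size, dtype=bool)
    mask[local] = True
    mask3 = np.repeat(mask, 3)
    return Xc[:, mask3] @ v[mask3]


def atom_contribution_vectors(
    result: EssentialDynamicsResult, component: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-atom 3-vectors of one eigenvector and their norms.

    Norms squared sum to 1 over atoms (eigenvector normalization).  The
    third element flags a null-space component (eigenvalue ~ 0), whose
    direction is arbitrary.
    """
    if component >= result.n_components:
        raise ValueError(f"component {component} not available")
    vec = result.eigenvectors[component].reshape(-1, 3)
    norms = np.linalg.norm(vec, axis=1)
    is_null = bool(
        result.eigenvalues[component] <= 1e-12 * max(result.eigenvalues[0], 1e-300)
    )
    return vec, norms, is_null
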