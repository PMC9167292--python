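# Methods

## The six-bead model and its observables

The antibody is reduced to six beads, each the mass-weighted center of a
domain pair (Fc: CH3, CH2; each Fab: CH1+CL, VH+VL). Hinge residues and
glycans belong to no bead: beads are defined by explicit chain/residue
ranges in the YAML config, and non-amino-acid residues are never
auto-assigned even when a range covers them. Centers are mass-weighted
by default (a geometric-center option exists); hydrogens, when present,
are included in the masses and this choice is recorded in the run
manifest.

Per frame the pipeline evaluates nine measures: Fab–Fc displacements
R_23 and R_25, orientations θ_123 and θ_125, dihedrals Θ_1234 and
Θ_1256, intra-Fab R_34 and R_56, and intra-Fc R_12. Angles place the
vertex at the middle listed bead, which is the only reading under which
"the angle subtended by beads i, j, k" is well defined for this
geometry. Dihedrals are signed, range (−180°, 180°], with the sign
fixed by the right-hand rule about the j→k axis; the convention was
cross-checked against mdtraj's dihedral routine. Mirror reflection
flips the dihedral sign and leaves distances and angles unchanged.
Frames where an angle or dihedral is degenerate (zero-length arm,
collinear beads) are reported with their frame indices and carried as
NaN — never silently dropped, never returned as a number.

Distributions are normalized histograms (Freedman–Diaconis bins by
default, fixed-count fallback when the interquartile range is zero).
Peaks are histogram modes, not fitted-Gaussian means, because peak
separations compare possibly non-Gaussian densities; sample mean/sd and
a Kolmogorov–Smirnov Gaussian-adequacy score are reported separately.
The Fab1/Fab2 variance-asymmetry ratio carries a percentile bootstrap
interval with circular block resampling (default block 50 frames) to
respect the serial correlation of MD frames. Peak separation is
reported as the absolute peak difference; normalization by a pooled
width is available as an option but not the default, since "relative
separation" admits several readings.

## Hydrogen bonds

Candidates pair every N–H and O–H donor (hydrogen assigned to the
nearest N/O heavy atom within 0.12 nm in frame 0) with every N/O
acceptor, excluding same-residue pairs. Bond identity is the full
donor–hydrogen–acceptor triple, so a donor with two hydrogens
contributes two distinct bonds; unique counts are additionally reported
as donor–acceptor pairs since the two conventions differ. A frame is
bound iff H···A < 0.25 nm AND ∠D–H–A > 120°, both strict, so boundary
frames are unbound. Occupancy is the exact bound-frame fraction over
all analyzed frames of a replicate, with no smoothing window; the
frame-saving stride is a user choice and occupancies are fractions of
analyzed frames. A bond is *persistent* in a replicate when its
occupancy strictly exceeds 0.80, and *stable* when persistent in at
least two replicates; replicates with differing candidate sets are
aligned by the union of bond keys with missing bonds counted as
occupancy 0. Salt bridges have no separate detector — where their
geometry qualifies they appear as hydrogen bonds (a documented
limitation). Trajectories are assumed non-periodic (implicit-solvent
style); no minimum-image handling is applied.

## Essential dynamics

Frames are superposed onto the Fc Cα atoms of the first frame by the
Kabsch least-squares fit, unweighted, with the determinant-corrected
SVD so the rotation is always proper (reflections are never returned;
a collinear alignment subset raises). PCA is computed per trajectory —
pooling replicates is an explicit flag — by SVD of the mean-centered
F × 3M Cα coordinate matrix; eigenvalues use the population (1/F)
normalization, which only scales the spectrum. Coordinates are centered
on a single global mean structure. Eigenvector signs are fixed by
making the largest-magnitude entry positive so outputs are
deterministic. Fragment attribution uses partial projections — the PC
score restricted to a subset's displacement terms — which sum exactly
to the full score over disjoint covering subsets; per-atom 3-subvectors
of each eigenvector and their norms (squared norms summing to 1) supply
porcupine-style contribution maps, with zero-eigenvalue components
flagged as null space.

## Pulling and work

The pulling specification applies +f·r̂ to every Fab2 atom and −f·r̂ to
every Fc atom (default f = 0.01 kcal/mol/nm per atom), with r̂ the unit
vector from the Fc to the Fab2 mass-weighted center in the initial
frame. Because the magnitudes are per-atom, net group forces are
unbalanced when atom counts differ; the resulting center-of-mass drift
is accepted, not corrected. External work between two structures is
endpoint-based, W = Σᵢ f_Fab2 (R⃗ᵢ·r̂) − Σⱼ f_Fc (R⃗ⱼ·r̂), computed on
raw displacements with no prior superposition — this makes W
frame-of-reference sensitive, which the run manifest records
prominently. A path-integrated variant (summing endpoint work over
successive frames) exists for dense toy trajectories; for a constant
force it telescopes to the endpoint value. Rupture is the first frame
at which the inter-fragment bond count stays zero for a configurable
sustain window, so transient rebinding postpones it.

## The synthetic-data generators

The generators define the study conditions for all tests.

**Topology.** Three chains (A: Fc, B: Fab1, C: Fab2), each domain a
rigid cloud of CA pseudo-atoms (one per residue, default 10 per domain)
whose centroid coincides exactly with the template bead position; hinge
linker atoms ride with the Fc CH2 bead; optional donor–H–acceptor
triads (N, H at 0.10 nm, O) host planted hydrogen bonds on a spatial
grid with 1.2 nm spacing so candidates never collide.

**Rigid motion.** Per frame the nine measures are drawn from
independent normals and realized *exactly* by z-matrix construction
(bead 1 at the origin, bead 2 along +z, beads 3/5 placed by
distance+angle in the xz-plane on opposite sides, beads 4/6 by
bond–angle–dihedral placement with fixed auxiliary angles of 150°).
Domains then translate rigidly to the sampled centers. Default
conditions mirror an asymmetric IgG1: R_23 ~ N(6.0, 0.5²) nm vs
R_25 ~ N(3.5, 0.08²) nm; θ_123 ~ N(120°, 10°²) vs θ_125 ~ N(60°, 3°²);
Θ_1234 sd 15° vs Θ_1256 sd 4°; intra-fragment distances narrow
(sd ≤ 0.1 nm). Angle draws outside (0°, 180°) raise an unsatisfiable-
geometry error rather than being clamped. Planted bond schedules set
H···A to 0.20 nm (D–H–A 160°) on bound frames and 0.40 nm on unbound
frames, touching no other atoms. What the generator does *not* emulate:
internal domain deformation, correlated measure fluctuations, solvent
or glycan chemistry, and realistic hydrogen-bond geometry fluctuations
— so green tests certify the bookkeeping and statistics of the
pipeline, not force-field-level realism.

**Langevin toy.** Overdamped (inertialess) updates
x ← x + μF dt + √(2μk_BT dt)·η with per-bead mobility μ = 1/(γm),
chosen over velocity Verlet because it has fewer parameters and the
same equilibrium distribution; energies in kcal/mol are converted with
1 kcal/mol = 4.184 amu·nm²/ps². The breakable Fc–Fab2 attraction is a
truncated shifted harmonic well U(r) = −ε(1 − ((r−r₀)/w)²) on
|r−r₀| ≤ w — continuous at the cutoff, closed-form maximum restoring
force 2ε/w, easy quadrature — rather than a Lennard-Jones form.
Two pulling modes exist: a constant external per-bead force (the assay
mode; work ledger Σ F·Δx), and a stiff harmonic trap on the bead-pair
distance whose center moves linearly (constant-velocity steered
protocol; work booked as Σ [V(x, λ_new) − V(x, λ_old)]). The trap mode
is used for work-vs-free-energy comparisons because constant-force work
has no clean quasi-static free-energy limit. The toy is collinear
(1-dimensional relative coordinate), so the free energy of the pulling
coordinate needs no radial Jacobian and ΔF = 0 exactly when ε = 0;
F(λ) = −k_BT ln ∫ exp(−β[U(r) + k(r−λ)²/2]) dr is evaluated by
adaptive quadrature over a window covering the trap (width √(k_BT/k))
and the well, with breakpoints at the well edges.

Default toy conditions: ε = 3 kcal/mol, r₀ = 1.0 nm, w = 0.3 nm,
k_BT = 0.6 kcal/mol (~300 K), trap k = 50 kcal/mol/nm² moved from 1.0
to 2.0 nm, dt = 0.002 ps (trap relaxation time ≈ 0.03 ps), masses 12
amu, friction 1 ps⁻¹. The 20 ps pull (10⁴ steps) is the quasi-static
condition: dissipation there is a few percent of ΔF ≈ 2.75 kcal/mol,
while 3 ps pulls show visible excess work, illustrating the second-law
ordering mean W ≥ ΔF at every rate. Work statistics use 200
independent replicas integrated as one vectorized batch from a single
seeded generator, making every run bit-reproducible.

## Problem sizes and numerical choices

Analysis drivers use 5000-frame replicates for distribution statistics,
150 frames × 3 replicates × 298 bonds for the persistence study,
500–1000 frames for PCA, and 200 × 10⁴-step pulls for work statistics —
sizes at which the planted parameters are recovered within the stated
tolerances (sds within 15%, means within Monte-Carlo error) while a
full run of every driver completes in seconds. Geometric degeneracy
thresholds are 1e-12 (zero-length arms); arccos arguments are clamped
to [−1, 1]; density-histogram ties at the mode resolve to the lowest
bin; bootstrap and Langevin runs require explicit seeds.

## Known limitations

Beads require a hand-specified domain config (no automatic boundary
detection); the elbow angle is not implemented; no mmCIF/PSF readers;
no time-lagged (tICA/MSM) analyses; no periodic-boundary support; the
shipped IgG1 EU-numbered ranges are a documented reconstruction to be
edited against the user's structure, not measured values.
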