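# igdyn — six-bead analysis of antibody internal dynamics

`igdyn` analyzes the internal dynamics of IgG-class antibodies from
molecular-dynamics trajectories, for structural biologists and antibody
engineers who want to quantify how the two Fab arms and the Fc stem move
relative to each other.

An IgG is coarse-grained into six beads, each the mass-weighted center
of a domain pair:

| bead | domain | fragment |
|------|--------|----------|
| 1 | CH3 | Fc |
| 2 | CH2 | Fc |
| 3 | CH1 + CL | Fab1 |
| 4 | VH + VL | Fab1 |
| 5 | CH1 + CL | Fab2 |
| 6 | VH + VL | Fab2 |

From the per-frame bead positions the pipeline computes inter-bead
distances R_ij, angles θ_ijk (vertex at the middle bead) and signed
dihedrals Θ_ijkl, and turns them into probability densities, Gaussian
summaries and Fab1-vs-Fab2 peak separations. Around that core it
provides:

- **Hydrogen-bond persistence** — Baker–Hubbard-style donor–H–acceptor
  candidates evaluated per frame with the geometric criterion
  (H···A < 0.25 nm and ∠D–H–A > 120°, strict), occupancy per replicate,
  and the persistence filter (occupancy > 0.80 in a replicate; *stable*
  when persistent in ≥ 2 replicates).
- **Essential dynamics** — every frame is superposed onto the Fc Cα
  atoms of a reference frame (Kabsch, proper rotations only), the Cα
  coordinate covariance is diagonalized, and each principal component is
  attributed to fragments by partial projections and per-atom
  contribution vectors (porcupine-style).
- **Pulling work** — a constant-force pulling specification
  (±f·r̂ on every Fab2/Fc atom, r̂ from the initial Fc→Fab2 COM vector)
  and the endpoint external work
  W = Σᵢ f_Fab2 (R⃗ᵢ·r̂) − Σⱼ f_Fc (R⃗ⱼ·r̂) in kcal/mol.
- **Synthetic ground truth** — an antibody-like topology generator, a
  rigid-motion trajectory generator that realizes sampled inter-bead
  measures *exactly* (z-matrix construction), planted hydrogen-bond
  schedules, and an overdamped Langevin toy with a breakable Fc–Fab2
  attraction whose pulling free energy has a quadrature reference, so
  every stage of the pipeline is testable against known truth.

Internal units: nm, degrees, ps, amu, kcal/mol.

## Worked example

Generate a synthetic system and measure its bead geometry:

```bash
igdyn synth --seed 9 --n-frames 20 --atoms-per-domain 5 --out demo/
igdyn geometry --config src/igdyn/configs/synthetic.yaml \
    --structure demo/synthetic.pdb --trajectory demo/synthetic.xtc \
    --out demo_geometry/
```

The analysis drivers under `analysis/` run the same pipeline at study
scale. `python analysis/01_domain_geometry.py` prints

```
analyzed 5000 frames x 3 replicates
R_23 mean 6.01 nm (sd 0.50) vs R_25 mean 3.50 nm (sd 0.080)
theta_123 sd 9.88 deg vs theta_125 sd 3.01 deg (Fab2 orientation constrained)
R_23 vs R_25 peak separation: 2.62 nm
```

i.e. the Fab1 arm explores a broad range of Fc distances and
orientations while Fab2 is tightly constrained near 3.5 nm — the
asymmetric-dynamics signature the pipeline is built to detect.
`analysis/02_hbond_persistence.py` screens 298 planted Fab2–Fc
hydrogen bonds and reports 38 persistent (occupancy > 0.80) and 4
stable across replicates; `analysis/03_essential_dynamics.py` shows
PC1/PC2 attributing ~100% of the collective motion to Fab1 when only
Fab1 moves; `analysis/04_pulling_work.py` ruptures the toy Fc–Fab2
attraction under supercritical constant force and verifies that the
mean constant-velocity pulling work bounds the analytic free-energy
difference (mean W = 2.83 ± 0.36 kcal/mol vs ΔF = 2.75 kcal/mol at the
20 ps rate).

Domain boundaries come from a YAML config; `src/igdyn/configs/`
ships one for the synthetic layout and a documented reconstruction of
standard IgG1 EU-numbered domain ranges to adapt to a real structure.

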