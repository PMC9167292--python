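"""Six-bead geometry of three synthetic replicates with asymmetric Fab
dynamics.

Generates three seeded replicates from the rigid-motion model (Fab1
broad: R_23 sd 0.5 nm, theta_123 sd 10 deg; Fab2 constrained: R_25 sd
0.08 nm, theta_125 sd 3 deg), runs the bead -> geometry -> distributions
pipeline and writes per-measure summaries and Fab1-vs-Fab2 peak
separations under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from igdyn.distributions import estimate_density, gaussian_summary, separation_table
from igdyn.domain_model import assign_beads, compute_bead_trajectory
from igdyn.geometry import evaluate_measures
from igdyn.synthetic_data import (
    SyntheticAntibodySpec,
    build_synthetic_topology,
    generate_rigid_motion_trajectory,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_FRAMES = 5000
SEED = 11


def main() -> None:
    spec = SyntheticAntibodySpec(seed=SEED, atoms_per_domain=8, n_frames=N_FRAMES)
    ab = build_synthetic_topology(spec)
    bead_map, _ = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)

    rows = []
    densities = {}
    for rep in range(3):
        traj, _ = generate_rigid_motion_trajectory(ab, seed=SEED + rep)
        beads = compute_bead_trajectory(traj, bead_map)
        for s in evaluate_measures(beads):
            mean, sd, ks = gaussian_summary(s)
            d = estimate_density(s)
            rows.append((f"E{rep + 1}", s.label, s.kind, mean, sd, d.peak_location, ks))
            if rep == 0:
                densities[s.label] = d

    df = pd.DataFrame(
        rows,
        columns=["replicate", "measure", "kind", "mean", "sd", "peak", "ks_score"],
    )
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "geometry_summary.csv", index=False)

    seps = separation_table(densities)
    with open(RESULTS / "peak_separations.json", "w") as fh:
        json.dump(seps, fh, indent=2)

    e1 = df[df.replicate == "E1"].set_index("measure")
    print(f"analyzed {N_FRAMES} frames x 3 replicates")
    print(f"R_23 mean {e1.loc['R_23', 'mean']:.2f} nm (sd {e1.loc['R_23', 'sd']:.2f}) "
          f"vs R_25 mean {e1.loc['R_25', 'mean']:.2f} nm (sd {e1.loc['R_25', 'sd']:.3f})")
    print(f"theta_123 sd {e1.loc['theta_123', 'sd']:.2f} deg vs "
          f"theta_125 sd {e1.loc['theta_125', 'sd']:.2f} deg "
          f"(Fab2 orientation constrained)")
    print(f"R_23 vs R_25 peak separation: {seps['R_23_vs_R_25']:.2f} nm")
    print(f"wrote {RESULTS / 'geometry_summary.csv'}")


if __name__ == "__main__":
    main()
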