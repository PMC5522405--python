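#!/usr/bin/env python
"""Generate the synthetic tunnel systems used by the downstream analyses.

System I is pinned to the converged parallel N-N state (both TGs
tuning-fork, sigma 10°, truncation 20°). Systems II–IV emulate the
partially converged runs as Markov chains whose stationary laws match the
reported pair-state percentages. Trajectories (xyzcsv + ground-truth
sidecars) land under scratch/; a summary table under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cetptraj.io_core import write_trajectory
from cetptraj.synthetic_data import TrajectorySpec, generate_trajectory

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "trajectories"
RESULTS = ROOT / "results"

N_FRAMES = 5000
SEED = 42

#: stationary pair-state laws (NN, NC, CC, CN, random) the four systems
#: converge to; system I stays fully parallel N-N
SYSTEM_LAWS = {
    "system_I": None,    # explicit all-parallel-NN sequence
    "system_II": [0.646, 0.199, 0.0, 0.0, 0.155],
    "system_III": [0.379, 0.221, 0.01, 0.047, 0.343],
    "system_IV": [0.671, 0.003, 0.001, 0.163, 0.162],
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, law in SYSTEM_LAWS.items():
        if law is None:
            spec = TrajectorySpec(
                n_frames=N_FRAMES,
                state_sequence=["PARALLEL_NN"] * N_FRAMES,
                angular_noise_sigma=10.0, noise_truncation=20.0, seed=SEED,
            )
        else:
            law = np.asarray(law) / np.sum(law)
            spec = TrajectorySpec(
                n_frames=N_FRAMES,
                transition_matrix=np.tile(law, (5, 1)),
                angular_noise_sigma=3.0, noise_truncation=5.0, seed=SEED,
            )
        traj, truth = generate_trajectory(spec)
        out = SCRATCH / f"{name}.csv"
        write_trajectory(traj, out, "xyzcsv")
        out.with_suffix(".truth.json").write_text(json.dumps({
            "pair": [s.value for s in truth.pair],
            "orientation_N": [s.value for s in truth.orientation_N],
            "orientation_C": [s.value for s in truth.orientation_C],
        }) + "\n")
        rows.append({
            "system": name,
            "n_frames": traj.n_frames,
            "sigma_deg": spec.angular_noise_sigma,
            "truncation_deg": spec.noise_truncation,
            "file": str(out.relative_to(ROOT)),
        })
        print(f"{name}: {traj.n_frames} frames -> {out.name}")
    pd.DataFrame(rows).to_csv(RESULTS / "simulated_systems.csv", index=False)
    print(f"summary -> {RESULTS / 'simulated_systems.csv'}")


if __name__ == "__main__":
    main()
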