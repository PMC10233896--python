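#!/usr/bin/env python
"""Generate paired synthetic co-culture recordings (control-like vs
FTD-like) with planted ground truth.

Bulk traces go to scratch/data/ (HDF5); the planted networks, module labels
and spike events are written as CSV next to them. Later analysis steps load
these files by seed and condition.
"""

from pathlib import Path

import numpy as np

from caimnet import DynamicsSpec, NetworkSpec, generate_dataset
from caimnet.io import save_ground_truth, save_recording

SEEDS = [0, 1000, 2000]
N_NEURONS, N_MODULES, DURATION_S = 60, 6, 600.0
DATA_DIR = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main():
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for seed in SEEDS:
        for cond in ("control_like", "ftd_like"):
            rec, truth = generate_dataset(
                NetworkSpec(n_neurons=N_NEURONS, n_modules=N_MODULES),
                DynamicsSpec(duration_s=DURATION_S),
                condition=cond,
                seed=seed,
            )
            stem = DATA_DIR / f"{cond}_seed{seed}"
            save_recording(rec, stem.with_suffix(".h5"))
            save_ground_truth(truth, stem)
            n_spikes = sum(len(s) for s in truth.spike_times)
            print(
                f"{cond} seed {seed}: {rec.n_frames} frames x {rec.n_rois} ROIs, "
                f"{truth.adjacency.sum()} planted edges, {n_spikes} planted spikes"
            )
    print(f"\nwrote {2 * len(SEEDS)} recordings under {DATA_DIR}")


if __name__ == "__main__":
    main()
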