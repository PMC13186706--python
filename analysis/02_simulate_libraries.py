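#!/usr/bin/env python
"""Simulate the footprint libraries analysed by the rest of the pipeline.

Draws three 100k-read control replicates under the study-condition dwell
models (initiation pausing, discrete elongation pauses, topology-linked
periodic slowing, published per-unit read shares) and two knockdown series
(COX1 at 0.30x, COX2 at 0.40x abundance).  Writes BED-like TSVs under
results/libraries/.
"""

import argparse
from pathlib import Path

import numpy as np

from mitoribo.fixtures import human_mtdna_like_annotation, human_mtdna_like_topology
from mitoribo.simulate import KDSpec, simulate_replicates, study_conditions, write_footprints

TOTAL_READS = 100_000
N_REPLICATES = 3


def _seeds(root, n):
    return [int(s) for s in np.random.SeedSequence(root).generate_state(n) % (2**31)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/libraries"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ann = human_mtdna_like_annotation()
    models, abundances = study_conditions(ann, human_mtdna_like_topology())
    ctrl_seed, kd1_seed, kd2_seed = _seeds(args.seed, 3)

    runs = [
        ("control", None, ctrl_seed),
        ("kd_cox1", KDSpec("COX1", 0.30), kd1_seed),
        ("kd_cox2", KDSpec("COX2", 0.40), kd2_seed),
    ]
    for name, kd, seed in runs:
        df = simulate_replicates(ann, models, N_REPLICATES, TOTAL_READS,
                                 _seeds(seed, N_REPLICATES), kd=kd, abundances=abundances)
        path = args.out_dir / f"{name}.tsv"
        write_footprints(df, path, meta={"seed": args.seed, "condition": name,
                                         "reads_per_replicate": TOTAL_READS})
        shares = df["unit_id"].value_counts(normalize=True)
        print(f"{name}: {len(df)} records -> {path}")
        for uid in ("COX1", "COX2", "COX3", "ATP8-ATP6"):
            print(f"  {uid:<10} read share {shares.get(uid, 0):.3f}")


if __name__ == "__main__":
    main()
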