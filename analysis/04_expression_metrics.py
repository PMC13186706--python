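#!/usr/bin/env python
"""Per-transcript expression metrics on the control libraries.

RPKM/RPM per unit and replicate, the first-15-codon vs downstream split, and
the COX1 initiation-pause share (fraction of its reads in codons 1-10).
Writes results/metrics.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from mitoribo.fixtures import human_mtdna_like_annotation
from mitoribo.metrics import stats_table
from mitoribo.pauses import initiation_pause_share
from mitoribo.processing import profiles_by_replicate, read_profiles


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--profiles", type=Path,
                        default=Path("results/profiles/control_profiles.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/metrics.tsv"))
    args = parser.parse_args()

    ann = human_mtdna_like_annotation()
    profiles = read_profiles(args.profiles, ann)
    df = stats_table(profiles, ann)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)

    mean_rpkm = df.groupby("unit_id", sort=False)["rpkm"].mean().sort_values(ascending=False)
    print("mean RPKM per unit (replicate average):")
    for uid, v in mean_rpkm.items():
        print(f"  {uid:<10} {v:10.1f}")

    shares = []
    for rep, plist in profiles_by_replicate(profiles).items():
        p = next(p for p in plist if p.unit_id == "COX1")
        shares.append(initiation_pause_share(p))
    print(f"COX1 reads in codons 1-10: {100 * np.mean(shares):.1f}% "
          f"(per replicate: {', '.join(f'{100*s:.1f}%' for s in shares)})")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
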