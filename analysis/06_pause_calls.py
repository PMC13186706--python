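#!/usr/bin/env python
"""Translational pause calling with TMH-emergence annotation.

Calls pauses per replicate on the control profiles, keeps sites supported in
at least two of three replicates, annotates each against the protein's TMH
emergence codons (TMH start + 30-residue tunnel occlusion) and attaches the
implied nascent-chain fragment.  Writes results/pauses.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mitoribo.fixtures import human_mtdna_like_annotation, human_mtdna_like_topology
from mitoribo.pauses import (
    annotate_tmh_linkage,
    call_pauses,
    calls_table,
    combine_replicate_calls,
)
from mitoribo.processing import profiles_by_replicate, read_profiles


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--profiles", type=Path,
                        default=Path("results/profiles/control_profiles.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/pauses.tsv"))
    args = parser.parse_args()

    ann = human_mtdna_like_annotation()
    topo_by_id = {t.protein_id: t for t in human_mtdna_like_topology()}
    profiles = read_profiles(args.profiles, ann)
    by_rep = profiles_by_replicate(profiles)

    frames = []
    for unit in ann.units:
        per_rep = [
            call_pauses(next(p for p in by_rep[rep] if p.unit_id == unit.unit_id))
            for rep in sorted(by_rep)
        ]
        combined = combine_replicate_calls(per_rep)
        for gid in unit.member_genes:
            if gid in topo_by_id:
                annotate_tmh_linkage(combined, topo_by_id[gid], ann)
        if combined:
            frames.append(calls_table(combined))
            for c in combined:
                link = f" (TMH {c.linked_tmh} emergence)" if c.tmh_linked else ""
                print(f"{unit.unit_id:<10} pause {c.label:<8} score {c.score:5.1f} "
                      f"support {c.replicate_support}/3  "
                      f"fragment {c.fragment.mass_kda:4.1f} kDa{link}")
    df = pd.concat(frames, ignore_index=True) if frames else calls_table([])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    print(f"wrote {len(df)} calls -> {args.out}")


if __name__ == "__main__":
    main()
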