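"""Membrane-topology annotation and nascent-chain fragment estimates.

All 13 mitochondrial-encoded proteins are polytopic inner-membrane proteins.
Each is described by its transmembrane helix (TMH) spans (1-based, inclusive,
in amino acids) and the orientation of its N terminus: ``N-in`` (matrix) or
``N-out`` (intermembrane space).  Because ~30 residues of the nascent chain
are occluded inside the ribosomal exit tunnel, the N terminus of a TMH
reaches the vestibule roughly 30 codons after its first codon is decoded —
the *emergence codon* used to link translational pauses to membrane
insertion events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = [
    "TopologyRecord",
    "FragmentEstimate",
    "tmh_emergence_codons",
    "estimate_fragment",
    "read_topology_table",
    "write_topology_table",
    "DEFAULT_OCCLUSION_AA",
    "AVERAGE_RESIDUE_KDA",
]

DEFAULT_OCCLUSION_AA = 30
AVERAGE_RESIDUE_KDA = 0.110  # standard average residue mass approximation

N_CLASSES = ("N-in", "N-out")


@dataclass
class TopologyRecord:
    """TMH spans and N-terminus class for one protein."""

    protein_id: str
    tmh_spans: list[tuple[int, int]]
    n_class: str
    sequence_aa: str | None = None

    def __post_init__(self) -> None:
        if self.n_class not in N_CLASSES:
            raise ValueError(f"{self.protein_id}: n_class must be one of {N_CLASSES}")
        spans = [(int(s), int(e)) for s, e in self.tmh_spans]
        for s, e in spans:
            if not 1 <= s <= e:
                raise ValueError(f"{self.protein_id}: invalid TMH span ({s}, {e})")
        if spans != sorted(spans):
            raise ValueError(f"{self.protein_id}: TMH spans must be sorted")
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.protein_id}: overlapping TMH spans")
        self.tmh_spans = spans

    @property
    def n_tmh(self) -> int:
        return len(self.tmh_spans)

    @property
    def first_tmh_start(self) -> int:
        if not self.tmh_spans:
            raise ValueError(f"{self.protein_id}: no TMH spans")
        return self.tmh_spans[0][0]


@dataclass(frozen=True)
class FragmentEstimate:
    """Nascent-chain fragment implied by a ribosome with its P-site at a codon."""

    length_aa: int
    mass_kda: float
    mass_model: str  # "average-residue" or "sequence-exact"


def tmh_emergence_codons(
    rec: TopologyRecord, occlusion_aa: int = DEFAULT_OCCLUSION_AA
) -> list[int]:
    """Codon at which each TMH's N terminus reaches the ribosome vestibule.

    With the default 30-residue tunnel occlusion, a TMH starting at residue 1
    emerges when codon 31 is in the P-site.
    """
    if occlusion_aa < 0:
        raise ValueError("occlusion_aa must be >= 0")
    return [start + occlusion_aa for start, _ in rec.tmh_spans]


def estimate_fragment(
    psite_codon: int,
    rec: TopologyRecord | None = None,
    model: str = "average-residue",
) -> FragmentEstimate:
    """Estimate the nascent-chain fragment for a ribosome paused at a codon.

    The fragment length equals the P-site codon index; mass is either
    ``length x 0.110 kDa`` (average-residue) or the exact average molecular
    weight of the N-terminal subsequence when a protein sequence is supplied.
    """
    if psite_codon < 1:
        raise ValueError("psite_codon must be >= 1")
    if model == "average-residue":
        return FragmentEstimate(psite_codon, psite_codon * AVERAGE_RESIDUE_KDA, model)
    if model == "sequence-exact":
        if rec is None or rec.sequence_aa is None:
            raise ValueError("sequence-exact mass requires a protein sequence")
        if psite_codon > len(rec.sequence_aa):
            raise ValueError(
                f"psite_codon {psite_codon} beyond {rec.protein_id} length "
                f"{len(rec.sequence_aa)}"
            )
        mass = molecular_weight(rec.sequence_aa[:psite_codon], seq_type="protein") / 1000.0
        return FragmentEstimate(psite_codon, mass, model)
    raise ValueError(f"unknown mass model {model!r}")


# ---------------------------------------------------------------------------
# TSV I/O: protein_id, n_class, semicolon-separated "start-end" spans
# ---------------------------------------------------------------------------

def write_topology_table(records: list[TopologyRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "n_class": r.n_class,
            "tmh_spans": ";".join(f"{s}-{e}" for s, e in r.tmh_spans),
        }
        for r in records
    ]
    with open(path, "w") as fh:
        fh.write("# mitoribo topology table; TMH spans 1-based inclusive (aa)\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_topology_table(path: str | Path) -> list[TopologyRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples():
        spans = []
        if isinstance(row.tmh_spans, str) and row.tmh_spans:
            for part in row.tmh_spans.split(";"):
                s, e = part.split("-")
                spans.append((int(s), int(e)))
        records.append(
            TopologyRecord(protein_id=str(row.protein_id), tmh_spans=spans, n_class=str(row.n_class))
        )
    return records
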