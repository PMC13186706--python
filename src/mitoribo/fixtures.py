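"""Synthetic reference fixtures.

Everything here is generated programmatically from fixed-seed RNGs; no real
genomic sequence is shipped.  Two fixtures are provided:

* a tiny *toy* genome (three genes, one incomplete stop, one bicistronic
  pair) for fast unit tests;
* a *human-mtDNA-like* genome: 13 protein-coding genes with lengths close to
  the real human mitochondrial CDS lengths, the real incomplete-stop set
  (ND1, ND2, ND3, ND4, CYTB, COX3, ATP6) and the two bicistronic pairs
  (ATP8-ATP6, ND4L-ND4), yielding 11 transcript units.  Unlike the real
  genome, the bicistronic pairs abut in frame so that merged-unit codon
  bookkeeping is exact; ND6 is placed on the minus strand.

The accompanying topology table mirrors published span counts for COX1 (12
TMHs) and COX2 (2 TMHs) and the N-in/N-out classes of COX3 and ND1; all other
spans and classes are plausible synthetic stand-ins (fixture-quality).
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from .reference import (
    DEFAULT_POLYA_LEN,
    GeneRecord,
    MitoAnnotation,
    build_modified_reference,
)
from .topology import TopologyRecord

__all__ = [
    "toy_genome",
    "toy_annotation",
    "human_mtdna_like_genome",
    "human_mtdna_like_annotation",
    "human_mtdna_like_topology",
]

_FIXTURE_SEED = 20240917

# (gene_id, complete ORF length incl. stop, incomplete-stop tail kept on genome)
# tail "TA" keeps ORF length - 1 nt on the genome, "T" keeps length - 2.
_GENE_PLAN = [
    ("ND1", 957, "TA"),
    ("ND2", 1044, "T"),
    ("COX1", 1542, None),
    ("COX2", 684, None),
    ("ATP8", 207, None),
    ("ATP6", 681, "TA"),
    ("COX3", 786, "T"),
    ("ND3", 348, "T"),
    ("ND4L", 297, None),
    ("ND4", 1380, "T"),
    ("ND5", 1812, None),
    ("ND6", 528, None),
    ("CYTB", 1143, "T"),
]

_PAIRS = {"ATP8": "ATP6", "ND4L": "ND4"}  # upstream -> downstream, abutting
_MINUS_STRAND = {"ND6"}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


def _random_orf(rng: np.random.Generator, length_nt: int) -> str:
    """ATG + random stop-free codons + TAA, ``length_nt`` total."""
    assert length_nt % 3 == 0 and length_nt >= 9
    n_internal = length_nt // 3 - 2
    codons = []
    while len(codons) < n_internal:
        chunk = ["".join(_BASES[rng.integers(0, 4, 3)]) for _ in range(n_internal - len(codons))]
        codons.extend(c for c in chunk if c not in _STOPS)
    return "ATG" + "".join(codons[:n_internal]) + "TAA"


def _random_spacer(rng: np.random.Generator, length_nt: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length_nt)])


def _assemble(plan, pairs, minus, rng, spacer=50):
    genome_parts = [_random_spacer(rng, spacer)]
    pos = spacer
    genes: list[GeneRecord] = []
    downstream = set(pairs.values())
    for gene_id, orf_len, tail in plan:
        if gene_id in downstream:
            continue  # written right after its upstream partner
        chain = [(gene_id, orf_len, tail)]
        if gene_id in pairs:
            down_id = pairs[gene_id]
            chain.append(next(p for p in plan if p[0] == down_id))
        for i, (gid, glen, gtail) in enumerate(chain):
            orf = _random_orf(rng, glen)
            if gtail == "TA":
                gseq = orf[:-1]
            elif gtail == "T":
                gseq = orf[:-2]
            else:
                gseq = orf
            strand = "-" if gid in minus else "+"
            genome_seq = gseq if strand == "+" else str(Seq(gseq).reverse_complement())
            genome_parts.append(genome_seq)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    genome_start=pos,
                    genome_end=pos + len(gseq),
                    strand=strand,
                    incomplete_stop=gtail is not None,
                    bicistronic_partner=pairs.get(gid),
                )
            )
            pos += len(gseq)
            if i == len(chain) - 1:
                genome_parts.append(_random_spacer(rng, spacer))
                pos += spacer
    return "".join(genome_parts), genes


def human_mtdna_like_genome() -> tuple[str, list[GeneRecord]]:
    """Deterministic synthetic genome with human-like mitochondrial gene layout."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    return _assemble(_GENE_PLAN, _PAIRS, _MINUS_STRAND, rng)


def human_mtdna_like_annotation(polya_len: int = DEFAULT_POLYA_LEN) -> MitoAnnotation:
    genome, genes = human_mtdna_like_genome()
    return build_modified_reference(
        genome,
        genes,
        polya_len=polya_len,
        genome_id="chrM-like",
        provenance="synthetic human-mtDNA-like fixture (seeded RNG, mitoribo.fixtures)",
    )


# ---------------------------------------------------------------------------
# Topology fixture
# ---------------------------------------------------------------------------

# protein_id -> (n_class, [(start_aa, end_aa), ...]); COX1/COX2 span counts and
# COX3/ND1 classes follow the literature, the rest are fixture-quality.
_TOPOLOGY_PLAN: dict[str, tuple[str, list[tuple[int, int]]]] = {
    "COX1": ("N-in", [(12, 40), (51, 86), (95, 117), (141, 170), (178, 210),
                      (228, 265), (270, 290), (299, 327), (335, 356),
                      (371, 400), (405, 425), (447, 478)]),
    "COX2": ("N-out", [(28, 48), (62, 82)]),
    "COX3": ("N-in", [(15, 35), (42, 62), (81, 101), (125, 145), (159, 179),
                      (197, 217), (239, 259)]),
    "ND1": ("N-out", [(8, 28), (75, 95), (100, 120), (134, 154), (171, 191),
                      (223, 243), (253, 273), (294, 314)]),
    "ND2": ("N-out", [(2, 22), (35, 55), (62, 82), (88, 108), (114, 134),
                      (150, 170), (196, 216), (224, 244), (249, 269), (275, 295)]),
    "ATP8": ("N-in", [(8, 28)]),
    "ATP6": ("N-in", [(20, 40), (70, 90), (100, 120), (140, 160), (180, 200)]),
    "ND3": ("N-in", [(5, 25), (40, 60), (85, 105)]),
    "ND4L": ("N-in", [(2, 22), (30, 50), (65, 85)]),
    "ND4": ("N-out", [(20, 40), (60, 80), (95, 115), (130, 150), (165, 185),
                      (200, 220), (240, 260), (280, 300), (310, 330),
                      (350, 370), (385, 405), (420, 440)]),
    "ND5": ("N-in", [(s, s + 20) for s in (10, 45, 85, 120, 155, 190, 230, 265,
                                           300, 340, 375, 410, 450, 485, 520)]),
    "ND6": ("N-out", [(10, 30), (40, 60), (75, 95), (105, 125), (140, 160)]),
    "CYTB": ("N-in", [(33, 53), (77, 97), (113, 133), (140, 160), (178, 198),
                      (228, 248), (288, 308), (322, 342)]),
}


def human_mtdna_like_topology() -> list[TopologyRecord]:
    """Per-protein TMH spans and N-terminus classes for the fixture proteome."""
    return [
        TopologyRecord(protein_id=pid, tmh_spans=list(spans), n_class=n_class)
        for pid, (n_class, spans) in _TOPOLOGY_PLAN.items()
    ]


# ---------------------------------------------------------------------------
# Toy fixture: three genes, one incomplete stop, one bicistronic pair
# ---------------------------------------------------------------------------

_TOY_PLAN = [
    ("geneA", 120, "TA"),
    ("geneB", 90, None),
    ("geneC", 150, "T"),
]
_TOY_PAIRS = {"geneB": "geneC"}


def toy_genome() -> tuple[str, list[GeneRecord]]:
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    return _assemble(_TOY_PLAN, _TOY_PAIRS, set(), rng, spacer=20)


def toy_annotation(polya_len: int = DEFAULT_POLYA_LEN) -> MitoAnnotation:
    genome, genes = toy_genome()
    return build_modified_reference(
        genome, genes, polya_len=polya_len, genome_id="toy",
        provenance="synthetic toy fixture (seeded RNG, mitoribo.fixtures)",
    )
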