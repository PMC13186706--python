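"""Modified mitochondrial reference construction.

Human mitochondrial mRNAs deviate from textbook ORFs in two ways that matter
for read alignment and codon-level counting:

* seven transcripts (ND1, ND2, ND3, ND4, CYTB, COX3, ATP6) end in ``T`` or
  ``TA`` on the genome; the ``TAA`` stop codon is only completed by
  post-transcriptional polyadenylation;
* two transcript pairs (ATP8/ATP6 and ND4L/ND4) are carried on single
  bicistronic mRNAs and are best represented as one alignable unit.

This module builds the "modified" reference used throughout the pipeline: one
:class:`TranscriptUnit` per mature mRNA, with incomplete stops completed by
simulated polyadenylation, bicistronic pairs merged into a single unit, and a
short poly(A) tail appended so that stop-proximal footprints still align.

Coordinates are 0-based half-open on the nucleotide level internally; codons
are 1-based in every output (``codon 306`` style).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotationError",
    "GeneRecord",
    "TranscriptUnit",
    "MitoAnnotation",
    "complete_stop_codon",
    "merge_bicistronic",
    "build_modified_reference",
    "write_reference",
    "read_reference",
    "read_gene_table",
    "write_gene_table",
]

DEFAULT_POLYA_LEN = 10
STOP_CODON = "TAA"


class AnnotationError(ValueError):
    """Inconsistent gene annotation (spans, stops, bicistronic pairing)."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on the mitochondrial genome.

    ``incomplete_stop`` marks genes whose genomic sequence ends in ``T`` or
    ``TA`` and whose TAA stop is completed by polyadenylation.
    ``bicistronic_partner`` is set on the *upstream* member of a pair only and
    names the downstream gene.
    """

    gene_id: str
    genome_start: int
    genome_end: int
    strand: str = "+"
    incomplete_stop: bool = False
    bicistronic_partner: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.genome_start < self.genome_end:
            raise AnnotationError(
                f"{self.gene_id}: invalid span [{self.genome_start}, {self.genome_end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")

    def extract(self, genome: str) -> str:
        """Gene sequence in transcript orientation."""
        if self.genome_end > len(genome):
            raise AnnotationError(f"{self.gene_id}: span exceeds genome length")
        seq = genome[self.genome_start : self.genome_end]
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class TranscriptUnit:
    """One alignable mRNA unit of the modified reference.

    ``sequence`` is the completed ORF followed by the poly(A) tail.  For merged
    bicistronic units the codon frame follows the upstream gene;
    ``member_codon_counts`` gives each member's codon extent so downstream
    genes can be addressed in their own 1-based codon frame.
    """

    unit_id: str
    sequence: str
    orf_length_nt: int
    polya_len: int
    member_genes: list[str]
    member_codon_counts: list[int]

    @property
    def codon_count(self) -> int:
        return self.orf_length_nt // 3

    @property
    def orf_sequence(self) -> str:
        return self.sequence[: self.orf_length_nt]

    def gene_codon_offset(self, gene_id: str) -> int:
        """0-based codon offset of ``gene_id``'s first codon within the unit."""
        if gene_id not in self.member_genes:
            raise KeyError(f"{gene_id} is not a member of unit {self.unit_id}")
        i = self.member_genes.index(gene_id)
        return sum(self.member_codon_counts[:i])

    def gene_codon_count(self, gene_id: str) -> int:
        return self.member_codon_counts[self.member_genes.index(gene_id)]


@dataclass
class MitoAnnotation:
    """The full modified reference: all transcript units of a genome."""

    genome_id: str
    units: list[TranscriptUnit]
    provenance: str = ""
    _by_id: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._by_id = {u.unit_id: u for u in self.units}
        if len(self._by_id) != len(self.units):
            raise AnnotationError("duplicate unit_ids in annotation")

    def unit(self, unit_id: str) -> TranscriptUnit:
        try:
            return self._by_id[unit_id]
        except KeyError:
            raise KeyError(f"unknown transcript unit {unit_id!r}") from None

    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit_for_gene(self, gene_id: str) -> TranscriptUnit:
        for u in self.units:
            if gene_id in u.member_genes:
                return u
        raise KeyError(f"gene {gene_id!r} not found in any unit")

    def gene_ids(self) -> list[str]:
        return [g for u in self.units for g in u.member_genes]


def complete_stop_codon(seq: str, incomplete_stop: bool) -> str:
    """Complete an incomplete stop codon by simulated polyadenylation.

    Genes flagged ``incomplete_stop`` end in ``T`` (remainder 1) or ``TA``
    (remainder 2) after their last full codon; enough ``A`` is appended so the
    final codon reads ``TAA``.  Unflagged sequences are returned unchanged.
    Already-completed flagged sequences pass through, making the operation
    idempotent.
    """
    if not seq:
        raise AnnotationError("empty sequence")
    if not incomplete_stop:
        return seq
    seq = seq.upper()
    rem = len(seq) % 3
    if rem == 0:
        if seq[-3:] == STOP_CODON:
            return seq
        raise AnnotationError(
            "flagged sequence has no incomplete stop tail (length divisible by 3, "
            f"last codon {seq[-3:]!r})"
        )
    tail = seq[-rem:]
    if rem == 1 and tail == "T":
        return seq + "AA"
    if rem == 2 and tail == "TA":
        return seq + "A"
    raise AnnotationError(
        f"flagged sequence ends in {tail!r}; expected 'T' or 'TA' before polyadenylation"
    )


def _completed_gene_seq(gene: GeneRecord, genome: str) -> str:
    return complete_stop_codon(gene.extract(genome), gene.incomplete_stop)


def merge_bicistronic(a: GeneRecord, b: GeneRecord, genome: str) -> TranscriptUnit:
    """Merge a bicistronic gene pair into a single ORF unit.

    The merged sequence spans from the upstream gene's first nucleotide to the
    downstream gene's completed stop; codon indexing follows the upstream
    gene's frame.  No poly(A) tail is appended here (the reference builder
    does that uniformly).
    """
    if a.bicistronic_partner != b.gene_id:
        raise AnnotationError(
            f"{a.gene_id} does not name {b.gene_id} as its bicistronic partner"
        )
    if a.strand != b.strand:
        raise AnnotationError(
            f"bicistronic pair {a.gene_id}/{b.gene_id} on different strands"
        )
    if a.strand == "+":
        if not a.genome_start < b.genome_start:
            raise AnnotationError(f"{a.gene_id} is not upstream of {b.gene_id}")
        if b.genome_start > a.genome_end:
            raise AnnotationError(
                f"bicistronic pair {a.gene_id}/{b.gene_id} is not adjacent"
            )
        span = genome[a.genome_start : b.genome_end]
    else:
        if not a.genome_end > b.genome_end:
            raise AnnotationError(f"{a.gene_id} is not upstream of {b.gene_id}")
        if b.genome_end < a.genome_start:
            raise AnnotationError(
                f"bicistronic pair {a.gene_id}/{b.gene_id} is not adjacent"
            )
        span = str(Seq(genome[b.genome_start : a.genome_end]).reverse_complement())
    # complete the downstream gene's stop in its own frame; append to the span
    b_completed = _completed_gene_seq(b, genome)
    n_appended = len(b_completed) - (b.genome_end - b.genome_start)
    sequence = span + "A" * n_appended

    a_codons = _codon_len(a, genome)
    b_codons = len(b_completed) // 3
    unit_id = f"{a.gene_id}-{b.gene_id}"
    return TranscriptUnit(
        unit_id=unit_id,
        sequence=sequence,
        orf_length_nt=len(sequence),
        polya_len=0,
        member_genes=[a.gene_id, b.gene_id],
        member_codon_counts=[a_codons, b_codons],
    )


def _codon_len(gene: GeneRecord, genome: str) -> int:
    return len(_completed_gene_seq(gene, genome)) // 3


def build_modified_reference(
    genome: str,
    genes: list[GeneRecord],
    polya_len: int = DEFAULT_POLYA_LEN,
    genome_id: str = "chrM",
    provenance: str = "",
) -> MitoAnnotation:
    """Build the modified reference from a genome and its gene records.

    Produces one :class:`TranscriptUnit` per non-bicistronic gene plus one per
    bicistronic pair; every incomplete stop is completed and a poly(A) tail of
    ``polya_len`` nt is appended to every unit.
    """
    genome = genome.upper()
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise AnnotationError("duplicate gene_ids in gene table")
    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        if g.genome_end > len(genome):
            raise AnnotationError(f"{g.gene_id}: span outside genome")
        if g.bicistronic_partner is not None and g.bicistronic_partner not in by_id:
            raise AnnotationError(
                f"{g.gene_id}: unknown bicistronic partner {g.bicistronic_partner!r}"
            )

    downstream_members = {g.bicistronic_partner for g in genes if g.bicistronic_partner}
    units: list[TranscriptUnit] = []
    for g in genes:
        if g.gene_id in downstream_members:
            continue  # emitted with its upstream partner
        if g.bicistronic_partner is not None:
            unit = merge_bicistronic(g, by_id[g.bicistronic_partner], genome)
        else:
            seq = _completed_gene_seq(g, genome)
            unit = TranscriptUnit(
                unit_id=g.gene_id,
                sequence=seq,
                orf_length_nt=len(seq),
                polya_len=0,
                member_genes=[g.gene_id],
                member_codon_counts=[len(seq) // 3],
            )
        unit.sequence = unit.sequence + "A" * polya_len
        unit.polya_len = polya_len
        units.append(unit)
    return MitoAnnotation(
        genome_id=genome_id, units=units, provenance=provenance
    )


# ---------------------------------------------------------------------------
# I/O: FASTA (one record per unit), GFF3 (gene features), TSV summary
# ---------------------------------------------------------------------------

def write_reference(
    ann: MitoAnnotation,
    fasta_path: str | Path,
    tsv_path: str | Path,
    gff3_path: str | Path | None = None,
    genes: list[GeneRecord] | None = None,
) -> None:
    """Write the modified reference as FASTA + TSV summary (+ optional GFF3)."""
    records = [
        SeqRecord(Seq(u.sequence), id=u.unit_id, description=f"orf_length_nt={u.orf_length_nt} polya_len={u.polya_len}")
        for u in ann.units
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    rows = []
    for u in ann.units:
        rows.append(
            {
                "unit_id": u.unit_id,
                "members": ",".join(u.member_genes),
                "member_codon_counts": ",".join(str(c) for c in u.member_codon_counts),
                "orf_length_nt": u.orf_length_nt,
                "codon_count": u.codon_count,
                "polya_len": u.polya_len,
            }
        )
    df = pd.DataFrame(rows)
    with open(tsv_path, "w") as fh:
        fh.write(f"# mitoribo reference summary; genome_id={ann.genome_id}\n")
        fh.write("# nt coordinates 0-based half-open; codons 1-based\n")
        df.to_csv(fh, sep="\t", index=False)

    if gff3_path is not None:
        _write_gff3(ann, gff3_path, genes)


def _write_gff3(
    ann: MitoAnnotation, path: str | Path, genes: list[GeneRecord] | None
) -> None:
    gene_by_id = {g.gene_id: g for g in genes} if genes else {}
    lines = ["##gff-version 3"]
    for u in ann.units:
        lines.append(
            "\t".join(
                [u.unit_id, "mitoribo", "mRNA", "1", str(len(u.sequence)), ".", "+", ".",
                 f"ID={u.unit_id};orf_length_nt={u.orf_length_nt};polya_len={u.polya_len}"]
            )
        )
        for gid in u.member_genes:
            off_nt = 3 * u.gene_codon_offset(gid)
            end_nt = off_nt + 3 * u.gene_codon_count(gid)
            attrs = [f"ID={gid}", f"Parent={u.unit_id}"]
            g = gene_by_id.get(gid)
            if g is not None:
                attrs += [
                    f"genome_start={g.genome_start}",
                    f"genome_end={g.genome_end}",
                    f"genome_strand={g.strand}",
                    f"incomplete_stop={int(g.incomplete_stop)}",
                ]
            lines.append(
                "\t".join(
                    [u.unit_id, "mitoribo", "gene", str(off_nt + 1), str(end_nt), ".",
                     "+", "0", ";".join(attrs)]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference(fasta_path: str | Path, tsv_path: str | Path) -> MitoAnnotation:
    """Re-read a reference written by :func:`write_reference`."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genome_id = "chrM"
    with open(tsv_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "genome_id=" in line:
                genome_id = line.split("genome_id=")[1].strip()
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    units = []
    for row in df.itertuples():
        units.append(
            TranscriptUnit(
                unit_id=row.unit_id,
                sequence=seqs[row.unit_id],
                orf_length_nt=int(row.orf_length_nt),
                polya_len=int(row.polya_len),
                member_genes=str(row.members).split(","),
                member_codon_counts=[int(c) for c in str(row.member_codon_counts).split(",")],
            )
        )
    return MitoAnnotation(genome_id=genome_id, units=units)


_GENE_COLS = ["gene_id", "genome_start", "genome_end", "strand", "incomplete_stop", "bicistronic_partner"]


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(g) for g in genes])[_GENE_COLS]
    df["incomplete_stop"] = df["incomplete_stop"].astype(int)
    df["bicistronic_partner"] = df["bicistronic_partner"].fillna(".")
    with open(path, "w") as fh:
        fh.write("# mitoribo gene table; nt coordinates 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = []
    for row in df.itertuples():
        partner = None if str(row.bicistronic_partner) in (".", "nan", "") else str(row.bicistronic_partner)
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                genome_start=int(row.genome_start),
                genome_end=int(row.genome_end),
                strand=str(row.strand),
                incomplete_stop=bool(int(row.incomplete_stop)),
                bicistronic_partner=partner,
            )
        )
    return genes
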