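"""Normalized expression metrics for codon profiles.

RPKM (reads per kilobase of transcript per million mapped reads) is computed
within the mito-mapped library: ``rpkm = C / (L_kb * N_M)`` with C the unit's
retained P-site counts, L the ORF length (poly(A) tail excluded) and N the
replicate's total retained reads.  The first-15-codon split separates
initiation-proximal from elongating footprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .processing import CodonProfile
from .reference import MitoAnnotation

__all__ = [
    "TranscriptStats",
    "compute_rpkm",
    "split_first15",
    "normalize_density",
    "stats_table",
]

FIRST_SPLIT_CODON = 15  # boundary inclusive


@dataclass(frozen=True)
class TranscriptStats:
    unit_id: str
    replicate_id: str
    count: int
    orf_length_nt: int
    rpkm: float
    rpm: float
    first15: int
    downstream: int


def compute_rpkm(profile: CodonProfile, ann: MitoAnnotation) -> TranscriptStats:
    """Length- and library-normalized expression for one unit."""
    if profile.library_size <= 0:
        raise ValueError("library size must be positive for RPKM")
    unit = ann.unit(profile.unit_id)
    c = profile.total
    l_kb = unit.orf_length_nt / 1000.0
    n_m = profile.library_size / 1e6
    first15, downstream = split_first15(profile)
    return TranscriptStats(
        unit_id=profile.unit_id,
        replicate_id=profile.replicate_id,
        count=c,
        orf_length_nt=unit.orf_length_nt,
        rpkm=c / (l_kb * n_m),
        rpm=c / n_m,
        first15=first15,
        downstream=downstream,
    )


def split_first15(profile: CodonProfile, boundary: int = FIRST_SPLIT_CODON) -> tuple[int, int]:
    """Reads with P-site in codons 1..boundary vs codon boundary+1 and beyond."""
    first = int(profile.counts[:boundary].sum())
    return first, profile.total - first


def normalize_density(profile: CodonProfile | np.ndarray) -> np.ndarray:
    """Transcript-mean-normalized per-codon densities (uniform profile -> 1.0)."""
    counts = profile.counts if isinstance(profile, CodonProfile) else np.asarray(profile)
    counts = counts.astype(float)
    mean = counts.mean() if counts.size else 0.0
    if mean == 0:
        warnings.warn("normalize_density: empty profile, returning zeros")
        return np.zeros_like(counts)
    return counts / mean


def stats_table(profiles: list[CodonProfile], ann: MitoAnnotation) -> pd.DataFrame:
    """Per-unit, per-replicate expression table."""
    rows = [compute_rpkm(p, ann).__dict__ for p in profiles]
    return pd.DataFrame(rows)
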