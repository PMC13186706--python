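"""Codon-level translational pause calling and TMH-emergence annotation.

A pause is a codon whose P-site density stands out against the transcript's
own background, summarized by the score ``s = d_c / trimmed_mean(d)`` (10%
trimmed from each tail, robust to the pauses themselves).  Codons with
``s >= s_min`` are called; runs of one or two consecutive above-threshold
codons are merged into a single call at the maximum (reported in the
``92/93`` pair style), longer runs are split into separate calls.  The
initiation region (codons 1..10) is excluded from elongation-pause calling
and reported separately as initiation pausing.

Calls are annotated against the protein's TMH emergence codons (TMH start +
tunnel occlusion) and carry a nascent-chain fragment estimate whose length
in residues equals the P-site codon index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .processing import CodonProfile
from .reference import MitoAnnotation
from .topology import (
    DEFAULT_OCCLUSION_AA,
    FragmentEstimate,
    TopologyRecord,
    estimate_fragment,
    tmh_emergence_codons,
)

__all__ = [
    "PauseConfig",
    "PauseCall",
    "call_pauses",
    "combine_replicate_calls",
    "annotate_tmh_linkage",
    "initiation_pause_share",
    "calls_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PauseConfig:
    s_min: float = 4.0
    trim_fraction: float = 0.1
    quorum: int = 2
    min_coverage_mean: float = 5.0  # mean P-site count per codon
    init_exclude: int = 10          # codons excluded as initiation pausing
    occlusion_aa: int = DEFAULT_OCCLUSION_AA
    emergence_tolerance: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.s_min <= 0:
            raise ValueError("s_min must be positive")


@dataclass
class PauseCall:
    unit_id: str
    codon: int                     # codon of the maximum within the call
    codons: tuple[int, ...]        # 1 or 2 merged codons, e.g. (92, 93)
    score: float
    replicate_support: int = 1
    replicates: list[str] = field(default_factory=list)
    tmh_linked: bool = False
    linked_tmh: int | None = None  # 1-based TMH index
    fragment: FragmentEstimate | None = None

    @property
    def label(self) -> str:
        return "/".join(str(c) for c in self.codons)


def _trimmed_background(d: np.ndarray, trim: float) -> float:
    return float(stats.trim_mean(d, trim)) if len(d) else 0.0


def call_pauses(profile: CodonProfile, cfg: PauseConfig | None = None) -> list[PauseCall]:
    """Pause calls on a single replicate's profile, ranked by score."""
    cfg = cfg or PauseConfig()
    d = profile.counts.astype(float)
    if d.mean() < cfg.min_coverage_mean:
        logger.warning(
            "call_pauses: %s %s coverage %.2f below %.2f reads/codon; no calls",
            profile.unit_id, profile.replicate_id, d.mean(), cfg.min_coverage_mean,
        )
        return []
    background = _trimmed_background(d, cfg.trim_fraction)
    if background <= 0:
        logger.warning("call_pauses: zero background on %s", profile.unit_id)
        return []
    scores = d / background
    above = scores >= cfg.s_min
    above[: cfg.init_exclude] = False

    calls: list[PauseCall] = []
    i = 0
    n = len(scores)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        calls.extend(_split_run(profile.unit_id, scores, i, j, profile.replicate_id))
        i = j + 1
    calls.sort(key=lambda c: (-c.score, c.codon))
    return calls


def _split_run(
    unit_id: str, scores: np.ndarray, i: int, j: int, replicate_id: str
) -> list[PauseCall]:
    """Merge runs of <=2 above-threshold codons; split longer runs greedily
    into single/pair calls around local maxima (deterministic, ties toward
    the smaller codon)."""
    idx = list(range(i, j + 1))
    calls = []
    remaining = set(idx)
    while remaining:
        k = min(remaining, key=lambda x: (-scores[x], x))
        pair = [k]
        # absorb one adjacent above-threshold codon into a pair call
        neighbors = [x for x in (k - 1, k + 1) if x in remaining]
        if neighbors:
            nb = max(neighbors, key=lambda x: (scores[x], -x))
            pair.append(nb)
        codons = tuple(sorted(p + 1 for p in pair))
        calls.append(
            PauseCall(
                unit_id=unit_id,
                codon=k + 1,
                codons=codons,
                score=float(scores[k]),
                replicates=[replicate_id],
            )
        )
        remaining.difference_update(pair)
    return calls


def combine_replicate_calls(
    per_replicate: list[list[PauseCall]],
    cfg: PauseConfig | None = None,
    merge_tolerance: int = 1,
) -> list[PauseCall]:
    """Aggregate per-replicate calls; keep those supported in >= quorum
    replicates (codons matching within ``merge_tolerance``)."""
    cfg = cfg or PauseConfig()
    clusters: list[list[PauseCall]] = []
    for calls in per_replicate:
        for call in calls:
            for cluster in clusters:
                if (
                    cluster[0].unit_id == call.unit_id
                    and abs(cluster[0].codon - call.codon) <= merge_tolerance
                ):
                    cluster.append(call)
                    break
            else:
                clusters.append([call])
    combined = []
    for cluster in clusters:
        support_reps = sorted({r for c in cluster for r in c.replicates})
        if len(support_reps) < cfg.quorum:
            continue
        best = max(cluster, key=lambda c: c.score)
        combined.append(
            PauseCall(
                unit_id=best.unit_id,
                codon=best.codon,
                codons=best.codons,
                score=float(np.mean([c.score for c in cluster])),
                replicate_support=len(support_reps),
                replicates=support_reps,
            )
        )
    combined.sort(key=lambda c: (-c.score, c.codon))
    return combined


def annotate_tmh_linkage(
    calls: list[PauseCall],
    topo: TopologyRecord,
    ann: MitoAnnotation | None = None,
    cfg: PauseConfig | None = None,
) -> list[PauseCall]:
    """Set ``tmh_linked`` and attach fragment estimates to each call.

    A call is linked to TMH *k* when its codon (in the protein's own frame)
    lies within ``emergence_tolerance`` codons of that TMH's emergence codon.
    For proteins inside bicistronic units, the annotation is used to convert
    unit codons to the protein frame.
    """
    cfg = cfg or PauseConfig()
    emergence = tmh_emergence_codons(topo, cfg.occlusion_aa)
    offset = 0
    if ann is not None:
        unit = ann.unit_for_gene(topo.protein_id)
        offset = unit.gene_codon_offset(topo.protein_id)
    for call in calls:
        protein_codon = call.codon - offset
        call.fragment = estimate_fragment(max(protein_codon, 1))
        call.tmh_linked = False
        call.linked_tmh = None
        for k, em in enumerate(emergence, start=1):
            if abs(protein_codon - em) <= cfg.emergence_tolerance:
                call.tmh_linked = True
                call.linked_tmh = k
                break
    return calls


def initiation_pause_share(profile: CodonProfile, span: int = 10) -> float:
    """Fraction of the unit's reads with P-site in codons 1..span."""
    total = profile.total
    if total == 0:
        return float("nan")
    return float(profile.counts[:span].sum() / total)


def calls_table(calls: list[PauseCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "unit_id": c.unit_id,
                "codons": c.label,
                "codon": c.codon,
                "score": c.score,
                "replicate_support": c.replicate_support,
                "tmh_linked": c.tmh_linked,
                "linked_tmh": c.linked_tmh if c.linked_tmh is not None else ".",
                "fragment_aa": c.fragment.length_aa if c.fragment else ".",
                "fragment_kda": round(c.fragment.mass_kda, 3) if c.fragment else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "codons", "codon", "score", "replicate_support",
                 "tmh_linked", "linked_tmh", "fragment_aa", "fragment_kda"],
    )
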