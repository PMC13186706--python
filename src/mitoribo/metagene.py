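"""Metagene profiles: start-, stop- and first-TMH-anchored ribosome density.

Transcripts are aligned at a common anchor and their per-codon densities
averaged per offset:

* ``start``: offsets 1..window are codons 1..window;
* ``stop``: offsets -window..-1, offset -1 being the last ORF codon;
* ``first-TMH``: offset 0 is the first codon of the protein's first TMH, and
  profiles are computed per *protein* (members of bicistronic units are
  treated separately) and can be stratified by N-terminus topology class.

Transcripts shorter than the window contribute only to the offsets they
cover.  Densities default to raw averaged P-site counts so that the peak
threshold is expressed on the library's count scale; transcript-mean
normalization is selectable.  The mean and s.e.m. are taken across
transcripts within each replicate, then averaged across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median_low

import numpy as np
import pandas as pd

from .metrics import normalize_density
from .processing import CodonProfile, profiles_by_replicate
from .reference import MitoAnnotation
from .topology import TopologyRecord

__all__ = [
    "MetageneConfig",
    "MetageneProfile",
    "anchored_metagene",
    "detect_peaks",
    "peak_spacing",
    "stop_proximal_drop",
    "metagene_table",
]

ANCHORS = ("start", "stop", "first-TMH")


@dataclass(frozen=True)
class MetageneConfig:
    window: int = 100
    density_threshold: float = 200.0  # averaged-density units (count scale)
    min_peak_separation: int = 5
    normalize: str = "none"  # "none" (raw counts) or "mean"
    moving_average: int = 0  # optional smoothing window, 0 = off

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.density_threshold < 0:
            raise ValueError("density threshold must be >= 0")
        if self.normalize not in ("none", "mean"):
            raise ValueError("normalize must be 'none' or 'mean'")


@dataclass
class MetageneProfile:
    anchor: str
    group: str
    offsets: np.ndarray
    mean_density: np.ndarray
    sem: np.ndarray
    n_transcripts: int
    replicates: list[str] = field(default_factory=list)


def _aligned_vector(density: np.ndarray, anchor: str, anchor_codon: int, window: int) -> np.ndarray:
    """Density at the window's offsets; NaN where the transcript has no codon."""
    n = len(density)
    out = np.full(window + (1 if anchor == "first-TMH" else 0), np.nan)
    if anchor == "start":
        k = min(window, n)
        out[:k] = density[:k]
    elif anchor == "stop":
        k = min(window, n)
        out[window - k :] = density[n - k :]
    elif anchor == "first-TMH":
        # offsets 0..window, anchor_codon is 1-based within the density vector
        lo = anchor_codon - 1
        k = min(window + 1, n - lo)
        if k > 0:
            out[:k] = density[lo : lo + k]
    else:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")
    return out


def _protein_density(profile: CodonProfile, ann: MitoAnnotation, gene_id: str) -> np.ndarray:
    unit = ann.unit(profile.unit_id)
    off = unit.gene_codon_offset(gene_id)
    return profile.counts[off : off + unit.gene_codon_count(gene_id)].astype(float)


def anchored_metagene(
    profiles: list[CodonProfile],
    anchor: str,
    ann: MitoAnnotation,
    cfg: MetageneConfig | None = None,
    topology: list[TopologyRecord] | None = None,
    groups: tuple[str, ...] | None = None,
) -> dict[str, MetageneProfile]:
    """Metagene profile(s) for one anchor, optionally stratified by topology.

    For ``start``/``stop`` anchors a single profile over all units is
    returned under group ``all``.  For ``first-TMH``, a topology table is
    required and one profile per N-terminus class (default groups
    ``("N-in", "N-out")``) is returned, each over the member proteins of that
    class.
    """
    cfg = cfg or MetageneConfig()
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")

    if anchor == "first-TMH":
        if topology is None:
            raise ValueError("first-TMH anchor requires a topology table")
        groups = groups or ("N-in", "N-out")
        members = {
            g: [t for t in topology if t.n_class == g and t.tmh_spans] for g in groups
        }
        for g, recs in members.items():
            if not recs:
                raise ValueError(f"empty topology group {g!r}")
        offsets = np.arange(0, cfg.window + 1)
    else:
        groups = ("all",)
        offsets = (
            np.arange(1, cfg.window + 1) if anchor == "start"
            else np.arange(-cfg.window, 0)
        )

    by_rep = profiles_by_replicate(profiles)
    out: dict[str, MetageneProfile] = {}
    for group in groups:
        rep_means, rep_sems, n_tx = [], [], 0
        for rep in sorted(by_rep):
            rows = []
            if anchor == "first-TMH":
                prof_by_unit = {p.unit_id: p for p in by_rep[rep]}
                for topo in members[group]:
                    unit = ann.unit_for_gene(topo.protein_id)
                    p = prof_by_unit.get(unit.unit_id)
                    if p is None:
                        continue
                    dens = _protein_density(p, ann, topo.protein_id)
                    dens = _maybe_normalize(dens, cfg)
                    rows.append(
                        _aligned_vector(dens, anchor, topo.first_tmh_start, cfg.window)
                    )
            else:
                for p in by_rep[rep]:
                    dens = _maybe_normalize(p.counts.astype(float), cfg)
                    rows.append(_aligned_vector(dens, anchor, 1, cfg.window))
            if not rows:
                raise ValueError(f"no transcripts for group {group!r} in {rep}")
            mat = np.vstack(rows)
            n_tx = mat.shape[0]
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                # offsets covered by <2 transcripts have no defined spread
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(mat, axis=0)
                n_per = np.sum(~np.isnan(mat), axis=0)
                sd = np.nanstd(mat, axis=0, ddof=1) if n_tx > 1 else np.zeros(mat.shape[1])
            # s.e.m. is 0 where fewer than two transcripts cover the offset
            sem = np.where(n_per > 1, np.nan_to_num(sd) / np.sqrt(np.maximum(n_per, 1)), 0.0)
            rep_means.append(mean)
            rep_sems.append(sem)
        with warnings.catch_warnings():
            # offsets covered by no transcript stay NaN by design
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_density = np.nanmean(np.vstack(rep_means), axis=0)
        sem = np.mean(np.vstack(rep_sems), axis=0)
        if cfg.moving_average > 1:
            mean_density = _moving_average(mean_density, cfg.moving_average)
        out[group] = MetageneProfile(
            anchor=anchor,
            group=group,
            offsets=offsets,
            mean_density=mean_density,
            sem=np.nan_to_num(sem),
            n_transcripts=n_tx,
            replicates=sorted(by_rep),
        )
    return out


def _maybe_normalize(density: np.ndarray, cfg: MetageneConfig) -> np.ndarray:
    if cfg.normalize == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return normalize_density(density)
    return density


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    kernel = np.ones(k) / k
    pad = k // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def detect_peaks(mg: MetageneProfile, cfg: MetageneConfig | None = None) -> list[int]:
    """Local density maxima above the averaged-density threshold.

    Maxima must be separated by at least ``min_peak_separation`` codons;
    within a conflict the higher peak wins, ties toward the smaller offset.
    """
    cfg = cfg or MetageneConfig()
    d = np.nan_to_num(mg.mean_density)
    candidates = []
    for i in range(len(d)):
        # the left window edge is never a peak (a plateau or ramp truncated by
        # the window would otherwise always report its first element)
        left = d[i - 1] if i > 0 else np.inf
        right = d[i + 1] if i < len(d) - 1 else -np.inf
        if d[i] >= cfg.density_threshold and d[i] > left and d[i] >= right:
            candidates.append(i)
    # highest density first; ties toward smaller offset
    candidates.sort(key=lambda i: (-d[i], mg.offsets[i]))
    accepted: list[int] = []
    for i in candidates:
        if all(abs(int(mg.offsets[i]) - a) >= cfg.min_peak_separation for a in accepted):
            accepted.append(int(mg.offsets[i]))
    return sorted(accepted)


def peak_spacing(peaks: list[int]) -> float:
    """Modal spacing of a repeating peak motif, in codons.

    Peaks are split into motif occurrences at large inter-peak gaps; peaks of
    consecutive occurrences are associated by rank within their occurrence
    and the mode of the resulting differences is returned (median on ties).
    """
    if len(peaks) < 2:
        raise ValueError("peak spacing requires at least two peaks")
    peaks = sorted(peaks)
    gaps = np.diff(peaks)
    if len(peaks) == 2:
        return float(gaps[0])
    threshold = (gaps.max() + gaps.min()) / 2.0
    motifs: list[list[int]] = [[peaks[0]]]
    for p, gap in zip(peaks[1:], gaps):
        if gap >= threshold:
            motifs.append([p])
        else:
            motifs[-1].append(p)
    diffs: list[float] = []
    for a, b in zip(motifs, motifs[1:]):
        for p, q in zip(a, b):
            diffs.append(float(q - p))
    if not diffs:
        raise ValueError("no consecutive motif occurrences to compare")
    values, counts = np.unique(diffs, return_counts=True)
    top = values[counts == counts.max()]
    if len(top) == 1:
        return float(top[0])
    return float(median_low(sorted(top)))


def stop_proximal_drop(
    profile: CodonProfile, last_k: int = 10
) -> float:
    """Descriptive stop-proximal density drop: mean of the last k codons
    relative to the transcript mean (values < 1 indicate the drop)."""
    d = profile.counts.astype(float)
    if d.mean() == 0:
        return float("nan")
    return float(d[-last_k:].mean() / d.mean())


def metagene_table(mg: MetageneProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "anchor": mg.anchor,
            "group": mg.group,
            "offset": mg.offsets,
            "mean_density": mg.mean_density,
            "sem": mg.sem,
            "n_transcripts": mg.n_transcripts,
        }
    )
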