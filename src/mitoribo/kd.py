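"""Knockdown vs control enrichment analysis.

Compares a morpholino-knockdown library against an untreated control at the
transcript level (percent RPKM reduction) and the codon level (enrichment
over control, ``e_c``).

Normalization modes
-------------------
``matched`` (default): library sizes are corrected with median-of-ratios
size factors across transcript units, so that a pure abundance knockdown of
one target yields an unbiased percent reduction (the estimator is consistent
for ``100 x (1 - scale)``).  ``rpm``: plain per-million scaling by total
retained mito reads; this mode reproduces the compositional effect whereby
non-target transcripts appear to rise when the target falls.

Codon-level enrichment uses no pseudocount: codons with zero control counts
are flagged missing rather than reported as infinite enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .processing import CodonProfile, profiles_by_replicate
from .reference import MitoAnnotation

__all__ = ["KDComparison", "compare_libraries", "compare_replicates", "comparison_table"]


@dataclass
class KDComparison:
    unit_id: str
    replicate_id: str
    rpkm_ctrl: float
    rpkm_kd: float
    percent_reduction: float       # 100 x (1 - corrected RPKM ratio)
    enrichment: np.ndarray         # e_c per codon; NaN where control is 0
    log2_enrichment: np.ndarray
    missing: np.ndarray = field(default=None)  # True where control count is 0
    size_factor: float = 1.0       # KD-vs-control normalization factor applied


def _rpm(counts: float | np.ndarray, library_size: int) -> float | np.ndarray:
    return counts / (library_size / 1e6)


def compare_libraries(
    kd_profiles: list[CodonProfile],
    ctrl_profiles: list[CodonProfile],
    ann: MitoAnnotation,
    normalization: str = "matched",
) -> list[KDComparison]:
    """Per-unit comparison of one KD library against one control library."""
    if normalization not in ("matched", "rpm"):
        raise ValueError("normalization must be 'matched' or 'rpm'")
    kd_by_unit = {p.unit_id: p for p in kd_profiles}
    ctrl_by_unit = {p.unit_id: p for p in ctrl_profiles}
    if set(kd_by_unit) != set(ctrl_by_unit):
        raise ValueError("KD and control libraries cover different unit sets")

    # median-of-ratios size factor: robust to the (single) changed target
    ratios = []
    for uid in kd_by_unit:
        kd_p, ctrl_p = kd_by_unit[uid], ctrl_by_unit[uid]
        if kd_p.total > 0 and ctrl_p.total > 0:
            ratios.append(
                _rpm(kd_p.total, kd_p.library_size)
                / _rpm(ctrl_p.total, ctrl_p.library_size)
            )
    size_factor = float(np.median(ratios)) if (normalization == "matched" and ratios) else 1.0

    out = []
    for unit in ann.units:
        uid = unit.unit_id
        kd_p, ctrl_p = kd_by_unit[uid], ctrl_by_unit[uid]
        l_kb = unit.orf_length_nt / 1000.0
        rpkm_ctrl = _rpm(ctrl_p.total, ctrl_p.library_size) / l_kb
        rpkm_kd = _rpm(kd_p.total, kd_p.library_size) / l_kb
        ratio = (rpkm_kd / size_factor) / rpkm_ctrl if rpkm_ctrl > 0 else np.nan
        kd_rpm = _rpm(kd_p.counts.astype(float), kd_p.library_size) / size_factor
        ctrl_rpm = _rpm(ctrl_p.counts.astype(float), ctrl_p.library_size)
        missing = ctrl_p.counts == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(missing, np.nan, kd_rpm / np.where(missing, 1.0, ctrl_rpm))
            log2_e = np.log2(np.where(e > 0, e, np.nan))
        out.append(
            KDComparison(
                unit_id=uid,
                replicate_id=kd_p.replicate_id,
                rpkm_ctrl=float(rpkm_ctrl),
                rpkm_kd=float(rpkm_kd),
                percent_reduction=float(100.0 * (1.0 - ratio)),
                enrichment=e,
                log2_enrichment=log2_e,
                missing=missing,
                size_factor=size_factor,
            )
        )
    return out


def compare_replicates(
    kd_profiles: list[CodonProfile],
    ctrl_profiles: list[CodonProfile],
    ann: MitoAnnotation,
    normalization: str = "matched",
) -> pd.DataFrame:
    """Pair KD and control replicates by order and average percent reductions.

    Returns a per-unit table with the mean and s.d. of percent_reduction
    across replicate pairs.
    """
    kd_reps = profiles_by_replicate(kd_profiles)
    ctrl_reps = profiles_by_replicate(ctrl_profiles)
    pairs = list(zip(sorted(kd_reps), sorted(ctrl_reps)))
    rows = []
    for kd_rep, ctrl_rep in pairs:
        comps = compare_libraries(
            kd_reps[kd_rep], ctrl_reps[ctrl_rep], ann, normalization
        )
        for c in comps:
            rows.append(
                {
                    "unit_id": c.unit_id,
                    "kd_replicate": kd_rep,
                    "ctrl_replicate": ctrl_rep,
                    "rpkm_ctrl": c.rpkm_ctrl,
                    "rpkm_kd": c.rpkm_kd,
                    "percent_reduction": c.percent_reduction,
                }
            )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("unit_id", sort=False)["percent_reduction"]
        .agg(mean_percent_reduction="mean", sd_percent_reduction="std")
        .reset_index()
    )
    return df.merge(summary, on="unit_id")


def comparison_table(comps: list[KDComparison]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(transcript table, long-format codon enrichment track)."""
    tx = pd.DataFrame(
        [
            {
                "unit_id": c.unit_id,
                "replicate_id": c.replicate_id,
                "rpkm_ctrl": c.rpkm_ctrl,
                "rpkm_kd": c.rpkm_kd,
                "percent_reduction": c.percent_reduction,
                "size_factor": c.size_factor,
            }
            for c in comps
        ]
    )
    tracks = []
    for c in comps:
        tracks.append(
            pd.DataFrame(
                {
                    "unit_id": c.unit_id,
                    "replicate_id": c.replicate_id,
                    "codon": np.arange(1, len(c.enrichment) + 1),
                    "enrichment": c.enrichment,
                    "log2_enrichment": c.log2_enrichment,
                    "flag": np.where(c.missing, "missing_control", "ok"),
                }
            )
        )
    return tx, pd.concat(tracks, ignore_index=True)
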