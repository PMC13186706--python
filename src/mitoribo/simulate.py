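"""Synthetic mitochondrial ribosome-profiling libraries.

The generator draws footprints from an explicit dwell-time model so that every
downstream stage (P-site assignment, metrics, metagene, pause calling,
knockdown comparison) can be tested without deposited sequencing data.

Sampling model
--------------
Each transcript unit ``u`` has a per-codon dwell weight vector ``w`` (baseline
1.0) modulated by three components:

* an *initiation* multiplier over the first ``init_span`` codons (the strong
  start-proximal occupancy seen on all mitochondrial mRNAs);
* discrete *pause sites* ``(codon, multiplier)``;
* an optional *periodic* component anchored at the first TMH codon of each
  member protein: bumps at fixed codon offsets repeated every ``period``
  codons, emulating topology-linked slowing.

A read is generated by drawing its transcript (probability proportional to
``abundance x sum(w)``), its P-site codon (multinomial on ``w / sum(w)``), its
length (30-40 nt window with configurable off-window contamination) and its 5'
start derived from the P-site offset model in reverse.  The 5' start is
clamped to the transcript: footprints over the first codons of a leaderless
mRNA begin at position 0, and 3'-terminal footprints may not extend past the
poly(A) tail.  Morpholino knockdown is modeled purely as scaling of the
target unit's expected read mass.

All randomness flows from one integer seed; the same seed yields a
byte-identical record table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reference import MitoAnnotation, TranscriptUnit
from .topology import TopologyRecord

__all__ = [
    "DwellModel",
    "PeriodicComponent",
    "LibrarySpec",
    "KDSpec",
    "default_length_distribution",
    "initiation_multiplier_for_share",
    "set_initiation_share",
    "default_dwell_models",
    "abundances_for_read_shares",
    "DEFAULT_READ_SHARES",
    "study_conditions",
    "apply_kd",
    "simulate_footprints",
    "simulate_replicates",
    "write_footprints",
    "read_footprints",
    "DEFAULT_PSITE_OFFSET_NT",
]

DEFAULT_PSITE_OFFSET_NT = 14  # 5' end -> P-site first nt, shared with processing
DEFAULT_UMI_LENGTH = 8
DEFAULT_INIT_SPAN = 10

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PeriodicComponent:
    """Topology-linked slowing: bumps at ``anchor + offset + k*period`` codons."""

    anchor_codon: int            # 1-based unit codon of metagene offset 0
    offsets: tuple[int, ...]     # codon offsets relative to the anchor
    period: int                  # repeat spacing in codons (0 = no repeat)
    multiplier: float
    max_codon: int | None = None  # restrict bumps to the member protein's span


@dataclass
class DwellModel:
    """Per-codon dwell weights for one transcript unit."""

    codon_count: int
    initiation_multiplier: float = 1.0
    init_span: int = DEFAULT_INIT_SPAN
    pause_sites: list[tuple[int, float]] = field(default_factory=list)
    periodic_components: list[PeriodicComponent] = field(default_factory=list)

    def weights(self) -> np.ndarray:
        """Dwell weight vector, index 0 = codon 1; strictly positive."""
        w = np.ones(self.codon_count, dtype=float)
        span = min(self.init_span, self.codon_count)
        w[:span] *= self.initiation_multiplier
        for codon, mult in self.pause_sites:
            if not 1 <= codon <= self.codon_count:
                raise ValueError(f"pause codon {codon} outside 1..{self.codon_count}")
            w[codon - 1] *= mult
        for pc in self.periodic_components:
            hi = min(pc.max_codon or self.codon_count, self.codon_count)
            for off in pc.offsets:
                k = 0
                while True:
                    codon = pc.anchor_codon + off + k * pc.period
                    if codon > hi:
                        break
                    if codon >= 1:
                        w[codon - 1] *= pc.multiplier
                    if pc.period <= 0:
                        break
                    k += 1
        if not np.all(w > 0):
            raise ValueError("dwell weights must be strictly positive")
        return w


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: depth, length distribution, UMI scheme, seed."""

    total_reads: int = 100_000
    length_distribution: dict[int, float] | None = None  # nt -> probability
    umi_length: int = DEFAULT_UMI_LENGTH
    seed: int = 0
    replicate_id: str = "rep1"

    def lengths_and_probs(self) -> tuple[np.ndarray, np.ndarray]:
        dist = self.length_distribution or default_length_distribution()
        lengths = np.array(sorted(dist), dtype=int)
        probs = np.array([dist[l] for l in lengths], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("footprint length probabilities must sum to 1")
        return lengths, probs


@dataclass(frozen=True)
class KDSpec:
    """Morpholino knockdown of one transcript: pure abundance scaling."""

    target_unit: str
    scale: float
    mask_region_nt: tuple[int, int] | None = None  # targeted nt window (1-based)

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("kd scale must be in (0, 1]")


def default_length_distribution(contamination: float = 0.10) -> dict[int, float]:
    """Uniform mass on 30-40 nt plus off-window contamination on 20-29 & 41-50."""
    window = range(30, 41)
    off = list(range(20, 30)) + list(range(41, 51))
    dist = {l: (1.0 - contamination) / len(window) for l in window}
    dist.update({l: contamination / len(off) for l in off})
    return dist


def initiation_multiplier_for_share(
    share: float, codon_count: int, init_span: int = DEFAULT_INIT_SPAN,
    residual_weight: float | None = None,
) -> float:
    """Multiplier m such that codons 1..span carry ``share`` of the dwell mass.

    ``residual_weight`` is the total dwell weight outside the initiation span
    (defaults to ``codon_count - span`` for an otherwise-uniform model).
    """
    if not 0 < share < 1:
        raise ValueError("share must be in (0, 1)")
    if residual_weight is None:
        residual_weight = float(codon_count - init_span)
    return share * residual_weight / (init_span * (1.0 - share))


def set_initiation_share(model: DwellModel, share: float) -> DwellModel:
    """Return a copy of ``model`` with the initiation multiplier solved so the
    expected share of reads in codons 1..init_span equals ``share``."""
    w = model.weights()
    span = min(model.init_span, model.codon_count)
    residual = float(w[span:].sum())
    init_shape = w[:span] / model.initiation_multiplier  # non-init structure
    m = share * residual / (init_shape.sum() * (1.0 - share))
    return replace(model, initiation_multiplier=m)


# ---------------------------------------------------------------------------
# Study-condition defaults
# ---------------------------------------------------------------------------

# Read shares per transcript unit as printed for the CHL-treated dataset:
# complex IV 49% (COX1 20, COX2 15, COX3 13... remainder ~1% folded into COX3),
# complex V 17% (ATP8-ATP6), complex III 5% (CYTB), complex I 30% split evenly
# over its six units.
DEFAULT_READ_SHARES: dict[str, float] = {
    "COX1": 0.20,
    "COX2": 0.15,
    "COX3": 0.13,
    "ATP8-ATP6": 0.17,
    "CYTB": 0.05,
    "ND1": 0.05,
    "ND2": 0.05,
    "ND3": 0.05,
    "ND4L-ND4": 0.05,
    "ND5": 0.05,
    "ND6": 0.05,
}

# Elongation pause sites (unit codon, multiplier); the ND2 distal pair is the
# strongest, matching its standing as the major site.
_DEFAULT_PAUSES: dict[str, list[tuple[int, float]]] = {
    "COX1": [(180, 6.0), (230, 6.0)],
    "COX2": [(92, 8.0), (93, 8.0)],
    "ND2": [(92, 6.0), (93, 6.0), (144, 6.0), (145, 6.0), (305, 8.0), (306, 12.0)],
    "ATP8-ATP6": [(35, 5.0), (36, 5.0), (37, 5.0), (38, 5.0)],
}

# Topology-linked metagene bump offsets (relative to first-TMH codon).
_PERIODIC_OFFSETS = {"N-in": (15, 30, 78), "N-out": (30, 55, 78)}
DEFAULT_PERIOD_CODONS = 50
DEFAULT_PERIODIC_MULTIPLIER = 6.0
DEFAULT_INITIATION_MULTIPLIER = 8.0
COX1_FIRST10_SHARE = 0.37


def default_dwell_models(
    ann: MitoAnnotation,
    topology: list[TopologyRecord] | None = None,
    cox1_first10_share: float | None = COX1_FIRST10_SHARE,
    periodic_multiplier: float = DEFAULT_PERIODIC_MULTIPLIER,
    period: int = DEFAULT_PERIOD_CODONS,
) -> dict[str, DwellModel]:
    """Dwell models encoding the study conditions on the fixture annotation."""
    topo_by_id = {t.protein_id: t for t in (topology or [])}
    models: dict[str, DwellModel] = {}
    for unit in ann.units:
        model = DwellModel(
            codon_count=unit.codon_count,
            initiation_multiplier=DEFAULT_INITIATION_MULTIPLIER,
            pause_sites=list(_DEFAULT_PAUSES.get(unit.unit_id, [])),
        )
        for gid in unit.member_genes:
            topo = topo_by_id.get(gid)
            if topo is None or not topo.tmh_spans:
                continue
            off = unit.gene_codon_offset(gid)
            model.periodic_components.append(
                PeriodicComponent(
                    anchor_codon=off + topo.first_tmh_start,
                    offsets=_PERIODIC_OFFSETS[topo.n_class],
                    period=period,
                    multiplier=periodic_multiplier,
                    max_codon=off + unit.gene_codon_count(gid),
                )
            )
        if unit.unit_id == "COX1" and cox1_first10_share is not None:
            model = set_initiation_share(model, cox1_first10_share)
        models[unit.unit_id] = model
    return models


def abundances_for_read_shares(
    shares: dict[str, float], models: dict[str, DwellModel]
) -> dict[str, float]:
    """Abundances such that expected read shares match ``shares``.

    The generator draws transcripts proportionally to ``abundance x sum(w)``,
    so the abundance of each unit is its target share divided by its total
    dwell weight.
    """
    return {uid: shares[uid] / models[uid].weights().sum() for uid in shares}


def study_conditions(
    ann: MitoAnnotation, topology: list[TopologyRecord] | None = None, **kwargs
) -> tuple[dict[str, DwellModel], dict[str, float]]:
    """Default (dwell models, abundances) reproducing the study conditions."""
    models = default_dwell_models(ann, topology, **kwargs)
    shares = {uid: DEFAULT_READ_SHARES[uid] for uid in models}
    total = sum(shares.values())
    shares = {uid: s / total for uid, s in shares.items()}
    return models, abundances_for_read_shares(shares, models)


def apply_kd(
    masses: dict[str, float], kd: KDSpec
) -> tuple[dict[str, float], dict[str, float]]:
    """Scale the target unit's expected read mass by ``kd.scale``.

    Returns the modified masses and an info dict logging the explicit
    renormalization of the library total (reads are drawn at fixed depth, so
    the removed target mass is redistributed proportionally by the
    multinomial draw).
    """
    if kd.target_unit not in masses:
        raise KeyError(f"KD target {kd.target_unit!r} not in transcript set")
    out = dict(masses)
    out[kd.target_unit] = masses[kd.target_unit] * kd.scale
    info = {
        "target_mass_before": masses[kd.target_unit],
        "target_mass_after": out[kd.target_unit],
        "library_mass_factor": sum(out.values()) / sum(masses.values()),
    }
    return out, info


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _reads_for_unit(
    unit: TranscriptUnit,
    codon_counts: np.ndarray,
    lengths: np.ndarray,
    length_probs: np.ndarray,
    psite_offset_nt: int,
    umi_length: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = int(codon_counts.sum())
    if n == 0:
        return pd.DataFrame(columns=["unit_id", "start_nt", "length_nt", "umi"])
    codons = np.repeat(np.arange(1, unit.codon_count + 1), codon_counts)
    jitter = rng.integers(0, 3, n)
    read_len = lengths[rng.choice(len(lengths), size=n, p=length_probs)]
    start = 3 * (codons - 1) + jitter - psite_offset_nt
    np.clip(start, 0, None, out=start)
    max_start = len(unit.sequence) - read_len
    start = np.minimum(start, max_start)
    umi_idx = rng.integers(0, 4, (n, umi_length))
    umis = ["".join(row) for row in _BASES[umi_idx]]
    return pd.DataFrame(
        {
            "unit_id": unit.unit_id,
            "start_nt": start.astype(int),
            "length_nt": read_len.astype(int),
            "umi": umis,
        }
    )


def simulate_footprints(
    ann: MitoAnnotation,
    models: dict[str, DwellModel],
    lib: LibrarySpec,
    kd: KDSpec | None = None,
    abundances: dict[str, float] | None = None,
    psite_offset_nt: int = DEFAULT_PSITE_OFFSET_NT,
) -> pd.DataFrame:
    """Draw one library of footprint records.

    Returns a table with columns ``unit_id, start_nt, length_nt, umi,
    replicate_id`` (nt coordinates 0-based half-open on the transcript unit).
    Deterministic given ``lib.seed``.
    """
    for unit in ann.units:
        if unit.unit_id not in models:
            raise KeyError(f"no dwell model for unit {unit.unit_id}")
        if models[unit.unit_id].codon_count != unit.codon_count:
            raise ValueError(f"dwell model length mismatch for {unit.unit_id}")
    if abundances is None:
        abundances = {u.unit_id: 1.0 for u in ann.units}

    weights = {u.unit_id: models[u.unit_id].weights() for u in ann.units}
    masses = {uid: abundances[uid] * w.sum() for uid, w in weights.items()}
    if kd is not None:
        masses, _ = apply_kd(masses, kd)
    total_mass = sum(masses.values())
    if total_mass <= 0:
        raise ValueError("zero total transcript mass")

    rng = np.random.default_rng(lib.seed)
    unit_ids = [u.unit_id for u in ann.units]
    p_unit = np.array([masses[uid] for uid in unit_ids]) / total_mass
    n_per_unit = rng.multinomial(lib.total_reads, p_unit)

    lengths, length_probs = lib.lengths_and_probs()
    frames = []
    for unit, n_u in zip(ann.units, n_per_unit):
        w = weights[unit.unit_id]
        codon_counts = rng.multinomial(int(n_u), w / w.sum())
        frames.append(
            _reads_for_unit(
                unit, codon_counts, lengths, length_probs,
                psite_offset_nt, lib.umi_length, rng,
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["unit_id", "start_nt", "length_nt", "umi"]
    )
    df["replicate_id"] = lib.replicate_id
    return df


def simulate_replicates(
    ann: MitoAnnotation,
    models: dict[str, DwellModel],
    n_replicates: int,
    total_reads: int,
    seeds: list[int],
    kd: KDSpec | None = None,
    abundances: dict[str, float] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Concatenate ``n_replicates`` libraries with per-replicate seeds."""
    if len(seeds) < n_replicates:
        raise ValueError("need one seed per replicate")
    frames = []
    for i in range(n_replicates):
        lib = LibrarySpec(
            total_reads=total_reads, seed=int(seeds[i]), replicate_id=f"rep{i + 1}"
        )
        frames.append(simulate_footprints(ann, models, lib, kd=kd, abundances=abundances, **kwargs))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# BED-like TSV I/O
# ---------------------------------------------------------------------------

def write_footprints(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """BED-like TSV: unit_id, start (0-based), end (half-open), umi, replicate."""
    out = pd.DataFrame(
        {
            "unit_id": df["unit_id"],
            "start_nt": df["start_nt"],
            "end_nt": df["start_nt"] + df["length_nt"],
            "umi": df["umi"],
            "replicate_id": df["replicate_id"],
        }
    )
    with open(path, "w") as fh:
        fh.write("# mitoribo footprints; nt 0-based half-open on transcript unit\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_footprints(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return pd.DataFrame(
        {
            "unit_id": df["unit_id"].astype(str),
            "start_nt": df["start_nt"].astype(int),
            "length_nt": (df["end_nt"] - df["start_nt"]).astype(int),
            "umi": df["umi"].astype(str),
            "replicate_id": df["replicate_id"].astype(str),
        }
    )
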