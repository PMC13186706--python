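# Methods

This document describes the models and numerical choices behind `mitoribo`:
what each stage computes, which parameters control it, and where the synthetic
generator's realism ends.

## 1. Modified reference

Mitochondrial mRNAs are leaderless and polyadenylated. The reference builder
(`mitoribo.reference.build_modified_reference`) turns a genome plus a gene
table into transcript units:

1. **Stop completion.** Genes flagged `incomplete_stop` end in `T` (one
   nucleotide short of a full codon) or `TA` (two short) on the genome;
   polyadenylation completes the final codon to `TAA`. The operation is
   idempotent and rejects flagged sequences whose tail cannot complete to a
   stop. In the human-like fixture the flagged set is ND1, ND2, ND3, ND4,
   CYTB, COX3 and ATP6.
2. **Bicistronic merging.** ATP8–ATP6 and ND4L–ND4 are transcribed as single
   mRNAs. `merge_bicistronic` concatenates the pair into one unit whose codon
   indexing follows the upstream gene's frame; per-gene codon offsets are kept
   so downstream analyses can convert unit codons to protein residues.
3. **Poly(A) tail.** A configurable tail (default `polya_len = 10` nt) is
   appended to every unit. P-sites landing in the tail are excluded from
   profiles and tallied in QC.

Result: 13 protein genes → 11 transcript units.

Coordinates: genomic intervals are 0-based half-open; codons and TMH residues
are 1-based inclusive.

### Fixture

`mitoribo.fixtures` generates a human-mtDNA-like genome at run time from a
fixed-seed RNG: 13 genes with close-to-real CDS lengths, the real
incomplete-stop set, both bicistronic pairs, and ND6 on the minus strand. The
bicistronic pairs abut in frame (unlike the real out-of-frame overlaps), so
merged-unit codon bookkeeping is exact. The topology table fixes the
literature values that matter downstream — COX1 has 12 TMHs, COX2 has 2, COX3
is N-in, ND1 is N-out — and uses plausible synthetic spans elsewhere. No real
genomic sequence is shipped; everything is regenerated deterministically on
import.

## 2. Membrane topology and nascent fragments

Each protein carries sorted, non-overlapping TMH spans and an N-terminus
class (`N-in` = matrix, `N-out` = intermembrane space). Because roughly 30
residues of nascent chain are occluded in the ribosomal exit tunnel
(`occlusion_aa = 30`), a TMH starting at residue *s* *emerges* when codon
`s + 30` is decoded — the emergence codon used to link pauses to membrane
insertion. A ribosome paused at codon *c* implies a nascent fragment of *c*
residues; its mass is estimated as `c × 0.110 kDa` (average residue mass) or
exactly from the protein sequence when available. A pause at codons 35–38 of
a small upstream ORF therefore implies a ~3.6–4.2 kDa fragment.

## 3. Synthetic footprint generator

The generator (`mitoribo.simulate`) is explicitly a *statistical emulator*:
it reproduces the distributional structure the pipeline must detect, not the
biophysics that produces it.

**Dwell model.** Each unit has a per-codon weight vector `w` (index 0 =
codon 1), the product of:

- a uniform baseline;
- an initiation multiplier on codons 1–10 (default 8.0; for COX1 it is
  solved analytically so the expected first-10-codon read share is 0.37);
- discrete pause sites `(codon, multiplier)` — e.g. ND2 carries 92/93,
  144/145 and 305/306 with the distal pair strongest (multipliers 6–12);
- periodic topology-linked components: bumps at
  `first-TMH codon + offset + k × 50` with offsets (15, 30, 78) for N-in and
  (30, 55, 78) for N-out proteins, multiplier 6.0, truncated at the member
  protein's boundary.

**Sampling.** Given per-unit abundances, reads are drawn by a two-level
multinomial: first over units (probability ∝ abundance × Σw, so abundances
are solved from target read shares by `share / Σw`), then over codons
(∝ w). Default read shares follow the published complex-level distribution
(COX1 20 %, COX2 15 %, COX3 13 %, ATP8-ATP6 17 %, CYTB 5 %, the six
complex-I units 5 % each).

**Read geometry.** A read decoding codon *c* gets 5′ start
`3(c−1) + j − offset` with frame jitter `j ∈ {0,1,2}` and
`offset = 14 nt`; lengths are 90 % uniform on 30–40 nt plus 10 %
contamination on 20–29 ∪ 41–50 nt; 8-nt random UMIs are attached. Starts are
clamped to the transcript: on a leaderless mRNA a ribosome at codon 1 still
yields a read starting at nucleotide 0, so under the fixed-offset model reads
from codons 1–4 are assigned to codon 5. This is a physical edge effect, not
a bug; first-10/first-15 splits are unaffected.

**Knockdown.** A morpholino knockdown is modeled as pure abundance scaling
of the target (`scale ∈ (0, 1]`) before the unit-level multinomial; at fixed
sequencing depth the removed mass is redistributed proportionally, which is
exactly the compositional effect real RPM-normalized libraries show.

**Determinism.** Every library is a pure function of its integer seed
(`numpy.random.default_rng`); replicate seeds are spawned from a root seed
via `numpy.random.SeedSequence` and kept below 2³¹.

## 4. Footprint processing

`process_records` runs: UMI deduplication on (unit, 5′ start, length, UMI)
per replicate → inclusive 30–40-nt length selection → P-site assignment
`codon = (start + 14) // 3 + 1`, excluding P-sites in the poly(A) tail. Each
profile records its replicate's total retained reads as `library_size`. QC
tallies every stage; retained read counts are conserved exactly.

A single fixed offset is used for all lengths in the window because
micrococcal-nuclease ends are ragged — per-length offset tables would fit
noise. `calibrate_offset` recovers the offset from any library with strong
initiation pausing by maximizing the density contrast across the
initiation-window boundary (mean of codons 8–10 minus mean of codons 11–13,
summed over units) over candidate offsets 10–18; ties break toward the
smaller offset. If the best contrast does not beat Poisson counting noise by
4σ the library has no usable start enrichment and the default offset is kept
with a warning. (A naive objective — the fraction of P-sites in codons
1–10 — is degenerate here: clamping at the 5′ edge plus background influx
from above makes it monotonically favor the smallest candidate offset.)

## 5. Expression metrics

`rpkm = C / (L_kb × N_M)` with C the unit's retained P-site counts, L the
ORF length in kb (poly(A) excluded) and N the replicate's retained
mito-mapped total in millions. The first-15-codon split (boundary inclusive)
separates initiation-proximal from elongating footprints.
`normalize_density` divides by the transcript mean (uniform profile → 1.0).

## 6. Metagene analysis

Transcripts are aligned at an anchor and averaged per offset:

- `start`: offsets 1–100 = codons 1–100;
- `stop`: offsets −100…−1, −1 being the last ORF codon;
- `first-TMH`: offset 0 is the first codon of the protein's first TMH;
  computed per *protein* (bicistronic members handled via codon offsets) and
  stratified by N-terminus class.

Transcripts shorter than the window contribute only to offsets they cover
(NaN elsewhere). Mean and s.e.m. are taken across transcripts within a
replicate, then averaged across replicates.

**Density scale and the threshold 200.** Densities default to *raw averaged
P-site counts* so the peak threshold `density_threshold = 200` is expressed
on the library's own count scale. On the default generator this threshold is
calibrated to 400k-read libraries for the first-TMH analysis (the depth at
which the planted topology-linked accumulations clearly exceed 200 while the
background stays well below); start/stop metagenes and all other analyses use
the standard 100k depth. Transcript-mean normalization is selectable
(`normalize="mean"`) for cross-library comparisons.

**Peaks.** Local maxima above the threshold, minimum separation 5 codons;
within a conflict the higher peak wins, ties toward the smaller offset; the
left window edge is never reported (a truncated ramp/plateau would otherwise
always nominate its first element). Note the inherent collision of
accumulation positions 78 and 80 (= 30 + 50): with 5-codon separation only
one of the pair survives, so position 78 is recovered to within ±2.
`peak_spacing` estimates the modal repeat of a clean peak motif (~50 codons)
by splitting peaks into occurrences at large gaps and differencing by rank.

## 7. Pause calling

Score `s = d_c / trimmed_mean(d)` with 10 % trimmed per tail — robust to the
pauses themselves. Codons with `s ≥ s_min = 4` are called; runs of ≤ 2
consecutive above-threshold codons merge into one call labeled in the
"92/93" style, longer runs split greedily around local maxima. Codons 1–10
are excluded (initiation pausing is reported separately as the first-10-codon
share). Profiles with mean coverage below 5 reads/codon are skipped with a
warning. Per-replicate calls whose codons agree within ±1 are clustered;
clusters supported by ≥ 2 of 3 replicates survive, scored by the cluster
mean and located at the best-scoring member. Calls are then annotated
against emergence codons (±5) and carry nascent-fragment estimates.

## 8. Knockdown comparison

Percent reduction is `100 × (1 − corrected RPKM ratio)` per unit. Two
normalization modes:

- **`matched`** (default): the KD library is rescaled by the median of
  per-unit RPM ratios (median-of-ratios size factor, as in standard
  differential-expression practice). Because only the target changes, the
  median sits on unchanged units and the estimator is unbiased for
  `100 × (1 − scale)` — a 0.30× knockdown reads out as 70 %.
- **`rpm`**: plain per-million scaling. This reproduces the compositional
  effect: when a target carrying ~20 % of reads falls, everything else
  appears to rise and the target's reduction is understated by ~5 points.
  The mode is kept deliberately to demonstrate the artifact.

Codon-level enrichment `e_c` uses no pseudocount; codons with zero control
counts are flagged `missing_control` (NaN) instead of reporting infinite
enrichment. Replicates are paired by sorted order and summarized by
mean ± s.d. across pairs.

## 9. Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| footprint window | 30–40 nt (inclusive) | monosome-protected MNase fragment range |
| P-site offset | 14 nt from 5′ end | single offset for ragged MNase ends; recoverable by calibration |
| poly(A) tail | 10 nt | long enough to absorb read-through, short enough to keep files small |
| tunnel occlusion | 30 aa | standard exit-tunnel capacity |
| reads/replicate | 100 000 | typical mito-mapped depth; 400 000 for first-TMH metagene only |
| replicates | 3, quorum 2 | pause reproducibility requirement |
| `s_min` | 4.0 | separates planted multipliers (≥ 5) from multinomial noise |
| trim fraction | 0.10/tail | excludes pause codons from their own background |
| `min_coverage_mean` | 5 reads/codon | below this, score estimates are dominated by shot noise |
| metagene threshold | 200 (count scale) | calibrated to the generator's default depth, see §6 |
| min peak separation | 5 codons | merges jitter around one accumulation |
| periodic multiplier | 6.0 | same strength class as discrete pauses; clears the threshold at 400k reads |
| initiation multiplier | 8.0 (COX1: solved for 37 % share) | strong leaderless-initiation pausing |

## 10. Scope and limitations

- The generator plants the pause/accumulation structure it is later asked to
  recover; end-to-end tests therefore validate the *pipeline's inference*,
  not the biology. Parameter-recovery tests use plants the detector was not
  tuned on (non-repeating components, shifted offsets).
- Sequence content is random stop-free codons; no codon-usage, GC or
  MNase-bias structure. UMIs are uniform, so PCR-duplicate rates are tiny at
  default depth.
- Bicistronic pairs abut in frame in the fixture; the real genome's
  out-of-frame overlaps would need the merge operation's general span
  handling plus frame-aware extraction.
- The knockdown model scales abundance only; it does not model morpholino
  position effects within the targeted window (`mask_region_nt` is carried
  but not interpreted by the generator).
- Topology spans other than the fixed literature values (COX1 12, COX2 2,
  COX3 N-in, ND1 N-out) are fixture-quality stand-ins; TMH-linkage results
  on other proteins demonstrate mechanics, not biology.
- `calibrate_offset` needs initiation-pause-rich libraries; it declines
  (keeps the default, warns) on flat ones rather than guessing.
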