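"""Footprint processing: dedup, length filter, P-site assignment, QC."""

import logging

import numpy as np
import pandas as pd
import pytest

from mitoribo.processing import (
    CodonProfile,
    ProcessingConfig,
    assign_psite,
    build_codon_profiles,
    calibrate_offset,
    dedup_umi,
    filter_length,
    process_records,
    profiles_by_replicate,
    read_profiles,
    write_profiles,
)
from mitoribo.simulate import DwellModel, LibrarySpec, simulate_footprints


def _records(rows):
    return pd.DataFrame(rows, columns=["unit_id", "start_nt", "length_nt", "umi", "replicate_id"])


class TestDedup:
    def test_exact_duplicates_collapsed(self):
        rec = _records([
            ("u", 10, 33, "AAAA", "rep1"),
            ("u", 10, 33, "AAAA", "rep1"),  # PCR duplicate
            ("u", 10, 33, "CCCC", "rep1"),  # distinct molecule, same position
            ("u", 11, 33, "AAAA", "rep1"),  # distinct position
        ])
        out = dedup_umi(rec)
        assert len(out) == 3

    def test_same_key_in_different_replicates_kept(self):
        rec = _records([
            ("u", 10, 33, "AAAA", "rep1"),
            ("u", 10, 33, "AAAA", "rep2"),
        ])
        assert len(dedup_umi(rec)) == 2

    def test_missing_umi_rejected(self):
        rec = _records([("u", 10, 33, None, "rep1")])
        with pytest.raises(ValueError, match="UMI"):
            dedup_umi(rec)


class TestLengthFilter:
    def test_window_bounds_inclusive(self):
        rec = _records([
            ("u", 0, 29, "A", "rep1"),
            ("u", 0, 30, "B", "rep1"),
            ("u", 0, 40, "C", "rep1"),
            ("u", 0, 41, "D", "rep1"),
        ])
        out = filter_length(rec, ProcessingConfig())
        assert sorted(out["length_nt"]) == [30, 40]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            ProcessingConfig(len_min=40, len_max=30)


class TestAssignPsite:
    def test_offset_arithmetic(self):
        cfg = ProcessingConfig()
        # start 0 + 14 -> nt 14 -> codon 5 (nt 12-14); start 31 -> nt 45 -> codon 16
        assert assign_psite(0, cfg) == 5
        assert assign_psite(31, cfg) == 16

    def test_vectorized_matches_scalar(self):
        cfg = ProcessingConfig(psite_offset_nt=12)
        starts = np.array([0, 5, 29, 300])
        vec = assign_psite(starts, cfg)
        assert list(vec) == [assign_psite(int(s), cfg) for s in starts]

    def test_clipped_to_codon_count(self):
        cfg = ProcessingConfig()
        assert assign_psite(10_000, cfg, codon_count=100) == 100


class TestBuildProfiles:
    def test_counts_and_library_size(self, toy_ann):
        unitA = toy_ann.units[0].unit_id
        rec = _records([
            (unitA, 0, 33, "A", "rep1"),   # P-site nt 14 -> codon 5
            (unitA, 1, 33, "B", "rep1"),   # nt 15 -> codon 6
            (unitA, 2, 33, "C", "rep1"),   # nt 16 -> codon 6
        ])
        profiles = build_codon_profiles(rec, toy_ann, ProcessingConfig())
        p = next(p for p in profiles if p.unit_id == unitA)
        assert p.counts[4] == 1 and p.counts[5] == 2
        assert p.total == 3
        assert p.library_size == 3  # all retained reads of the replicate

    def test_polya_psites_excluded_and_tallied(self, toy_ann):
        unit = toy_ann.units[0]
        polya_start = unit.orf_length_nt  # first nt of the tail
        rec = _records([
            (unit.unit_id, polya_start - 14, 33, "A", "rep1"),  # P-site on tail
            (unit.unit_id, 0, 33, "B", "rep1"),
        ])
        from mitoribo.processing import QCReport

        qc = QCReport()
        profiles = build_codon_profiles(rec, toy_ann, ProcessingConfig(), qc=qc)
        assert qc.n_psite_in_polya == 1
        assert sum(p.total for p in profiles) == 1

    def test_unknown_unit_rejected(self, toy_ann):
        rec = _records([("nope", 0, 33, "A", "rep1")])
        with pytest.raises(KeyError):
            build_codon_profiles(rec, toy_ann, ProcessingConfig())


class TestProcessRecords:
    def test_read_count_conserved_through_chain(self, human_ann, study):
        models, abundances = study
        df = simulate_footprints(human_ann, models, LibrarySpec(total_reads=10_000, seed=9),
                                 abundances=abundances)
        profiles, qc = process_records(df, human_ann)
        assert qc.n_input == 10_000
        assert qc.n_after_dedup <= qc.n_input
        assert qc.n_after_length <= qc.n_after_dedup
        assert qc.n_retained == qc.n_after_length - qc.n_psite_in_polya
        assert sum(p.total for p in profiles) == qc.n_retained

    def test_profiles_cover_all_units_and_replicates(self, human_ann, study):
        models, abundances = study
        frames = [
            simulate_footprints(human_ann, models,
                                LibrarySpec(total_reads=3_000, seed=s, replicate_id=f"rep{s}"),
                                abundances=abundances)
            for s in (1, 2)
        ]
        profiles, _ = process_records(pd.concat(frames, ignore_index=True), human_ann)
        by_rep = profiles_by_replicate(profiles)
        assert set(by_rep) == {"rep1", "rep2"}
        for plist in by_rep.values():
            assert {p.unit_id for p in plist} == set(human_ann.unit_ids())

    def test_library_size_is_per_replicate(self, human_ann, study):
        models, abundances = study
        frames = [
            simulate_footprints(human_ann, models,
                                LibrarySpec(total_reads=n, seed=n, replicate_id=f"rep{i}"),
                                abundances=abundances)
            for i, n in enumerate((4_000, 8_000), start=1)
        ]
        profiles, _ = process_records(pd.concat(frames, ignore_index=True), human_ann)
        by_rep = profiles_by_replicate(profiles)
        sizes = {rep: plist[0].library_size for rep, plist in by_rep.items()}
        assert sizes["rep2"] > sizes["rep1"]
        for rep, plist in by_rep.items():
            assert all(p.library_size == sizes[rep] for p in plist)
            assert sum(p.total for p in plist) == sizes[rep]


class TestCalibrateOffset:
    def test_recovers_planted_offset(self, human_ann):
        models = {
            u.unit_id: DwellModel(codon_count=u.codon_count, initiation_multiplier=8.0)
            for u in human_ann.units
        }
        df = simulate_footprints(human_ann, models,
                                 LibrarySpec(total_reads=40_000, seed=21),
                                 psite_offset_nt=14)
        assert calibrate_offset(df, human_ann) == 14

    def test_recovers_nondefault_offset(self, human_ann):
        models = {
            u.unit_id: DwellModel(codon_count=u.codon_count, initiation_multiplier=8.0)
            for u in human_ann.units
        }
        df = simulate_footprints(human_ann, models,
                                 LibrarySpec(total_reads=40_000, seed=22),
                                 psite_offset_nt=12)
        assert calibrate_offset(df, human_ann) == 12

    def test_flat_library_keeps_default_with_warning(self, human_ann, caplog):
        models = {u.unit_id: DwellModel(codon_count=u.codon_count) for u in human_ann.units}
        df = simulate_footprints(human_ann, models,
                                 LibrarySpec(total_reads=20_000, seed=23))
        with caplog.at_level(logging.WARNING):
            off = calibrate_offset(df, human_ann)
        assert off == ProcessingConfig().psite_offset_nt
        assert any("no initiation enrichment" in r.message for r in caplog.records)


def test_profile_round_trip(tmp_path, human_ann, study):
    models, abundances = study
    df = simulate_footprints(human_ann, models, LibrarySpec(total_reads=5_000, seed=13),
                             abundances=abundances)
    profiles, _ = process_records(df, human_ann)
    path = tmp_path / "profiles.tsv"
    write_profiles(profiles, path)
    back = read_profiles(path, human_ann)
    key = lambda p: (p.replicate_id, p.unit_id)
    for a, b in zip(sorted(profiles, key=key), sorted(back, key=key)):
        assert a.unit_id == b.unit_id
        assert a.library_size == b.library_size
        assert np.array_equal(a.counts, b.counts)
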