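"""Metagene profiles: anchoring, peak detection, repeat spacing."""

import numpy as np
import pytest

from mitoribo.metagene import (
    MetageneConfig,
    MetageneProfile,
    anchored_metagene,
    detect_peaks,
    metagene_table,
    peak_spacing,
    stop_proximal_drop,
)
from mitoribo.processing import CodonProfile
from mitoribo.simulate import simulate_replicates, study_conditions


def _profile(uid, counts, rep="rep1"):
    counts = np.asarray(counts, dtype=int)
    return CodonProfile(unit_id=uid, counts=counts,
                        library_size=int(counts.sum()), replicate_id=rep)


def _uniform_profiles(ann, value=10, rep="rep1"):
    return [_profile(u.unit_id, np.full(u.codon_count, value), rep) for u in ann.units]


def _mg(offsets, density):
    return MetageneProfile(
        anchor="start", group="all",
        offsets=np.asarray(offsets), mean_density=np.asarray(density, float),
        sem=np.zeros(len(offsets)), n_transcripts=1,
    )


class TestAnchoring:
    def test_start_anchor_offsets_and_flat_density(self, human_ann):
        mgs = anchored_metagene(_uniform_profiles(human_ann, 10), "start", human_ann)
        mg = mgs["all"]
        assert mg.offsets[0] == 1 and mg.offsets[-1] == 100
        assert np.allclose(mg.mean_density, 10.0)
        assert mg.n_transcripts == 11

    def test_stop_anchor_aligns_last_codon(self, human_ann):
        profiles = []
        for u in human_ann.units:
            counts = np.zeros(u.codon_count, dtype=int)
            counts[-1] = 50  # plant at the stop codon
            profiles.append(_profile(u.unit_id, counts))
        mg = anchored_metagene(profiles, "stop", human_ann)["all"]
        assert mg.offsets[-1] == -1
        assert mg.mean_density[-1] == pytest.approx(50.0)
        assert np.allclose(mg.mean_density[:-1], 0.0)

    def test_short_transcripts_contribute_only_covered_offsets(self, toy_ann):
        # geneA has 40 codons, geneB-geneC 80: past codon 40 only the merged
        # unit contributes to the start-anchored mean
        cfg = MetageneConfig(window=60)
        counts = {"geneA": 4, "geneB-geneC": 8}
        profiles = [
            _profile(u.unit_id, np.full(u.codon_count, counts[u.unit_id]))
            for u in toy_ann.units
        ]
        mg = anchored_metagene(profiles, "start", toy_ann, cfg)["all"]
        n_a = toy_ann.unit("geneA").codon_count
        assert np.allclose(mg.mean_density[:n_a], 6.0)    # mean of 4 and 8
        assert np.allclose(mg.mean_density[n_a:], 8.0)    # long unit only

    def test_first_tmh_anchor_requires_topology(self, human_ann):
        with pytest.raises(ValueError, match="topology"):
            anchored_metagene(_uniform_profiles(human_ann), "first-TMH", human_ann)

    def test_first_tmh_anchor_aligns_on_protein_frame(self, human_ann, human_topo, topo_by_id):
        """A count planted at the first-TMH codon of a protein inside a merged
        unit must land at metagene offset 0."""
        unit = human_ann.unit("ATP8-ATP6")
        off = unit.gene_codon_offset("ATP6")
        anchor_unit_codon = off + topo_by_id["ATP6"].first_tmh_start  # 1-based
        profiles = []
        for u in human_ann.units:
            counts = np.zeros(u.codon_count, dtype=int)
            if u.unit_id == "ATP8-ATP6":
                counts[anchor_unit_codon - 1] = 900
            profiles.append(_profile(u.unit_id, counts))
        mg = anchored_metagene(profiles, "first-TMH", human_ann,
                               topology=human_topo)["N-in"]
        assert mg.offsets[0] == 0
        idx = np.nanargmax(mg.mean_density)
        assert mg.offsets[idx] == 0

    def test_replicates_averaged(self, human_ann):
        profiles = _uniform_profiles(human_ann, 10, "rep1") + _uniform_profiles(
            human_ann, 30, "rep2"
        )
        mg = anchored_metagene(profiles, "start", human_ann)["all"]
        assert np.allclose(mg.mean_density, 20.0)
        assert mg.replicates == ["rep1", "rep2"]

    def test_unknown_anchor_rejected(self, human_ann):
        with pytest.raises(ValueError):
            anchored_metagene(_uniform_profiles(human_ann), "middle", human_ann)

    def test_mean_normalization_mode(self, human_ann):
        cfg = MetageneConfig(normalize="mean", density_threshold=0.0)
        mg = anchored_metagene(_uniform_profiles(human_ann, 7), "start", human_ann, cfg)["all"]
        assert np.allclose(mg.mean_density, 1.0)


class TestDetectPeaks:
    def test_peaks_above_threshold_only(self):
        d = np.zeros(100)
        d[20] = 500
        d[60] = 150  # below threshold
        peaks = detect_peaks(_mg(np.arange(100), d))
        assert peaks == [20]

    def test_flat_profile_has_no_peaks(self):
        peaks = detect_peaks(_mg(np.arange(50), np.full(50, 300.0)))
        assert peaks == []

    def test_min_separation_keeps_higher_peak(self):
        d = np.zeros(100)
        d[30] = 400
        d[33] = 600  # within 5 codons of 30; higher wins
        d[50] = 300
        peaks = detect_peaks(_mg(np.arange(100), d))
        assert peaks == [33, 50]

    def test_equal_conflicting_peaks_tie_to_smaller_offset(self):
        d = np.zeros(100)
        d[40] = 500
        d[43] = 500
        peaks = detect_peaks(_mg(np.arange(100), d))
        assert peaks == [40]

    def test_plateau_reported_once_at_left_edge(self):
        d = np.zeros(100)
        d[25] = d[26] = 500
        peaks = detect_peaks(_mg(np.arange(100), d))
        assert peaks == [25]

    def test_custom_threshold(self):
        d = np.zeros(60)
        d[10] = 50
        cfg = MetageneConfig(density_threshold=40.0)
        assert detect_peaks(_mg(np.arange(60), d), cfg) == [10]


class TestPeakSpacing:
    def test_two_peaks(self):
        assert peak_spacing([30, 80]) == 50.0

    def test_repeating_two_peak_motif(self):
        assert peak_spacing([15, 30, 65, 80]) == 50.0

    def test_three_occurrence_motif(self):
        assert peak_spacing([10, 25, 60, 75, 110, 125]) == 50.0

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            peak_spacing([40])


class TestStopProximalDrop:
    def test_depleted_tail_below_one(self):
        counts = np.full(100, 20)
        counts[-10:] = 4
        assert stop_proximal_drop(_profile("u", counts)) < 1.0

    def test_uniform_is_one(self):
        assert stop_proximal_drop(_profile("u", np.full(80, 9))) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def deep_metagene(human_ann, human_topo):
    from mitoribo.processing import process_records

    models, abundances = study_conditions(human_ann, human_topo)
    records = simulate_replicates(human_ann, models, 3, 400_000,
                                  [101, 102, 103], abundances=abundances)
    profiles, _ = process_records(records, human_ann)
    return anchored_metagene(profiles, "first-TMH", human_ann,
                             topology=human_topo)


class TestTopologyLinkedAccumulations:
    """End-to-end: deep libraries recover the planted topology-linked pattern."""

    @pytest.mark.parametrize("group,positions", [
        ("N-in", (15, 30, 78)),
        ("N-out", (30, 55, 78)),
    ])
    def test_accumulation_positions_recovered(self, deep_metagene, group, positions):
        peaks = detect_peaks(deep_metagene[group])
        for pos in positions:
            assert any(abs(p - pos) <= 2 for p in peaks), (group, pos, peaks)

    def test_fifty_codon_repeat_present(self, deep_metagene):
        for group in ("N-in", "N-out"):
            peaks = detect_peaks(deep_metagene[group])
            assert any(b - a == 50 for a in peaks for b in peaks), (group, peaks)

    def test_threshold_separates_peaks_from_background(self, deep_metagene):
        mg = deep_metagene["N-in"]
        d = np.nan_to_num(mg.mean_density)
        background = np.median(d)
        assert background < 200.0 < d.max()


def test_metagene_table_columns(human_ann):
    mg = anchored_metagene(_uniform_profiles(human_ann, 5), "start", human_ann)["all"]
    df = metagene_table(mg)
    assert list(df.columns) == ["anchor", "group", "offset", "mean_density",
                                "sem", "n_transcripts"]
    assert len(df) == 100
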