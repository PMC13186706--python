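"""Synthetic footprint generator: dwell models, KD scaling, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoribo.simulate import (
    DwellModel,
    KDSpec,
    LibrarySpec,
    PeriodicComponent,
    abundances_for_read_shares,
    apply_kd,
    default_length_distribution,
    initiation_multiplier_for_share,
    read_footprints,
    set_initiation_share,
    simulate_footprints,
    simulate_replicates,
    write_footprints,
)


class TestDwellModel:
    def test_uniform_weights(self):
        w = DwellModel(codon_count=50).weights()
        assert w.shape == (50,)
        assert np.all(w == 1.0)

    def test_initiation_and_pause_multipliers(self):
        m = DwellModel(codon_count=100, initiation_multiplier=5.0,
                       pause_sites=[(40, 8.0)])
        w = m.weights()
        assert np.all(w[:10] == 5.0)
        assert w[39] == 8.0
        assert w[10] == 1.0

    def test_periodic_component_repeats_and_truncates(self):
        pc = PeriodicComponent(anchor_codon=10, offsets=(15,), period=50,
                               multiplier=3.0, max_codon=130)
        w = DwellModel(codon_count=200, periodic_components=[pc]).weights()
        bumped = np.flatnonzero(w > 1.0) + 1
        assert list(bumped) == [25, 75, 125]  # 175 cut by max_codon

    def test_pause_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            DwellModel(codon_count=50, pause_sites=[(51, 2.0)]).weights()


class TestInitiationShare:
    def test_multiplier_solves_target_share(self):
        m = initiation_multiplier_for_share(0.37, codon_count=514)
        w = DwellModel(codon_count=514, initiation_multiplier=m).weights()
        assert w[:10].sum() / w.sum() == pytest.approx(0.37)

    def test_set_initiation_share_with_structure(self):
        base = DwellModel(codon_count=300, initiation_multiplier=2.0,
                          pause_sites=[(150, 6.0)])
        tuned = set_initiation_share(base, 0.25)
        w = tuned.weights()
        assert w[:10].sum() / w.sum() == pytest.approx(0.25)

    def test_invalid_share_rejected(self):
        with pytest.raises(ValueError):
            initiation_multiplier_for_share(1.2, 100)


class TestStudyConditions:
    def test_models_cover_all_units(self, human_ann, study):
        models, abundances = study
        assert set(models) == set(human_ann.unit_ids())
        assert set(abundances) == set(models)

    def test_cox1_expected_first10_share(self, study):
        models, _ = study
        w = models["COX1"].weights()
        assert w[:10].sum() / w.sum() == pytest.approx(0.37)

    def test_expected_read_shares_match_targets(self, study):
        models, abundances = study
        masses = {u: abundances[u] * models[u].weights().sum() for u in models}
        total = sum(masses.values())
        assert masses["COX1"] / total == pytest.approx(0.20, abs=1e-9)
        assert masses["COX2"] / total == pytest.approx(0.15, abs=1e-9)
        assert masses["ATP8-ATP6"] / total == pytest.approx(0.17, abs=1e-9)

    def test_nd2_major_pause_is_strongest(self, study):
        models, _ = study
        w = models["ND2"].weights()
        interior = w[10:]
        assert np.argmax(interior) + 11 == 306


class TestApplyKD:
    def test_target_mass_scaled(self):
        masses = {"A": 10.0, "B": 30.0}
        out, info = apply_kd(masses, KDSpec("A", 0.3))
        assert out == {"A": pytest.approx(3.0), "B": 30.0}
        assert info["library_mass_factor"] == pytest.approx(33.0 / 40.0)

    def test_scale_one_is_identity(self):
        masses = {"A": 10.0, "B": 30.0}
        out, _ = apply_kd(masses, KDSpec("B", 1.0))
        assert out == masses

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            apply_kd({"A": 1.0}, KDSpec("Z", 0.5))

    @pytest.mark.parametrize("scale", [0.0, -0.1, 1.5])
    def test_invalid_scale_rejected(self, scale):
        with pytest.raises(ValueError):
            KDSpec("A", scale)


class TestLengthDistribution:
    def test_mass_split_between_window_and_contamination(self):
        dist = default_length_distribution()
        window = sum(p for l, p in dist.items() if 30 <= l <= 40)
        assert window == pytest.approx(0.90)
        assert sum(dist.values()) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_lib(human_ann, study):
    models, abundances = study
    lib = LibrarySpec(total_reads=20_000, seed=7)
    return simulate_footprints(human_ann, models, lib, abundances=abundances)


class TestSimulateFootprints:
    def test_schema_and_depth(self, small_lib):
        assert list(small_lib.columns) == ["unit_id", "start_nt", "length_nt", "umi", "replicate_id"]
        assert len(small_lib) == 20_000

    def test_reads_stay_on_transcript(self, small_lib, human_ann):
        for uid, grp in small_lib.groupby("unit_id"):
            n = len(human_ann.unit(uid).sequence)
            assert (grp["start_nt"] >= 0).all()
            assert (grp["start_nt"] + grp["length_nt"] <= n).all()

    def test_same_seed_is_byte_identical(self, human_ann, study):
        models, abundances = study
        lib = LibrarySpec(total_reads=5_000, seed=42)
        a = simulate_footprints(human_ann, models, lib, abundances=abundances)
        b = simulate_footprints(human_ann, models, lib, abundances=abundances)
        assert a.equals(b)

    def test_different_seeds_differ(self, human_ann, study):
        models, abundances = study
        a = simulate_footprints(human_ann, models, LibrarySpec(total_reads=5_000, seed=1),
                                abundances=abundances)
        b = simulate_footprints(human_ann, models, LibrarySpec(total_reads=5_000, seed=2),
                                abundances=abundances)
        assert not a.equals(b)

    def test_interior_codon_counts_match_dwell_weights(self, human_ann):
        """Chi-square goodness of fit of sampled P-site codons on a uniform
        interior region (clamping only perturbs the transcript edges)."""
        uid = "COX1"
        models = {u.unit_id: DwellModel(codon_count=u.codon_count) for u in human_ann.units}
        abundances = {u.unit_id: (1.0 if u.unit_id == uid else 1e-12) for u in human_ann.units}
        lib = LibrarySpec(total_reads=50_000, seed=11)
        df = simulate_footprints(human_ann, models, lib, abundances=abundances)
        reads = df[df["unit_id"] == uid]
        codons = (reads["start_nt"] + 14) // 3 + 1
        unit = human_ann.unit(uid)
        interior = codons[(codons >= 10) & (codons <= unit.codon_count - 10)]
        observed = np.bincount(
            interior.to_numpy(dtype=int), minlength=unit.codon_count + 1
        )[10 : unit.codon_count - 9]
        chi2, p = stats.chisquare(observed)
        assert p > 1e-3

    def test_kd_reduces_target_share(self, human_ann, study):
        models, abundances = study
        lib = LibrarySpec(total_reads=30_000, seed=3)
        ctrl = simulate_footprints(human_ann, models, lib, abundances=abundances)
        kd = simulate_footprints(human_ann, models, lib,
                                 kd=KDSpec("COX1", 0.3), abundances=abundances)
        share_ctrl = (ctrl["unit_id"] == "COX1").mean()
        share_kd = (kd["unit_id"] == "COX1").mean()
        assert share_ctrl == pytest.approx(0.20, abs=0.02)
        # expected KD share: 0.2*0.3 / (1 - 0.2*0.7) ~ 0.0698
        assert share_kd == pytest.approx(0.0698, abs=0.02)

    def test_model_mismatch_rejected(self, human_ann):
        models = {u.unit_id: DwellModel(codon_count=u.codon_count) for u in human_ann.units}
        models["COX1"] = DwellModel(codon_count=10)
        with pytest.raises(ValueError, match="mismatch"):
            simulate_footprints(human_ann, models, LibrarySpec(total_reads=100, seed=0))


class TestReplicatesAndIO:
    def test_replicates_labeled_and_independent(self, human_ann, study):
        models, abundances = study
        df = simulate_replicates(human_ann, models, 3, 2_000, [1, 2, 3],
                                 abundances=abundances)
        assert sorted(df["replicate_id"].unique()) == ["rep1", "rep2", "rep3"]
        r1 = df[df["replicate_id"] == "rep1"].reset_index(drop=True)
        r2 = df[df["replicate_id"] == "rep2"].reset_index(drop=True)
        assert not r1["start_nt"].equals(r2["start_nt"])

    def test_too_few_seeds_rejected(self, human_ann, study):
        models, abundances = study
        with pytest.raises(ValueError):
            simulate_replicates(human_ann, models, 3, 100, [1, 2], abundances=abundances)

    def test_footprint_round_trip(self, tmp_path, human_ann, study):
        models, abundances = study
        df = simulate_footprints(human_ann, models, LibrarySpec(total_reads=1_000, seed=5),
                                 abundances=abundances)
        path = tmp_path / "fp.tsv"
        write_footprints(df, path, meta={"seed": 5})
        back = read_footprints(path)
        pd.testing.assert_frame_equal(back, df)
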