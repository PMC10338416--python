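"""Synthetic cohort generator: bead tubes, subject tubes, cohort structure."""

import math

import numpy as np
import pandas as pd
import pytest

import qflow
from qflow.errors import InvalidArgumentError
from qflow.synthdata import default_group_configs


@pytest.fixture(scope="module")
def configs():
    return default_group_configs()


class TestBeadTube:
    def test_zero_noise_identity_gives_delta_peaks(self):
        inst = qflow.InstrumentModel(m_true=1.0, b_true=0.0, bead_cv=0.0)
        beads = qflow.generate_bead_tube(inst, 10, seed=0)
        values = np.sort(np.unique(beads.channel("ch_pe")))
        np.testing.assert_allclose(values, (474, 5359, 23843, 62336), rtol=1e-12)

    def test_geomeans_affine_in_log_nominal(self, instrument):
        beads = qflow.generate_bead_tube(instrument, 2000, seed=2)
        levels = qflow.cluster_bead_levels(beads)
        log_n = np.log10([n for n, _ in levels])
        log_g = np.log10([g for _, g in levels])
        resid = np.polyfit(log_n, log_g, 1, full=True)[1][0]
        assert resid < 1e-3

    def test_level_geomeans_match_mean_of_logs_oracle(self):
        """Per-level geomean lands within 3 SE of the instrument response."""
        inst = qflow.InstrumentModel(m_true=0.95, b_true=0.1, bead_cv=0.05)
        n = 10_000
        beads = qflow.generate_bead_tube(inst, n, seed=1)
        level = beads.truth["bead_level"].to_numpy()
        sigma_log10 = math.sqrt(math.log(1 + 0.05**2)) / math.log(10)
        se = 3 * sigma_log10 / math.sqrt(n)
        for i, nominal in enumerate(inst.nominal_pe_per_bead):
            observed = np.log10(beads.channel("ch_pe")[level == i]).mean()
            assert observed == pytest.approx(0.95 * np.log10(nominal) + 0.1, abs=se)

    def test_nonpositive_count_rejected(self, instrument):
        with pytest.raises(InvalidArgumentError):
            qflow.generate_bead_tube(instrument, 0, seed=0)


class TestSubjectTubes:
    def test_zero_cec_fraction_yields_no_cecs(self, instrument, configs):
        from dataclasses import replace

        cfg = replace(configs["male_under50"], cec_fraction=0.0)
        profile = qflow.make_profile("s", 30, "male")
        tubes = qflow.generate_subject_tubes(profile, cfg, instrument, 10_000, seed=0)
        for tube in tubes.values():
            assert not tube.truth["is_cec"].any()

    def test_female_post_cec_truth_median_near_2900(self, instrument, configs):
        profile = qflow.make_profile("s", 55, "female")
        tubes = qflow.generate_subject_tubes(
            profile, configs["female_post"], instrument, 50_000, seed=3
        )
        truth = tubes["stained_v1"].truth
        r = truth.loc[truth["is_cec"], "receptor_true"]
        assert np.median(r) == pytest.approx(2900, rel=0.15)

    def test_male_high_component_fraction_matches_planted_weight(
        self, instrument, configs
    ):
        profile = qflow.make_profile("s", 40, "male")
        tubes = qflow.generate_subject_tubes(
            profile, configs["male_under50"], instrument, 100_000, seed=7
        )
        truth = tubes["stained_v1"].truth
        comp = truth.loc[truth["is_cec"], "subpop_index"]
        n = len(comp)
        se = math.sqrt(0.269 * (1 - 0.269) / n)
        assert np.mean(comp == 1) == pytest.approx(0.269, abs=3 * se)

    def test_mismatched_group_rejected(self, instrument, configs):
        profile = qflow.make_profile("s", 30, "male")
        with pytest.raises(InvalidArgumentError):
            qflow.generate_subject_tubes(
                profile, configs["female_post"], instrument, 2000, seed=0
            )

    def test_bad_weights_rejected(self, configs):
        from dataclasses import replace

        base = configs["male_under50"]
        bad = (qflow.Subpop(0.6, 3100, 0.35), qflow.Subpop(0.3, 206000, 0.35))
        with pytest.raises(InvalidArgumentError):
            replace(base, subpops_v1_cec=bad)

    def test_determinism_bit_identical(self, instrument, configs):
        profile = qflow.make_profile("s", 55, "female")
        a = qflow.generate_subject_tubes(profile, configs["female_post"], instrument, 2000, seed=9)
        b = qflow.generate_subject_tubes(profile, configs["female_post"], instrument, 2000, seed=9)
        for role in a:
            pd.testing.assert_frame_equal(a[role].data, b[role].data)
            pd.testing.assert_frame_equal(a[role].truth, b[role].truth)

    def test_composition_conservation(self, instrument, configs):
        profile = qflow.make_profile("s", 30, "male")
        tubes = qflow.generate_subject_tubes(
            profile, configs["male_under50"], instrument, 20_000, seed=4
        )
        for tube in tubes.values():
            t = tube.truth
            total = (
                t["is_cec"].sum()
                + t["is_cpc"].sum()
                + t["is_debris"].sum()
                + t["is_doublet"].sum()
                + t["is_dead"].sum()
            )
            assert total == len(tube)

    def test_planted_median_within_two_percent(self, instrument, configs):
        """Empirical truth median of a >=1e4-draw subpopulation is on target."""
        profile = qflow.make_profile("s", 55, "female")
        tubes = qflow.generate_subject_tubes(
            profile, configs["female_post"], instrument, 20_000, seed=5
        )
        truth = tubes["stained_v1"].truth
        r = truth.loc[truth["is_cpc"], "receptor_true"]
        assert len(r) >= 10_000
        assert np.median(r) == pytest.approx(650, rel=0.02)

    def test_fmo_pe_separated_from_stained_high_components(self, instrument, configs):
        """The PE-FMO control sits far below VEGFR-high stained signal."""
        profile = qflow.make_profile("s", 30, "male")
        tubes = qflow.generate_subject_tubes(
            profile, configs["male_under50"], instrument, 20_000, seed=6
        )
        fmo_995 = np.quantile(tubes["fmo_pe"].channel("ch_pe"), 0.995)
        for sub in configs["male_under50"].subpops_v1_cec:
            if sub.median > 10_000:
                assert fmo_995 < instrument.response(sub.median)


class TestCohort:
    def test_empty_cohort(self):
        cohort = qflow.generate_cohort({g: 0 for g in qflow.synthdata.GROUPS}, seed=0)
        assert cohort.subjects == []

    def test_default_cohort_has_23_subjects(self, default_cohort):
        assert len(default_cohort.subjects) == 23
        assert len(default_cohort.by_group("female_pre")) == 5
        assert len(default_cohort.by_group("female_post")) == 6

    def test_menopause_rule(self, default_cohort):
        for s in default_cohort.subjects:
            p = s.profile
            if p.sex == "male":
                assert p.menopausal == "not_applicable"
            elif p.age >= 50:
                assert p.menopausal == "meno_post"
            else:
                assert p.menopausal == "pre_peri"

    def test_cohort_determinism(self):
        a = qflow.generate_cohort({"female_post": 2}, seed=42, n_events=2000, n_beads_per_level=200)
        b = qflow.generate_cohort({"female_post": 2}, seed=42, n_events=2000, n_beads_per_level=200)
        pd.testing.assert_frame_equal(a.bead_tube.data, b.bead_tube.data)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.profile == sb.profile
            for role in sa.tubes:
                pd.testing.assert_frame_equal(sa.tubes[role].data, sb.tubes[role].data)

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qflow.generate_cohort({"female_post": -1}, seed=0)

    def test_group_mean_cec_fraction_preserved(self, default_cohort):
        """Subject-level jitter leaves each group's mean fraction exact."""
        for group in ("female_post", "male_under50"):
            subjects = default_cohort.by_group(group)
            mean_f = np.mean([s.config.cec_fraction for s in subjects])
            assert mean_f == pytest.approx(0.0098, rel=1e-9)


def test_event_table_csv_round_trip(tmp_path, instrument):
    beads = qflow.generate_bead_tube(instrument, 50, seed=0)
    path = tmp_path / "beads.csv"
    beads.to_csv(path)
    back = qflow.EventTable.from_csv(path, path.with_suffix(".truth.csv"))
    pd.testing.assert_frame_equal(back.data, beads.data)
    assert back.tube_role == "beads"
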