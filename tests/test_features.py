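"""Feature definitions: directional stats, FQFFT, REOH, aggregation."""

import numpy as np
import pandas as pd
import pytest

from turngait import features as feat
from turngait.features import (
    FeatureMatrix,
    ParticipantExcluded,
    SectionFeatures,
    aggregate_participant,
    build_feature_matrix,
    combine_conditions,
    directional_stats,
    fqfft,
    read_feature_matrix,
    reoh,
    section_features,
    temporal_features,
    write_feature_matrix,
)
from turngait.preprocess import Session


class TestDirectionalStats:
    @pytest.mark.parametrize("signal, expected", [
        ([1, 2, 3], (3, 2, 1, 0, 0, 0)),
        ([-2, -2], (0, 0, 0, 2, 2, 0)),
        ([-1, 0, 1, 4], (4, 2.5, np.std([1, 4], ddof=1), 1, 1, 0)),
    ])
    def test_hand_computed_cases(self, signal, expected):
        got = directional_stats(np.array(signal, dtype=float))
        assert got == pytest.approx(expected)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            directional_stats(np.array([1.0]))


class TestFqfft:
    def test_low_tone_is_all_first_quartile(self):
        t = np.arange(500) / 50.0
        assert fqfft(np.sin(2 * np.pi * 5 * t)) == pytest.approx(1.0, abs=1e-6)

    def test_high_tone_has_no_first_quartile_content(self):
        t = np.arange(500) / 50.0
        assert fqfft(np.sin(2 * np.pi * 20 * t)) == pytest.approx(0.0, abs=1e-6)

    def test_equal_mixture_splits_evenly(self):
        t = np.arange(500) / 50.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 20 * t)
        assert fqfft(x) == pytest.approx(0.5, abs=0.01)

    def test_all_zero_signal_defined_as_one(self):
        assert fqfft(np.zeros(100)) == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        assert fqfft(3.7 * x) == pytest.approx(fqfft(x))


class TestReoh:
    def test_pure_stride_tone_is_all_odd(self):
        t = np.arange(1000) / 50.0
        x = np.sin(2 * np.pi * 1.0 * t)
        assert reoh(x, stride_frequency=1.0) == pytest.approx(0.0, abs=1e-6)

    def test_pure_step_tone_is_all_even(self):
        t = np.arange(1000) / 50.0
        x = np.sin(2 * np.pi * 2.0 * t)
        assert reoh(x, stride_frequency=1.0) == pytest.approx(1.0, abs=1e-6)

    def test_literal_quotient_form(self):
        t = np.arange(1000) / 50.0
        x = np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        bounded = reoh(x, 1.0, normalized=True)
        quotient = reoh(x, 1.0, normalized=False)
        assert quotient == pytest.approx(bounded / (1 - bounded), rel=1e-6)
        assert quotient == pytest.approx(2.0, rel=1e-2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(600)
        assert reoh(2.5 * x, 0.95) == pytest.approx(reoh(x, 0.95))

    def test_rejects_bad_stride_frequency(self):
        with pytest.raises(ValueError):
            reoh(np.ones(100), 0.0)


class TestTemporal:
    def test_half_second_steps_give_cadence_120(self):
        lb = np.arange(0, 500, 25)      # every 0.5 s at 50 Hz
        ls = np.arange(0, 500, 50)
        cadence, _ = temporal_features(lb, ls)
        assert cadence == pytest.approx(120.0)

    def test_one_second_strides(self):
        ls = np.arange(0, 500, 50)
        _, stride = temporal_features(np.arange(0, 500, 25), ls)
        assert stride == pytest.approx(1.0)

    def test_planted_schedule_cadence(self, clean_bundle):
        synth, session, steps, _, straights = clean_bundle
        sf = section_features(session, straights[0], steps)
        expected = 60.0 * 2 * 0.95      # 2 x stride frequency, steps/min
        assert sf.values["LB|cadence"] == pytest.approx(expected, abs=2.0)
        assert sf.values["LB|stride_time"] == pytest.approx(1 / 0.95, abs=0.03)


class TestSectionFeatures:
    def test_exactly_74_named_values(self, clean_bundle):
        _, session, steps, turns, straights = clean_bundle
        for seg in (turns[0], straights[0]):
            sf = section_features(session, seg, steps)
            assert sf is not None
            assert len(sf.values) == 74
            assert list(sf.values) == feat.SECTION_FEATURE_NAMES

    def test_per_site_feature_counts(self):
        names = feat.SECTION_FEATURE_NAMES
        per_site = {s: sum(1 for n in names if n.startswith(s + "|"))
                    for s in ("LB", "LS", "RS")}
        assert per_site == {"LB": 26, "LS": 24, "RS": 24}

    def test_spectral_ratios_bounded(self, clean_bundle):
        _, session, steps, turns, straights = clean_bundle
        for seg in turns + straights:
            sf = section_features(session, seg, steps)
            for name, v in sf.values.items():
                if "FQFFT" in name or "REOH" in name:
                    assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_doubling_acceleration_scales_stats_only(self, clean_bundle):
        _, session, steps, _, straights = clean_bundle
        seg = straights[0]
        doubled = Session(time_s=session.time_s,
                          signals={s: 2.0 * sig for s, sig in
                                   session.signals.items()})
        a = section_features(session, seg, steps).values
        b = section_features(doubled, seg, steps).values
        for name in a:
            if any(tag in name for tag in ("FQFFT", "cadence", "stride_time")):
                assert b[name] == pytest.approx(a[name], rel=1e-9)
            elif "REOH" in name:
                assert b[name] == pytest.approx(a[name], rel=1e-6)
            else:
                assert b[name] == pytest.approx(2.0 * a[name], rel=1e-9)


def _fake_section(kind, value):
    values = {n: value for n in feat.SECTION_FEATURE_NAMES}
    return SectionFeatures(kind=kind, values=values)


class TestAggregation:
    def test_vector_length_is_296(self):
        p = aggregate_participant([_fake_section("turn", 1.0)], "turn", "P0", "NF")
        assert len(p.values) == 296

    def test_identical_sections_collapse(self):
        p = aggregate_participant([_fake_section("turn", 2.0)] * 2,
                                  "turn", "P0", "NF")
        for name in feat.SECTION_FEATURE_NAMES:
            assert p.values[f"max|{name}"] == p.values[f"min|{name}"] == 2.0
            assert p.values[f"sd|{name}"] == 0.0

    def test_two_valued_aggregate(self):
        p = aggregate_participant([_fake_section("turn", 1.0),
                                   _fake_section("turn", 3.0)],
                                  "turn", "P0", "PF")
        name = feat.SECTION_FEATURE_NAMES[0]
        assert p.values[f"max|{name}"] == 3.0
        assert p.values[f"min|{name}"] == 1.0
        assert p.values[f"mean|{name}"] == 2.0
        assert p.values[f"sd|{name}"] == pytest.approx(np.sqrt(2.0))

    def test_no_sections_excludes_participant(self):
        with pytest.raises(ParticipantExcluded):
            aggregate_participant([_fake_section("turn", 1.0)],
                                  "straight", "P0", "NF")

    def test_nan_sections_are_ignored_in_aggregates(self):
        good = _fake_section("turn", 2.0)
        holed = dict(good.values)
        holed[feat.SECTION_FEATURE_NAMES[0]] = np.nan
        p = aggregate_participant(
            [good, SectionFeatures(kind="turn", values=holed)], "turn", "P", "NF")
        assert p.values[f"sd|{feat.SECTION_FEATURE_NAMES[0]}"] == 0.0


class TestCombine:
    def _pair(self):
        s = aggregate_participant([_fake_section("straight", 1.0)],
                                  "straight", "P0", "PF")
        t = aggregate_participant([_fake_section("turn", 5.0)],
                                  "turn", "P0", "PF")
        return s, t

    def test_combined_length_592_disjoint_names_values_kept(self):
        s, t = self._pair()
        c = combine_conditions(s, t)
        assert len(c.values) == 592
        s_names = {k for k in c.values if k.startswith("straight|")}
        t_names = {k for k in c.values if k.startswith("turn|")}
        assert len(s_names) == len(t_names) == 296
        assert all(c.values[f"straight|{k}"] == v for k, v in s.values.items())
        assert all(c.values[f"turn|{k}"] == v for k, v in t.values.items())

    def test_mismatched_participants_rejected(self):
        s, t = self._pair()
        bad = feat.ParticipantFeatures("P1", "PF", "turn", t.values)
        with pytest.raises(ValueError, match="participant"):
            combine_conditions(s, bad)


class TestFeatureMatrixIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((4, 6)),
                         index=[f"P{i}" for i in range(4)],
                         columns=[f"f{i}" for i in range(6)])
        labels = pd.Series(["NF", "PF", "NF", "PF"], index=X.index, name="label")
        fm = FeatureMatrix(X=X, labels=labels)
        path = tmp_path / "m.csv"
        write_feature_matrix(fm, path)
        back = read_feature_matrix(path)
        pd.testing.assert_frame_equal(back.X, fm.X, check_exact=False,
                                      check_names=False)
        assert (back.labels == fm.labels).all()

    def test_duplicate_columns_rejected(self):
        X = pd.DataFrame(np.zeros((2, 2)), columns=["a", "a"], index=["P0", "P1"])
        labels = pd.Series(["NF", "PF"], index=X.index)
        with pytest.raises(ValueError, match="unique"):
            FeatureMatrix(X=X, labels=labels)
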