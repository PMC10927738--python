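import numpy as np
import pytest
from scipy.stats import chi2_contingency

import stutterkit as sk
from stutterkit.segmentation import DropReason, Scheme, make_intervals

F = sk.FluencyClass


def recording(events, duration=10.0, sr=16000):
    return sk.AnnotatedRecording(
        "r", "s", sr, np.zeros(int(duration * sr)),
        [sk.FluencyEvent(lab, a, b) for lab, a, b in events],
    ).validate()


class TestExtractEvents:
    def test_bounds_and_labels_copied(self):
        rec = recording([(F.FLUENT, 0.0, 0.2), (F.BLOCK, 0.2, 0.8)])
        segs = sk.extract_events(rec)
        assert [(s.label, s.start, s.end) for s in segs] == [
            (F.FLUENT, 0.0, 0.2), (F.BLOCK, 0.2, 0.8)]
        assert all(s.scheme is Scheme.EVENT for s in segs)

    def test_empty_recording_gives_no_segments(self):
        assert sk.extract_events(recording([])) == []

    def test_generator_class_frequencies_match_config(self):
        # ~2,000 events sampled from the default class probabilities:
        # the empirical fluent share must sit within 2 points of 82.48%.
        corpus = sk.generate_corpus(
            sk.SynthConfig(n_speakers=4, seconds_per_speaker=160.0, seed=11))
        segs = [s for rec in corpus for s in sk.extract_events(rec)]
        assert len(segs) > 1500
        dist = sk.class_distribution(segs)
        assert dist.relative_frequencies[F.FLUENT] == pytest.approx(82.48, abs=2.0)


class TestMakeIntervals:
    def test_trailing_remainder_dropped(self):
        rec = recording([(F.FLUENT, 0.0, 10.0)], duration=10.0)
        segs = make_intervals(rec, 3.0)
        assert [(s.start, s.end) for s in segs] == [(0, 3), (3, 6), (6, 9)]

    def test_exact_multiple_keeps_all(self):
        rec = recording([(F.FLUENT, 0.0, 9.0)], duration=9.0)
        assert len(make_intervals(rec, 3.0)) == 3

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            make_intervals(recording([]), 0.0)

    def test_matches_bruteforce_rescan(self):
        # independent oracle: re-derive each interval's fate directly from
        # event overlaps, without going through label_interval
        corpus = sk.generate_corpus(
            sk.SynthConfig(n_speakers=2, seconds_per_speaker=60.0, seed=3))
        for rec in corpus:
            for L in (2.0, 3.0, 4.0):
                got = {(s.start, s.label) for s in make_intervals(rec, L)}
                expected = set()
                k = 0
                while (k + 1) * L <= rec.duration + 1e-9:
                    lo, hi = k * L, (k + 1) * L
                    labs = {e.label for e in rec.events
                            if e.onset < hi and e.offset > lo}
                    dis = labs - {F.FLUENT}
                    if labs and len(dis) <= 1:
                        expected.add((lo, dis.pop() if dis else F.FLUENT))
                    k += 1
                assert got == expected


class TestLabelInterval:
    @pytest.fixture()
    def rec(self):
        return recording([
            (F.FLUENT, 0.0, 1.0), (F.BLOCK, 1.2, 1.8),
            (F.PWR, 2.0, 2.5), (F.FLUENT, 4.0, 5.0),
        ], duration=10.0)

    def test_all_fluent(self, rec):
        assert sk.label_interval(rec, 4.0, 5.0) is F.FLUENT

    def test_fluent_plus_one_disfluent_marks_whole_interval(self, rec):
        assert sk.label_interval(rec, 0.0, 1.5) is F.BLOCK

    def test_two_disfluent_classes_dropped(self, rec):
        assert sk.label_interval(rec, 1.0, 2.2) is DropReason.MULTIPLE

    def test_silent_interval_dropped(self, rec):
        assert sk.label_interval(rec, 6.0, 8.0) is DropReason.SILENT

    def test_boundary_touch_does_not_overlap(self, rec):
        # event ending exactly at the interval start is excluded
        assert sk.label_interval(rec, 1.0, 1.2) is DropReason.SILENT

    def test_out_of_range_rejected(self, rec):
        with pytest.raises(ValueError):
            sk.label_interval(rec, 9.0, 11.0)


class TestAttachLookback:
    def test_before_ends_at_event_end(self):
        seg = sk.SpeechSegment("x", "r", Scheme.EVENT, F.FLUENT, 5.0, 5.5)
        out = sk.attach_lookback(seg, 100.0, 3.0, sk.Context.BEFORE)
        assert (out.lookback_start, out.lookback_end) == (2.5, 5.5)

    def test_middle_centres_on_midpoint(self):
        seg = sk.SpeechSegment("x", "r", Scheme.EVENT, F.FLUENT, 5.0, 5.5)
        out = sk.attach_lookback(seg, 100.0, 3.0, sk.Context.MIDDLE)
        assert (out.lookback_start, out.lookback_end) == (3.75, 6.75)

    def test_clipped_to_recording_start(self):
        seg = sk.SpeechSegment("x", "r", Scheme.EVENT, F.FLUENT, 0.1, 0.4)
        out = sk.attach_lookback(seg, 100.0, 3.0, sk.Context.BEFORE)
        assert (out.lookback_start, out.lookback_end) == (0.0, 0.4)


class TestClassDistribution:
    def test_event_table_frequencies(self):
        dist = sk.class_distribution([11837, 396, 469, 173, 1476])
        assert dist.total == 14351
        assert round(dist.relative_frequencies[F.FLUENT], 2) == 82.48
        assert round(dist.ratio_to_fluent[F.BLOCK], 2) == 0.12
        assert dist.ratio_to_fluent[F.FLUENT] == 1.0

    def test_percentages_sum_to_100(self):
        dist = sk.class_distribution([5, 4, 3, 2, 1])
        assert sum(dist.relative_frequencies.values()) == pytest.approx(100.0)

    def test_empty_flagged(self):
        dist = sk.class_distribution([0, 0, 0, 0, 0])
        assert dist.empty and dist.total == 0
        assert all(v == 0 for v in dist.relative_frequencies.values())


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        res = sk.chi_square_independence([[10, 20, 30], [10, 20, 30]])
        assert res.statistic == pytest.approx(0.0)
        assert res.degrees_of_freedom == 2

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            shape = (rng.integers(2, 5), rng.integers(2, 6))
            table = rng.integers(1, 50, size=shape)
            ours = sk.chi_square_independence(table)
            ref_stat, ref_p, ref_df, _ = chi2_contingency(table, correction=False)
            assert ours.statistic == pytest.approx(ref_stat, abs=1e-6)
            assert ours.degrees_of_freedom == ref_df
            assert ours.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_small_table_matches_direct_formula(self):
        table = np.array([[3.0, 7.0, 2.0], [5.0, 1.0, 4.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        res = sk.chi_square_independence(table)
        assert res.statistic == pytest.approx(stat, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            sk.chi_square_independence([[0, 5], [0, 7]])

    def test_drop_classes_removes_columns(self):
        full = [[10, 20, 30, 40, 50], [50, 40, 30, 20, 10]]
        res = sk.chi_square_independence(full, drop_classes=[F.FLUENT])
        assert res.degrees_of_freedom == 3


class TestFluentUndersampling:
    def test_event_scheme_keeps_more_fluent_than_any_interval(self, tiny_corpus):
        events = [s for r in tiny_corpus for s in sk.extract_events(r)]
        ev_fluent = sk.class_distribution(events).relative_frequencies[F.FLUENT]
        for L in (2.0, 3.0, 4.0):
            ivs = [s for r in tiny_corpus for s in make_intervals(r, L)]
            iv_fluent = sk.class_distribution(ivs).relative_frequencies[F.FLUENT]
            assert ev_fluent >= iv_fluent
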