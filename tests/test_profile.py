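"""Profiles, smoothing, composition, segment calling and agreement metrics."""

import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prefrp import (
    FluctuationClass,
    SequenceRecord,
    UnknownResidueError,
    agreement,
    call_segments,
    composition,
    profile_sequence,
    smooth_profile,
)
from prefrp.profile import profile_to_dataframe, segments_to_dataframe

from conftest import ALPHABET, brute_force_composition, brute_force_segments, random_sequence


def rec(seq, rid="s"):
    return SequenceRecord(id=rid, residues=seq, source="synthetic")


class TestProfileSequence:
    def test_uniform_high_class(self):
        assert profile_sequence(rec("GGGGG")).values == (-2, -2, -2, -2, -2)

    def test_one_residue_per_class(self):
        prof = profile_sequence(rec("GTW"))
        assert prof.values == (-2, -1, 2)
        assert prof.positions == (1, 2, 3)

    def test_skip_policy_drops_and_counts(self):
        with pytest.warns(UserWarning, match="skipped 1"):
            prof = profile_sequence(rec("GXW"), unknown_policy="skip")
        assert prof.values == (-2, 2)
        assert prof.positions == (1, 3)  # source coordinates preserved
        assert prof.skipped == 1

    def test_zero_policy_keeps_length(self):
        prof = profile_sequence(rec("GXW"), unknown_policy="zero")
        assert prof.values == (-2, 0, 2)
        assert prof.skipped == 0

    def test_error_policy_names_position(self):
        with pytest.raises(UnknownResidueError, match="position 2"):
            profile_sequence(rec("GXW"), unknown_policy="error")

    @given(seq=st.text(alphabet=ALPHABET, min_size=1, max_size=200))
    def test_length_preserved_for_standard_sequences(self, seq):
        prof = profile_sequence(rec(seq))
        assert len(prof) == len(seq)
        assert set(prof.values) <= {-2, -1, 2}


class TestSmoothing:
    def test_window_one_is_identity(self):
        prof = smooth_profile(profile_sequence(rec("GTWKA")), window=1)
        assert prof.smoothed == tuple(float(v) for v in prof.values)

    def test_window_three_center_mean(self):
        prof = smooth_profile(profile_sequence(rec("GTW")), window=3)
        assert prof.smoothed[1] == pytest.approx((-2 - 1 + 2) / 3)
        # ends shrink symmetrically to the raw value
        assert prof.smoothed[0] == -2 and prof.smoothed[2] == 2

    def test_constant_profile_stays_constant(self):
        prof = smooth_profile(profile_sequence(rec("A" * 11)), window=5)
        assert all(v == pytest.approx(-2) for v in prof.smoothed)

    @pytest.mark.parametrize("window", [0, -3, 2, 4])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValueError):
            smooth_profile(profile_sequence(rec("GTWKA")), window=window)

    @given(seq=st.text(alphabet=ALPHABET, min_size=3, max_size=80),
           half=st.integers(min_value=0, max_value=10))
    def test_smoothed_values_within_raw_range(self, seq, half):
        window = min(2 * half + 1, len(seq) - (1 - len(seq) % 2))
        prof = smooth_profile(profile_sequence(rec(seq)), window=window)
        assert min(prof.values) - 1e-12 <= min(prof.smoothed)
        assert max(prof.smoothed) <= max(prof.values) + 1e-12


class TestComposition:
    def test_all_high(self):
        summary = composition([rec("GASPD")])
        assert summary.fractions[FluctuationClass.HIGH] == 1.0
        assert summary.fractions[FluctuationClass.WEAK] == 0.0

    def test_two_class_split(self):
        summary = composition([rec("GW")])
        assert summary.fractions[FluctuationClass.HIGH] == 0.5
        assert summary.fractions[FluctuationClass.MODERATE] == 0.0
        assert summary.fractions[FluctuationClass.WEAK] == 0.5

    def test_crotamine_matches_letter_tally(self, crotamine):
        summary = composition([crotamine])
        expected, _ = brute_force_composition([crotamine.residues])
        assert summary.total == 42
        for cls in FluctuationClass:
            assert summary.counts[cls] == expected[cls.value]
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pooling_is_additive_and_permutation_invariant(self):
        rng = random.Random(7)
        seqs = [random_sequence(rng, rng.randint(5, 60)) for _ in range(12)]
        whole = composition([rec(s, f"r{i}") for i, s in enumerate(seqs)])
        part_a = composition([rec(s, f"a{i}") for i, s in enumerate(seqs[:5])])
        part_b = composition([rec(s, f"b{i}") for i, s in enumerate(seqs[5:])])
        for cls in FluctuationClass:
            assert whole.counts[cls] == part_a.counts[cls] + part_b.counts[cls]
        shuffled = ["".join(rng.sample(s, len(s))) for s in seqs]
        rng.shuffle(shuffled)
        again = composition([rec(s, f"p{i}") for i, s in enumerate(shuffled)])
        assert again.counts == whole.counts

    def test_no_classifiable_residues_errors(self):
        with pytest.raises(ValueError):
            composition([rec("XXX")])


class TestSegments:
    def test_all_weak_yields_nothing(self):
        assert call_segments(profile_sequence(rec("W" * 10)), threshold=-1, min_length=1) == []

    def test_uniform_long_run(self):
        (seg,) = call_segments(profile_sequence(rec("G" * 35)), threshold=-1, min_length=30)
        assert (seg.start, seg.end, seg.length) == (1, 35, 35)
        assert seg.mean_index == pytest.approx(-2.0)

    def test_interrupted_run_min_length_interplay(self):
        prof = profile_sequence(rec("G" * 20 + "W" * 5 + "G" * 20))
        assert call_segments(prof, threshold=-1, min_length=30) == []
        segs = call_segments(prof, threshold=-1, min_length=20)
        assert [(s.start, s.end) for s in segs] == [(1, 20), (26, 45)]

    def test_smoothed_series_is_used_when_present(self):
        prof = smooth_profile(profile_sequence(rec("GGWGG")), window=5)
        # smoothing pulls the central W below the threshold
        assert call_segments(prof, threshold=-0.5, min_length=5)
        assert call_segments(profile_sequence(rec("GGWGG")), threshold=-0.5, min_length=5) == []

    @given(seq=st.text(alphabet=ALPHABET, min_size=1, max_size=200),
           threshold=st.sampled_from([-2, -1.5, -1, 0, 2]),
           min_length=st.integers(min_value=1, max_value=40))
    def test_matches_brute_force_run_scan(self, seq, threshold, min_length):
        prof = profile_sequence(rec(seq))
        got = [(s.start, s.end) for s in call_segments(prof, threshold, min_length)]
        assert got == brute_force_segments(prof.values, threshold, min_length)


class TestAgreement:
    def test_perfect_prediction(self):
        prof = profile_sequence(rec("G" * 10 + "W" * 10))
        segs = call_segments(prof, threshold=-1, min_length=1)
        mask = [1] * 10 + [0] * 10
        report = agreement(segs, mask, 20)
        assert (report.sensitivity, report.specificity) == (1.0, 1.0)

    def test_empty_prediction_all_positive_reference(self):
        report = agreement([], [1] * 30, 30)
        assert report.sensitivity == 0.0
        assert report.fn == 30

    def test_matches_position_by_position_oracle(self):
        rng = random.Random(11)
        seq = random_sequence(rng, 50)
        mask = [rng.randint(0, 1) for _ in range(50)]
        prof = profile_sequence(rec(seq))
        segs = call_segments(prof, threshold=-1, min_length=3)
        report = agreement(segs, mask, 50)
        predicted = [0] * 50
        for s in segs:
            for p in range(s.start, s.end + 1):
                predicted[p - 1] = 1
        tp = sum(p and r for p, r in zip(predicted, mask))
        fp = sum(p and not r for p, r in zip(predicted, mask))
        fn = sum(not p and r for p, r in zip(predicted, mask))
        tn = sum(not p and not r for p, r in zip(predicted, mask))
        assert (report.tp, report.fp, report.fn, report.tn) == (tp, fp, fn, tn)
        assert report.tp + report.fp + report.fn + report.tn == 50

    def test_out_of_range_segment_rejected(self):
        prof = profile_sequence(rec("G" * 10))
        (seg,) = call_segments(prof, threshold=-1, min_length=1)
        with pytest.raises(ValueError):
            agreement([seg], [0] * 5, 5)


def test_tabular_outputs():
    prof = smooth_profile(profile_sequence(rec("GTW", "pep")), window=3)
    table = profile_to_dataframe(prof)
    assert list(table.columns) == ["position", "residue", "class", "index", "smoothed"]
    assert table["class"].tolist() == ["high", "moderate", "weak"]
    segs = call_segments(prof, threshold=0, min_length=1)
    native = segments_to_dataframe(segs, "pep")
    bed = segments_to_dataframe(segs, "pep", bed=True)
    assert (native["start"] - 1).tolist() == bed["start"].tolist()
    assert native["end"].tolist() == bed["end"].tolist()
    assert np.all(native["length"] == native["end"] - native["start"] + 1)
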