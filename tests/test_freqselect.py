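import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegrefine.freqselect import (
    FrequencyTally,
    NoPeakError,
    SelectionConfig,
    TooShortError,
    peak_frequency,
    select_filter_frequencies,
    tally,
)
from eegrefine.gradcam import LabeledInterval
from eegrefine.io import Epoch, EpochSet
from eegrefine.montage import default_montage


def tone(freqs_amps, fs=250.0, n=125):
    t = np.arange(n) / fs
    return sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)


class TestPeakFrequency:
    def test_single_tone(self):
        assert peak_frequency(tone([(10, 1)]), 250) == 10

    def test_dominant_tone_wins(self):
        assert peak_frequency(tone([(8, 1), (20, 2)]), 250) == 20

    def test_dc_only_has_no_in_band_peak(self):
        with pytest.raises(NoPeakError):
            peak_frequency(np.full(125, 3.7), 250)

    def test_all_zero_segment(self):
        with pytest.raises(NoPeakError):
            peak_frequency(np.zeros(125), 250)

    def test_too_short_segment(self):
        with pytest.raises(TooShortError):
            peak_frequency(np.ones(7), 250)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            peak_frequency(tone([(10, 1)]), 250, band=(0.5, 130))


def planted_set(plant):
    """One 22-channel epoch whose channel 0 carries the given tones."""
    m = default_montage()
    sig = np.zeros((22, 312))
    sig[0] = tone(plant, n=312)
    e = Epoch(signal=sig, fs=250, cue_index=0, label=0, trial_id="p0")
    return EpochSet([e], m.electrodes, m)


def iv(kind, start=0, end=312, electrode="C5", trial="p0"):
    # C5 is channel 0 in the shipped montage ordering? use explicit electrode
    return LabeledInterval(electrode=electrode, start=start, end=end,
                           kind=kind, trial_id=trial, branch="SRF")


class TestTally:
    def _first_electrode(self, eset):
        return eset.electrodes[0]

    def test_three_useless_intervals_with_50hz(self):
        eset = planted_set([(50, 2), (5, 0.5)])
        el = self._first_electrode(eset)
        ivs = [iv("useless", 0, 150, el), iv("useless", 100, 250, el),
               iv("useless", 150, 300, el)]
        good, bad = tally(ivs, eset)
        assert bad.counts[50] == 3
        assert good.counts == {}

    def test_single_useful_10hz(self):
        eset = planted_set([(10, 1)])
        el = self._first_electrode(eset)
        good, bad = tally([iv("useful", 0, 312, el)], eset)
        assert good.counts == {10: 1}
        assert bad.counts == {}

    def test_empty_interval_list(self, small_set):
        good, bad = tally([], small_set)
        assert good.counts == {} and bad.counts == {}

    def test_degenerate_intervals_counted_as_skipped(self):
        eset = planted_set([(10, 1)])
        el = self._first_electrode(eset)
        zero_el = eset.electrodes[1]  # channel with all-zero signal
        ivs = [iv("useless", 0, 6, el), iv("useless", 0, 312, zero_el),
               iv("useful", 0, 312, el)]
        good, bad = tally(ivs, eset)
        assert bad.skipped["too_short"] == 1
        assert bad.skipped["no_peak"] == 1
        assert good.counts == {10: 1}


def mktally(kind, counts):
    return FrequencyTally(kind, dict(counts))


class TestSelection:
    def test_spec_fixture_top3_minus_top2(self):
        fset = select_filter_frequencies(
            mktally("bad", {50: 10, 8: 9, 12: 8}),
            mktally("good", {8: 20, 12: 15}),
            SelectionConfig(k_bad=3, m_good=2),
        )
        assert fset.frequencies == [50]

    def test_full_overlap_gives_empty_set(self):
        bad = mktally("bad", {10: 5, 20: 4})
        good = mktally("good", {10: 9, 20: 8, 30: 1})
        assert select_filter_frequencies(bad, good, SelectionConfig(k_bad=2, m_good=3)
                                         ).frequencies == []

    def test_count_tie_resolved_to_lower_hz(self):
        fset = select_filter_frequencies(
            mktally("bad", {30: 5, 40: 5}), mktally("good", {}),
            SelectionConfig(k_bad=1, m_good=1),
        )
        assert fset.frequencies == [30]

    def test_good_rank_cutoff_excludes_rare_good_bins(self):
        bad = mktally("bad", {50: 3, 60: 2})
        good = mktally("good", {10: 9, 50: 1})
        fset = select_filter_frequencies(bad, good, SelectionConfig(k_bad=2, m_good=1))
        assert fset.frequencies == [50, 60]  # 50 fell outside good's top 1

    def test_empty_bad_tally_warns_and_returns_empty(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            fset = select_filter_frequencies(mktally("bad", {}), mktally("good", {1: 1}))
        assert len(fset) == 0

    def test_provenance_captures_counts_and_config(self):
        fset = select_filter_frequencies(
            mktally("bad", {50: 2}), mktally("good", {}),
            SelectionConfig(), seed=42,
        )
        assert fset.provenance["seed"] == 42
        assert fset.provenance["bad_counts"] == {"50": 2}
        assert fset.bad_counts == {50: 2}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        bad=st.dictionaries(st.integers(1, 100), st.integers(1, 50), max_size=60),
        good=st.dictionaries(st.integers(1, 100), st.integers(1, 50), max_size=60),
        k_bad=st.integers(1, 25),
        m_good=st.integers(1, 100),
    )
    def test_result_bounded_by_k_bad_and_monotone_in_m_good(self, bad, good, k_bad, m_good):
        cfg = SelectionConfig(k_bad=k_bad, m_good=m_good)
        fset = select_filter_frequencies(mktally("bad", bad), mktally("good", good), cfg)
        assert len(fset) <= k_bad
        assert fset.frequencies == sorted(fset.frequencies)
        assert set(fset.frequencies) <= set(bad)
        if m_good < 100:
            bigger = SelectionConfig(k_bad=k_bad, m_good=m_good + 1)
            wider = select_filter_frequencies(
                mktally("bad", bad), mktally("good", good), bigger)
            assert set(wider.frequencies) <= set(fset.frequencies)
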