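"""Spectrogram parser: binarization, syllable extraction, features, songs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songpeth import synth
from songpeth.segmentation import (
    SegmentationConfig,
    Spectrogram,
    binarize_and_clean,
    compute_features,
    compute_spectrogram,
    extract_syllables,
    group_songs,
    segment_audio,
)

from conftest import make_ridge_spectrogram

FS = 250_000.0


def tone(freq_hz, dur_s, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return np.sin(2 * np.pi * freq_hz * t)


class TestSpectrogram:
    def test_pure_tone_localizes_to_its_frequency_row(self):
        spec = compute_spectrogram(tone(70_000, 0.1), FS)
        df = spec.freqs[1] - spec.freqs[0]
        peak_freq = spec.freqs[spec.power.mean(axis=1).argmax()]
        assert abs(peak_freq - 70_000) <= df

    def test_silence_gives_near_zero_power(self):
        spec = compute_spectrogram(np.zeros(int(0.1 * FS)), FS)
        assert spec.power.max() < 1e-20

    def test_chirp_ridge_spans_programmed_sweep(self):
        # linear chirp 60 -> 80 kHz over 20 ms
        dur = 0.020
        t = np.arange(int(dur * FS)) / FS
        wave = np.sin(2 * np.pi * (60_000 * t + 0.5 * (20_000 / dur) * t**2))
        spec = compute_spectrogram(wave, FS)
        prof = spec.power.max(axis=1)
        rows = np.flatnonzero(prof > 0.05 * prof.max())
        lo, hi = spec.freqs[rows.min()], spec.freqs[rows.max()]
        assert lo == pytest.approx(60_000, abs=2_000)
        assert hi == pytest.approx(80_000, abs=2_000)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            compute_spectrogram(np.zeros(1000), 100_000.0)


class TestBinarize:
    def _spec_with_pixels(self, pixels):
        rng = np.random.default_rng(1)
        power = rng.exponential(1.0, size=(20, 50))
        for r, c in pixels:
            power[r, c] = 1e6
        return Spectrogram(power=power, times=np.arange(50) * 1e-3,
                           freqs=20_000 + np.arange(20) * 1e3)

    def test_single_isolated_pixel_removed(self):
        mask = binarize_and_clean(self._spec_with_pixels([(10, 25)]))
        assert not mask[10, 25]
        assert mask.sum() == 0

    def test_full_3x3_block_retained(self):
        pix = [(r, c) for r in (9, 10, 11) for c in (24, 25, 26)]
        mask = binarize_and_clean(self._spec_with_pixels(pix))
        assert all(mask[r, c] for r, c in pix)

    def test_diagonal_pair_retained(self):
        # each pixel sees the other inside its 3x3 window
        mask = binarize_and_clean(self._spec_with_pixels([(10, 25), (11, 26)]))
        assert mask[10, 25] and mask[11, 26]

    def test_raising_detect_z_never_adds_pixels(self):
        spec = make_ridge_spectrogram([(100, 140, 20, 24)], seed=5)
        lo = binarize_and_clean(spec, SegmentationConfig(detect_z=4))
        hi = binarize_and_clean(spec, SegmentationConfig(detect_z=8, feature_z=8))
        assert not np.any(hi & ~lo)


class TestExtractSyllables:
    def test_twenty_ms_ridge_is_one_syllable(self):
        spec = make_ridge_spectrogram([(100, 120, 20, 24)])
        mask = binarize_and_clean(spec)
        syls = extract_syllables(mask, spec.times)
        assert len(syls) == 1
        assert syls[0].end_s - syls[0].start_s == pytest.approx(0.020, abs=0.0011)

    def test_seven_ms_ridge_rejected_eight_ms_retained(self):
        for ms, expected in [(7, 0), (8, 1)]:
            spec = make_ridge_spectrogram([(100, 100 + ms, 20, 24)])
            mask = binarize_and_clean(spec)
            assert len(extract_syllables(mask, spec.times)) == expected

    def test_sub_gap_fragments_merge_before_duration_floor(self):
        # two 10 ms ridges separated by 10 ms (< 16 ms) -> one ~30 ms syllable
        spec = make_ridge_spectrogram([(100, 110, 20, 24), (120, 130, 20, 24)])
        mask = binarize_and_clean(spec)
        syls = extract_syllables(mask, spec.times)
        assert len(syls) == 1
        assert syls[0].end_s - syls[0].start_s == pytest.approx(0.030, abs=0.0015)

    def test_sixteen_ms_gap_splits(self):
        spec = make_ridge_spectrogram([(100, 110, 20, 24), (126, 136, 20, 24)])
        mask = binarize_and_clean(spec)
        assert len(extract_syllables(mask, spec.times)) == 2

    def test_empty_mask_gives_no_syllables(self):
        assert extract_syllables(np.zeros((5, 100), bool), np.arange(100) * 1e-3) == []

    @given(min_ms=st.sampled_from([8.0, 12.0, 20.0, 30.0]))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_raising_duration_floor_never_adds_syllables(self, min_ms):
        spec = make_ridge_spectrogram(
            [(50, 60, 10, 14), (100, 125, 20, 24), (200, 240, 30, 34)], seed=2)
        mask = binarize_and_clean(spec)
        base = extract_syllables(mask, spec.times, SegmentationConfig(min_syllable_ms=8.0))
        strict = extract_syllables(mask, spec.times, SegmentationConfig(min_syllable_ms=min_ms))
        assert len(strict) <= len(base)


class TestFeatures:
    def test_constant_tone_features(self):
        spec = make_ridge_spectrogram([(100, 125, 30, 31)])  # 25 ms, one freq row
        mask = binarize_and_clean(spec)
        syl = compute_features(spec, extract_syllables(mask, spec.times)[0])
        assert syl.duration_ms == pytest.approx(25.0, abs=1.1)
        assert syl.mean_freq_hz == pytest.approx(spec.freqs[30], abs=1_000)
        assert syl.bandwidth_hz <= 2 * (spec.freqs[1] - spec.freqs[0])

    def test_chirp_mean_freq_and_bandwidth(self):
        # audio-level check against a programmed 60->80 kHz sweep
        dur = 0.030
        t = np.arange(int(dur * FS)) / FS
        chirp = np.sin(2 * np.pi * (60_000 * t + 0.5 * (20_000 / dur) * t**2))
        rng = np.random.default_rng(0)
        pad = int(0.05 * FS)
        wave = rng.normal(0, 0.005, 2 * pad + chirp.size)
        # ~20 dB SNR; at much higher SNR the Hann sidelobes themselves pass
        # the feature threshold and inflate the measured bandwidth
        wave[pad : pad + chirp.size] += 0.05 * chirp
        syls, _ = segment_audio(wave, FS)
        assert len(syls) == 1
        assert syls[0].mean_freq_hz == pytest.approx(70_000, abs=1_500)
        assert syls[0].bandwidth_hz == pytest.approx(20_000, abs=2_000)

    def test_no_surviving_pixels_flags_missing_features(self):
        spec = make_ridge_spectrogram([(100, 120, 20, 24)], signal=1e4)
        mask = binarize_and_clean(spec)
        syl = extract_syllables(mask, spec.times)[0]
        out = compute_features(spec, syl, SegmentationConfig(detect_z=4, feature_z=1e9))
        assert np.isnan(out.mean_freq_hz) and np.isnan(out.bandwidth_hz)
        assert not np.isnan(out.duration_ms)


class TestSongs:
    def _syllables_at(self, starts, dur=0.03):
        spec = make_ridge_spectrogram([], n_time=10)
        from songpeth.segmentation import Syllable
        return [Syllable(start_s=s, end_s=s + dur) for s in starts]

    def test_short_gaps_make_one_song(self):
        songs = group_songs(self._syllables_at([0.0, 0.13, 0.26, 0.39]))
        assert len(songs) == 1
        assert songs[0].onset_s == 0.0

    def test_clusters_12s_apart_make_two_songs(self):
        songs = group_songs(self._syllables_at([0.0, 0.2, 12.23, 12.43]))
        assert len(songs) == 2

    def test_exactly_10s_gap_splits(self):
        # gap measured from previous syllable end to next start; >= is inclusive
        songs = group_songs(self._syllables_at([0.0, 10.03]))
        assert len(songs) == 2

    def test_every_syllable_in_exactly_one_song(self):
        syls = self._syllables_at([0.0, 0.2, 12.0, 12.2, 40.0])
        songs = group_songs(syls)
        all_ids = [i for s in songs for i in s.syllable_ids]
        assert sorted(all_ids) == list(range(len(syls)))
        assert all(syls[i].song_id == s.song_id for s in songs for i in s.syllable_ids)


class TestRecovery:
    def test_recall_precision_on_synthetic_audio(self, short_audio_session):
        """At 20 dB SNR the parser recovers >= 95% of truth syllables with
        <= 2 ms boundary error and no false detections."""
        cfg, wave, truth = short_audio_session
        syls, songs = segment_audio(wave, cfg.audio_fs)
        det = np.array([[s.start_s, s.end_s] for s in syls])
        hits = 0
        for row in truth.syllables.itertuples(index=False):
            err = np.abs(det - [row.start_s, row.end_s]).max(axis=1)
            if err.min() <= 0.002:
                hits += 1
        recall = hits / len(truth.syllables)
        precision = hits / len(det)
        assert recall >= 0.95
        assert precision >= 0.95
        assert len(songs) == len(truth.songs)

    def test_no_syllables_in_pure_noise(self):
        cfg = synth.SynthSessionConfig(duration_s=60.0, n_se=0, seed=11)
        wave, truth = synth.synth_usv_audio(cfg)
        assert len(truth.syllables) == 0
        syls, _ = segment_audio(wave, cfg.audio_fs)
        assert syls == []

    def test_syllable_intervals_disjoint_and_sorted(self, short_audio_session):
        cfg, wave, _ = short_audio_session
        syls, songs = segment_audio(wave, cfg.audio_fs)
        starts = np.array([s.start_s for s in syls])
        ends = np.array([s.end_s for s in syls])
        assert np.all(starts[1:] >= ends[:-1])
        concat = [i for s in songs for i in s.syllable_ids]
        assert concat == list(range(len(syls)))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SegmentationConfig(f_lo=50_000, f_hi=40_000)
    with pytest.raises(ValueError):
        SegmentationConfig(min_syllable_ms=0)
    with pytest.raises(ValueError):
        SegmentationConfig(square_size=4)
    with pytest.raises(ValueError):
        SegmentationConfig(song_gap_s=0.001)
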