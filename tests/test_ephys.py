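"""Common-median referencing, spike detection, PETHs, responsiveness."""

import numpy as np
import pytest

from songpeth import synth
from songpeth.ephys import (
    PETH,
    SpikeDetectionConfig,
    SpikeTrain,
    categorize_unit,
    common_median_reference,
    compute_peth,
    detect_spikes,
    responsiveness_test,
)

FS = 25_000.0


class TestCMR:
    def test_identical_channels_cancel_exactly(self):
        x = np.tile(np.sin(np.linspace(0, 10, 1000)), (5, 1))
        assert np.allclose(common_median_reference(x), 0.0)

    def test_single_channel_spike_preserved(self):
        x = np.zeros((5, 1000))
        x[2, 500] = -80.0
        ref = common_median_reference(x)
        assert ref[2, 500] == -80.0
        assert np.count_nonzero(ref) == 1

    def test_idempotent_on_median_free_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(7, 2000))
        once = common_median_reference(x)
        twice = common_median_reference(once)
        assert np.allclose(once, twice)

    def test_shared_sinusoid_removed_spikes_kept(self):
        """The full raw-data oracle: common mode out, per-channel spikes in."""
        rng = np.random.default_rng(1)
        dur, n_ch = 10.0, 8
        spike_times = [np.sort(rng.uniform(0.1, dur - 0.1, 20)) for _ in range(n_ch)]
        t = np.arange(int(dur * FS)) / FS
        common = 5.0 * np.sin(2 * np.pi * 50 * t)
        x = synth.synth_raw_voltage(spike_times, dur, fs=FS, spike_amp_sd=12.0,
                                    common_mode=common, seed=2)
        ref = common_median_reference(x)
        for ch in range(n_ch):
            det = detect_spikes(ref[ch], FS)
            hits = sum(np.min(np.abs(det - st)) < 0.0005 for st in spike_times[ch])
            assert hits >= 0.99 * len(spike_times[ch])

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="3 channels"):
            common_median_reference(np.zeros((2, 100)))


class TestDetectSpikes:
    def test_gaussian_noise_yields_no_false_positives(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, int(60 * FS))
        assert detect_spikes(x, FS).size == 0

    def test_planted_templates_recovered(self):
        rng = np.random.default_rng(4)
        dur = 30.0
        times = np.sort(rng.uniform(0.1, dur - 0.1, 50))
        x = synth.synth_raw_voltage([times], dur, fs=FS, spike_amp_sd=12.0, seed=5)[0]
        det = detect_spikes(x, FS)
        hits = sum(np.min(np.abs(det - st)) < 0.0005 for st in times)
        assert hits >= 0.99 * times.size

    def test_refractory_collapses_nearby_crossings(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 0.1, int(FS))  # noise floor sets the MAD
        i = 12_000
        x[i] = 50.0
        x[i + int(0.0004 * FS)] = 60.0  # 0.4 ms later, larger
        det = detect_spikes(x, FS, SpikeDetectionConfig(threshold_k=10))
        big = det[det > 0.4]
        assert big.size == 1
        assert big[0] == pytest.approx((i + int(0.0004 * FS)) / FS, abs=1e-4)

    def test_raising_threshold_never_adds_spikes(self):
        rng = np.random.default_rng(6)
        x = rng.standard_t(df=3, size=int(10 * FS))  # heavy tails: some events
        n = [detect_spikes(x, FS, SpikeDetectionConfig(threshold_k=k)).size
             for k in (6.0, 8.0, 10.0, 12.0)]
        assert n == sorted(n, reverse=True)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            detect_spikes(np.ones(int(2 * FS)), FS)


class TestPETH:
    def test_single_spike_single_trial_rate(self):
        peth = compute_peth(np.array([10.1]), np.array([10.0]), pre_s=1, post_s=1, bin_s=0.25)
        centers = peth.centers
        hot = (centers > 0) & (centers < 0.25)
        assert peth.rate[hot] == pytest.approx(4.0)  # 1 spike / (1 trial * 0.25 s)
        assert peth.rate[~hot] == pytest.approx(0.0)

    def test_homogeneous_poisson_is_flat(self):
        rng = np.random.default_rng(7)
        dur, rate = 2000.0, 5.0
        spikes = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        triggers = np.arange(20, dur - 20, 15.0)
        peth = compute_peth(spikes, triggers, pre_s=5, post_s=5, bin_s=0.25)
        sd = np.sqrt(rate / (triggers.size * 0.25))
        # family-wise bound over 40 bins: P(max |z| > 4.5) ~ 3e-4 under the null
        assert np.all(np.abs(peth.rate - rate) < 4.5 * sd)
        assert peth.rate.mean() == pytest.approx(rate, rel=0.05)

    def test_silent_unit_gives_zero_peth(self):
        peth = compute_peth(np.empty(0), np.array([50.0]), pre_s=5, post_s=5)
        assert np.all(peth.rate == 0)

    def test_mass_conservation(self):
        rng = np.random.default_rng(8)
        spikes = np.sort(rng.uniform(0, 500, 2000))
        triggers = rng.uniform(10, 490, 30)
        peth = compute_peth(spikes, triggers, pre_s=5, post_s=5, bin_s=0.25)
        total = peth.rate.sum() * peth.bin_s * peth.n_trials
        expected = sum(((spikes >= trg - 5) & (spikes < trg + 5)).sum() for trg in triggers)
        assert total == pytest.approx(expected)

    def test_zero_triggers_rejected(self):
        with pytest.raises(ValueError, match="trigger"):
            compute_peth(np.array([1.0]), np.empty(0))


class TestResponsiveness:
    def test_planted_se_response_detected_positive(self, small_truth):
        unit = synth.UnitSpec("SE", baseline_hz=5.0, amp_hz=15.0)
        df = synth.synth_spike_data(small_truth, [unit], seed=9)
        peth = responsiveness_test(
            df["time_s"].to_numpy(), small_truth.se_events["onset_s"].to_numpy(),
            small_truth.duration_s, n_perm=300, seed=1, trigger_type="SE")
        assert peth.responsive
        assert peth.response_sign == 1
        assert 0.0 <= peth.response_latency_s <= 2.0

    def test_untuned_unit_rarely_flagged(self, small_truth):
        flags = []
        rng = np.random.default_rng(10)
        for k in range(20):
            df = synth.synth_spike_data(small_truth, [synth.UnitSpec("None", 5.0)],
                                        seed=100 + k)
            peth = responsiveness_test(
                df["time_s"].to_numpy(), small_truth.se_events["onset_s"].to_numpy(),
                small_truth.duration_s, n_perm=200, seed=rng, trigger_type="SE")
            flags.append(peth.responsive)
        assert sum(flags) <= 4  # false-positive control (~0.05 expected rate)

    def test_fixed_seed_reproducible(self, small_truth):
        df = synth.synth_spike_data(small_truth, [synth.UnitSpec("SE", 4.0, 10.0)], seed=11)
        args = (df["time_s"].to_numpy(), small_truth.se_events["onset_s"].to_numpy(),
                small_truth.duration_s)
        p1 = responsiveness_test(*args, n_perm=200, seed=3)
        p2 = responsiveness_test(*args, n_perm=200, seed=3)
        assert np.array_equal(p1.null_mean, p2.null_mean)
        assert p1.responsive == p2.responsive

    def test_span_too_short_rejected(self):
        with pytest.raises(ValueError, match="span"):
            responsiveness_test(np.array([1.0]), np.array([2.0]), span_s=5.0)


class TestCategories:
    @pytest.mark.parametrize(
        "se,song,expected",
        [(True, True, "Both"), (True, False, "SE-only"),
         (False, True, "Song-only"), (False, False, "None")])
    def test_category_from_flags(self, se, song, expected):
        def peth(flag):
            return PETH(trigger_type="song", edges=np.arange(5, dtype=float),
                        rate=np.zeros(4), n_trials=1, responsive=flag)
        assert categorize_unit(peth(song), peth(se)).category == expected

    def test_unfilled_flags_rejected(self):
        p = PETH(trigger_type="song", edges=np.arange(5, dtype=float),
                 rate=np.zeros(4), n_trials=1)
        with pytest.raises(ValueError, match="responsiveness"):
            categorize_unit(p, p)


def test_spike_train_validates_ordering():
    with pytest.raises(ValueError, match="increasing"):
        SpikeTrain(unit_id=0, times=np.array([1.0, 0.5]))
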