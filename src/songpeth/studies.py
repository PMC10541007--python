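"""Calibration and recovery studies on synthetic ground truth.

Each function runs a small simulation study that checks one statistical
property of the analysis chain — type-I error of the photometry permutation
test, calcium-onset recovery, spike-detection sensitivity/specificity, and
ΔPETH category calibration/power — and returns the measured quantities.
They are the package's own evidence that its nulls are calibrated and its
estimators recover planted parameters; problem sizes are arguments so the
studies can be scaled to the time available.
"""

from __future__ import annotations

import numpy as np

from . import conditioning, ephys, photometry, synth

__all__ = [
    "photometry_null_calibration",
    "onset_recovery_study",
    "spike_detection_study",
    "delta_peth_study",
    "segmentation_recovery_study",
]


def photometry_null_calibration(
    n_sessions: int = 500,
    *,
    n_perm: int = 200,
    duration_s: float = 240.0,
    fs: float = 50.0,
    n_events: int = 20,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive rate of the permutation p-value on signal-free traces.

    Each session is stationary noise with random triggers carrying no
    event-locked signal; a calibrated test rejects at ``alpha`` a fraction
    ~``alpha`` of the time.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    hits = 0
    for _ in range(n_sessions):
        raw = 1.0 + 0.02 * rng.standard_normal(n)
        trace = photometry.compute_dff(raw, fs, decimate_to=fs)
        triggers = rng.uniform(pre_s + 1, duration_s - post_s - 1, n_events)
        avg = photometry.triggered_average(trace, triggers, pre_s=pre_s, post_s=post_s)
        res = photometry.permutation_bands(trace, avg, n_perm=n_perm, seed=rng)
        hits += res.p_value < alpha
    return {"fpr": hits / n_sessions, "n_sessions": n_sessions, "alpha": alpha}


def onset_recovery_study(
    n_sims: int = 50,
    *,
    lead_s: float = 2.3,
    transient_snr: float = 10.0,
    amp: float = 0.5,
    fs: float = 100.0,
    duration_s: float = 600.0,
    n_se: int = 15,
    seed: int = 0,
) -> dict:
    """Recovery of a programmed calcium-onset lead before song initiation.

    ``transient_snr`` = transient amplitude / trace noise SD.  Returns the
    mean estimated lead (positive = before song onset) and its bias against
    the programmed value.
    """
    ss = np.random.SeedSequence(seed)
    onsets = []
    for child in ss.spawn(n_sims):
        s = int(child.generate_state(1)[0] % 2**31)
        truth = synth.synth_session_truth(
            synth.SynthSessionConfig(duration_s=duration_s, n_se=n_se, seed=s))
        raw = synth.synth_photometry(
            truth, lead_s=lead_s, amp=amp, noise_sd=amp / transient_snr,
            fs=fs, seed=s + 1)
        trace = photometry.compute_dff(raw, fs, decimate_to=fs)
        avg = photometry.triggered_average(trace, truth.song_onsets, pre_s=8.0, post_s=5.0)
        onsets.append(photometry.estimate_onset(avg, search_window=(-5.0, 2.0)))
    onsets = np.asarray(onsets)
    lead_est = -onsets  # onset is negative (before trigger); lead is positive
    return {
        "lead_s": lead_s,
        "mean_lead_est_s": float(lead_est.mean()),
        "bias_s": float(lead_est.mean() - lead_s),
        "sd_s": float(lead_est.std(ddof=1)),
        "n_sims": n_sims,
    }


def spike_detection_study(
    *,
    duration_s: float = 60.0,
    fs: float = 25_000.0,
    n_spikes: int = 100,
    spike_amp_sd: float = 12.0,
    threshold_k: float = 10.0,
    seed: int = 0,
) -> dict:
    """Sensitivity on planted templates and specificity on pure noise.

    Plants ``n_spikes`` biphasic 12-SD templates in Gaussian noise, counts
    recoveries within 0.5 ms, and separately counts detections on an equal
    span of template-free noise at the same threshold.
    """
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.1, duration_s - 0.1, n_spikes))
    # enforce separation so templates never overlap
    while np.any(np.diff(times) < 0.005):
        times = np.sort(rng.uniform(0.1, duration_s - 0.1, n_spikes))
    cfg = ephys.SpikeDetectionConfig(threshold_k=threshold_k)
    x = synth.synth_raw_voltage([times], duration_s, fs=fs, spike_amp_sd=spike_amp_sd,
                                seed=seed + 1)[0]
    det = ephys.detect_spikes(x, fs, cfg)
    hits = sum(np.min(np.abs(det - st)) < 0.0005 for st in times)
    noise = rng.normal(0.0, 1.0, int(duration_s * fs))
    false_pos = int(ephys.detect_spikes(noise, fs, cfg).size)
    return {
        "recovery_pct": 100.0 * hits / n_spikes,
        "false_positives": false_pos,
        "n_planted": n_spikes,
        "duration_s": duration_s,
    }


def delta_peth_study(
    n_units: int = 200,
    *,
    gain: float = 1.0,
    baseline_hz: float = 4.0,
    amp_hz: float = 4.0,
    n_se: int = 40,
    n_shuffle: int = 500,
    units_per_session: int = 20,
    seed: int = 0,
) -> dict:
    """Category rates of the ΔPETH shuffle test at a planted gain.

    ``gain=1`` measures calibration (how often an outcome-blind unit is
    called Agnostic); ``gain>=2`` measures power (how often a modulated unit
    is called Song-Inducing).  Units are spread over several independent SE
    schedules of ``n_se`` exposures each.
    """
    duration = n_se * synth.SE_MIN_SPACING_S + 60.0
    ccfg = conditioning.ConditioningConfig(n_shuffle=n_shuffle, max_se_per_unit=n_se)
    ss = np.random.SeedSequence(seed)
    categories: list[str] = []
    n_sessions = int(np.ceil(n_units / units_per_session))
    for child in ss.spawn(n_sessions):
        s = int(child.generate_state(1)[0] % 2**31)
        truth = synth.synth_session_truth(
            synth.SynthSessionConfig(duration_s=duration, n_se=n_se, seed=s))
        log = conditioning.label_se_outcomes(truth.se_events, truth.songs, ccfg)
        if (log.se["outcome"] == "Song-Inducing").sum() in (0, len(log.se)):
            continue  # degenerate schedule; units would be Agnostic-by-default
        k = min(units_per_session, n_units - len(categories))
        units = [synth.UnitSpec("SE", baseline_hz, amp_hz, gain=gain)] * k
        df = synth.synth_spike_data(truth, units, seed=s + 1)
        rng = np.random.default_rng(s + 2)
        for _, g in df.groupby("unit_id"):
            res = conditioning.shuffle_null(g["time_s"].to_numpy(), log, ccfg, seed=rng)
            categories.append(res.category)
        if len(categories) >= n_units:
            break
    categories = categories[:n_units]
    n = len(categories)
    return {
        "gain": gain,
        "n_units": n,
        "agnostic_rate": categories.count("Agnostic") / n,
        "song_inducing_rate": categories.count("Song-Inducing") / n,
        "quiet_rate": categories.count("Quiet") / n,
    }


def segmentation_recovery_study(
    *,
    duration_s: float = 60.0,
    n_se: int = 3,
    snr_db: float = 20.0,
    seed: int = 0,
) -> dict:
    """Syllable recall/precision of the parser against generated truth."""
    from . import segmentation

    cfg = synth.SynthSessionConfig(duration_s=duration_s, n_se=n_se, snr_db=snr_db,
                                   p_song_given_se=1.0, seed=seed)
    wave, truth = synth.synth_usv_audio(cfg)
    syls, songs = segmentation.segment_audio(wave, cfg.audio_fs)
    det = np.array([[s.start_s, s.end_s] for s in syls]) if syls else np.empty((0, 2))
    hits = 0
    for row in truth.syllables.itertuples(index=False):
        if det.size and np.abs(det - [row.start_s, row.end_s]).max(axis=1).min() <= 0.002:
            hits += 1
    n_true = len(truth.syllables)
    return {
        "recall_pct": 100.0 * hits / n_true if n_true else float("nan"),
        "precision_pct": 100.0 * hits / len(det) if len(det) else float("nan"),
        "n_true": n_true,
        "n_detected": int(len(det)),
        "n_songs_detected": len(songs),
        "n_songs_true": len(truth.songs),
    }
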