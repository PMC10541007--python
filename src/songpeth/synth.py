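"""Synthetic courtship-session generator with ground truth.

Emulates the three data modalities of a head-restrained / freely-moving mouse
courtship experiment so that every analysis stage can be validated against a
known answer:

* ultrasonic audio — frequency-modulated syllable whistles (~60-110 kHz,
  tens of ms) grouped into songs separated by long silences, on a white-noise
  floor;
* fiber-photometry fluorescence — slow indicator transients whose onsets
  *lead* song onsets by a configurable time;
* spike trains — inhomogeneous-Poisson units with baseline rate plus
  social-exposure-locked and/or song-locked rate kernels, with a
  multiplicative gain on Song-Inducing trials.

Social exposures (SEs, brief female presentations) are scheduled with a
minimum spacing so Quiet SEs and isolated songs remain constructible; each SE
produces a song with probability ``p_song_given_se`` (default 0.65, the
fraction of presentations that elicit song in this paradigm) after a latency
with mode ~1-2 s.

Everything is driven by a single :class:`numpy.random.Generator` seed:
identical (config, seed) pairs give byte-identical sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyllableParams",
    "SynthSessionConfig",
    "UnitSpec",
    "GroundTruth",
    "synth_session_truth",
    "synth_usv_audio",
    "synth_photometry",
    "synth_spike_data",
    "synth_raw_voltage",
    "SPIKE_TEMPLATE_MS",
]

#: Minimum spacing between consecutive SE onsets, seconds.  Chosen so that the
#: 5 s isolation rule and the 10 s inter-song gap are satisfiable by design.
SE_MIN_SPACING_S = 15.0
#: Session edge margin for event placement, seconds.
_EDGE_S = 10.0


@dataclass(frozen=True)
class SyllableParams:
    """Acoustic parameters of synthesized syllables.

    Carrier frequencies are drawn per syllable from a normal distribution and
    clipped into the ultrasonic band; each syllable is a single-component
    sinusoid-FM tone sweeping ``bandwidth_khz`` around its carrier, with
    cosine on/off ramps of at most 1 ms.
    """

    carrier_mean_khz: float = 75.0
    carrier_sd_khz: float = 8.0
    duration_ms: tuple[float, float] = (20.0, 60.0)
    bandwidth_khz: float = 20.0
    gap_ms: tuple[float, float] = (30.0, 80.0)


@dataclass(frozen=True)
class SynthSessionConfig:
    duration_s: float = 300.0
    audio_fs: float = 250_000.0
    n_se: int = 10
    se_duration_s: float = 8.0  # SEs never exceed 10 s in this paradigm
    p_song_given_se: float = 0.65
    #: lognormal (mu, sigma) of SE-onset -> song-onset latency; defaults give
    #: mode ~1.5 s; samples clipped to latency_clip_s.
    song_latency_lognorm: tuple[float, float] = (0.655, 0.5)
    latency_clip_s: tuple[float, float] = (0.3, 3.0)
    #: inclusive integer range of syllables per song
    syllable_count: tuple[int, int] = (4, 12)
    syllable_params: SyllableParams = field(default_factory=SyllableParams)
    snr_db: float = 20.0
    n_spontaneous_songs: int = 0
    noise_sd: float = 0.005
    song_gap_s: float = 10.0  # enforced minimum syllable-free gap between songs
    enforce_song_gap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.se_duration_s > 10.0:
            raise ValueError("se_duration_s must be <= 10 s")
        if not 0.0 <= self.p_song_given_se <= 1.0:
            raise ValueError("p_song_given_se must be in [0, 1]")
        if self.duration_s <= 0 or self.audio_fs <= 0:
            raise ValueError("duration_s and audio_fs must be positive")


@dataclass(frozen=True)
class UnitSpec:
    """Tuning of one synthetic unit.

    ``tuning`` selects which event kernels have nonzero amplitude:
    ``"SE"`` (exposure-locked), ``"Song"`` (song-locked), ``"Both"`` or
    ``"None"``.  ``gain`` multiplies the SE response on Song-Inducing trials.
    """

    tuning: str = "None"
    baseline_hz: float = 5.0
    amp_hz: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tuning not in ("SE", "Song", "Both", "None"):
            raise ValueError(f"unknown tuning {self.tuning!r}")
        if self.baseline_hz < 0 or self.amp_hz < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class GroundTruth:
    """Event-level truth tables for one synthetic session.

    ``syllables``: start_s, end_s, carrier_hz, bandwidth_hz, song_id.
    ``songs``: song_id, onset_s, offset_s, n_syllables, provenance
    (``SE-preceded`` / ``isolated``), se_id (-1 when isolated).
    ``se_events``: se_id, onset_s, offset_s, outcome
    (``Song-Inducing`` / ``Quiet``).
    """

    duration_s: float
    audio_fs: float
    syllables: pd.DataFrame
    songs: pd.DataFrame
    se_events: pd.DataFrame
    photometry_lead_s: float = float("nan")
    units: pd.DataFrame | None = None

    @property
    def song_onsets(self) -> np.ndarray:
        return self.songs["onset_s"].to_numpy()


def _place_spaced(rng, n, lo, hi, min_spacing):
    """n sorted points in [lo, hi], consecutive spacing >= min_spacing.

    Uniform over the constrained simplex (shift construction).
    """
    span = hi - lo - (n - 1) * min_spacing
    if n <= 0:
        return np.empty(0)
    if span < 0:
        raise ValueError(
            f"infeasible packing: cannot fit {n} events with spacing {min_spacing} s in {hi - lo:.1f} s"
        )
    pts = np.sort(rng.uniform(0.0, span, size=n))
    return lo + pts + np.arange(n) * min_spacing


def _build_song(rng, onset, params: SyllableParams, n_syl: int):
    """Syllable rows of one song starting at ``onset``."""
    rows = []
    t = onset
    for k in range(n_syl):
        dur = rng.uniform(*params.duration_ms) / 1000.0
        carrier = np.clip(
            rng.normal(params.carrier_mean_khz, params.carrier_sd_khz), 40.0, 110.0
        ) * 1000.0
        rows.append((t, t + dur, carrier, params.bandwidth_khz * 1000.0))
        t += dur + rng.uniform(*params.gap_ms) / 1000.0
    return rows


def _schedule_events(cfg: SynthSessionConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """SE schedule, song schedule and syllable table for one session."""
    se_onsets = _place_spaced(
        rng, cfg.n_se, _EDGE_S, cfg.duration_s - _EDGE_S - cfg.se_duration_s, SE_MIN_SPACING_S
    )
    outcomes = rng.random(cfg.n_se) < cfg.p_song_given_se if cfg.n_se else np.empty(0, bool)

    songs = []  # (onset, provenance, se_id)
    mu, sigma = cfg.song_latency_lognorm
    for i, (se_on, sings) in enumerate(zip(se_onsets, outcomes)):
        if sings:
            lat = float(np.clip(rng.lognormal(mu, sigma), *cfg.latency_clip_s))
            songs.append((se_on + lat, "SE-preceded", i))

    # Spontaneous (isolated) songs: rejection-sample onsets clear of SEs and
    # other songs.
    iso_margin = 6.0  # > the 5 s isolation rule
    for _ in range(cfg.n_spontaneous_songs):
        for _attempt in range(200):
            cand = rng.uniform(_EDGE_S, cfg.duration_s - _EDGE_S)
            clear_se = all(
                cand < on - iso_margin or cand > on + cfg.se_duration_s + iso_margin
                for on in se_onsets
            )
            clear_songs = all(abs(cand - s[0]) > cfg.song_gap_s + 5.0 for s in songs)
            if clear_se and clear_songs:
                songs.append((cand, "isolated", -1))
                break
        else:
            raise ValueError("infeasible packing: no room for a spontaneous song")

    songs.sort(key=lambda s: s[0])
    syl_rows, song_rows = [], []
    for sid, (onset, provenance, se_id) in enumerate(songs):
        n_syl = int(rng.integers(cfg.syllable_count[0], cfg.syllable_count[1] + 1))
        rows = _build_song(rng, onset, cfg.syllable_params, n_syl)
        syl_rows += [r + (sid,) for r in rows]
        song_rows.append((sid, onset, rows[-1][1], n_syl, provenance, se_id))

    songs_df = pd.DataFrame(
        song_rows, columns=["song_id", "onset_s", "offset_s", "n_syllables", "provenance", "se_id"]
    )
    if cfg.enforce_song_gap and len(songs_df) > 1:
        gaps = songs_df["onset_s"].to_numpy()[1:] - songs_df["offset_s"].to_numpy()[:-1]
        if np.any(gaps < cfg.song_gap_s):
            raise ValueError(
                "infeasible packing: generated songs violate the inter-song gap "
                f"(min gap {gaps.min():.2f} s < {cfg.song_gap_s} s)"
            )
    if len(songs_df) and songs_df["offset_s"].max() > cfg.duration_s:
        raise ValueError("infeasible packing: a song extends past the session end")

    syllables = pd.DataFrame(
        syl_rows, columns=["start_s", "end_s", "carrier_hz", "bandwidth_hz", "song_id"]
    )
    se_df = pd.DataFrame(
        {
            "se_id": np.arange(cfg.n_se, dtype=int),
            "onset_s": se_onsets,
            "offset_s": se_onsets + cfg.se_duration_s,
            "outcome": np.where(outcomes, "Song-Inducing", "Quiet"),
        }
    )
    return syllables, songs_df, se_df


def synth_session_truth(cfg: SynthSessionConfig) -> GroundTruth:
    """Event schedule (ground truth) only, without audio synthesis.

    Same schedule as :func:`synth_usv_audio` for the same (config, seed) —
    the waveform draws come after the schedule draws — at negligible cost.
    Useful when only photometry or spike modalities are needed.
    """
    rng = np.random.default_rng(cfg.seed)
    syllables, songs, se_df = _schedule_events(cfg, rng)
    return GroundTruth(
        duration_s=cfg.duration_s,
        audio_fs=cfg.audio_fs,
        syllables=syllables,
        songs=songs,
        se_events=se_df,
    )


def _fm_tone(fs, dur_s, carrier_hz, bandwidth_hz, rng):
    """Single-component sinusoid-FM whistle with <=1 ms cosine ramps."""
    n = max(int(round(dur_s * fs)), 2)
    t = np.arange(n) / fs
    # one full FM cycle over the syllable: instantaneous frequency sweeps the
    # whole bandwidth around the carrier
    inst_f = carrier_hz + 0.5 * bandwidth_hz * np.sin(2 * np.pi * t / dur_s + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    tone = np.sin(phase)
    ramp_n = min(int(0.001 * fs), n // 4)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        tone[:ramp_n] *= ramp
        tone[-ramp_n:] *= ramp[::-1]
    return tone


def synth_usv_audio(cfg: SynthSessionConfig) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one session's ultrasonic audio and its ground truth.

    The waveform is a sum of FM tone bursts (one per syllable) on white
    Gaussian noise; tone amplitude is set so the per-sample tone-to-noise
    power ratio equals ``snr_db``.  Returns ``(waveform, truth)`` with all
    syllable intervals half-open in seconds.
    """
    rng = np.random.default_rng(cfg.seed)
    syllables, songs, se_df = _schedule_events(cfg, rng)

    n_samples = int(round(cfg.duration_s * cfg.audio_fs))
    wave = rng.normal(0.0, cfg.noise_sd, size=n_samples)
    amp = cfg.noise_sd * 10 ** (cfg.snr_db / 20.0) * np.sqrt(2.0)
    for row in syllables.itertuples(index=False):
        i0 = int(round(row.start_s * cfg.audio_fs))
        tone = amp * _fm_tone(cfg.audio_fs, row.end_s - row.start_s, row.carrier_hz, row.bandwidth_hz, rng)
        wave[i0 : i0 + tone.size] += tone[: n_samples - i0]

    truth = GroundTruth(
        duration_s=cfg.duration_s,
        audio_fs=cfg.audio_fs,
        syllables=syllables,
        songs=songs,
        se_events=se_df,
    )
    return wave.astype(np.float32), truth


def _double_exp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Indicator transient (1 - e^{-t/tr}) e^{-t/td}, peak-normalized to 1."""
    k = np.where(t >= 0, (1 - np.exp(-np.maximum(t, 0) / tau_rise)) * np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
    t_peak = tau_rise * np.log1p(tau_decay / tau_rise)
    peak = (1 - np.exp(-t_peak / tau_rise)) * np.exp(-t_peak / tau_decay)
    return k / peak


def synth_photometry(
    truth: GroundTruth,
    *,
    tau_rise_s: float = 0.5,
    tau_decay_s: float = 2.0,
    lead_s: float = 2.3,
    amp: float = 0.5,
    baseline: float = 1.0,
    noise_sd: float = 0.01,
    drift_amp: float = 0.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """Raw fluorescence trace with song-locked transients.

    One double-exponential transient (rise ``tau_rise_s``, decay
    ``tau_decay_s``, amplitude ``amp`` on a positive ``baseline``) starts
    ``lead_s`` seconds *before* each song onset, emulating premotor activity
    reported by a slow calcium indicator.  Gaussian noise and an optional
    slow sinusoidal drift are added.  Onsets that would fall before t=0 are
    clipped to 0 with a warning.
    """
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("kernel taus must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(truth.duration_s * fs))
    t = np.arange(n) / fs
    trace = np.full(n, baseline) + rng.normal(0.0, noise_sd, size=n)
    if drift_amp:
        trace += drift_amp * np.sin(2 * np.pi * t / truth.duration_s)

    onsets = truth.song_onsets - lead_s
    if np.any(onsets < 0):
        warnings.warn("some transient onsets precede the recording start; clipped to 0")
        onsets = np.clip(onsets, 0.0, None)
    support = tau_rise_s * 3 + tau_decay_s * 6
    for on in onsets:
        i0 = int(round(on * fs))
        i1 = min(n, i0 + int(support * fs))
        trace[i0:i1] += amp * _double_exp_kernel(t[i0:i1] - on, tau_rise_s, tau_decay_s)

    truth.photometry_lead_s = lead_s
    return trace


def _gauss_kernel(t, center, sd):
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


#: Default event-kernel shapes: the SE response peaks ~1 s after exposure
#: onset; the song kernel is a premotor elevation peaking shortly before the
#: first syllable.
SE_KERNEL = {"center_s": 1.0, "sd_s": 0.5}
SONG_KERNEL = {"center_s": -0.5, "sd_s": 0.75}


def unit_rate_on_grid(
    truth: GroundTruth,
    unit: UnitSpec,
    dt: float = 0.001,
    se_kernel: dict = SE_KERNEL,
    song_kernel: dict = SONG_KERNEL,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of ``unit`` on a ``dt``-spaced grid.

    rate(t) = baseline + amp * g^{1[Song-Inducing]} * K_SE(t - SE onset)
    for SE-tuned units, plus amp * K_song(t - song onset) for song-tuned
    units; Gaussian kernels, peak-normalized.
    """
    n = int(round(truth.duration_s / dt))
    t = np.arange(n) * dt
    rate = np.full(n, float(unit.baseline_hz))

    def _add(center_abs, sd, amplitude):
        lo = max(0, int((center_abs - 4 * sd) / dt))
        hi = min(n, int((center_abs + 4 * sd) / dt))
        rate[lo:hi] += amplitude * _gauss_kernel(t[lo:hi], center_abs, sd)

    if unit.tuning in ("SE", "Both"):
        for row in truth.se_events.itertuples(index=False):
            g = unit.gain if row.outcome == "Song-Inducing" else 1.0
            _add(row.onset_s + se_kernel["center_s"], se_kernel["sd_s"], unit.amp_hz * g)
    if unit.tuning in ("Song", "Both"):
        for on in truth.song_onsets:
            _add(on + song_kernel["center_s"], song_kernel["sd_s"], unit.amp_hz)
    return rate


def synth_spike_data(
    truth: GroundTruth,
    units: list[UnitSpec],
    *,
    dt: float = 0.001,
    seed: int = 0,
    se_kernel: dict = SE_KERNEL,
    song_kernel: dict = SONG_KERNEL,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike tables for a list of units.

    Spike counts are drawn per ``dt`` bin (default 1 ms) from the unit's rate
    grid and jittered uniformly within the bin.  Returns a tidy frame with
    columns ``unit_id``, ``time_s``; unit metadata lands in
    ``truth.units``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    meta = []
    for uid, unit in enumerate(units):
        rate = unit_rate_on_grid(truth, unit, dt, se_kernel, song_kernel)
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(counts.size), counts)
        times = (idx + rng.random(idx.size)) * dt
        times.sort()
        frames.append(pd.DataFrame({"unit_id": uid, "time_s": times}))
        meta.append((uid, unit.tuning, unit.baseline_hz, unit.amp_hz, unit.gain))
    truth.units = pd.DataFrame(meta, columns=["unit_id", "tuning", "baseline_hz", "amp_hz", "gain"])
    if not frames:
        return pd.DataFrame({"unit_id": pd.Series(dtype=int), "time_s": pd.Series(dtype=float)})
    return pd.concat(frames, ignore_index=True)


#: Biphasic spike-template span used by :func:`synth_raw_voltage`, ms.
SPIKE_TEMPLATE_MS = 1.6


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic extracellular waveform, negative peak normalized to -1."""
    n = int(SPIKE_TEMPLATE_MS / 1000 * fs)
    t = np.arange(n) / fs * 1000.0  # ms
    w = -np.exp(-((t - 0.4) ** 2) / (2 * 0.1**2)) + 0.45 * np.exp(-((t - 0.85) ** 2) / (2 * 0.18**2))
    return w / np.abs(w.min())


def synth_raw_voltage(
    spike_times: list[np.ndarray],
    duration_s: float,
    *,
    fs: float = 25_000.0,
    spike_amp_sd: float = 12.0,
    noise_sd: float = 1.0,
    common_mode: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """channels x samples voltage matrix: one unit per channel.

    Each channel carries its unit's biphasic templates (negative peak at
    ``spike_amp_sd`` times the noise SD) plus independent Gaussian noise;
    ``common_mode`` (length n_samples), if given, is added to *every*
    channel — the target of common-median referencing.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_ch = len(spike_times)
    x = rng.normal(0.0, noise_sd, size=(n_ch, n))
    tmpl = _spike_template(fs) * spike_amp_sd * noise_sd
    for ch, times in enumerate(spike_times):
        for st in np.asarray(times, dtype=float):
            i0 = int(round(st * fs))
            seg = tmpl[: n - i0]
            if seg.size > 0 and i0 >= 0:
                x[ch, i0 : i0 + seg.size] += seg
    if common_mode is not None:
        x += np.asarray(common_mode)[None, :]
    return x
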