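"""Extracellular electrophysiology: referencing, spike detection, PETHs.

The analysis chain mirrors a high-SNR multi-channel recording workflow that
deliberately skips spike sorting: the voltage matrix is common-median
referenced to remove shared noise, spikes are taken as large robust-SD
threshold crossings on manually selected single-unit channels, and each
unit's relation to behavioral events (song initiation, social exposure) is
quantified with a peri-event time histogram whose baseline statistics come
from a random-trigger permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SpikeDetectionConfig",
    "SpikeTrain",
    "PETH",
    "UnitCategory",
    "common_median_reference",
    "detect_spikes",
    "compute_peth",
    "responsiveness_test",
    "categorize_unit",
    "binned_counts",
]

#: Gaussian consistency factor: SD = MAD / 0.6745.
_MAD_TO_SD = 0.6745


@dataclass(frozen=True)
class SpikeDetectionConfig:
    """Threshold-crossing detection parameters.

    ``threshold_k`` is the multiple of the robust SD (MAD-based) a deviation
    from the signal median must exceed; crossings within ``refractory_ms``
    collapse to the largest-amplitude sample.
    """

    threshold_k: float = 10.0
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")


@dataclass
class SpikeTrain:
    unit_id: int
    times: np.ndarray  # seconds, strictly increasing
    channel: int = -1
    region: str = "ACC"  # {"ACC", "M2"} metadata label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def mean_rate(self, duration_s: float) -> float:
        return self.times.size / duration_s


@dataclass
class PETH:
    """Trial-averaged event-locked firing rate, optionally with a null."""

    trigger_type: str  # {"song", "SE"}
    edges: np.ndarray  # bin edges, seconds relative to trigger
    rate: np.ndarray  # Hz per bin
    n_trials: int
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    responsive: bool | None = None
    response_sign: int = 0
    response_latency_s: float = float("nan")

    @property
    def bin_s(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class UnitCategory:
    se_responsive: bool
    song_responsive: bool

    @property
    def category(self) -> str:
        if self.se_responsive and self.song_responsive:
            return "Both"
        if self.se_responsive:
            return "SE-only"
        if self.song_responsive:
            return "Song-only"
        return "None"


def common_median_reference(raw: np.ndarray) -> np.ndarray:
    """Subtract the per-sample across-channel median from every channel."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 3:
        raise ValueError("need a channels x samples matrix with >= 3 channels")
    return raw - np.median(raw, axis=0, keepdims=True)


def detect_spikes(
    x: np.ndarray, fs: float, cfg: SpikeDetectionConfig | None = None
) -> np.ndarray:
    """Spike times (s) as robust threshold crossings on one channel.

    The noise SD is estimated as MAD/0.6745 around the channel median;
    samples whose absolute deviation exceeds ``threshold_k`` SDs are grouped
    into events (crossings closer than ``refractory_ms`` collapse), and each
    event is stamped at its largest-amplitude sample.
    """
    cfg = cfg or SpikeDetectionConfig()
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("need at least 1 s of signal for SD estimation")
    center = np.median(x)
    mad = np.median(np.abs(x - center))
    if mad == 0:
        raise ValueError("zero-variance signal")
    sd = mad / _MAD_TO_SD
    dev = np.abs(x - center)
    above = np.flatnonzero(dev > cfg.threshold_k * sd)
    if above.size == 0:
        return np.empty(0)
    refr = max(1, int(round(cfg.refractory_ms / 1000.0 * fs)))
    # split threshold-exceeding samples into events separated by > refractory
    breaks = np.flatnonzero(np.diff(above) > refr)
    groups = np.split(above, breaks + 1)
    peaks = np.array([g[np.argmax(dev[g])] for g in groups])
    return peaks / fs


def binned_counts(spike_times: np.ndarray, triggers: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Spike counts per (trigger, bin) via searchsorted on sorted spikes.

    ``triggers`` may be any shape; returns shape ``triggers.shape + (n_bins,)``.
    """
    triggers = np.asarray(triggers, dtype=float)
    cut = np.searchsorted(spike_times, triggers[..., None] + edges)
    return np.diff(cut, axis=-1)


def compute_peth(
    spikes: SpikeTrain | np.ndarray,
    triggers: np.ndarray,
    *,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    bin_s: float = 0.25,
    trigger_type: str = "song",
) -> PETH:
    """PETH: rate(bin) = total spikes in bin across trials / (n_trials * bin_s)."""
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, dtype=float)
    triggers = np.atleast_1d(np.asarray(triggers, dtype=float))
    if triggers.size == 0:
        raise ValueError("need at least one trigger")
    n_bins = int(round((pre_s + post_s) / bin_s))
    edges = -pre_s + np.arange(n_bins + 1) * bin_s
    counts = binned_counts(np.sort(times), triggers, edges).sum(axis=0)
    return PETH(
        trigger_type=trigger_type,
        edges=edges,
        rate=counts / (triggers.size * bin_s),
        n_trials=int(triggers.size),
    )


def _consecutive_deviation(dev_ok: np.ndarray, min_run: int) -> int:
    """Index of the first bin starting a run of >= min_run True values, else -1."""
    run = 0
    for i, ok in enumerate(dev_ok):
        run = run + 1 if ok else 0
        if run >= min_run:
            return i - min_run + 1
    return -1


def responsiveness_test(
    spikes: SpikeTrain | np.ndarray,
    triggers: np.ndarray,
    span_s: float,
    *,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    bin_s: float = 0.25,
    response_window: tuple[float, float] = (-2.5, 2.5),
    n_perm: int = 1000,
    n_sd: float = 2.0,
    min_consecutive: int = 2,
    seed: int | np.random.Generator = 0,
    trigger_type: str = "song",
) -> PETH:
    """PETH with a random-trigger permutation null and responsiveness flag.

    The null rebuilds the PETH on ``n_perm`` sets of uniformly random trigger
    times (same count, over the valid span).  A unit is *responsive* when at
    least ``min_consecutive`` consecutive bins inside ``response_window``
    deviate by ``n_sd`` or more null-SDs from the null mean; the response
    sign is the sign of the first such deviation and the latency is the left
    edge of its first bin.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if span_s <= pre_s + post_s:
        raise ValueError("recording span too short for the PETH window")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peth = compute_peth(
        spikes, triggers, pre_s=pre_s, post_s=post_s, bin_s=bin_s, trigger_type=trigger_type
    )
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.sort(np.asarray(spikes, float))
    times = np.sort(times)
    rand_triggers = rng.uniform(pre_s, span_s - post_s, size=(n_perm, peth.n_trials))
    null_counts = binned_counts(times, rand_triggers, peth.edges).sum(axis=1)
    null_rates = null_counts / (peth.n_trials * bin_s)
    null_mean = null_rates.mean(axis=0)
    null_sd = null_rates.std(axis=0, ddof=0)

    centers = peth.centers
    in_win = (centers >= response_window[0]) & (centers < response_window[1])
    sd_safe = np.where(null_sd > 0, null_sd, np.inf)
    z = (peth.rate - null_mean) / sd_safe
    dev = np.abs(z) >= n_sd
    # a run must stay on one side of the null to count as one response
    first = -1
    for sign in (1, -1):
        cand = _consecutive_deviation(dev & in_win & (np.sign(z) == sign), min_consecutive)
        if cand >= 0 and (first < 0 or cand < first):
            first, found_sign = cand, sign
    responsive = first >= 0
    return replace(
        peth,
        null_mean=null_mean,
        null_sd=null_sd,
        responsive=responsive,
        response_sign=int(found_sign) if responsive else 0,
        response_latency_s=float(peth.edges[first]) if responsive else float("nan"),
    )


def categorize_unit(song_peth: PETH, se_peth: PETH) -> UnitCategory:
    """Combine song- and SE-responsiveness flags into the 2x2 category."""
    if song_peth.responsive is None or se_peth.responsive is None:
        raise ValueError("both PETHs must have responsiveness filled")
    return UnitCategory(se_responsive=bool(se_peth.responsive), song_responsive=bool(song_peth.responsive))
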