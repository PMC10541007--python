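"""Fiber-photometry ΔF/F and event-triggered analysis.

Implements the event-locked analysis used to relate a population calcium
signal to song production:

* ΔF/F against a whole-session 10th-percentile baseline F0;
* the song-onset-triggered average of ΔF/F;
* a permutation null built from uniformly random trigger times, summarized
  per time point (mean, SD) and as a single max-statistic p-value;
* calcium onset estimation by fitting a line through the 10-90% rising phase
  of the triggered average and extrapolating to its zero crossing.

Raw photodiode traces are typically grossly oversampled (tens of kHz) for
hardware reasons; :func:`compute_dff` decimates to ~1 kHz with an
anti-aliasing filter before anything else, since indicator dynamics live far
below that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "PhotometryTrace",
    "TriggeredAverage",
    "compute_dff",
    "triggered_average",
    "permutation_bands",
    "estimate_onset",
]

_F0_PERCENTILE = 10.0
_TARGET_FS = 1000.0


@dataclass
class PhotometryTrace:
    """A session's fluorescence signal.

    ``dff = (f - f0) / f0`` with ``f0`` the 10th percentile of the (decimated)
    session trace.
    """

    f: np.ndarray
    fs: float
    f0: float
    dff: np.ndarray

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def duration_s(self) -> float:
        return self.f.size / self.fs


@dataclass
class TriggeredAverage:
    """Event-locked mean of ΔF/F with (optional) permutation statistics."""

    time: np.ndarray  # seconds relative to trigger, [-pre_s, +post_s)
    mean: np.ndarray
    n_events: int
    n_dropped: int = 0
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    p_value: float = float("nan")
    onset_s: float = float("nan")

    @property
    def fs(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


def _decimation_factors(fs: float, target: float) -> list[int]:
    """Greedy chain of integer decimation factors (each <= 10) from fs to ~target."""
    factors = []
    current = fs
    while current / target >= 2:
        q = min(10, int(current / target))
        if q < 2:
            break
        factors.append(q)
        current /= q
    return factors


def compute_dff(raw: np.ndarray, fs: float, *, decimate_to: float = _TARGET_FS,
                detrend: bool = False) -> PhotometryTrace:
    """ΔF/F of a raw fluorescence trace.

    The trace is anti-alias decimated to about ``decimate_to`` Hz, optionally
    linearly detrended (off by default), and F0 is taken as the 10th
    percentile of the whole decimated session.  Raises on negative samples or
    a non-positive baseline.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("fluorescence trace must be positive-valued")
    f = raw
    out_fs = fs
    for q in _decimation_factors(fs, decimate_to):
        f = signal.decimate(f, q, ftype="fir", zero_phase=True)
        out_fs /= q
    if detrend:
        # remove a linear drift but keep the DC level so F0 stays meaningful
        f = signal.detrend(f) + float(np.mean(f))
    f0 = float(np.percentile(f, _F0_PERCENTILE))
    if f0 <= 0:
        raise ValueError(f"baseline f0 = {f0:.4g} is not positive")
    return PhotometryTrace(f=f, fs=out_fs, f0=f0, dff=(f - f0) / f0)


def _window_samples(fs: float, pre_s: float, post_s: float) -> tuple[int, int]:
    return int(round(pre_s * fs)), int(round(post_s * fs))


def _gather_means(dff: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    """Mean segment for each row of start indices: (n_sets, length).

    Accumulates event by event so peak memory stays at one
    (n_sets, length) buffer regardless of event count.
    """
    offsets = np.arange(length)
    acc = np.zeros((starts.shape[0], length))
    for i in range(starts.shape[1]):
        acc += dff[starts[:, i, None] + offsets]
    return acc / starts.shape[1]


def triggered_average(
    trace: PhotometryTrace, triggers: np.ndarray, pre_s: float = 5.0, post_s: float = 5.0
) -> TriggeredAverage:
    """Mean ΔF/F in windows [-pre_s, +post_s) around each trigger.

    Triggers whose window would clip the recording edge are dropped and
    counted in ``n_dropped``.  Raises if no trigger is usable.
    """
    triggers = np.asarray(triggers, dtype=float)
    n_pre, n_post = _window_samples(trace.fs, pre_s, post_s)
    length = n_pre + n_post
    starts = np.round(triggers * trace.fs).astype(int) - n_pre
    ok = (starts >= 0) & (starts + length <= trace.dff.size)
    n_dropped = int((~ok).sum())
    starts = starts[ok]
    if starts.size == 0:
        raise ValueError("no trigger has a full window inside the recording")
    mean = _gather_means(trace.dff, starts[None, :], length)[0]
    time = (np.arange(length) - n_pre) / trace.fs
    return TriggeredAverage(time=time, mean=mean, n_events=int(starts.size), n_dropped=n_dropped)


def permutation_bands(
    trace: PhotometryTrace,
    observed: TriggeredAverage,
    *,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TriggeredAverage:
    """Random-trigger permutation null for a triggered average.

    Each of ``n_perm`` draws places ``n_events`` triggers uniformly over the
    valid span and recomputes the triggered mean; ``null_mean``/``null_sd``
    are the per-timepoint moments across draws.  The p-value compares the
    *peak* of the observed mean with the peaks of the null means:
    ``p = (1 + #{peak_null >= peak_obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = observed.time.size
    n_valid = trace.dff.size - length
    if n_valid <= 0:
        raise ValueError("recording too short to place trigger windows")
    starts = rng.integers(0, n_valid + 1, size=(n_perm, observed.n_events))
    null_traces = _gather_means(trace.dff, starts, length)
    null_peaks = null_traces.max(axis=1)
    p = (1.0 + np.sum(null_peaks >= observed.mean.max())) / (n_perm + 1.0)
    return TriggeredAverage(
        time=observed.time,
        mean=observed.mean,
        n_events=observed.n_events,
        n_dropped=observed.n_dropped,
        null_mean=null_traces.mean(axis=0),
        null_sd=null_traces.std(axis=0, ddof=0),
        p_value=float(p),
        onset_s=observed.onset_s,
    )


def estimate_onset(
    avg: TriggeredAverage,
    search_window: tuple[float, float] | None = None,
    *,
    baseline_frac: float = 0.2,
    smooth_s: float = 0.15,
) -> float:
    """Signal onset from the 10-90% rising phase of a triggered average.

    The average is baseline-subtracted (mean of the earliest
    ``baseline_frac`` of the window), the peak located inside
    ``search_window``, the rise walked back from the peak to the last sample
    below 10% of peak, and a least-squares line through the contiguous
    rising samples with amplitude in [10%, 90%] of peak is extrapolated to
    its zero crossing.  Returns the crossing time in seconds relative to the
    trigger (negative = before the trigger).

    A centered moving average of width ``smooth_s`` is applied first: it
    leaves locally linear segments (the rising phase) unchanged while
    keeping noise from corrupting the 10%/90% anchors.
    """
    t, y = avg.time, avg.mean.astype(float)
    win = int(round(smooth_s * avg.fs))
    if win > 1:
        kernel = np.ones(win) / win
        y = np.convolve(y, kernel, mode="same")
    n_base = max(1, int(baseline_frac * y.size))
    y = y - y[:n_base].mean()
    if search_window is None:
        lo_i, hi_i = 0, y.size
    else:
        lo_i = int(np.searchsorted(t, search_window[0]))
        hi_i = int(np.searchsorted(t, search_window[1]))
    if hi_i - lo_i < 3:
        raise ValueError("search window too narrow")
    seg = y[lo_i:hi_i]
    peak_rel = int(np.argmax(seg))
    peak = seg[peak_rel]
    if peak <= 0:
        raise ValueError("no positive peak in the search window")
    peak_i = lo_i + peak_rel
    below = np.flatnonzero(y[:peak_i] < 0.1 * peak)
    rise_start = below[-1] + 1 if below.size else 0
    rise = slice(rise_start, peak_i + 1)
    in_band = (y[rise] >= 0.1 * peak) & (y[rise] <= 0.9 * peak)
    tt, yy = t[rise][in_band], y[rise][in_band]
    if tt.size < 3:
        raise ValueError("rise too fast to fit")
    slope, intercept = np.polyfit(tt, yy, 1)
    if slope <= 0:
        raise ValueError("rising phase has non-positive slope")
    return float(-intercept / slope)
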