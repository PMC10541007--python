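"""Song-Inducing vs Quiet social-exposure conditioning of unit activity.

A social exposure (SE) is a brief female presentation.  Some SEs are followed
by a song, some are not; splitting each unit's SE-triggered PETH by that
outcome isolates vocal-production-related modulation from the sensory/social
response to the exposure itself.  The per-unit contrast is

    ΔPETH = mean response-window rate (Song-Inducing SEs)
          - mean response-window rate (Quiet SEs)

tested against a label-shuffle null that permutes the Song-Inducing/Quiet
assignment over the same SEs (class counts preserved).  At the population
level, per-unit ΔPETHs standardized by their own null SD are compared to the
pooled standardized null as a CDF shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import PETH, SpikeTrain, binned_counts, compute_peth

__all__ = [
    "ConditioningConfig",
    "SELog",
    "DeltaPethResult",
    "UnitExcluded",
    "label_se_outcomes",
    "split_peth",
    "delta_peth",
    "shuffle_null",
    "population_cdf_shift",
]


@dataclass(frozen=True)
class ConditioningConfig:
    """Parameters of the outcome-conditioned analysis.

    ``follow_window_s`` extends past the SE offset: an SE counts as
    Song-Inducing when a song starts between its onset and offset +
    follow_window_s.  ``max_se_per_unit`` caps each unit at its first N SEs
    (session order); ``response_window`` is the post-SE interval over which
    the PETH is scalarized to a rate.
    """

    follow_window_s: float = 5.0
    isolation_s: float = 5.0
    min_rate_hz: float = 1.0
    max_se_per_unit: int = 40
    response_window: tuple[float, float] = (0.0, 2.0)
    pre_s: float = 5.0
    post_s: float = 5.0
    bin_s: float = 0.25
    n_shuffle: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.follow_window_s <= 0:
            raise ValueError("follow_window_s must be positive")
        if self.n_shuffle < 100:
            raise ValueError("n_shuffle must be >= 100")


@dataclass
class SELog:
    """Outcome-labeled SEs and provenance-labeled songs.

    ``se``: se_id, onset_s, offset_s, outcome ∈ {Song-Inducing, Quiet}.
    ``songs``: song_id, onset_s, provenance ∈ {SE-preceded, isolated}, se_id.
    """

    se: pd.DataFrame
    songs: pd.DataFrame

    @property
    def pct_song_inducing(self) -> float:
        return 100.0 * (self.se["outcome"] == "Song-Inducing").mean()

    @property
    def pct_isolated_songs(self) -> float:
        return 100.0 * (self.songs["provenance"] == "isolated").mean()


@dataclass
class DeltaPethResult:
    unit_id: int
    delta_hz: float
    null: np.ndarray  # shuffle null of delta, Hz
    quantile: float  # fraction of null strictly below observed
    category: str  # {"Song-Inducing", "Quiet", "Agnostic"}
    degenerate: bool = False  # one outcome class empty -> Agnostic by default
    n_si: int = 0
    n_quiet: int = 0


class UnitExcluded(Exception):
    """Raised when a unit fails the inclusion criteria for the SE analysis."""


def label_se_outcomes(
    se_events: pd.DataFrame, songs: pd.DataFrame, cfg: ConditioningConfig | None = None
) -> SELog:
    """Label each SE by vocal outcome and each song by provenance.

    An SE is Song-Inducing iff at least one song onset falls in
    ``[onset, offset + follow_window_s]``; otherwise Quiet.  A song is
    ``isolated`` iff its onset is at least ``isolation_s`` after every
    earlier SE offset and not inside any SE; otherwise it is assigned to the
    nearest preceding qualifying SE.
    """
    cfg = cfg or ConditioningConfig()
    se = se_events.sort_values("onset_s").reset_index(drop=True).copy()
    on = se["onset_s"].to_numpy(float)
    off = se["offset_s"].to_numpy(float)
    if np.any(off[:-1] > on[1:]):
        raise ValueError("overlapping SE intervals")
    song_onsets = np.asarray(songs["onset_s"], dtype=float)

    se_ids = se["se_id"].to_numpy(int) if "se_id" in se else np.arange(len(se))

    outcome = np.full(len(se), "Quiet", dtype=object)
    provenance = np.full(song_onsets.size, "isolated", dtype=object)
    song_se = np.full(song_onsets.size, -1, dtype=int)
    for j, s in enumerate(song_onsets):
        # SEs qualifying to claim this song: onset inside [SE on, SE off + window]
        qual = np.flatnonzero((on <= s) & (s <= off + cfg.follow_window_s))
        if qual.size:
            i = int(qual[-1])  # nearest preceding qualifying SE
            outcome[i] = "Song-Inducing"
            song_se[j] = int(se_ids[i])
        # a song is isolated iff it starts outside every SE and >= isolation_s
        # after every earlier SE offset
        inside = np.any((on <= s) & (s < off))
        recent = np.any((s >= off) & (s - off < cfg.isolation_s))
        if inside or recent:
            provenance[j] = "SE-preceded"

    se["outcome"] = outcome
    songs_out = songs.copy().reset_index(drop=True)
    songs_out["provenance"] = provenance
    songs_out["se_id"] = song_se
    return SELog(se=se, songs=songs_out)


def _capped_se(se_log: SELog, cfg: ConditioningConfig) -> pd.DataFrame:
    return se_log.se.sort_values("onset_s").head(cfg.max_se_per_unit)


def split_peth(
    spikes: SpikeTrain | np.ndarray,
    se_log: SELog,
    cfg: ConditioningConfig | None = None,
) -> tuple[PETH, PETH]:
    """SE-onset-triggered PETHs from the Song-Inducing and Quiet SE subsets.

    The unit must fire at >= ``min_rate_hz`` on average during SE epochs;
    SEs are capped at the first ``max_se_per_unit`` in session order before
    splitting.  Raises :class:`UnitExcluded` with the reason otherwise.
    """
    cfg = cfg or ConditioningConfig()
    times = np.sort(spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float))
    se = _capped_se(se_log, cfg)
    on = se["onset_s"].to_numpy(float)
    off = se["offset_s"].to_numpy(float)
    total_dur = float(np.sum(off - on))
    n_in = int(np.sum(np.searchsorted(times, off) - np.searchsorted(times, on)))
    if total_dur <= 0 or n_in / total_dur < cfg.min_rate_hz:
        raise UnitExcluded(
            f"firing rate during SE = {n_in / max(total_dur, 1e-12):.2f} Hz < {cfg.min_rate_hz} Hz floor"
        )
    out = []
    for label in ("Song-Inducing", "Quiet"):
        trig = on[(se["outcome"] == label).to_numpy()]
        if trig.size == 0:
            raise UnitExcluded(f"no {label} SE available after capping")
        out.append(
            compute_peth(times, trig, pre_s=cfg.pre_s, post_s=cfg.post_s, bin_s=cfg.bin_s,
                         trigger_type="SE")
        )
    return out[0], out[1]


def delta_peth(peth_si: PETH, peth_q: PETH, cfg: ConditioningConfig | None = None) -> float:
    """Response-window mean rate difference, Song-Inducing minus Quiet (Hz)."""
    cfg = cfg or ConditioningConfig()
    if peth_si.edges.size != peth_q.edges.size or not np.allclose(peth_si.edges, peth_q.edges):
        raise ValueError("PETHs must share bin edges")
    lo, hi = cfg.response_window
    if lo < peth_si.edges[0] or hi > peth_si.edges[-1]:
        raise ValueError("response window outside PETH span")
    centers = peth_si.centers
    sel = (centers >= lo) & (centers < hi)
    return float(peth_si.rate[sel].mean() - peth_q.rate[sel].mean())


def shuffle_null(
    spikes: SpikeTrain | np.ndarray,
    se_log: SELog,
    cfg: ConditioningConfig | None = None,
    *,
    seed: int | np.random.Generator | None = None,
) -> DeltaPethResult:
    """ΔPETH with a label-shuffle null and outcome category for one unit.

    ``n_shuffle`` random relabelings of the (capped) SE outcomes, preserving
    class counts, give the null distribution of ΔPETH.  The unit is
    Song-Inducing when the observed delta exceeds the upper ``alpha/2`` null
    quantile, Quiet when below the lower, Agnostic otherwise.  If one outcome
    class is empty the unit is Agnostic-by-default with ``degenerate=True``.
    """
    cfg = cfg or ConditioningConfig()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    unit_id = spikes.unit_id if isinstance(spikes, SpikeTrain) else -1
    times = np.sort(spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float))
    se = _capped_se(se_log, cfg)
    on = se["onset_s"].to_numpy(float)
    is_si = (se["outcome"] == "Song-Inducing").to_numpy()
    n_si, n_q = int(is_si.sum()), int((~is_si).sum())
    if n_si == 0 or n_q == 0:
        return DeltaPethResult(
            unit_id=unit_id, delta_hz=float("nan"), null=np.empty(0), quantile=float("nan"),
            category="Agnostic", degenerate=True, n_si=n_si, n_quiet=n_q,
        )

    # per-SE response-window rate; every shuffle is then a re-partition of
    # this fixed vector, so the null costs O(n_shuffle * n_se)
    lo, hi = cfg.response_window
    per_se_rate = binned_counts(times, on, np.array([lo, hi]))[:, 0] / (hi - lo)

    def _delta(mask_si: np.ndarray) -> float:
        return float(per_se_rate[mask_si].mean() - per_se_rate[~mask_si].mean())

    observed = _delta(is_si)
    null = np.empty(cfg.n_shuffle)
    for k in range(cfg.n_shuffle):
        null[k] = _delta(rng.permutation(is_si))

    lo_q, hi_q = np.quantile(null, [cfg.alpha / 2, 1 - cfg.alpha / 2])
    if observed > hi_q:
        category = "Song-Inducing"
    elif observed < lo_q:
        category = "Quiet"
    else:
        category = "Agnostic"
    return DeltaPethResult(
        unit_id=unit_id,
        delta_hz=observed,
        null=null,
        quantile=float(np.mean(null < observed)),
        category=category,
        n_si=n_si,
        n_quiet=n_q,
    )


def population_cdf_shift(results: list[DeltaPethResult], *,
                         seed: int | np.random.Generator = 0) -> dict:
    """Population summary of standardized ΔPETHs against the pooled null.

    Each unit's observed delta is standardized by its own null SD; the
    summary reports the empirical CDF of standardized deltas, the pooled
    standardized null CDF, their signed mean difference, and a one-sided
    label-shuffle p for the mean shift (fraction of shuffle indices whose
    across-unit mean standardized null delta reaches the observed mean).
    """
    usable = [r for r in results if not r.degenerate and r.null.size and r.null.std() > 0]
    if len(usable) < 2:
        raise ValueError("need >= 2 non-degenerate units")
    sds = np.array([r.null.std(ddof=0) for r in usable])
    z_obs = np.array([r.delta_hz for r in usable]) / sds
    z_null = np.stack([r.null for r in usable]) / sds[:, None]  # units x shuffles
    mean_shift = float(z_obs.mean() - z_null.mean())
    null_means = z_null.mean(axis=0)
    p_shift = float((1 + np.sum(null_means >= z_obs.mean())) / (null_means.size + 1))
    categories = pd.Series([r.category for r in results]).value_counts().to_dict()
    return {
        "n_units": len(usable),
        "z_observed": np.sort(z_obs),
        "z_null_pooled": np.sort(z_null.ravel()),
        "mean_shift": mean_shift,
        "p_shift": p_shift,
        "categories": categories,
    }
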