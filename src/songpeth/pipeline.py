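"""End-to-end session orchestration and cross-condition feature statistics.

``run_session`` drives synth -> segmentation -> photometry -> ephys ->
SE-conditioning on a synthetic session described by one YAML config, writing
plain CSV/JSON artifacts plus a provenance log (config hash and seed for
every derived file).  ``compare_feature_sets`` is the paired per-animal
syllable-feature test used to compare vocalizations across conditions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import conditioning, ephys, io, photometry, segmentation, synth

__all__ = ["SessionBundle", "run_session", "compare_feature_sets"]

log = logging.getLogger("songpeth")

FEATURES = ("duration_ms", "mean_freq_khz", "bandwidth_khz")


@dataclass
class SessionBundle:
    out_dir: Path
    config: dict
    seed: int
    files: dict[str, Path] = field(default_factory=dict)
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _synth_config(cfg: dict, seed: int) -> synth.SynthSessionConfig:
    section = dict(cfg.get("synth", {}))
    section.pop("seed", None)  # the run-level seed wins
    syl = section.pop("syllable_params", None)
    if syl:
        section["syllable_params"] = synth.SyllableParams(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in syl.items()}
        )
    section = {k: tuple(v) if isinstance(v, list) else v for k, v in section.items()}
    return synth.SynthSessionConfig(seed=seed, **section)


def run_session(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> SessionBundle:
    """Run every applicable stage of the pipeline on one synthetic session.

    Stages whose modality is disabled in the config are skipped.  All output
    files are listed in ``bundle.files``; stage-level tallies (syllables
    found, units excluded, ...) land in ``bundle.counts`` and the log.
    """
    cfg = io.load_config(config) if not isinstance(config, dict) else config
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = SessionBundle(out_dir=out, config=cfg, seed=seed)
    rng_children = np.random.SeedSequence(seed).spawn(4)

    # --- synth ---------------------------------------------------------
    scfg = _synth_config(cfg, seed)
    wave, truth = synth.synth_usv_audio(scfg)
    io.write_wav(out / "session.wav", wave, scfg.audio_fs)
    truth.syllables.to_csv(out / "truth_syllables.csv", index=False)
    truth.songs.to_csv(out / "songs.csv", index=False)
    truth.se_events.to_csv(out / "se_events.csv", index=False)
    bundle.files.update({k: out / f for k, f in [
        ("audio", "session.wav"), ("songs", "songs.csv"), ("se_events", "se_events.csv")]})
    bundle.counts["n_songs_truth"] = len(truth.songs)
    log.info("synth: %d songs, %d syllables, %d SEs", len(truth.songs),
             len(truth.syllables), len(truth.se_events))

    # --- segmentation --------------------------------------------------
    if cfg.get("segment", {}).get("enabled", True):
        seg_cfg = segmentation.SegmentationConfig(**{
            k: v for k, v in cfg.get("segment", {}).items() if k != "enabled"})
        syllables, songs = segmentation.segment_audio(wave, scfg.audio_fs, seg_cfg)
        segmentation.syllables_to_frame(syllables).to_csv(out / "syllables.csv", index=False)
        segmentation.songs_to_frame(songs).to_csv(out / "songs_detected.csv", index=False)
        bundle.files["syllables"] = out / "syllables.csv"
        bundle.counts["n_syllables_detected"] = len(syllables)
        bundle.counts["n_songs_detected"] = len(songs)
        log.info("segment: %d syllables in %d songs", len(syllables), len(songs))

    # --- photometry ----------------------------------------------------
    pcfg = cfg.get("photometry", {})
    if pcfg.get("enabled", True) and len(truth.songs):
        fs = float(pcfg.get("fs", 1000.0))
        raw = synth.synth_photometry(
            truth, lead_s=float(pcfg.get("lead_s", 2.3)),
            noise_sd=float(pcfg.get("noise_sd", 0.01)), fs=fs,
            seed=int(rng_children[0].generate_state(1)[0] % 2**31),
        )
        trace = photometry.compute_dff(raw, fs)
        avg = photometry.triggered_average(trace, truth.song_onsets,
                                           pre_s=float(pcfg.get("pre_s", 8.0)),
                                           post_s=float(pcfg.get("post_s", 5.0)))
        avg = photometry.permutation_bands(
            trace, avg, n_perm=int(pcfg.get("n_perm", 1000)),
            seed=np.random.default_rng(rng_children[1].generate_state(1)[0] % 2**31))
        try:
            onset = photometry.estimate_onset(avg, search_window=(-5.0, 2.0))
        except ValueError as err:
            log.warning("photometry onset not estimable: %s", err)
            onset = float("nan")
        pd.DataFrame({"t": avg.time, "mean": avg.mean, "null_mean": avg.null_mean,
                      "null_sd": avg.null_sd}).to_csv(out / "triggered_average.csv", index=False)
        summary = {"p_value": avg.p_value, "onset_s": onset, "n_events": avg.n_events}
        (out / "photometry_summary.json").write_text(json.dumps(summary, indent=2))
        bundle.files["triggered_average"] = out / "triggered_average.csv"
        bundle.counts["photometry_p"] = avg.p_value
        log.info("photometry: p=%.4f onset=%.2f s over %d songs", avg.p_value, onset, avg.n_events)

    # --- ephys + conditioning ------------------------------------------
    ecfg = cfg.get("ephys", {})
    if ecfg.get("enabled", True) and len(truth.se_events):
        units = [synth.UnitSpec(**u) for u in ecfg.get(
            "units", [{"tuning": "SE", "baseline_hz": 5.0, "amp_hz": 8.0, "gain": 2.0},
                      {"tuning": "Song", "baseline_hz": 5.0, "amp_hz": 8.0},
                      {"tuning": "None", "baseline_hz": 5.0}])]
        spikes_df = synth.synth_spike_data(
            truth, units, seed=int(rng_children[2].generate_state(1)[0] % 2**31))
        spikes_df.to_csv(out / "spikes.csv", index=False)
        bundle.files["spikes"] = out / "spikes.csv"
        trains = io.spike_trains_from_table(spikes_df)
        n_perm = int(ecfg.get("n_perm", 500))
        rng = np.random.default_rng(rng_children[3].generate_state(1)[0] % 2**31)

        ccfg = conditioning.ConditioningConfig(**cfg.get("condition", {}))
        se_log = conditioning.label_se_outcomes(truth.se_events, truth.songs, ccfg)
        se_log.se.to_csv(out / "se_log.csv", index=False)

        rows, delta_rows = [], []
        results = []
        for uid, times in trains.items():
            song_peth = ephys.responsiveness_test(
                times, truth.song_onsets, truth.duration_s, n_perm=n_perm, seed=rng,
                trigger_type="song") if len(truth.songs) else None
            se_peth = ephys.responsiveness_test(
                times, truth.se_events["onset_s"].to_numpy(), truth.duration_s,
                n_perm=n_perm, seed=rng, trigger_type="SE")
            cat = ephys.categorize_unit(song_peth, se_peth) if song_peth else None
            rows.append({"unit_id": uid, "region": "ACC",
                         "se_responsive": bool(se_peth.responsive),
                         "song_responsive": bool(song_peth.responsive) if song_peth else False,
                         "category": cat.category if cat else "n/a"})
            try:
                res = conditioning.shuffle_null(times, se_log, ccfg, seed=rng)
                results.append(res)
                delta_rows.append({
                    "unit_id": uid, "delta_hz": res.delta_hz,
                    "null_lo": float(np.quantile(res.null, ccfg.alpha / 2)) if res.null.size else float("nan"),
                    "null_hi": float(np.quantile(res.null, 1 - ccfg.alpha / 2)) if res.null.size else float("nan"),
                    "category": res.category})
            except conditioning.UnitExcluded as err:
                log.info("unit %d excluded from conditioning: %s", uid, err)
                bundle.counts["n_units_excluded"] = bundle.counts.get("n_units_excluded", 0) + 1
        pd.DataFrame(rows).to_csv(out / "units_summary.csv", index=False)
        pd.DataFrame(delta_rows).to_csv(out / "delta_peth.csv", index=False)
        bundle.files["units_summary"] = out / "units_summary.csv"
        bundle.files["delta_peth"] = out / "delta_peth.csv"
        if len([r for r in results if not r.degenerate]) >= 2:
            pop = conditioning.population_cdf_shift(results)
            (out / "population_summary.json").write_text(json.dumps(
                {k: v for k, v in pop.items() if not isinstance(v, np.ndarray)}, indent=2))
        bundle.counts["n_units"] = len(trains)
        log.info("ephys: %d units analysed", len(trains))

    provenance = {"config_hash": bundle.config_hash, "seed": seed,
                  "files": {k: str(v.name) for k, v in bundle.files.items()},
                  "counts": bundle.counts}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return bundle


def compare_feature_sets(features_a: pd.DataFrame, features_b: pd.DataFrame) -> pd.DataFrame:
    """Paired two-sided t test per syllable feature across animals.

    Inputs are per-animal mean feature tables (index = animal, columns =
    duration_ms, mean_freq_khz, bandwidth_khz) for two conditions.  Rows with
    zero-variance differences are flagged ``degenerate`` rather than given a
    p-value, since the paired t statistic is undefined there.
    """
    if not features_a.index.equals(features_b.index):
        raise ValueError("mismatched animal sets between conditions")
    if len(features_a) < 2:
        raise ValueError("need >= 2 animals for a paired test")
    rows = []
    for feat in FEATURES:
        d = features_a[feat].to_numpy(float) - features_b[feat].to_numpy(float)
        if np.all(d == 0):
            # identical conditions: no evidence of any difference
            rows.append({"feature": feat, "t": 0.0, "p": 1.0, "mean_diff": 0.0,
                         "degenerate": False})
            continue
        if np.allclose(d, d[0]):
            rows.append({"feature": feat, "t": float("nan"), "p": float("nan"),
                         "mean_diff": float(d.mean()), "degenerate": True})
            continue
        t, p = stats.ttest_rel(features_a[feat], features_b[feat])
        rows.append({"feature": feat, "t": float(t), "p": float(p),
                     "mean_diff": float(d.mean()), "degenerate": False})
    return pd.DataFrame(rows)
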