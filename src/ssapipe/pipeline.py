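"""End-to-end orchestration: simulate -> quantify -> statistics report.

A "recording" is one simulated imaging session: for each repetition rate, a
set of interleaved light-off/light-on trials sharing one ground-truth
amplitude law.  Quantification runs the preprocessing, ROI and amplitude
stages per rate and emits a long-format amplitude table plus one summary row
per rate.  The statistics stage consumes summaries from a cohort of
recordings and reproduces the comparison structure of the study: one-sample
tests of adaptation / deviance / light-modulation against their nulls,
paired tests across rates, a light x tone RM-ANOVA per rate, and Holm
correction within each family.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .exceptions import DataError, InsufficientDataError
from .metrics import summarize_recording
from .preprocess import (
    ResponseMap,
    butterworth_filter_frames,
    compute_dff,
    localization_map,
)
from .quantify import (
    TrialAmplitudes,
    average_across_trials,
    train_amplitudes,
)
from .roi import (
    A1,
    assign_field_labels,
    detect_responsive_regions,
    extract_trace,
    motion_exclusion,
)
from .stats import gated_one_sample_test, gated_paired_test, holm_bonferroni_adjust, rm_anova_gg
from .stimulus import STANDARD, make_train, tone_windows
from .synth import LIGHT_OFF, LIGHT_ON, generate_experiment

logger = logging.getLogger(__name__)

#: fixed float precision for byte-identical CSV re-runs
FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate_experiment(config: PipelineConfig, outdir) -> Path:
    """Render a full interleaved experiment to ``outdir`` (TIFFs + manifest)."""
    records = build_experiment_records(config)
    manifest_path = _io.write_experiment(records, outdir)
    logger.info(
        "simulated %d trials (config %s) -> %s",
        len(records),
        config.config_hash(),
        manifest_path,
    )
    return manifest_path


def build_experiment_records(config: PipelineConfig, seed: int | None = None):
    """In-memory experiment for one recording (no disk I/O)."""
    params = config.synth.to_params(config.seed if seed is None else seed)
    st = config.stimulus
    return generate_experiment(
        params,
        rates=st.rates_hz,
        n_trials_per_condition=config.synth.n_trials_per_condition,
        n_standards=st.n_standards,
        std_freq_hz=st.std_freq_hz,
        dev_freq_hz=st.dev_freq_hz,
        tone_dur_s=st.tone_dur_s,
    )


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------


def quantify_records(records, config: PipelineConfig, recording_id: str = "rec0"):
    """Quantify one in-memory recording.

    Returns ``(amplitudes_df, summary_df, exclusions_df, per_tone_df)``.
    ``per_tone_df`` holds the trial-averaged standard-tone amplitudes per
    condition, the input to the light x tone RM-ANOVA.
    """
    pp, rc, qc = config.preprocess, config.roi, config.quantify
    amp_rows, summary_rows, excl_rows, per_tone_rows = [], [], [], []
    rates = sorted({r.rate_hz for r in records})
    for rate in rates:
        trial_recs = [r for r in records if r.rate_hz == rate]
        train = make_train(
            rate,
            config.stimulus.n_standards,
            config.stimulus.std_freq_hz,
            config.stimulus.dev_freq_hz,
            config.stimulus.tone_dur_s,
            config.stimulus.ramp_s,
        )
        windows = tone_windows(train, config.stimulus.last_window_s)

        dffs, excluded = {}, {}
        for rec in trial_recs:
            if rc.motion_check:
                report = motion_exclusion(
                    rec.movie, rc.motion_threshold_px, rc.motion_search_px
                )
                excluded[rec.trial_id] = report.excluded
                excl_rows.append(
                    {
                        "recording_id": recording_id,
                        "trial_id": rec.trial_id,
                        "rate_hz": rate,
                        "condition": rec.condition,
                        "motion_score_px": report.score,
                        "excluded": report.excluded,
                    }
                )
                if report.excluded:
                    logger.info("trial %s excluded (motion %.1f px)", rec.trial_id, report.score)
                    continue
            else:
                excluded[rec.trial_id] = False
            dffs[rec.trial_id] = compute_dff(rec.movie, 0.0, pp.baseline_s)

        off_ids = [
            r.trial_id
            for r in trial_recs
            if r.condition == LIGHT_OFF and not excluded.get(r.trial_id, True)
        ]
        if not off_ids:
            raise InsufficientDataError(
                f"all light-off trials at {rate:g} Hz were excluded"
            )

        mask = _roi_mask(dffs, off_ids, train, config)

        traces = {tid: extract_trace(dffs[tid], mask, A1) for tid in dffs}
        per_trial = {}
        for rec in trial_recs:
            if rec.trial_id not in traces:
                continue
            per_trial[rec.trial_id] = train_amplitudes(
                traces[rec.trial_id],
                train,
                windows,
                condition=rec.condition,
                trial_id=rec.trial_id,
                mode=qc.amplitude_mode,
            )

        averages = {}
        for condition in (LIGHT_OFF, LIGHT_ON):
            ids = [
                r.trial_id
                for r in trial_recs
                if r.condition == condition and r.trial_id in traces
            ]
            if not ids:
                continue
            if qc.average_order == "traces_first":
                mean_values = np.mean([traces[t].values for t in ids], axis=0)
                mean_trace = dataclasses.replace(traces[ids[0]], values=mean_values)
                avg = train_amplitudes(
                    mean_trace, train, windows, condition=condition, mode=qc.amplitude_mode
                )
                avg = dataclasses.replace(avg, n_trials=len(ids))
            else:
                avg = average_across_trials(
                    [per_trial[t] for t in ids], condition, rate
                )
            averages[condition] = avg

        off_avg = averages[LIGHT_OFF]
        on_avg = averages.get(LIGHT_ON)
        summary = summarize_recording(
            off_avg, on_avg, modulation_method=qc.modulation_method
        )
        summary_rows.append(
            {
                "recording_id": recording_id,
                "rate_hz": rate,
                "adaptation_diff": summary.adaptation_diff,
                "deviance_diff": summary.deviance_diff,
                "opto_modulation": summary.opto_modulation,
                "tau_hat": summary.tau_hat,
                "n_trials_used": summary.n_trials_used,
            }
        )

        c1 = off_avg.amps[0]
        for tid, ta in per_trial.items():
            for i, (amp, label) in enumerate(zip(ta.amps, ta.labels)):
                amp_rows.append(
                    {
                        "recording_id": recording_id,
                        "trial_id": tid,
                        "rate_hz": rate,
                        "condition": ta.condition,
                        "tone_index": i + 1,
                        "label": label,
                        "amplitude": amp,
                        "norm_to_first_control": amp / c1,
                        "norm_to_matched_control": amp / off_avg.amps[i],
                    }
                )
        for condition, avg in averages.items():
            for i, (amp, label) in enumerate(zip(avg.amps, avg.labels)):
                if label != STANDARD:
                    continue
                per_tone_rows.append(
                    {
                        "recording_id": recording_id,
                        "rate_hz": rate,
                        "condition": condition,
                        "tone_index": i + 1,
                        "value": amp / c1,
                    }
                )

    return (
        pd.DataFrame(amp_rows),
        pd.DataFrame(summary_rows),
        pd.DataFrame(excl_rows),
        pd.DataFrame(per_tone_rows),
    )


def _roi_mask(dffs, off_ids, train, config: PipelineConfig):
    """A1 mask from the light-off localization map (or a user mask file)."""
    pp, rc = config.preprocess, config.roi
    if rc.mask_path is not None:
        return _io.read_mask_tiff(rc.mask_path)
    sound_end = float(train.onsets_s[0] + train.tone_dur_s)
    maps = []
    for tid in off_ids:
        dff = dffs[tid]
        loc = localization_map(dff, sound_end, pp.locmap_frames)
        k, n = loc.frames_used
        filtered = butterworth_filter_frames(
            dff.frames[k : k + n], pp.butter_cutoff, pp.butter_order
        )
        maps.append(filtered.mean(axis=0))
    mean_map = ResponseMap(np.mean(maps, axis=0), (0, pp.locmap_frames))
    regions = detect_responsive_regions(mean_map, rc.threshold_frac)
    labeled = assign_field_labels(regions, rc.anterior_axis)
    return labeled.by_label(A1).mask


def quantify_experiment(expdir, config: PipelineConfig, outdir=None, recording_id="rec0"):
    """Load a simulated experiment from disk and quantify it."""
    expdir = Path(expdir)
    manifest = _io.read_manifest(expdir)
    truths = _io.read_ground_truth(expdir)
    records = []
    for _, row in manifest.iterrows():
        movie = _io.load_trial_movie(expdir, row)
        from .synth import TrialRecord

        records.append(
            TrialRecord(
                row["trial_id"],
                float(row["rate_hz"]),
                row["condition"],
                int(row["seed"]),
                float(row["inter_trial_gap_s"]),
                movie,
                truths[row["trial_id"]],
            )
        )
    amps, summary, excl, per_tone = quantify_records(records, config, recording_id)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        amps.to_csv(outdir / "amplitudes.csv", index=False, float_format=FLOAT_FMT)
        summary.to_csv(outdir / "summary.csv", index=False, float_format=FLOAT_FMT)
        excl.to_csv(outdir / "exclusions.csv", index=False, float_format=FLOAT_FMT)
        per_tone.to_csv(outdir / "per_tone.csv", index=False, float_format=FLOAT_FMT)
    return amps, summary, excl, per_tone


# ---------------------------------------------------------------------------
# cohort simulation (multiple recordings with biological variability)
# ---------------------------------------------------------------------------


def run_cohort(
    config: PipelineConfig,
    n_recordings: int,
    vary_recordings: bool = True,
    recording_cv_a1: float = 0.2,
    recording_sd_gain: float = 0.08,
    recording_cv_tau: float = 0.15,
):
    """Simulate and quantify a cohort of recordings (in memory).

    Each recording gets a derived seed and, when ``vary_recordings`` is on,
    lognormal jitter on its response amplitude and adaptation constant and
    additive Gaussian jitter on the light-on gain, emulating animal-to-animal
    variability.  Returns ``(summary_df, per_tone_df)`` pooled over
    recordings.
    """
    rng = np.random.default_rng(config.seed)
    rec_seeds = rng.integers(0, 2**31 - 1, size=n_recordings)
    summaries, per_tones = [], []
    for i, rec_seed in enumerate(rec_seeds):
        rec_cfg = PipelineConfig.from_dict(config.to_dict())
        rec_cfg.seed = int(rec_seed)
        if vary_recordings:
            s = rec_cfg.synth
            s.a1 = float(s.a1 * rng.lognormal(0.0, recording_cv_a1))
            s.a_inf = float(s.a1 * (config.synth.a_inf / config.synth.a1))
            s.tau_tones = {
                k: float(v * rng.lognormal(0.0, recording_cv_tau))
                for k, v in s.tau_tones.items()
            }
            s.opto_gain = {
                k: float(max(0.05, v + rng.normal(0.0, recording_sd_gain)))
                for k, v in s.opto_gain.items()
            }
        records = build_experiment_records(rec_cfg, seed=int(rec_seed))
        _, summary, _, per_tone = quantify_records(
            records, rec_cfg, recording_id=f"rec{i:02d}"
        )
        summaries.append(summary)
        per_tones.append(per_tone)
    return pd.concat(summaries, ignore_index=True), pd.concat(per_tones, ignore_index=True)


# ---------------------------------------------------------------------------
# statistics report
# ---------------------------------------------------------------------------

#: metric column -> null value the one-sample family tests against
ONE_SAMPLE_FAMILIES = {
    "adaptation_diff": 0.0,
    "deviance_diff": 0.0,
    "opto_modulation": 1.0,
}


def run_stats(summary_df: pd.DataFrame, config: PipelineConfig, per_tone_df=None) -> dict:
    """Statistics report over a cohort of per-recording summaries.

    For each index (adaptation, deviance, light modulation): gated one-sample
    tests per rate against the index's null, Holm-corrected within the
    three-rate family, plus gated paired tests for every rate pair,
    Holm-corrected within their own family.  When a per-tone table is given,
    a light x tone RM-ANOVA with GG correction is run per rate.
    """
    sc = config.stats
    rates = sorted(summary_df["rate_hz"].unique())
    comparisons = []

    for metric, null in ONE_SAMPLE_FAMILIES.items():
        if metric not in summary_df or summary_df[metric].isna().all():
            continue
        family = f"{metric}_vs_null"
        results = []
        for rate in rates:
            x = summary_df.loc[summary_df["rate_hz"] == rate, metric].dropna().to_numpy()
            if x.size < 4:
                raise InsufficientDataError(
                    f"{metric} at {rate:g} Hz has n={x.size} < 4 recordings"
                )
            res = gated_one_sample_test(
                x, null, sc.gate_alpha, sc.lilliefors_mc, seed=config.seed
            )
            results.append((f"{rate:g} Hz vs {null:g}", rate, res))
        _append_family(comparisons, family, results, sc.alpha)

        results = []
        for r1, r2 in itertools.combinations(rates, 2):
            a = summary_df.loc[summary_df["rate_hz"] == r1, ["recording_id", metric]]
            b = summary_df.loc[summary_df["rate_hz"] == r2, ["recording_id", metric]]
            merged = a.merge(b, on="recording_id", suffixes=("_1", "_2")).dropna()
            if len(merged) < 4:
                continue
            res = gated_paired_test(
                merged[f"{metric}_1"].to_numpy(),
                merged[f"{metric}_2"].to_numpy(),
                sc.gate_alpha,
                sc.lilliefors_mc,
                seed=config.seed,
            )
            results.append((f"{r1:g} Hz vs {r2:g} Hz", (r1, r2), res))
        if results:
            _append_family(comparisons, f"{metric}_across_rates", results, sc.alpha)

    anova = {}
    if per_tone_df is not None and len(per_tone_df):
        for rate in rates:
            table = _per_tone_cube(per_tone_df, rate)
            if table is None:
                continue
            res = rm_anova_gg(table, factor_names=("light", "tone"))
            anova[f"{rate:g}"] = res.summary().to_dict(orient="records")

    return {"comparisons": comparisons, "rm_anova": anova}


def _append_family(comparisons, family, results, alpha):
    adj = holm_bonferroni_adjust([r.p_value for _, _, r in results], alpha)
    for (name, rate, res), p_adj, reject in zip(results, adj.adjusted, adj.reject):
        comparisons.append(
            {
                "family": family,
                "comparison": name,
                "rate_hz": rate,
                "test_used": res.test_used,
                "n": res.n,
                "statistic": res.statistic,
                "p_raw": res.p_value,
                "p_holm": float(p_adj),
                "significant": bool(reject),
                "lilliefors_p": res.lilliefors_p,
            }
        )


def _per_tone_cube(per_tone_df: pd.DataFrame, rate: float):
    """(subjects, light 2, tone k) array of normalized standard amplitudes."""
    sub = per_tone_df[per_tone_df["rate_hz"] == rate]
    if sub.empty or sub["condition"].nunique() < 2:
        return None
    pivot = sub.pivot_table(
        index="recording_id", columns=["condition", "tone_index"], values="value"
    )
    if pivot.isna().any().any() or len(pivot) < 3:
        return None
    conditions = [LIGHT_OFF, LIGHT_ON]
    tones = sorted({t for _, t in pivot.columns})
    cube = np.stack(
        [
            np.stack([pivot[(c, t)].to_numpy() for t in tones], axis=1)
            for c in conditions
        ],
        axis=1,
    )
    return cube


def write_stats_report(report: dict, out_json, out_csv=None) -> None:
    Path(out_json).write_text(json.dumps(report, indent=1, default=_jsonable))
    if out_csv is not None:
        pd.DataFrame(report["comparisons"]).to_csv(
            out_csv, index=False, float_format=FLOAT_FMT
        )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
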