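"""End-to-end orchestration: pupil cleaning -> binning -> behaviour ->
plasticity -> pupil regression -> gating, with structured outputs.

The pipeline is a pure function of (inputs, config): rerunning with the same
inputs and seed yields byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import behavior as bh
from . import evoked as ev
from . import regression as rg
from .config import AnalysisConfig
from .core import Session, bin_and_align
from .io import read_session
from .pupil import per_trial_fraction_change, remove_blinks

logger = logging.getLogger("vnspupil")


class StageError(RuntimeError):
    """An analysis stage failed; the message is tagged with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("pupil_preproc")
def _clean_pupil(session: Session, config: AnalysisConfig):
    return remove_blinks(session.pupil, sd_threshold=config.blink_sd, excision_s=config.excision_s)


@_stage("behavior_learning")
def _behavior(session: Session, config: AnalysisConfig):
    responses = bh.score_trials(session.trials, session.licks, window=config.response_window)
    blocks = bh.block_delta_r(responses, block_size=config.block_size)
    if len(blocks) == 0:
        return responses, blocks, pd.DataFrame(), pd.DataFrame()
    diff = bh.label_difficulty(session.trials)
    cond_diff = session.trials.assign(difficulty=diff).groupby("block_id")["difficulty"].first()
    blocks = blocks.assign(difficulty=blocks["block_id"].map(cond_diff))
    summary, contrasts = bh.condition_summary(blocks, alpha=config.alpha)
    return responses, blocks, summary, contrasts


@_stage("evoked_plasticity")
def _plasticity(session: Session, clean_pupil, config: AnalysisConfig, tone_label: str = "BF"):
    """Raw and pupil-corrected pre-vs-post comparisons for every included unit."""
    raw_results, corrected_results, gating_rows = [], [], []
    excluded = []
    cond = session.trials.loc[session.trials["vns_condition"] != "none", "vns_condition"]
    condition = f"bf_{cond.iloc[0]}" if len(cond) else "bf_paired"

    vns_trials = session.trials[np.isfinite(session.trials["vns_onset"].to_numpy(dtype=float))]
    dilation = np.nan
    if len(vns_trials):
        vals = per_trial_fraction_change(clean_pupil, vns_trials, baseline_s=0.8)
        dilation = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan

    for uid in sorted(session.units):
        unit = session.units[uid]
        binned = {
            phase: bin_and_align(
                session.trials, unit, clean_pupil,
                bin_width=config.bin_width, pupil_lag=config.pupil_lag_s,
                window=config.analysis_window, phase=phase, labels=(tone_label,),
            )
            for phase in ("pre", "post")
        }
        eps = {
            phase: ev.epoch_responses(b, session.trials, tone_label, epochs=_epoch_cfg(config))
            for phase, b in binned.items()
        }
        if not ev.has_sustained_response(list(eps.values()), min_rate=config.min_sustained_rate):
            excluded.append(uid)
            logger.info("pipeline: unit %s excluded (no sustained response above %.1f spk/s)", uid, config.min_sustained_rate)
            continue
        raw = ev.compare_pre_post(eps["pre"], eps["post"], alpha=config.alpha, condition=condition)
        raw_results.append(raw)

        fit_pre, fit_post = rg.fit_pupil_model(
            [binned["pre"], binned["post"]], folds=config.cv_folds, seed=config.seed
        )
        corr = rg.persistent_change(
            fit_pre, fit_post, epochs=_epoch_cfg(config), alpha=config.alpha, condition=condition
        )
        corrected_results.append(corr)
        gating_rows.append(
            {
                "unit_id": uid,
                "evoked_dilation": dilation,
                "persist_magnitude": abs(corr.diff),
                "significant": corr.significant,
            }
        )
    return raw_results, corrected_results, pd.DataFrame(gating_rows), excluded


def _epoch_cfg(config: AnalysisConfig) -> dict:
    return {k: tuple(v) for k, v in config.epochs.items()}


def run_pipeline(config: AnalysisConfig, input_dir: str, output_dir: str, tone_label: str = "BF") -> dict:
    """Run every stage on a session directory and write the report bundle.

    Outputs in ``output_dir``: ``pupil_clean.csv`` + ``blink_report.json``,
    ``responses.csv``/``blocks.csv``/``learning_summary.csv`` (when licks are
    present), ``plasticity_raw.csv``, ``plasticity_corrected.csv``,
    ``gating.csv`` and ``report.json``. Returns the report dict.
    """
    config.validate()
    os.makedirs(output_dir, exist_ok=True)
    log_path = os.path.join(output_dir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        session = read_session(input_dir)
        clean_pupil, blink_report = _clean_pupil(session, config)
        pd.DataFrame(
            {
                "timestamp": clean_pupil.timestamps,
                "diameter": clean_pupil.diameter,
                "blink": clean_pupil.blink_mask.astype(int),
            }
        ).to_csv(os.path.join(output_dir, "pupil_clean.csv"), index=False, float_format="%.9g")
        with open(os.path.join(output_dir, "blink_report.json"), "w") as fh:
            json.dump(blink_report.to_dict(), fh, indent=2)

        report: dict = {"n_trials": int(len(session.trials)), "n_units": len(session.units)}

        if session.licks.lick_times.size:
            responses, blocks, summary, contrasts = _behavior(session, config)
            responses.to_csv(os.path.join(output_dir, "responses.csv"), index=False)
            blocks.to_csv(os.path.join(output_dir, "blocks.csv"), index=False)
            summary.to_csv(os.path.join(output_dir, "learning_summary.csv"), index=False)
            contrasts.to_csv(os.path.join(output_dir, "learning_contrasts.csv"), index=False)
            report["behavior"] = {
                "n_blocks": int(len(blocks)),
                "mean_delta_r": float(np.nanmean(blocks["delta_r"])) if len(blocks) else None,
            }

        has_phases = {"pre", "post"} <= set(session.trials["session_phase"])
        if session.units and has_phases:
            raw, corrected, gating, excluded = _plasticity(session, clean_pupil, config, tone_label)
            ev.results_frame(raw).to_csv(os.path.join(output_dir, "plasticity_raw.csv"), index=False)
            ev.results_frame(corrected).to_csv(os.path.join(output_dir, "plasticity_corrected.csv"), index=False)
            gating.to_csv(os.path.join(output_dir, "gating.csv"), index=False)
            report["plasticity_raw"] = ev.population_summary(raw)
            report["plasticity_corrected"] = ev.population_summary(corrected)
            report["excluded_units"] = excluded
            if len(gating) >= 3 and gating["evoked_dilation"].std() > 0 and gating["persist_magnitude"].std() > 0:
                r, p, n = rg.gating_correlation(gating)
                report["gating"] = {"pearson_r": r, "p": p, "n": n}

        with open(os.path.join(output_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
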