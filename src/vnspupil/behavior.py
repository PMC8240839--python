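"""Classical-conditioning lick analysis: trial scoring, blockwise ΔR, summaries.

A trial counts as "responded" when at least one lick falls in the half-open
response window [sound_onset + 0.2 s, sound_offset + 0.15 s) — for a 1-s tone
this is the 0.95-s anticipatory window between tone onset and reward delivery.
Learning is quantified per block of consecutive T1/T2 trials as

    ΔR = R_T1 - R_T2,

the response probability to the rewarded tone minus that to the unrewarded
tone. ΔR > 0 indicates a learned reward preference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import LickEvents

logger = logging.getLogger("vnspupil")

RESPONSE_WINDOW = (0.2, 0.15)  # offsets from sound onset / sound offset

#: Trial-table columns copied through to scored responses when present.
_META_COLS = ["animal", "day", "vns_condition", "block_id", "session_phase", "t1_freq_hz", "t2_freq_hz"]


def score_trials(trials: pd.DataFrame, licks: LickEvents, window: tuple[float, float] = RESPONSE_WINDOW) -> pd.DataFrame:
    """Score each trial's anticipatory lick response.

    Returns a frame with ``trial_id``, ``sound_label``, ``responded`` plus any
    session metadata columns present in ``trials``. Empty lick streams score
    every trial False.
    """
    lt = licks.lick_times
    lo = trials["sound_onset"].to_numpy(dtype=float) + window[0]
    hi = trials["sound_offset"].to_numpy(dtype=float) + window[1]
    n_in = np.searchsorted(lt, hi, side="left") - np.searchsorted(lt, lo, side="left")
    out = trials[["trial_id", "sound_label"]].copy()
    out["responded"] = n_in > 0
    for c in _META_COLS:
        if c in trials.columns:
            out[c] = trials[c].to_numpy()
    return out


def label_difficulty(trials: pd.DataFrame) -> pd.Series:
    """Derive switch / no-switch difficulty per 2-d condition from tone frequencies.

    A condition (identified by ``block_id``) is a "switch" when the relative
    frequency order of T1 vs T2 reversed compared with the previous condition,
    and "no_switch" otherwise (including the first condition, which has no
    predecessor). Requires the optional ``t1_freq_hz``/``t2_freq_hz`` columns;
    without them every trial is labelled "unknown".
    """
    if "t1_freq_hz" not in trials.columns or "t2_freq_hz" not in trials.columns:
        return pd.Series(["unknown"] * len(trials), index=trials.index, name="difficulty")
    order = {}
    prev = None
    for cond_id in trials.sort_values("trial_id")["block_id"].drop_duplicates():
        row = trials[trials["block_id"] == cond_id].iloc[0]
        t1_high = bool(row["t1_freq_hz"] > row["t2_freq_hz"])
        order[cond_id] = "no_switch" if prev is None or t1_high == prev else "switch"
        prev = t1_high
    return trials["block_id"].map(order).rename("difficulty")


def block_delta_r(responses: pd.DataFrame, block_size: int = 20, min_partial: int = 3) -> pd.DataFrame:
    """Blockwise response probabilities and ΔR over consecutive T1/T2 trials.

    T1/T2 trials (reference/distractor trials are ignored) are chunked, in
    presentation order, into consecutive blocks of ``block_size`` trials within
    each (animal, condition, day) group. The final partial block is kept only if
    it contains at least ``min_partial`` trials of each type. A full block
    lacking one type yields NaN ΔR and is flagged.
    """
    tt = responses[responses["sound_label"].isin(["T1", "T2"])].copy()
    group_cols = [c for c in ["animal", "block_id", "day", "vns_condition"] if c in tt.columns]
    if not group_cols:
        tt["_g"] = 0
        group_cols = ["_g"]
    rows = []
    for key, grp in tt.groupby(group_cols, sort=True):
        grp = grp.sort_values("trial_id")
        n = len(grp)
        for bi, start in enumerate(range(0, n, block_size)):
            blk = grp.iloc[start : start + block_size]
            is_t1 = blk["sound_label"].to_numpy() == "T1"
            n1, n2 = int(is_t1.sum()), int((~is_t1).sum())
            if len(blk) < block_size:
                if n1 < min_partial or n2 < min_partial:
                    logger.info("block_delta_r: dropped partial block %s/%d (%d T1, %d T2)", key, bi, n1, n2)
                    continue
            r1 = float(blk["responded"].to_numpy()[is_t1].mean()) if n1 else np.nan
            r2 = float(blk["responded"].to_numpy()[~is_t1].mean()) if n2 else np.nan
            rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            rec.update(
                block_index=bi,
                r_t1=r1,
                r_t2=r2,
                delta_r=r1 - r2,
                n_t1=n1,
                n_t2=n2,
                flagged=not (n1 and n2),
            )
            rows.append(rec)
    cols = group_cols + ["block_index", "r_t1", "r_t2", "delta_r", "n_t1", "n_t2", "flagged"]
    out = pd.DataFrame(rows, columns=cols)
    return out.drop(columns=[c for c in ["_g"] if c in out.columns])


def cumulative_response_curve(
    trials: pd.DataFrame,
    licks: LickEvents,
    labels: tuple[str, ...] = ("T1", "T2", "REF"),
    t_max: float = 1.15,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Probability of having licked at least once within t of sound onset, per label.

    Returns a tidy frame with columns ``time``, one column per requested label.
    Curves are non-decreasing and bounded by [0, 1].
    """
    tgrid = np.arange(0.0, t_max + dt / 2, dt)
    out = {"time": tgrid}
    lt = licks.lick_times
    for lab in labels:
        sel = trials[trials["sound_label"] == lab]
        if len(sel) == 0:
            raise ValueError(f"no trials with label {lab}")
        onsets = sel["sound_onset"].to_numpy(dtype=float)
        if lt.size == 0:
            lat = np.full(onsets.shape, np.inf)
        else:
            # first lick latency after onset (inf if none before onset + t_max)
            nxt = np.searchsorted(lt, onsets, side="left")
            lat = np.where(nxt < lt.size, lt[np.minimum(nxt, lt.size - 1)] - onsets, np.inf)
            lat = np.where(lat <= t_max, lat, np.inf)
        out[lab] = (lat[None, :] <= tgrid[:, None]).mean(axis=1)
    return pd.DataFrame(out)


def delta_r_density(blocks: pd.DataFrame, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of blockwise ΔR values (integrates to 1)."""
    vals = blocks["delta_r"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if grid is None:
        grid = np.linspace(-1.2, 1.2, 481)
    kde = stats.gaussian_kde(vals)
    return grid, kde(grid)


def condition_summary(blocks: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize blockwise ΔR by animal x day x VNS condition x difficulty.

    Returns ``(summary, contrasts)``:

    * ``summary`` — one row per cell with n, mean ΔR, SEM and a classical
      two-sided one-sample t test of mean ΔR against 0. Cells with fewer than
      two blocks are omitted with a warning (no SEM is defined there).
    * ``contrasts`` — two-sample t tests of paired vs unpaired ΔR for each
      (day, difficulty) cell with data on both sides, plus per-day pooled rows.
    """
    b = blocks.copy()
    if "difficulty" not in b.columns:
        b["difficulty"] = "unknown"
    group_cols = [c for c in ["animal", "day", "vns_condition", "difficulty"] if c in b.columns]
    rows = []
    for key, grp in b.groupby(group_cols, sort=True):
        vals = grp["delta_r"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            logger.warning("condition_summary: cell %s has <2 blocks and was omitted", key)
            continue
        if vals.std(ddof=1) == 0:  # degenerate cell: no spread
            t, p = (0.0, 1.0) if vals.mean() == 0 else (np.inf * np.sign(vals.mean()), 0.0)
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows.append(
            dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            | {
                "n_blocks": int(vals.size),
                "mean_delta_r": float(vals.mean()),
                "sem_delta_r": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "t_vs_zero": float(t),
                "p_vs_zero": float(p),
                "significant": bool(p < alpha),
            }
        )
    summary = pd.DataFrame(rows)

    contrasts = []
    if "vns_condition" in b.columns:
        def _contrast(day, difficulty, sub):
            a = sub.loc[sub["vns_condition"] == "paired", "delta_r"].dropna().to_numpy()
            u = sub.loc[sub["vns_condition"] == "unpaired", "delta_r"].dropna().to_numpy()
            if a.size >= 2 and u.size >= 2:
                t, p = stats.ttest_ind(a, u)
                contrasts.append(
                    {
                        "day": day,
                        "difficulty": difficulty,
                        "n_paired": int(a.size),
                        "n_unpaired": int(u.size),
                        "mean_paired": float(a.mean()),
                        "mean_unpaired": float(u.mean()),
                        "t_paired_vs_unpaired": float(t),
                        "p_paired_vs_unpaired": float(p),
                    }
                )

        days = sorted(b["day"].dropna().unique()) if "day" in b.columns else [None]
        for day in days:
            sub_day = b if day is None else b[b["day"] == day]
            _contrast(day, "all", sub_day)
            for diff in sorted(sub_day["difficulty"].unique()):
                _contrast(day, diff, sub_day[sub_day["difficulty"] == diff])
    return summary, pd.DataFrame(contrasts)
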