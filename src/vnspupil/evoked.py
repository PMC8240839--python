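"""PSTH computation, epoch quantification, and pre/post plasticity testing.

The PSTH is the trial-averaged firing rate aligned to tone onset. Evoked
activity is obtained by subtracting the mean spontaneous rate during the 0.5 s
of silence preceding onset. The response is quantified in three
spontaneous-subtracted epochs — onset (0-60 ms), sustained (60-1000 ms) and
offset (0-100 ms after tone offset) — and changes in the sustained epoch are
the primary plasticity endpoint: per-unit pre-vs-post differences are assessed
with a two-sided Wilcoxon rank-sum (Mann-Whitney) test on per-trial sustained
responses, and the population direction among significant units with a
Wilcoxon sign-rank test on unit mean differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinnedUnitSession, ValidationError

logger = logging.getLogger("vnspupil")

#: Default epoch windows, seconds relative to tone onset (offset epoch is
#: relative to tone offset).
DEFAULT_EPOCHS = {
    "spont": (-0.5, 0.0),
    "onset": (0.0, 0.06),
    "sustained": (0.06, 1.0),
    "offset_post": (0.0, 0.1),
}


@dataclass
class PSTH:
    """Trial-averaged response aligned to tone onset."""

    time_rel_onset: np.ndarray
    mean_rate: np.ndarray  # spikes/s
    evoked_rate: np.ndarray  # spontaneous-subtracted, spikes/s
    spont_rate: float
    n_trials: int


@dataclass
class EpochResponse:
    """Per-trial epoch means for one unit/phase; onset/sustained/offset are
    spontaneous-subtracted per trial."""

    unit_id: str
    phase: str
    spont: np.ndarray  # per-trial spontaneous rate, spikes/s
    onset: np.ndarray
    sustained: np.ndarray
    offset: np.ndarray
    epochs: dict

    @property
    def n_trials(self) -> int:
        return int(self.spont.size)

    def mean(self, epoch: str) -> float:
        return float(getattr(self, epoch).mean())


@dataclass
class PlasticityResult:
    """Pre-vs-post comparison of the sustained response of one unit."""

    unit_id: str
    condition: str
    pre_sustained: float
    post_sustained: float
    diff: float  # post - pre, spikes/s
    p_unit: float
    significant: bool
    n_pre: int
    n_post: int
    corrected: bool = False  # True when computed on pupil-corrected residuals


def _select_rows(session: BinnedUnitSession, trials: pd.DataFrame, tone_label: str | None) -> np.ndarray:
    if tone_label is None:
        return np.arange(session.n_trials)
    labels = trials["sound_label"].to_numpy()[session.trial_index]
    rows = np.flatnonzero(labels == tone_label)
    if rows.size == 0:
        raise ValidationError(f"no trials with label {tone_label} in binned session")
    return rows


def _epoch_bins(session: BinnedUnitSession, lo: float, hi: float) -> np.ndarray:
    """Bins of the half-open epoch [lo, hi), edges snapped to the bin grid."""
    w = session.bin_width
    lo_s = session.window[0] + round((lo - session.window[0]) / w) * w
    hi_s = session.window[0] + round((hi - session.window[0]) / w) * w
    if abs(lo_s - lo) > 1e-9 or abs(hi_s - hi) > 1e-9:
        logger.info("epoch edge [%g, %g) snapped to [%g, %g)", lo, hi, lo_s, hi_s)
    if lo_s < session.window[0] - 1e-9 or hi_s > session.window[1] + 1e-9:
        raise ValidationError(f"epoch [{lo}, {hi}) outside binned window {session.window}")
    m = (session.time > lo_s) & (session.time < hi_s)
    if not m.any():
        raise ValidationError(f"epoch [{lo}, {hi}) contains no bins")
    return np.flatnonzero(m)


def compute_psth(session: BinnedUnitSession, trials: pd.DataFrame, tone_label: str | None = None) -> PSTH:
    """PSTH of one unit for trials of ``tone_label`` (all trials when None)."""
    rows = _select_rows(session, trials, tone_label)
    mean_rate = session.rate[rows].mean(axis=0)
    spont_bins = _epoch_bins(session, *DEFAULT_EPOCHS["spont"])
    spont = float(mean_rate[spont_bins].mean())
    return PSTH(
        time_rel_onset=session.time.copy(),
        mean_rate=mean_rate,
        evoked_rate=mean_rate - spont,
        spont_rate=spont,
        n_trials=rows.size,
    )


def epoch_responses(
    session: BinnedUnitSession,
    trials: pd.DataFrame,
    tone_label: str | None = None,
    epochs: dict | None = None,
    tone_dur: float | None = None,
) -> EpochResponse:
    """Per-trial epoch means (spontaneous subtracted per trial).

    ``epochs`` follows :data:`DEFAULT_EPOCHS`; the offset epoch is interpreted
    relative to tone offset, with the tone duration taken from the trial table
    (median offset - onset) unless given.
    """
    ep = dict(DEFAULT_EPOCHS, **(epochs or {}))
    rows = _select_rows(session, trials, tone_label)
    if tone_dur is None:
        sel = trials.iloc[session.trial_index[rows]]
        tone_dur = float(np.median(sel["sound_offset"].to_numpy() - sel["sound_onset"].to_numpy()))
    rate = session.rate[rows]
    spont = rate[:, _epoch_bins(session, *ep["spont"])].mean(axis=1)
    onset = rate[:, _epoch_bins(session, *ep["onset"])].mean(axis=1) - spont
    sustained = rate[:, _epoch_bins(session, *ep["sustained"])].mean(axis=1) - spont
    off_lo, off_hi = ep["offset_post"]
    offset = rate[:, _epoch_bins(session, tone_dur + off_lo, tone_dur + off_hi)].mean(axis=1) - spont
    return EpochResponse(
        unit_id=session.unit_id,
        phase=session.phase,
        spont=spont,
        onset=onset,
        sustained=sustained,
        offset=offset,
        epochs=ep,
    )


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value, midranks for ties.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise. Two identical constant
    samples give p = 1 by convention (no evidence of a shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def compare_pre_post(
    pre: EpochResponse,
    post: EpochResponse,
    alpha: float = 0.05,
    correction: str = "none",
    n_comparisons: int = 2,
    condition: str = "bf_paired",
    corrected: bool = False,
) -> PlasticityResult:
    """Rank-sum comparison of per-trial sustained responses pre vs post VNS.

    ``correction='bonferroni'`` multiplies the p-value by ``n_comparisons``
    (used in the repeated 20+20-trial pairing design); significance is
    ``p < alpha`` after correction.
    """
    if pre.n_trials < 5 or post.n_trials < 5:
        raise ValidationError("need at least 5 trials per side for the rank-sum comparison")
    p = ranksum_p(pre.sustained, post.sustained)
    if correction == "bonferroni":
        p = min(1.0, p * n_comparisons)
    elif correction != "none":
        raise ValueError(f"unknown correction: {correction}")
    diff = float(post.sustained.mean() - pre.sustained.mean())
    return PlasticityResult(
        unit_id=pre.unit_id,
        condition=condition,
        pre_sustained=float(pre.sustained.mean()),
        post_sustained=float(post.sustained.mean()),
        diff=diff,
        p_unit=p,
        significant=bool(p < alpha),
        n_pre=pre.n_trials,
        n_post=post.n_trials,
        corrected=corrected,
    )


def has_sustained_response(responses: list[EpochResponse], min_rate: float = 1.0) -> bool:
    """Unit inclusion rule: mean sustained response of at least ``min_rate``
    spikes/s (in magnitude) in at least one phase."""
    return any(abs(r.mean("sustained")) >= min_rate for r in responses)


def population_summary(results: list[PlasticityResult]) -> dict:
    """Population-level summary: counts of significant units and the direction
    of their mean change (sign-rank test on unit mean differences)."""
    n = len(results)
    sig = [r for r in results if r.significant]
    out = {
        "n_units": n,
        "n_significant": len(sig),
        "fraction_significant": len(sig) / n if n else np.nan,
        "mean_diff_significant": float(np.mean([r.diff for r in sig])) if sig else np.nan,
        "signrank_p": np.nan,
    }
    diffs = np.array([r.diff for r in sig])
    if diffs.size >= 5 and np.any(diffs != 0):
        out["signrank_p"] = float(stats.wilcoxon(diffs).pvalue)
    return out


def results_frame(results: list[PlasticityResult]) -> pd.DataFrame:
    """Tabulate plasticity results (one row per unit)."""
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "condition": r.condition,
                "pre_sustained": r.pre_sustained,
                "post_sustained": r.post_sustained,
                "diff": r.diff,
                "p_unit": r.p_unit,
                "significant": r.significant,
                "corrected": r.corrected,
                "n_pre": r.n_pre,
                "n_post": r.n_post,
            }
            for r in results
        ]
    )
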