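"""Cross-validated decomposition of responses into pupil-explained and
persistent components.

For each unit the trial x bin response matrix ``r(i, t)`` is modelled as

    r_pupil(i, t) = b0 + b1 * rbar(t) + b2 * p(i, t) + b3 * rbar(t) * p(i, t)

where ``rbar(t)`` is the trial-averaged PSTH estimated from the training folds
only and ``p(i, t)`` the lag-aligned, session-mean-centred pupil. b2 captures
pupil effects on baseline rate and b3 pupil effects on response gain. The model
is fitted by least squares with k-fold cross validation over trials; held-out
predictions are assembled into ``r_pupil``, and the residual

    r_persist = r - r_pupil

carries response changes that cannot be explained by pupil-indexed arousal
(the putative persistent VNS plasticity). Pre- and post-VNS phases are fitted
jointly with shared coefficients so that phase differences land in
``r_persist`` rather than being absorbed by phase-specific fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinnedUnitSession, ValidationError, concat_sessions
from .evoked import DEFAULT_EPOCHS, EpochResponse, PlasticityResult, compare_pre_post

logger = logging.getLogger("vnspupil")


@dataclass
class RegressionFit:
    """Result of the cross-validated pupil regression for one unit (one phase
    slice; coefficients may be shared with other slices of a joint fit)."""

    unit_id: str
    phase: str
    b0: float  # intercept, spikes/s
    b1: float  # PSTH-regressor weight, dimensionless
    b2: float  # pupil baseline weight, spikes/s per (centred) pupil unit
    b3: float  # pupil x PSTH gain interaction, per pupil unit
    r_pupil: np.ndarray  # trial x bin held-out prediction, spikes/s
    r_persist: np.ndarray  # trial x bin residual, spikes/s
    rate: np.ndarray  # the fitted response matrix (r = r_pupil + r_persist)
    time: np.ndarray
    bin_width: float
    window: tuple[float, float]
    cv_folds: int
    fold_coefs: np.ndarray = field(default=None)  # folds x 4
    pupil_mean: float = np.nan  # centring constant, pixels (or input pupil units)
    pupil_dropped: bool = False

    @property
    def n_trials(self) -> int:
        return int(self.rate.shape[0])


def _design(rbar: np.ndarray, pupil: np.ndarray, n_trials: int, drop_pupil: bool) -> np.ndarray:
    """Row-stacked design for trials x bins: columns [1, rbar, p, rbar*p]."""
    B = rbar.size
    ones = np.ones((n_trials, B))
    rb = np.broadcast_to(rbar, (n_trials, B))
    cols = [ones, rb]
    if not drop_pupil:
        cols += [pupil, rb * pupil]
    return np.stack([c.reshape(-1) for c in cols], axis=1)


def fit_pupil_model(
    session: BinnedUnitSession | list[BinnedUnitSession],
    folds: int = 20,
    seed: int | None = None,
    shuffle: bool = False,
    pupil_sd_floor: float = 0.01,
) -> RegressionFit | list[RegressionFit]:
    """Fit the pupil regression with k-fold cross validation over trials.

    ``session`` may be a single binned session or a list (e.g. [pre, post])
    fitted jointly with shared coefficients; in the latter case one
    :class:`RegressionFit` per input session is returned, in order.

    Fold assignment is interleaved by trial index (trial i -> fold i mod k) and
    deterministic; with ``shuffle=True`` trials are permuted first using
    ``seed``. If there are fewer trials than folds, the fold count is reduced.
    The pupil is centred on its session mean before fitting; if its standard
    deviation is below ``pupil_sd_floor`` times the mean diameter, the pupil
    terms are dropped (b2 = b3 = 0) with a warning.
    """
    sessions = [session] if isinstance(session, BinnedUnitSession) else list(session)
    joint = sessions[0] if len(sessions) == 1 else concat_sessions(sessions)
    R = joint.rate
    P_raw = joint.pupil
    N, B = R.shape
    k = min(folds, N)
    if k < folds:
        logger.info("fit_pupil_model unit=%s: folds reduced from %d to %d trials", joint.unit_id, folds, k)
    if N < 2:
        raise ValidationError("need at least 2 trials to fit")

    p_mean = float(P_raw.mean())
    p_sd = float(P_raw.std())
    drop_pupil = p_sd < pupil_sd_floor * abs(p_mean) if p_mean != 0 else p_sd == 0
    if drop_pupil:
        warnings.warn(
            f"unit {joint.unit_id}: pupil variance below floor; pupil terms dropped (b2 = b3 = 0)",
            stacklevel=2,
        )
    P = P_raw - p_mean

    order = np.arange(N)
    if shuffle:
        order = np.random.default_rng(seed).permutation(N)
    fold_of = np.empty(N, dtype=int)
    fold_of[order] = np.arange(N) % k

    r_pupil = np.empty_like(R)
    n_coef = 2 if drop_pupil else 4
    fold_coefs = np.zeros((max(k, 1), 4))
    if k == 1:  # degenerate: fit and predict on the full data (no held-out split)
        splits = [(np.arange(N), np.arange(N))]
    else:
        splits = [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)) for f in range(k)]
    for f, (train, test) in enumerate(splits):
        rbar = R[train].mean(axis=0)
        X = _design(rbar, P[train], train.size, drop_pupil)
        y = R[train].reshape(-1)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        Xt = _design(rbar, P[test], test.size, drop_pupil)
        r_pupil[test] = (Xt @ beta).reshape(test.size, B)
        fold_coefs[f, :n_coef] = beta
    r_persist = R - r_pupil
    mean_coefs = fold_coefs.mean(axis=0)

    fits = []
    start = 0
    for s in sessions:
        n = s.n_trials
        sl = slice(start, start + n)
        fits.append(
            RegressionFit(
                unit_id=joint.unit_id,
                phase=s.phase,
                b0=float(mean_coefs[0]),
                b1=float(mean_coefs[1]),
                b2=float(mean_coefs[2]),
                b3=float(mean_coefs[3]),
                r_pupil=r_pupil[sl],
                r_persist=r_persist[sl],
                rate=R[sl],
                time=joint.time.copy(),
                bin_width=joint.bin_width,
                window=joint.window,
                cv_folds=k,
                fold_coefs=fold_coefs,
                pupil_mean=p_mean,
                pupil_dropped=drop_pupil,
            )
        )
        start += n
    return fits[0] if isinstance(session, BinnedUnitSession) else fits


def _sustained_persist(fit: RegressionFit, epochs: dict | None) -> np.ndarray:
    ep = dict(DEFAULT_EPOCHS, **(epochs or {}))
    lo, hi = ep["sustained"]
    m = (fit.time > lo) & (fit.time < hi)
    if not m.any():
        raise ValidationError("sustained epoch contains no bins")
    return fit.r_persist[:, m].mean(axis=1)


def persistent_change(
    fit_pre: RegressionFit,
    fit_post: RegressionFit,
    epochs: dict | None = None,
    alpha: float = 0.05,
    correction: str = "none",
    condition: str = "bf_paired",
) -> PlasticityResult:
    """Pupil-corrected plasticity test: rank-sum on per-trial sustained
    ``r_persist`` pre vs post, diff = post - pre mean sustained residual."""
    if fit_pre.unit_id != fit_post.unit_id:
        raise ValidationError("fits must come from the same unit")
    if fit_pre.time.shape != fit_post.time.shape or not np.allclose(fit_pre.time, fit_post.time):
        raise ValidationError("fits must share the bin grid")
    pre = _sustained_persist(fit_pre, epochs)
    post = _sustained_persist(fit_post, epochs)
    ep = dict(DEFAULT_EPOCHS, **(epochs or {}))
    z = np.zeros_like
    pre_resp = EpochResponse(fit_pre.unit_id, fit_pre.phase, z(pre), z(pre), pre, z(pre), ep)
    post_resp = EpochResponse(fit_post.unit_id, fit_post.phase, z(post), z(post), post, z(post), ep)
    return compare_pre_post(
        pre_resp, post_resp, alpha=alpha, correction=correction, condition=condition, corrected=True
    )


@dataclass
class GatingRecord:
    """One unit's VNS-evoked pupil dilation and persistent-change magnitude."""

    unit_id: str
    evoked_dilation: float  # fraction change during VNS-pairing trials
    persist_magnitude: float  # |post - pre| mean sustained r_persist, spikes/s
    significant: bool = False

    def __post_init__(self) -> None:
        if self.persist_magnitude < 0:
            raise ValidationError("persist_magnitude must be non-negative")


def gating_correlation(records: list[GatingRecord] | pd.DataFrame) -> tuple[float, float, int]:
    """Pearson correlation between VNS-evoked pupil dilation and the magnitude
    of the persistent response change, with classical two-sided p."""
    if isinstance(records, pd.DataFrame):
        x = records["evoked_dilation"].to_numpy(dtype=float)
        y = records["persist_magnitude"].to_numpy(dtype=float)
    else:
        x = np.array([r.evoked_dilation for r in records], dtype=float)
        y = np.array([r.persist_magnitude for r in records], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("need at least 3 records")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in gating variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)
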