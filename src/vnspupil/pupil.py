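"""Pupillometry preprocessing: blink excision, normalization, evoked dilation.

Blink artifacts appear as rapid transient drops in the fitted pupil diameter.
They are detected on the first difference of the trace: samples whose derivative
lies more than ``sd_threshold`` standard deviations from the mean derivative are
flagged, flagged events are classified (a dip — decrease followed by recovery —
is a blink; a monotone jump is a tracking glitch), and a fixed-length window
centred on each event is excised and bridged by linear interpolation between the
nearest surviving samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PupilTrace, ValidationError

logger = logging.getLogger("vnspupil")


class UnrecoverableTraceError(ValueError):
    """Every sample of the trace was flagged; nothing survives to interpolate from."""


@dataclass
class BlinkReport:
    """Summary of one blink-removal pass."""

    blink_intervals: list[tuple[float, float]]
    n_samples_replaced: int
    threshold_used: float  # pixels/sample, deviation from the mean derivative
    n_blink_events: int = 0
    n_glitch_events: int = 0

    def to_dict(self) -> dict:
        return {
            "blink_intervals": [[float(a), float(b)] for a, b in self.blink_intervals],
            "n_samples_replaced": int(self.n_samples_replaced),
            "threshold_used": float(self.threshold_used),
            "n_blink_events": int(self.n_blink_events),
            "n_glitch_events": int(self.n_glitch_events),
        }


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def remove_blinks(
    trace: PupilTrace, sd_threshold: float = 6.0, excision_s: float = 6.0
) -> tuple[PupilTrace, BlinkReport]:
    """Excise blink artifacts and bridge them by linear interpolation.

    Returns a new trace (original is untouched) whose ``blink_mask`` marks every
    replaced sample, plus a :class:`BlinkReport`. Samples that were not excised
    are bit-identical to the input; the operation is idempotent. Events at the
    trace boundary are bridged one-sidedly by holding the nearest surviving
    value. A trace with no surviving samples raises
    :class:`UnrecoverableTraceError` ("trace unrecoverable").
    """
    if trace.n_samples < 2:
        raise ValidationError("trace must have at least 2 samples")
    t = trace.timestamps
    x = trace.diameter
    d = np.diff(x)

    # Robust global threshold: the derivative SD is re-estimated excluding
    # already-flagged samples until a fixed point, so the detection threshold
    # reflects the artifact-free derivative distribution rather than being
    # inflated by the blinks themselves (and a second pass flags nothing new).
    flagged = np.zeros(d.size, dtype=bool)
    threshold = 0.0
    for _ in range(50):
        good = d[~flagged]
        if good.size < 2:
            raise UnrecoverableTraceError("trace unrecoverable: all samples flagged as blink")
        mu, sd = float(good.mean()), float(good.std())
        threshold = sd_threshold * sd
        if sd == 0:
            break
        new = np.abs(d - mu) > threshold
        if not np.any(new & ~flagged):
            break
        flagged |= new

    if not flagged.any():
        return trace.copy(), BlinkReport([], 0, threshold)

    # contiguous runs of flagged first differences -> events over samples [i0, i1]
    idx = np.flatnonzero(flagged)
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))

    n_blink = n_glitch = 0
    intervals: list[tuple[float, float]] = []
    half = excision_s / 2.0
    for i0, i1 in runs:
        # classify within a local neighbourhood around the event
        lo = max(0, i0 - 2)
        hi = min(x.size - 1, i1 + 2)
        pre_level = x[lo]
        local_min = x[lo : hi + 1].min()
        if local_min < pre_level:  # decrease (below pre-event level) then recovery
            n_blink += 1
        else:  # pure monotone jump: tracking glitch, excised too
            n_glitch += 1
        center = 0.5 * (t[i0] + t[i1])
        intervals.append((center - half, center + half))

    intervals = _merge_intervals(intervals)
    replaced = np.zeros(x.size, dtype=bool)
    for a, b in intervals:
        replaced |= (t >= a) & (t <= b)
    keep = ~replaced
    if not keep.any():
        raise UnrecoverableTraceError("trace unrecoverable: all samples flagged as blink")

    out = x.copy()
    out[replaced] = np.interp(t[replaced], t[keep], x[keep])
    if n_glitch:
        logger.info("remove_blinks: %d tracking glitch event(s) excised alongside %d blink(s)", n_glitch, n_blink)
    report = BlinkReport(
        blink_intervals=[(max(a, t[0]), min(b, t[-1])) for a, b in intervals],
        n_samples_replaced=int(replaced.sum()),
        threshold_used=threshold,
        n_blink_events=n_blink,
        n_glitch_events=n_glitch,
    )
    return PupilTrace(t.copy(), out, trace.blink_mask | replaced), report


def normalize_trace(trace: PupilTrace, baseline: str, trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a pupil trace to a dimensionless scale.

    Modes
    -----
    ``first5_trials``
        Session mode: divide the whole trace by the mean diameter during the
        sound intervals of the first five pre-phase trials (output is a ratio,
        1 = baseline).
    ``per_trial_prevns_1s``
        Fraction change relative to the mean diameter in the 1 s preceding each
        trial's VNS onset; each sample uses the baseline of the trial segment it
        falls in (output = diameter/baseline - 1).
    ``per_trial_first_0.8s``
        Fraction change relative to the mean diameter in the first 0.8 s after
        each trial's sound onset.

    Returns the normalized values (aligned with ``trace.timestamps``) and the
    per-trial (or scalar) baselines used.
    """
    t = trace.timestamps
    x = trace.diameter

    def window_mean(lo: float, hi: float) -> float:
        m = (t >= lo) & (t < hi)
        if not m.any():
            raise ValidationError(f"no pupil samples in baseline window [{lo}, {hi})")
        return float(x[m].mean())

    if baseline == "first5_trials":
        pre = trials[trials["session_phase"] == "pre"]
        if len(pre) == 0:
            pre = trials
        head = pre.head(5)
        if len(head) == 0:
            raise ValidationError("no trials available for session baseline")
        vals = [window_mean(r["sound_onset"], r["sound_offset"]) for _, r in head.iterrows()]
        base = float(np.mean(vals))
        if base <= 0:
            raise ValidationError("session baseline is zero")
        return x / base, np.array([base])

    if baseline == "per_trial_prevns_1s":
        sel = trials[np.isfinite(trials["vns_onset"].to_numpy(dtype=float))]
        anchors = sel["vns_onset"].to_numpy(dtype=float)
        windows = [(a - 1.0, a) for a in anchors]
    elif baseline == "per_trial_first_0.8s":
        sel = trials
        anchors = sel["sound_onset"].to_numpy(dtype=float)
        windows = [(a, a + 0.8) for a in anchors]
    else:
        raise ValueError(f"unknown baseline mode: {baseline}")

    if len(windows) == 0:
        raise ValidationError("no trials define the requested per-trial baseline")
    bases = np.array([window_mean(lo, hi) for lo, hi in windows])
    if np.any(bases <= 0):
        raise ValidationError("zero per-trial baseline")
    # each sample is normalized by the baseline of the trial segment containing it
    seg = np.searchsorted(anchors, t, side="right") - 1
    seg = np.clip(seg, 0, len(bases) - 1)
    return x / bases[seg] - 1.0, bases


def per_trial_fraction_change(
    trace: PupilTrace, trials: pd.DataFrame, baseline_s: float = 0.8, span: tuple[float, float] = (0.8, 11.0)
) -> np.ndarray:
    """Per-trial evoked pupil change: mean fraction change over ``span`` relative
    to the mean diameter in the first ``baseline_s`` after each trial's sound onset."""
    t = trace.timestamps
    x = trace.diameter
    out = []
    for _, row in trials.iterrows():
        onset = float(row["sound_onset"])
        b = (t >= onset) & (t < onset + baseline_s)
        w = (t >= onset + span[0]) & (t < onset + span[1])
        if not b.any() or not w.any():
            out.append(np.nan)
            continue
        base = x[b].mean()
        out.append(float(x[w].mean() / base - 1.0) if base > 0 else np.nan)
    return np.asarray(out)


@dataclass
class DilationCurve:
    """Trial-averaged fraction change in pupil diameter aligned to VNS onset."""

    time_rel_vns: np.ndarray
    fraction_change: np.ndarray
    sem: np.ndarray
    n_trials: int
    peak_time: float = field(default=np.nan)
    peak_amplitude: float = field(default=np.nan)


def vns_evoked_dilation(
    trace: PupilTrace,
    trials: pd.DataFrame | np.ndarray,
    window: tuple[float, float] = (-1.0, 10.0),
    grid_hz: float | None = None,
    smooth_bins: int = 3,
) -> DilationCurve:
    """Average VNS-evoked pupil dilation across trials.

    Each trial with a VNS onset is interpolated onto a regular grid over
    ``window`` (seconds relative to VNS onset) and expressed as fraction change
    relative to the mean over the pre-VNS second; the per-trial curves are then
    averaged. The curve's baseline bins average zero by construction. The peak
    is read off a ``smooth_bins``-point moving average of the mean curve
    (``smooth_bins=1`` disables smoothing).
    """
    if isinstance(trials, pd.DataFrame):
        onsets = trials["vns_onset"].to_numpy(dtype=float)
    else:  # a bare array of VNS onset times (e.g. stimulation in silence)
        onsets = np.asarray(trials, dtype=float)
    onsets = onsets[np.isfinite(onsets)]
    if onsets.size == 0:
        raise ValidationError("no trials with VNS onset")
    if grid_hz is None:
        dt_med = float(np.median(np.diff(trace.timestamps)))
        grid_hz = 1.0 / dt_med
    dt = 1.0 / grid_hz
    tgrid = np.arange(window[0], window[1] + dt / 2, dt)
    base_bins = tgrid < 0

    lo, hi = trace.span
    segs = []
    for v in onsets:
        q = v + tgrid
        if q[0] < lo - 1e-9 or q[-1] > hi + 1e-9:
            logger.info("vns_evoked_dilation: trial at %.3f s extends past the trace and was dropped", v)
            continue
        seg = trace.interp(q)
        base = seg[base_bins].mean()
        if base <= 0:
            raise ValidationError("non-positive pre-VNS baseline")
        segs.append(seg / base - 1.0)
    if not segs:
        raise ValidationError("no VNS trial fits inside the pupil record")
    m = np.vstack(segs)
    mean = m.mean(axis=0)
    sem = m.std(axis=0, ddof=1) / np.sqrt(m.shape[0]) if m.shape[0] > 1 else np.full(mean.shape, np.nan)

    if smooth_bins > 1:
        k = np.ones(smooth_bins) / smooth_bins
        sm = np.convolve(mean, k, mode="same")
    else:
        sm = mean
    post = tgrid >= 0
    ipeak = int(np.argmax(np.where(post, sm, -np.inf)))
    return DilationCurve(
        time_rel_vns=tgrid,
        fraction_change=mean,
        sem=sem,
        n_trials=m.shape[0],
        peak_time=float(tgrid[ipeak]),
        peak_amplitude=float(sm[ipeak]),
    )
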