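"""Core data model: trial tables, spike/pupil/lick containers, trial-aligned binning.

All times are in seconds. Trial tables are plain :class:`pandas.DataFrame` objects
with the schema documented in :data:`TRIAL_COLUMNS`; array-like signals live in small
dataclasses. After alignment, times are trial-relative and bins are half-open
``[start, start + width)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("vnspupil")

#: Required columns of a trial table, in canonical order.
TRIAL_COLUMNS = [
    "trial_id",
    "sound_onset",
    "sound_offset",
    "sound_label",
    "is_rewarded",
    "vns_condition",
    "vns_onset",
    "session_phase",
    "day",
    "block_id",
]

#: Optional columns carried through when present.
OPTIONAL_TRIAL_COLUMNS = ["animal", "t1_freq_hz", "t2_freq_hz", "in_pupil_span"]

SOUND_LABELS = {"T1", "T2", "REF", "BF", "OFFBF"}
VNS_CONDITIONS = {"paired", "unpaired", "none"}
SESSION_PHASES = {"pre", "during", "post"}

#: Allowed range for analysis bin widths (30-50 Hz).
BIN_WIDTH_RANGE = (0.02, 1.0 / 30.0)


class ValidationError(ValueError):
    """Input data violates a schema or ordering contract."""


class ParseError(ValueError):
    """A delimited-text input file could not be parsed."""


@dataclass
class PupilTrace:
    """Timestamped pupil diameter (minor-axis length of the fit ellipse, pixels)."""

    timestamps: np.ndarray
    diameter: np.ndarray
    blink_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.blink_mask is None:
            self.blink_mask = np.zeros(self.timestamps.shape, dtype=bool)
        else:
            self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.diameter.shape:
            raise ValidationError("pupil timestamps and diameter must be 1-d and equal length")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("pupil timestamps must be strictly increasing")
        good = ~self.blink_mask
        if np.any(self.diameter[good] <= 0):
            raise ValidationError("pupil diameter must be positive outside blink samples")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the diameter at arbitrary times (edges held)."""
        return np.interp(np.asarray(t, dtype=float), self.timestamps, self.diameter)

    def copy(self) -> "PupilTrace":
        return PupilTrace(self.timestamps.copy(), self.diameter.copy(), self.blink_mask.copy())


@dataclass
class UnitSpikes:
    """Spike times for one sorted unit, with tuning metadata."""

    unit_id: str
    spike_times: np.ndarray
    best_frequency: float | None = None
    is_single_unit: bool = True
    bf_match: bool | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"spike times for unit {self.unit_id} must be sorted")
        if self.bf_match is not None and self.best_frequency is None:
            raise ValidationError("bf_match defined but best_frequency absent")


@dataclass
class LickEvents:
    """Sorted lick times from the piezo lick sensor."""

    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.lick_times.size and np.any(np.diff(self.lick_times) < 0):
            raise ValidationError("lick times must be sorted")


@dataclass
class BinnedUnitSession:
    """Trial x bin spike-rate and lag-aligned pupil matrices for one unit and phase.

    ``rate[i, j]`` is the firing rate (spikes/s) of trial ``i`` in the half-open bin
    starting at ``window[0] + j * bin_width`` relative to sound onset. ``pupil[i, j]``
    is the pupil diameter interpolated at the bin centre shifted back by the pupil
    lag (pupil leads spikes).
    """

    unit_id: str
    phase: str
    bin_width: float
    time: np.ndarray  # bin centres, trial-relative seconds
    rate: np.ndarray  # trials x bins, spikes/s
    pupil: np.ndarray  # trials x bins, same shape as rate
    trial_index: np.ndarray  # positional indices into the trial table used
    trial_id: np.ndarray
    window: tuple[float, float]
    excluded_trials: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate.shape != self.pupil.shape:
            raise ValidationError("rate and pupil matrices must share shape")
        if np.any(self.rate < 0):
            raise ValidationError("rates must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.rate.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.rate.shape[1])

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([self.time - self.bin_width / 2, [self.time[-1] + self.bin_width / 2]])


def validate_trials(trials: pd.DataFrame, vns_lead_s: tuple[float, ...] = (0.1, 0.15)) -> pd.DataFrame:
    """Validate a trial table against the documented schema; returns the table.

    Checks column presence, label vocabularies, interval ordering, strictly
    increasing trial ids and the VNS timing contract: paired stimulation precedes
    sound onset by one of the configured leads, unpaired stimulation starts at
    least 0.5 s after sound offset.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        return trials
    if not np.all(np.diff(trials["trial_id"].to_numpy()) > 0):
        raise ValidationError("trial_id must be strictly increasing")
    if not np.all(trials["sound_offset"].to_numpy() > trials["sound_onset"].to_numpy()):
        raise ValidationError("sound_offset must exceed sound_onset")
    bad = set(trials["sound_label"]) - SOUND_LABELS
    if bad:
        raise ValidationError(f"unknown sound labels: {sorted(bad)}")
    bad = set(trials["vns_condition"]) - VNS_CONDITIONS
    if bad:
        raise ValidationError(f"unknown vns conditions: {sorted(bad)}")
    bad = set(trials["session_phase"]) - SESSION_PHASES
    if bad:
        raise ValidationError(f"unknown session phases: {sorted(bad)}")
    paired = trials[trials["vns_condition"] == "paired"]
    if len(paired):
        if paired["vns_onset"].isna().any():
            raise ValidationError("paired trials must carry vns_onset")
        lead = paired["sound_onset"].to_numpy() - paired["vns_onset"].to_numpy()
        ok = np.zeros(len(paired), dtype=bool)
        for L in vns_lead_s:
            ok |= np.isclose(lead, L, atol=1e-6)
        if not ok.all():
            raise ValidationError("paired VNS onset must precede sound onset by a configured lead")
    unpaired = trials[trials["vns_condition"] == "unpaired"]
    if len(unpaired):
        if unpaired["vns_onset"].isna().any():
            raise ValidationError("unpaired trials must carry vns_onset")
        gap = unpaired["vns_onset"].to_numpy() - unpaired["sound_offset"].to_numpy()
        if np.any(gap < 0.5 - 1e-9):
            raise ValidationError("unpaired VNS must start >= 0.5 s after sound offset")
    return trials


@dataclass
class Session:
    """One recording/behaviour session: trials plus all signal streams."""

    trials: pd.DataFrame
    units: dict[str, UnitSpikes]
    pupil: PupilTrace
    licks: LickEvents

    def __post_init__(self) -> None:
        validate_trials(self.trials)


def _bin_edges(window: tuple[float, float], bin_width: float) -> np.ndarray:
    lo, hi = float(window[0]), float(window[1])
    n = (hi - lo) / bin_width
    n_round = int(round(n))
    if abs(n - n_round) > 1e-6 or n_round < 1:
        raise ValidationError("window length must be an integer number of bins")
    return lo + np.arange(n_round + 1) * bin_width


def bin_and_align(
    trials: pd.DataFrame,
    unit: UnitSpikes,
    pupil: PupilTrace,
    bin_width: float = 0.02,
    pupil_lag: float = 0.75,
    window: tuple[float, float] = (-0.5, 1.5),
    phase: str | None = None,
    labels: tuple[str, ...] | None = None,
) -> BinnedUnitSession:
    """Align spikes and pupil to sound onset and bin them on a common grid.

    Spike counts in each half-open bin are divided by ``bin_width`` to give rates.
    The pupil value assigned to the spike bin centred at trial-relative time ``t``
    is the (blink-corrected) trace linearly interpolated at ``t - pupil_lag`` in
    absolute time, i.e. the pupil *leads* the neural signal by the lag.

    Trials whose pupil query times fall outside the recorded trace are excluded
    (not zero-filled) and logged.
    """
    if not (BIN_WIDTH_RANGE[0] - 1e-9 <= bin_width <= BIN_WIDTH_RANGE[1] + 1e-9):
        raise ValidationError(f"bin_width {bin_width} outside allowed range {BIN_WIDTH_RANGE}")
    sel = trials
    if phase is not None:
        sel = sel[sel["session_phase"] == phase]
    if labels is not None:
        sel = sel[sel["sound_label"].isin(labels)]
    sel = sel.reset_index()
    edges = _bin_edges(window, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2

    lo, hi = pupil.span
    rates, pupils, keep_pos, keep_id, excluded = [], [], [], [], []
    for pos, row in sel.iterrows():
        onset = float(row["sound_onset"])
        q = onset + centers - pupil_lag
        if q[0] < lo - 1e-9 or q[-1] > hi + 1e-9 or onset + edges[0] < lo - 1e-9:
            excluded.append(int(row["trial_id"]))
            continue
        counts = np.diff(np.searchsorted(unit.spike_times, onset + edges, side="left"))
        rates.append(counts / bin_width)
        pupils.append(pupil.interp(q))
        keep_pos.append(int(row["index"]))
        keep_id.append(int(row["trial_id"]))
    if excluded:
        logger.info(
            "bin_and_align unit=%s phase=%s: excluded %d trial(s) outside pupil record: %s",
            unit.unit_id, phase, len(excluded), excluded,
        )
    n_bins = len(centers)
    rate = np.array(rates, dtype=float).reshape(len(rates), n_bins)
    pup = np.array(pupils, dtype=float).reshape(len(pupils), n_bins)
    return BinnedUnitSession(
        unit_id=unit.unit_id,
        phase=phase if phase is not None else "all",
        bin_width=bin_width,
        time=centers,
        rate=rate,
        pupil=pup,
        trial_index=np.array(keep_pos, dtype=int),
        trial_id=np.array(keep_id, dtype=int),
        window=(float(window[0]), float(window[1])),
        excluded_trials=excluded,
    )


def concat_sessions(sessions: list[BinnedUnitSession]) -> BinnedUnitSession:
    """Stack binned sessions of the same unit/grid along trials (e.g. pre + post)."""
    first = sessions[0]
    for s in sessions[1:]:
        if s.unit_id != first.unit_id or not np.allclose(s.time, first.time):
            raise ValidationError("sessions must share unit and bin grid")
    return dataclasses.replace(
        first,
        phase="+".join(s.phase for s in sessions),
        rate=np.vstack([s.rate for s in sessions]),
        pupil=np.vstack([s.pupil for s in sessions]),
        trial_index=np.concatenate([s.trial_index for s in sessions]),
        trial_id=np.concatenate([s.trial_id for s in sessions]),
        excluded_trials=sum((s.excluded_trials for s in sessions), []),
    )
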