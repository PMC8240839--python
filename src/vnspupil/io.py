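"""Delimited-text readers and writers for session data.

File dialect: UTF-8, comma-delimited, one header row, dot decimal.

Schemas
-------
``trials.csv``
    trial_id, sound_onset, sound_offset, sound_label, is_rewarded, vns_condition,
    vns_onset (empty if absent), session_phase, day, block_id
    [optional: animal, t1_freq_hz, t2_freq_hz]
``spikes.csv``
    unit_id, spike_time [optional per-unit metadata repeated on every row:
    best_frequency, is_single_unit, bf_match]
``pupil.csv``
    timestamp, diameter [optional: blink]
``licks.csv``
    lick_time
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import (
    OPTIONAL_TRIAL_COLUMNS,
    TRIAL_COLUMNS,
    LickEvents,
    ParseError,
    PupilTrace,
    Session,
    UnitSpikes,
    ValidationError,
    validate_trials,
)

FILE_NAMES = {"trials": "trials.csv", "spikes": "spikes.csv", "pupil": "pupil.csv", "licks": "licks.csv"}


def _read_csv(path: str, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text -> parse error naming the file
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def resolve_paths(input_dir: str) -> dict[str, str]:
    """Map stream name -> file path for the standard file set in ``input_dir``."""
    return {k: os.path.join(input_dir, v) for k, v in FILE_NAMES.items()}


def read_session(paths: dict[str, str] | str, vns_lead_s: tuple[float, ...] = (0.1, 0.15)) -> Session:
    """Read and cross-validate a session from its delimited-text file set.

    ``paths`` is either a directory containing the standard file names or a
    mapping with keys ``trials``, ``spikes``, ``pupil`` and (optionally)
    ``licks``. A missing licks file yields an empty :class:`LickEvents`.

    Every trial whose sound interval falls outside the pupil-trace span is
    flagged in the boolean column ``in_pupil_span`` rather than dropped.
    """
    if isinstance(paths, str):
        paths = resolve_paths(paths)

    trials = _read_csv(paths["trials"], TRIAL_COLUMNS)
    trials["sound_label"] = trials["sound_label"].astype(str)
    trials["is_rewarded"] = trials["is_rewarded"].astype(bool)
    validate_trials(trials, vns_lead_s=vns_lead_s)

    spikes = _read_csv(paths["spikes"], ["unit_id", "spike_time"])
    units: dict[str, UnitSpikes] = {}
    for unit_id, grp in spikes.groupby("unit_id", sort=True):
        st = np.sort(grp["spike_time"].to_numpy(dtype=float))
        bf = None
        bf_match = None
        single = True
        if "best_frequency" in grp.columns and not pd.isna(grp["best_frequency"].iloc[0]):
            bf = float(grp["best_frequency"].iloc[0])
        if "bf_match" in grp.columns and bf is not None:
            bf_match = bool(grp["bf_match"].iloc[0])
        if "is_single_unit" in grp.columns:
            single = bool(grp["is_single_unit"].iloc[0])
        units[str(unit_id)] = UnitSpikes(str(unit_id), st, bf, single, bf_match)

    pup = _read_csv(paths["pupil"], ["timestamp", "diameter"])
    ts = pup["timestamp"].to_numpy(dtype=float)
    if ts.size >= 2 and not np.all(np.diff(ts) > 0):
        raise ValidationError(f"{paths['pupil']}: timestamps must be strictly increasing")
    blink = pup["blink"].to_numpy(dtype=bool) if "blink" in pup.columns else None
    pupil = PupilTrace(ts, pup["diameter"].to_numpy(dtype=float), blink)

    licks = LickEvents()
    lick_path = paths.get("licks")
    if lick_path and os.path.exists(lick_path):
        lk = _read_csv(lick_path, ["lick_time"])
        licks = LickEvents(np.sort(lk["lick_time"].to_numpy(dtype=float)))

    lo, hi = pupil.span
    trials = trials.copy()
    trials["in_pupil_span"] = (trials["sound_onset"] >= lo) & (trials["sound_offset"] <= hi)
    return Session(trials=trials, units=units, pupil=pupil, licks=licks)


def write_session(session: Session, out_dir: str) -> dict[str, str]:
    """Write a session back to the standard file set; inverse of :func:`read_session`."""
    os.makedirs(out_dir, exist_ok=True)
    paths = resolve_paths(out_dir)

    cols = TRIAL_COLUMNS + [c for c in OPTIONAL_TRIAL_COLUMNS if c in session.trials.columns and c != "in_pupil_span"]
    session.trials[cols].to_csv(paths["trials"], index=False, float_format="%.9g")

    rows = []
    for uid in sorted(session.units):
        u = session.units[uid]
        df = pd.DataFrame({"unit_id": uid, "spike_time": u.spike_times})
        df["best_frequency"] = u.best_frequency if u.best_frequency is not None else np.nan
        df["is_single_unit"] = u.is_single_unit
        df["bf_match"] = u.bf_match if u.bf_match is not None else np.nan
        rows.append(df)
    spikes = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit_id", "spike_time", "best_frequency", "is_single_unit", "bf_match"]
    )
    spikes.to_csv(paths["spikes"], index=False, float_format="%.9g")

    pd.DataFrame(
        {
            "timestamp": session.pupil.timestamps,
            "diameter": session.pupil.diameter,
            "blink": session.pupil.blink_mask.astype(int),
        }
    ).to_csv(paths["pupil"], index=False, float_format="%.9g")

    pd.DataFrame({"lick_time": session.licks.lick_times}).to_csv(paths["licks"], index=False, float_format="%.9g")
    return paths
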