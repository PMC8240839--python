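"""Ground-truth synthetic data emulating passive VNS-tone pairing sessions and
classical-conditioning behaviour.

The generator reproduces the statistical structure the analysis assumes:

* pupil = slow AR(1) drift around a baseline diameter, a within-session decline,
  an arousal jump at the start of the post-VNS block, gamma-shaped VNS-evoked
  dilations peaking several seconds after stimulation, and V-shaped blink
  artifacts;
* spiking = inhomogeneous Poisson with rate
  ``(1 + g * p_norm(t - lag)) * template(t) + b * p_norm(t - lag)`` where the
  template (spontaneous + onset/sustained/offset box amplitudes) includes the
  spontaneous rate, so pupil gain modulates baseline and evoked activity alike;
* plasticity = the sustained evoked amplitude of a configurable subpopulation
  of units is multiplied by ``(1 - d)`` in the post-VNS block;
* licking = Bernoulli per trial with condition- and day-dependent response
  probabilities ramping towards configured ΔR asymptotes.

Every random quantity flows from the single config seed; identical configs give
bit-identical outputs. ``GroundTruth`` records every injected quantity so each
pipeline stage can be checked against the generative truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BinnedUnitSession, LickEvents, PupilTrace, UnitSpikes, validate_trials
from .regression import GatingRecord

logger = logging.getLogger("vnspupil")


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator (times in seconds, rates in
    spikes/s, pupil amplitudes as fractions of the baseline diameter)."""

    seed: int = 0
    animal: str = "sim"
    # --- neurophysiology session design ---
    n_units: int = 5
    n_trials_per_phase: int = 20  # presentations of each tone per block
    iti_s: float = 12.0
    tone_dur_s: float = 1.0
    vns_lead_s: float = 0.1
    vns_condition: str = "paired"  # VNS mode of the during block
    pair_target: str = "BF"  # which tone is paired ('BF' | 'OFFBF')
    include_offbf: bool = False  # interleave an off-BF tone in pre/post blocks
    unpaired_delay_s: float = 6.0  # unpaired VNS onset after tone onset
    lead_in_s: float = 15.0
    inter_block_gap_s: float = 30.0
    # --- pupil model ---
    fs_pupil: float = 30.0
    base_diameter_px: float = 60.0
    pupil_ar_coef: float = 0.9997  # ~110 s drift time constant at 30 Hz
    pupil_ar_sd: float = 0.0039  # AR(1) innovation SD (stationary SD ~0.15 of baseline)
    session_decay_frac: float = 0.35  # linear decline over each block
    post_jump_frac: float = 0.35  # arousal jump at post-block start
    post_jump_decay_s: float = 200.0
    dilation_amp_frac: float = 0.1
    dilation_peak_s: float = 6.0
    dilation_shape: float = 4.0
    blink_rate_per_min: float = 1.0
    blink_dur_range_s: tuple[float, float] = (0.2, 0.5)
    # --- neural model ---
    spont_rate: float = 10.0
    onset_amp: float = 40.0
    sustained_amp: float = 20.0
    offset_amp: float = 10.0
    unit_amp_jitter: float = 0.2  # lognormal sigma of per-unit amplitude scale
    pupil_gain_g: float = 0.3  # gain per unit fractional pupil change
    pupil_baseline_b: float = 2.0  # spikes/s per unit fractional pupil change
    persist_effect_d: float = 0.3  # fractional sustained suppression post-VNS
    plastic_fraction: float = 0.3
    pupil_lag_s: float = 0.75
    fine_dt: float = 0.001
    spike_window: tuple[float, float] = (-1.0, 2.5)
    max_clip_fraction: float = 0.01
    # --- behaviour experiment ---
    schedule: tuple = (
        ("paired", True), ("unpaired", False), ("unpaired", True), ("paired", False),
        ("paired", True), ("unpaired", False), ("paired", False), ("unpaired", True),
    )  # one (vns_condition, t1_is_high_frequency) entry per 2-d condition
    trials_per_day: int = 200  # T1 + T2 target trials per day
    ref_per_day: int = 50
    trial_period_s: float = 5.0
    day_gap_s: float = 600.0
    learning: dict = field(
        default_factory=lambda: {"paired": (0.1, 0.3), "unpaired": (0.0, 0.0)}
    )  # generative ΔR at end of day 1 / day 2 per condition
    switch_penalty: float = 0.7  # asymptote multiplier on switch transitions
    base_resp_p: float = 0.5
    ref_resp_p: float = 0.15

    def validate(self) -> "GeneratorConfig":
        if not 0.0 <= self.plastic_fraction <= 1.0:
            raise ConfigError("plastic_fraction must lie in [0, 1]")
        for name in ("spont_rate", "onset_amp", "sustained_amp", "offset_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.vns_condition not in {"paired", "unpaired"}:
            raise ConfigError("vns_condition must be 'paired' or 'unpaired'")
        if not 4.0 <= self.dilation_peak_s <= 8.0:
            logger.info("dilation peak %.2f s outside the typical 4.5-7 s range", self.dilation_peak_s)
        return self


# ---------------------------------------------------------------------------
# neurophysiology session


def _dilation_kernel(tau: np.ndarray, peak_s: float, shape: float) -> np.ndarray:
    """Gamma-shaped dilation kernel, unit peak amplitude at ``peak_s``."""
    theta = peak_s / (shape - 1.0)
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / theta
    out[pos] = (x / (shape - 1.0)) ** (shape - 1.0) * np.exp((shape - 1.0) - x)
    return out


@dataclass
class UnitTruth:
    """Injected parameters for one synthetic unit."""

    unit_id: str
    amp_scale: float
    g: float
    b: float
    d: float  # applied sustained suppression (0 for non-plastic units)
    plastic: bool
    best_frequency: float
    bf_match: bool


@dataclass
class GroundTruth:
    """Everything injected by :func:`simulate_session`."""

    config: GeneratorConfig
    pupil_clean: PupilTrace  # artifact-free latent pupil
    pupil_mean_px: float  # mean of the latent trace (p_norm reference)
    blink_times: np.ndarray
    vns_onsets: np.ndarray
    units: dict[str, UnitTruth]
    clipped_fraction: float = 0.0

    def p_norm(self, t: np.ndarray) -> np.ndarray:
        """Latent fractional pupil signal driving the neural gain."""
        return self.pupil_clean.interp(t) / self.pupil_mean_px - 1.0

    def template(self, unit_id: str, tau: np.ndarray, phase: str) -> np.ndarray:
        """Expected template rate (spikes/s) at trial-relative times ``tau``."""
        c = self.config
        u = self.units[unit_id]
        sus = c.sustained_amp * (1.0 - (u.d if phase == "post" else 0.0))
        rate = np.full_like(tau, c.spont_rate, dtype=float)
        rate += np.where((tau >= 0) & (tau < 0.06), c.onset_amp, 0.0)
        rate += np.where((tau >= 0.06) & (tau < c.tone_dur_s), sus, 0.0)
        rate += np.where((tau >= c.tone_dur_s) & (tau < c.tone_dur_s + 0.1), c.offset_amp, 0.0)
        return rate * u.amp_scale

    def expected_binned(
        self,
        unit_id: str,
        phase: str,
        trials: pd.DataFrame,
        bin_width: float = 0.02,
        window: tuple[float, float] = (-0.5, 1.5),
        pupil_lag: float = 0.75,
        tone_label: str = "BF",
        deterministic_pupil: bool = False,
    ) -> BinnedUnitSession:
        """Noise-free binned session: the expected rate in every analysis bin.

        With ``deterministic_pupil`` the pupil coupling is dropped (pure
        template), so the PSTH of the result equals the template exactly.
        """
        c = self.config
        u = self.units[unit_id]
        sel = trials[(trials["session_phase"] == phase) & (trials["sound_label"] == tone_label)]
        sel = sel.reset_index()
        n_bins = int(round((window[1] - window[0]) / bin_width))
        edges = window[0] + np.arange(n_bins + 1) * bin_width
        centers = (edges[:-1] + edges[1:]) / 2
        sub = max(1, int(round(bin_width / c.fine_dt)))
        fine = window[0] + (np.arange(n_bins * sub) + 0.5) * (bin_width / sub)
        rate_rows, pupil_rows = [], []
        for _, row in sel.iterrows():
            onset = float(row["sound_onset"])
            lam = self.template(unit_id, fine, phase)
            if not deterministic_pupil:
                p = self.p_norm(onset + fine - c.pupil_lag_s)
                lam = (1.0 + u.g * p) * lam + u.b * p
            rate_rows.append(np.clip(lam, 0.0, None).reshape(n_bins, sub).mean(axis=1))
            pupil_rows.append(self.pupil_clean.interp(onset + centers - pupil_lag))
        return BinnedUnitSession(
            unit_id=unit_id,
            phase=phase,
            bin_width=bin_width,
            time=centers,
            rate=np.asarray(rate_rows),
            pupil=np.asarray(pupil_rows),
            trial_index=sel["index"].to_numpy(dtype=int),
            trial_id=sel["trial_id"].to_numpy(dtype=int),
            window=(float(window[0]), float(window[1])),
        )


def _phase_trials(cfg: GeneratorConfig) -> pd.DataFrame:
    """Lay out the trial timeline for the three blocks."""
    rows = []
    t = cfg.lead_in_s
    trial_id = 0
    period = cfg.tone_dur_s + cfg.iti_s
    for phase in ("pre", "during", "post"):
        if phase == "during":
            labels = [cfg.pair_target] * cfg.n_trials_per_phase
        else:
            labels = ["BF"] * cfg.n_trials_per_phase
            if cfg.include_offbf:
                labels = [lab for pair in zip(["BF"] * cfg.n_trials_per_phase,
                                              ["OFFBF"] * cfg.n_trials_per_phase) for lab in pair]
        for lab in labels:
            onset = t
            vns_cond, vns_onset = "none", np.nan
            if phase == "during":
                vns_cond = cfg.vns_condition
                if vns_cond == "paired":
                    vns_onset = onset - cfg.vns_lead_s
                else:
                    vns_onset = onset + cfg.unpaired_delay_s
            rows.append(
                dict(
                    trial_id=trial_id,
                    sound_onset=onset,
                    sound_offset=onset + cfg.tone_dur_s,
                    sound_label=lab,
                    is_rewarded=False,
                    vns_condition=vns_cond,
                    vns_onset=vns_onset,
                    session_phase=phase,
                    day=1,
                    block_id={"pre": 0, "during": 1, "post": 2}[phase],
                    animal=cfg.animal,
                )
            )
            trial_id += 1
            t += period
        t += cfg.inter_block_gap_s
    return pd.DataFrame(rows)


def _simulate_pupil(cfg: GeneratorConfig, trials: pd.DataFrame, rng: np.random.Generator):
    """Latent (clean) and observed (blink-corrupted) pupil traces."""
    t_end = float(trials["sound_offset"].iloc[-1]) + cfg.lead_in_s
    n = int(np.ceil(t_end * cfg.fs_pupil))
    ts = np.arange(n) / cfg.fs_pupil

    innov = rng.normal(0.0, cfg.pupil_ar_sd, size=n)
    drift = np.empty(n)
    rho = cfg.pupil_ar_coef
    drift[0] = innov[0] / np.sqrt(1 - rho**2)
    for i in range(1, n):
        drift[i] = rho * drift[i - 1] + innov[i]

    trend = np.zeros(n)
    for phase in ("pre", "during", "post"):
        ph = trials[trials["session_phase"] == phase]
        t0 = float(ph["sound_onset"].iloc[0]) - cfg.lead_in_s if phase == "pre" else float(ph["sound_onset"].iloc[0])
        t1 = float(ph["sound_offset"].iloc[-1])
        m = (ts >= t0) & (ts <= t1 + cfg.inter_block_gap_s)
        span = max(t1 - t0, 1.0)
        trend[m] -= cfg.session_decay_frac * np.clip((ts[m] - t0) / span, 0, 1)
        if phase == "post":
            trend[m] += cfg.post_jump_frac * np.exp(-(ts[m] - t0) / cfg.post_jump_decay_s)

    kernels = np.zeros(n)
    vns_onsets = trials["vns_onset"].to_numpy(dtype=float)
    vns_onsets = vns_onsets[np.isfinite(vns_onsets)]
    for v in vns_onsets:
        kernels += cfg.dilation_amp_frac * _dilation_kernel(ts - v, cfg.dilation_peak_s, cfg.dilation_shape)

    frac = drift + trend + kernels
    clean = cfg.base_diameter_px * (1.0 + frac)
    clean = np.clip(clean, 1e-3, None)

    observed = clean.copy()
    n_blinks = rng.poisson(cfg.blink_rate_per_min * t_end / 60.0)
    blink_times = np.sort(rng.uniform(5.0, max(t_end - 5.0, 6.0), size=n_blinks))
    for bt in blink_times:
        dur = rng.uniform(*cfg.blink_dur_range_s)
        m = (ts >= bt) & (ts < bt + dur)
        if not m.any():
            continue
        tau = (ts[m] - bt) / dur
        depth = 1.0 - 0.95 * (1.0 - np.abs(2 * tau - 1.0))  # V down to 5% of diameter
        observed[m] = observed[m] * depth

    return (
        PupilTrace(ts, observed),
        PupilTrace(ts.copy(), clean),
        blink_times,
        vns_onsets,
    )


def simulate_session(config: GeneratorConfig) -> tuple[pd.DataFrame, dict, PupilTrace, LickEvents, GroundTruth]:
    """Simulate one passive VNS-tone pairing recording.

    Returns ``(trials, units, pupil, licks, truth)``. Spikes are generated only
    for the pre and post blocks (the amplifier is disconnected during
    stimulation, so no spiking exists in the during block); licks are empty in
    this passive paradigm.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    trials = _phase_trials(cfg)
    validate_trials(trials, vns_lead_s=(cfg.vns_lead_s,))
    pupil, clean, blink_times, vns_onsets = _simulate_pupil(cfg, trials, rng)
    mean_px = float(clean.diameter.mean())

    n_plastic = int(round(cfg.plastic_fraction * cfg.n_units))
    plastic_ids = set(rng.choice(cfg.n_units, size=n_plastic, replace=False).tolist())
    unit_truths: dict[str, UnitTruth] = {}
    units: dict[str, UnitSpikes] = {}

    truth = GroundTruth(
        config=cfg,
        pupil_clean=clean,
        pupil_mean_px=mean_px,
        blink_times=blink_times,
        vns_onsets=vns_onsets,
        units=unit_truths,
    )

    # per-trial lagged p_norm on the fine grid, shared by all units
    w0, w1 = cfg.spike_window
    n_fine = int(round((w1 - w0) / cfg.fine_dt))
    fine = w0 + (np.arange(n_fine) + 0.5) * cfg.fine_dt
    phase_data = {}
    for phase in ("pre", "post"):
        ph = trials[trials["session_phase"] == phase]
        onsets = ph["sound_onset"].to_numpy(dtype=float)
        P = np.vstack([truth.p_norm(o + fine - cfg.pupil_lag_s) for o in onsets])
        phase_data[phase] = (onsets, P)

    n_clip = 0
    n_tot = 0
    for ui in range(cfg.n_units):
        uid = f"u{ui:03d}"
        amp = float(np.exp(rng.normal(0.0, cfg.unit_amp_jitter))) if cfg.unit_amp_jitter > 0 else 1.0
        ut = UnitTruth(
            unit_id=uid,
            amp_scale=amp,
            g=cfg.pupil_gain_g,
            b=cfg.pupil_baseline_b,
            d=cfg.persist_effect_d if ui in plastic_ids else 0.0,
            plastic=ui in plastic_ids,
            best_frequency=float(2000.0 * 2 ** rng.uniform(-0.4, 0.4)),
            bf_match=True,
        )
        unit_truths[uid] = ut
        spikes = []
        for phase in ("pre", "post"):
            onsets, P = phase_data[phase]
            tmpl = truth.template(uid, fine, phase)
            lam = (1.0 + ut.g * P) * tmpl + ut.b * P
            n_clip += int((lam < 0).sum())
            n_tot += lam.size
            lam = np.clip(lam, 0.0, None)
            counts = rng.poisson(lam * cfg.fine_dt)
            for k, onset in enumerate(onsets):
                idx = np.flatnonzero(counts[k])
                if idx.size == 0:
                    continue
                reps = counts[k, idx]
                t0 = onset + fine[np.repeat(idx, reps)] - cfg.fine_dt / 2
                spikes.append(t0 + rng.random(t0.size) * cfg.fine_dt)
        st = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        units[uid] = UnitSpikes(uid, st, best_frequency=ut.best_frequency, bf_match=True)

    truth.clipped_fraction = n_clip / n_tot if n_tot else 0.0
    if truth.clipped_fraction > cfg.max_clip_fraction:
        raise ConfigError(
            f"rate clipping fraction {truth.clipped_fraction:.3f} exceeds {cfg.max_clip_fraction}"
        )
    if n_clip:
        logger.info("simulate_session: clipped %d negative-rate fine bins (%.4f%%)", n_clip, 100 * truth.clipped_fraction)
    return trials, units, pupil, LickEvents(), truth


# ---------------------------------------------------------------------------
# behaviour experiment


@dataclass
class BehaviorTruth:
    """Injected learning-curve parameters of a behaviour experiment."""

    config: GeneratorConfig
    conditions: pd.DataFrame  # condition_id, vns_condition, t1_high, difficulty, asymptotes
    trial_p: pd.DataFrame  # trial_id, p_respond, generative_delta


def simulate_behavior_experiment(config: GeneratorConfig) -> tuple[pd.DataFrame, LickEvents, BehaviorTruth]:
    """Simulate a multi-condition classical-conditioning experiment.

    Each schedule entry is one 2-d condition (``vns_condition``, whether T1 is
    the higher tone). Within a day the generative ΔR ramps linearly from the
    previous day's endpoint to that day's configured asymptote; responses are
    Bernoulli with p(T1) = base + Δ/2, p(T2) = base - Δ/2. Switch transitions
    (relative T1/T2 frequency order reversed vs the previous condition) have
    their asymptotes scaled by ``switch_penalty``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    rows, licks = [], []
    cond_rows, p_rows = [], []
    t = 0.0
    trial_id = 0
    prev_high: bool | None = None
    n_half = cfg.trials_per_day // 2
    for ci, (cond, t1_high) in enumerate(cfg.schedule):
        f2 = float(10 ** rng.uniform(np.log10(400.0), np.log10(3000.0)))
        ratio = 2.0 ** rng.uniform(2.0, 3.0)
        f1 = f2 * ratio if t1_high else f2 / ratio
        difficulty = "no_switch" if prev_high is None or t1_high == prev_high else "switch"
        prev_high = t1_high
        asym = np.asarray(cfg.learning[cond], dtype=float)
        if difficulty == "switch":
            asym = asym * cfg.switch_penalty
        cond_rows.append(
            dict(condition_id=ci, vns_condition=cond, t1_high=t1_high, difficulty=difficulty,
                 asym_day1=float(asym[0]), asym_day2=float(asym[1]), t1_freq_hz=f1, t2_freq_hz=f2)
        )
        start_delta = 0.0
        for day in (1, 2):
            labels = ["T1"] * n_half + ["T2"] * n_half + ["REF"] * cfg.ref_per_day
            rng.shuffle(labels)
            end_delta = float(asym[day - 1])
            n_targets = 2 * n_half
            ti = 0  # target-trial counter within the day
            for lab in labels:
                onset = t
                offset = onset + cfg.tone_dur_s
                if lab == "REF":
                    p, delta = cfg.ref_resp_p, np.nan
                    vns_cond, vns_onset = "none", np.nan
                    rewarded = False
                else:
                    frac = (ti + 1) / n_targets
                    delta = start_delta + (end_delta - start_delta) * frac
                    p = cfg.base_resp_p + (delta / 2 if lab == "T1" else -delta / 2)
                    p = float(np.clip(p, 0.0, 1.0))
                    vns_cond = cond
                    if cond == "paired":
                        vns_onset = onset - cfg.vns_lead_s
                    else:
                        vns_onset = offset + 0.5 + rng.uniform(0.0, 2.0)
                    rewarded = lab == "T1"
                    ti += 1
                if rng.random() < p:
                    licks.append(rng.uniform(onset + 0.2, offset + 0.15 - 1e-6))
                if rewarded:
                    licks.extend(rng.uniform(offset + 0.25, offset + 1.2, size=2))
                rows.append(
                    dict(
                        trial_id=trial_id, sound_onset=onset, sound_offset=offset, sound_label=lab,
                        is_rewarded=rewarded, vns_condition=vns_cond, vns_onset=vns_onset,
                        session_phase="during", day=day, block_id=ci, animal=cfg.animal,
                        t1_freq_hz=f1, t2_freq_hz=f2,
                    )
                )
                p_rows.append(dict(trial_id=trial_id, p_respond=p, generative_delta=delta))
                trial_id += 1
                t += cfg.trial_period_s
            start_delta = end_delta
            t += cfg.day_gap_s
    trials = pd.DataFrame(rows)
    validate_trials(trials, vns_lead_s=(cfg.vns_lead_s,))
    truth = BehaviorTruth(config=cfg, conditions=pd.DataFrame(cond_rows), trial_p=pd.DataFrame(p_rows))
    return trials, LickEvents(np.sort(np.asarray(licks))), truth


# ---------------------------------------------------------------------------
# cuff-validation pupillometry (VNS in silence)


def simulate_vns_pupil_validation(
    config: GeneratorConfig,
    n_vns: int = 20,
    inter_vns_s: float = 40.0,
    noise: bool = True,
) -> tuple[PupilTrace, np.ndarray, PupilTrace]:
    """Pupillometry-only cuff-validation session: VNS pulses in silence.

    Stimulations are spaced ``inter_vns_s`` apart so successive dilation
    kernels do not overlap, matching the paradigm used to validate cuff
    function. With ``noise=False`` the trace is the bare kernel train on the
    baseline diameter (generator identity). Returns
    ``(observed_trace, vns_onsets, clean_trace)``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    t_end = cfg.lead_in_s + n_vns * inter_vns_s + 20.0
    n = int(np.ceil(t_end * cfg.fs_pupil))
    ts = np.arange(n) / cfg.fs_pupil
    onsets = cfg.lead_in_s + np.arange(n_vns) * inter_vns_s

    frac = np.zeros(n)
    for v in onsets:
        frac += cfg.dilation_amp_frac * _dilation_kernel(ts - v, cfg.dilation_peak_s, cfg.dilation_shape)
    if noise:
        innov = rng.normal(0.0, cfg.pupil_ar_sd, size=n)
        drift = np.empty(n)
        rho = cfg.pupil_ar_coef
        drift[0] = innov[0] / np.sqrt(1 - rho**2)
        for i in range(1, n):
            drift[i] = rho * drift[i - 1] + innov[i]
        frac = frac + drift
    clean = np.clip(cfg.base_diameter_px * (1.0 + frac), 1e-3, None)
    observed = clean.copy()
    if noise:
        n_blinks = rng.poisson(cfg.blink_rate_per_min * t_end / 60.0)
        for bt in np.sort(rng.uniform(5.0, t_end - 5.0, size=n_blinks)):
            dur = rng.uniform(*cfg.blink_dur_range_s)
            m = (ts >= bt) & (ts < bt + dur)
            if m.any():
                tau = (ts[m] - bt) / dur
                observed[m] *= 1.0 - 0.95 * (1.0 - np.abs(2 * tau - 1.0))
    return PupilTrace(ts, observed), onsets, PupilTrace(ts.copy(), clean)


# ---------------------------------------------------------------------------
# gating records


def simulate_gating_records(
    n: int, rho: float, seed: int, dilation_mean: float = 0.1, dilation_sd: float = 0.03,
    magnitude_mean: float = 6.0, magnitude_sd: float = 1.5,
) -> list[GatingRecord]:
    """Unit-level gating records with a configurable true Pearson coupling
    between VNS-evoked dilation and persistent-change magnitude."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    dil = dilation_mean + dilation_sd * z1
    mag = np.clip(magnitude_mean + magnitude_sd * z2, 0.0, None)
    return [GatingRecord(f"u{i:03d}", float(dil[i]), float(mag[i])) for i in range(n)]


def null_config(seed: int = 0, n_units: int = 5, **overrides) -> GeneratorConfig:
    """Convenience: a config with no injected effect of any kind (d = g = b = 0)."""
    return replace(
        GeneratorConfig(seed=seed, n_units=n_units),
        pupil_gain_g=0.0, pupil_baseline_b=0.0, persist_effect_d=0.0, plastic_fraction=0.0,
        **overrides,
    )
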