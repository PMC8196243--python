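"""Synthetic session generator.

Produces the full data structure the analysis stages consume — trial
metadata, spike tables, spike waveforms, eye traces and reaction times —
from explicit ground-truth parameters, so that every downstream stage can be
validated against known planted effects.

Trial structure: 3 attention locations x 2 motion directions x 3 dimming
orders, run in blocks of 36 trials (2 repetitions of the 18 cells) with the
drug state held constant within a block.  Spike counts follow a
doubly-stochastic (modulated Poisson) model: counts in any window are
Poisson(G * mu) with G gamma-distributed across trials (mean 1, variance
``gain_variance``), which makes window counts negative-binomial with
variance mu + gain_variance * mu^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "GroundTruthUnit",
    "EyeTrace",
    "SessionData",
    "generate_session",
    "generate_trials",
    "generate_spikes",
    "generate_waveforms",
    "generate_eye_traces",
    "default_unit_population",
]

ATTENTION_LEVELS = ("RF", "away1", "away2")
MOTION_LEVELS = ("dir1", "dir2")
DRUG_LEVELS = ("off", "on")

#: native waveform sampling interval (us), acquisition-grade grid
NATIVE_WAVEFORM_DT_US = 1e6 / 32_556.0  # ~30.72 us


@dataclass
class TaskConfig:
    """Parameters of the attention task emulated by the generator."""

    n_attention_locations: int = 3
    n_motion_directions: int = 2
    drug_levels: tuple[str, str] = DRUG_LEVELS
    n_dimming_orders: int = 3
    cue_delay_range: tuple[float, float] = (300.0, 1400.0)
    dim_interval_range: tuple[float, float] = (600.0, 1750.0)
    stim_delay: float = 500.0
    block_length_min: int = 36
    trials_per_condition: int = 60
    response_window: float = 600.0
    rt_mean: float = 350.0
    rt_sd: float = 45.0
    miss_rate: float = 0.002
    false_alarm_rate: float = 0.002
    fixation_break_rate: float = 0.002
    seed: int | None = None

    def __post_init__(self) -> None:
        reps = 2
        cells = self.n_attention_locations * self.n_motion_directions * self.n_dimming_orders
        if cells * reps != self.block_length_min:
            raise ValueError(
                f"block structure inconsistent: {cells} condition cells x {reps} reps "
                f"!= block_length_min={self.block_length_min}"
            )
        lo, hi = self.cue_delay_range
        if not (0 < lo <= hi):
            raise ValueError("cue_delay_range must be a positive interval")
        lo, hi = self.dim_interval_range
        if not (0 < lo <= hi):
            raise ValueError("dim_interval_range must be a positive interval")
        if self.trials_per_condition < 10:
            raise ValueError("trials_per_condition must be >= 10")


@dataclass
class GroundTruthUnit:
    """Generative parameters for one unit.

    Epoch firing rate on a trial is
    ``baseline_rate * epoch_gain * attention_factor * drug_factor * G`` where
    the attention factor (``attention_effect``) applies from cue onset on
    attend-RF trials only, the drug factor (``drug_gain``) applies on drug-on
    trials, and G is the per-trial gamma gain.
    """

    unit_id: str
    baseline_rate: float
    stim_gain: float = 1.5
    cue_gain: float = 1.2
    predim_attend_gain: float = 1.4
    drug_gain: float = 1.0
    attention_effect: float = 1.0
    gain_variance: float = 0.0
    p2t_us: float = 300.0
    cell_class: str = "broad"
    cluster_label: str = "B1"
    response_type: str = "other"

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline_rate) or self.baseline_rate <= 0:
            raise ValueError(f"{self.unit_id}: baseline_rate must be finite and > 0")
        for name in ("stim_gain", "cue_gain", "predim_attend_gain", "attention_effect"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{self.unit_id}: {name} must be finite and >= 0")
        if not (0 < self.drug_gain <= 1):
            raise ValueError(f"{self.unit_id}: drug_gain must be in (0, 1]")
        if self.gain_variance < 0:
            raise ValueError(f"{self.unit_id}: gain_variance must be >= 0")
        if self.p2t_us <= 0:
            raise ValueError(f"{self.unit_id}: p2t_us must be > 0")


@dataclass
class EyeTrace:
    """One trial's eye-position trace at 250 Hz with injected ground truth."""

    trial_id: int
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    injected: list[tuple[float, float, float]] = field(default_factory=list)
    # each injected event: (onset_ms, amplitude_deg, direction_rad)


@dataclass
class SessionData:
    trials: pd.DataFrame
    spikes: pd.DataFrame
    waveforms: pd.DataFrame
    eyes: list[EyeTrace]
    rts: pd.DataFrame
    units: list[GroundTruthUnit]
    config: TaskConfig
    seed: int

    def ground_truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": asdict(self.config),
            "units": [asdict(u) for u in self.units],
        }


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    return int(seed)


def generate_trials(task: TaskConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate trial metadata in drug-alternating blocks until every
    (attention, motion, drug) cell has at least ``trials_per_condition``
    correct (hit) trials."""
    seed = _require_seed(seed if seed is not None else task.seed)
    rng = np.random.default_rng(seed)

    cells = [
        (a, m, d)
        for a in ATTENTION_LEVELS
        for m in MOTION_LEVELS
        for d in range(1, task.n_dimming_orders + 1)
    ]
    target = task.trials_per_condition
    hit_counts: dict[tuple[str, str, str], int] = {
        (a, m, dr): 0 for a in ATTENTION_LEVELS for m in MOTION_LEVELS for dr in DRUG_LEVELS
    }

    rows = []
    trial_id = 0
    block_id = 0
    while min(hit_counts.values()) < target:
        drug = DRUG_LEVELS[block_id % 2]
        block = cells * 2  # 2 repetitions per block
        order = rng.permutation(len(block))
        for within_idx, j in enumerate(order, start=1):
            att, mot, dim_order = block[j]
            trial_id += 1
            t_fix = 0.0
            t_stim = task.stim_delay
            t_cue = t_stim + rng.uniform(*task.cue_delay_range)
            dims = [t_cue + rng.uniform(*task.dim_interval_range)]
            for _ in range(dim_order - 1):
                dims.append(dims[-1] + rng.uniform(*task.dim_interval_range))
            t_target_dim = dims[-1]

            u = rng.uniform()
            if u < task.fixation_break_rate:
                outcome = "fixation_break"
            elif u < task.fixation_break_rate + task.miss_rate:
                outcome = "miss"
            elif (
                u < task.fixation_break_rate + task.miss_rate + task.false_alarm_rate
                and dim_order > 1
            ):
                outcome = "false_alarm"
            else:
                outcome = "hit"

            t_dim = [np.nan] * 3
            t_response = np.nan
            if outcome == "fixation_break":
                # break at a random time before the first dimming
                t_break = rng.uniform(t_stim, dims[0])
                t_cue_out = t_cue if t_cue < t_break else np.nan
                t_end = t_break
            else:
                t_cue_out = t_cue
                if outcome == "false_alarm":
                    # release on the first distractor dimming
                    n_dims_seen = 1
                    rt = float(np.clip(rng.normal(task.rt_mean, task.rt_sd), 150.0, task.response_window - 1))
                    t_response = dims[0] + rt
                    t_end = t_response
                else:
                    n_dims_seen = dim_order
                    if outcome == "hit":
                        rt = float(np.clip(rng.normal(task.rt_mean, task.rt_sd), 150.0, task.response_window - 1))
                        t_response = t_target_dim + rt
                        t_end = t_response
                    else:  # miss
                        t_end = t_target_dim + task.response_window
                for i in range(n_dims_seen):
                    t_dim[i] = dims[i]

            rows.append(
                dict(
                    trial_id=trial_id,
                    block_id=block_id,
                    within_block_index=within_idx,
                    attention=att,
                    motion=mot,
                    drug=drug,
                    dimming_order=dim_order,
                    t_fixation_on=t_fix,
                    t_stimulus_on=t_stim,
                    t_cue_on=t_cue_out,
                    t_dim1=t_dim[0],
                    t_dim2=t_dim[1],
                    t_dim3=t_dim[2],
                    t_response=t_response,
                    t_end=t_end,
                    outcome=outcome,
                )
            )
            if outcome == "hit":
                hit_counts[(att, mot, drug)] += 1
        block_id += 1
    return pd.DataFrame(rows)


def _segment_rates(unit: GroundTruthUnit, trial, transient_ms: float, predim_ms: float):
    """Piecewise-constant rate segments for one unit x trial.

    Returns (starts, ends, rates_hz) ignoring the per-trial gain G.
    """
    base = unit.baseline_rate
    att = unit.attention_effect if trial.attention == "RF" else 1.0
    drug = unit.drug_gain if trial.drug == "on" else 1.0
    t_stim = trial.t_stimulus_on
    t_cue = trial.t_cue_on
    t_dim1 = trial.t_dim1
    t_end = trial.t_end

    bounds = [0.0, t_stim]
    rates = [base]
    # stimulus transient then return toward baseline-level sustained activity
    t_trans_end = t_stim + transient_ms
    if not np.isnan(t_cue):
        t_trans_end = min(t_trans_end, t_cue)
    bounds.append(t_trans_end)
    rates.append(base * unit.stim_gain)
    if not np.isnan(t_cue):
        if t_cue > t_trans_end:
            bounds.append(t_cue)
            rates.append(base)
        if not np.isnan(t_dim1):
            t_predim = max(t_cue, t_dim1 - predim_ms)
            if t_predim > t_cue:
                bounds.append(t_predim)
                rates.append(base * unit.cue_gain * att)
            bounds.append(t_end)
            rates.append(base * unit.predim_attend_gain * att)
        else:
            bounds.append(t_end)
            rates.append(base * unit.cue_gain * att)
    else:
        bounds.append(t_end)
        rates.append(base)
    return np.asarray(bounds[:-1]), np.asarray(bounds[1:]), np.asarray(rates) * drug


def generate_spikes(
    trials: pd.DataFrame,
    units: Sequence[GroundTruthUnit],
    seed: int | None = None,
    transient_ms: float = 300.0,
    predim_ms: float = 500.0,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike tables with per-trial multiplicative gain."""
    seed = _require_seed(seed)
    if len(units) < 1:
        raise ValueError("at least one unit required")
    rng = np.random.default_rng(seed)

    out_unit, out_trial, out_time = [], [], []
    trial_tuples = list(trials.itertuples(index=False))
    for unit in units:
        if unit.gain_variance > 0:
            shape = 1.0 / unit.gain_variance
            gains = rng.gamma(shape, scale=unit.gain_variance, size=len(trial_tuples))
        else:
            gains = np.ones(len(trial_tuples))
        for g, tr in zip(gains, trial_tuples):
            starts, ends, rates = _segment_rates(unit, tr, transient_ms, predim_ms)
            durs = (ends - starts) / 1000.0
            counts = rng.poisson(np.clip(rates * durs * g, 0, None))
            n = int(counts.sum())
            if n == 0:
                continue
            seg_idx = np.repeat(np.arange(len(starts)), counts)
            times = starts[seg_idx] + rng.uniform(size=n) * (ends - starts)[seg_idx]
            times.sort()
            out_unit.append(np.full(n, unit.unit_id, dtype=object))
            out_trial.append(np.full(n, tr.trial_id))
            out_time.append(times)

    if not out_unit:
        return pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_ms"])
    return pd.DataFrame(
        {
            "unit_id": np.concatenate(out_unit),
            "trial_id": np.concatenate(out_trial),
            "spike_time_ms": np.concatenate(out_time),
        }
    )


def _waveform_template(p2t_us: float, t_us: np.ndarray) -> np.ndarray:
    """Noiseless extracellular-like waveform: negative trough followed by a
    positive peak whose continuous-time extrema are exactly ``p2t_us`` apart.

    The sum of two Gaussians shifts the extrema slightly when the lobes
    overlap, so the peak-centre offset is calibrated numerically.
    """
    t_trough = 400.0
    # sharp extrema keep the measured P2T robust to additive sample noise;
    # widths shrink with P2T so the two lobes stay resolvable
    sig1 = min(60.0, 0.45 * p2t_us)
    sig2 = max(35.0, 0.2 * p2t_us)
    amp2 = 0.7

    def wave(t, peak_centre):
        return -np.exp(-0.5 * ((t - t_trough) / sig1) ** 2) + amp2 * np.exp(
            -0.5 * ((t - peak_centre) / sig2) ** 2
        )

    fine = np.arange(0.0, float(t_us[-1]) + 1.0, 0.25)
    centre = t_trough + p2t_us
    for _ in range(8):
        w = wave(fine, centre)
        i_tr = int(np.argmin(w))
        after = w[i_tr:]
        i_pk = i_tr + int(np.argmax(after))
        measured = fine[i_pk] - fine[i_tr]
        err = p2t_us - measured
        if abs(err) < 0.25:
            break
        centre += err
    return wave(t_us, centre)


def generate_waveforms(
    units: Sequence[GroundTruthUnit],
    native_dt_us: float = NATIVE_WAVEFORM_DT_US,
    n_samples: int = 48,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Waveform sample matrix at the native (coarse) sampling grid.

    The noiseless trough-to-peak distance of each waveform equals the unit's
    ``p2t_us`` (up to the fine calibration grid, ~0.25 us).
    """
    t_us = np.arange(n_samples) * native_dt_us
    max_p2t = max(u.p2t_us for u in units)
    if t_us[-1] < 400.0 + max_p2t + 200.0:
        raise ValueError(
            f"n_samples={n_samples} too small to contain trough and peak "
            f"(needs >= {(400.0 + max_p2t + 200.0) / native_dt_us:.0f} samples)"
        )
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    rows = {}
    for u in units:
        w = _waveform_template(u.p2t_us, t_us)
        if noise_sd > 0:
            w = w + rng.normal(0.0, noise_sd * np.abs(w).max(), size=w.shape)
        rows[u.unit_id] = w
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"s{i}" for i in range(n_samples)])
    df.index.name = "unit_id"
    df.attrs["native_dt_us"] = native_dt_us
    return df.reset_index()


def _microsaccade_profile(n_samples: int) -> np.ndarray:
    """Smooth displacement profile 0 -> 1 (raised-cosine velocity)."""
    s = np.arange(1, n_samples + 1) / n_samples
    return (1.0 - np.cos(np.pi * s)) / 2.0


def generate_eye_traces(
    trials: pd.DataFrame,
    microsaccade_rate: float = 1.5,
    amplitude_dist: Callable[[np.random.Generator], float] | None = None,
    seed: int | None = None,
    noise_sd: float = 0.02,
    fs_hz: float = 250.0,
    event_duration_samples: int = 6,
) -> list[EyeTrace]:
    """Fixation eye traces with injected microsaccades.

    Traces span [fixation + 300 ms, first dimming) per trial; injected event
    counts are Poisson(rate * duration) with ground truth stored for
    validating the detector.
    """
    seed = _require_seed(seed)
    if microsaccade_rate < 0:
        raise ValueError("microsaccade_rate must be >= 0")
    rng = np.random.default_rng(seed)
    if amplitude_dist is None:
        amplitude_dist = lambda r: float(r.uniform(0.2, 0.5))

    dt_ms = 1000.0 / fs_hz
    profile = _microsaccade_profile(event_duration_samples)
    traces: list[EyeTrace] = []
    for tr in trials.itertuples(index=False):
        t_start = tr.t_fixation_on + 300.0
        t_stop = tr.t_dim1 if not np.isnan(tr.t_dim1) else tr.t_end
        n = int(np.floor((t_stop - t_start) / dt_ms))
        if n < 10:
            continue
        t_ms = t_start + np.arange(n) * dt_ms
        x = rng.normal(0.0, noise_sd, n)
        y = rng.normal(0.0, noise_sd, n)
        dur_s = n * dt_ms / 1000.0
        n_events = rng.poisson(microsaccade_rate * dur_s)
        injected = []
        margin = event_duration_samples + 4
        if n_events > 0 and n > 2 * margin:
            onsets = np.sort(rng.choice(np.arange(margin, n - margin), size=n_events, replace=False)) if n_events < n - 2 * margin else []
            last_end = -margin
            for onset_idx in onsets:
                if onset_idx < last_end + margin:
                    continue
                amp = float(amplitude_dist(rng))
                if amp <= 0:
                    raise ValueError("injected amplitude must be > 0")
                direction = float(rng.uniform(0, 2 * np.pi))
                dx = amp * np.cos(direction) * profile
                dy = amp * np.sin(direction) * profile
                x[onset_idx : onset_idx + event_duration_samples] += dx
                x[onset_idx + event_duration_samples :] += dx[-1]
                y[onset_idx : onset_idx + event_duration_samples] += dy
                y[onset_idx + event_duration_samples :] += dy[-1]
                injected.append((float(t_ms[onset_idx]), amp, direction))
                last_end = onset_idx + event_duration_samples
        traces.append(EyeTrace(tr.trial_id, t_ms, x, y, injected))
    return traces


def default_unit_population(
    n_units: int,
    seed: int | None = None,
    narrow_fraction: float = 0.4,
    attention_effect_mean: float = 1.4,
    drug_gain_mean: float = 0.78,
    gain_variance_mean: float = 0.15,
) -> list[GroundTruthUnit]:
    """A plausible heterogeneous population.

    Distribution shapes across units are choices of this artifact (population
    summaries constrain only their central tendencies); all parameters are
    explicit so tests can override them.
    """
    seed = _require_seed(seed)
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        narrow = rng.uniform() < narrow_fraction
        p2t = float(np.clip(rng.normal(165, 28), 80, 235)) if narrow else float(
            np.clip(rng.normal(390, 65), 260, 650)
        )
        base = float(np.clip(rng.lognormal(np.log(10.0), 0.5), 1.0, 80.0))
        att = float(np.clip(rng.normal(attention_effect_mean, 0.15), 1.0, 2.5))
        drug = float(np.clip(rng.normal(drug_gain_mean, 0.08), 0.4, 1.0))
        gv = float(np.clip(rng.gamma(2.0, gain_variance_mean / 2.0), 0.0, 1.0))
        r = rng.uniform()
        if r < 0.25:
            resp, sgain, pgain = "visual", 2.0, 0.9
        elif r < 0.55:
            resp, sgain, pgain = "visuo-attention", 1.6, 1.8
        elif r < 0.65:
            resp, sgain, pgain = "attention", 1.05, 1.6
        else:
            resp, sgain, pgain = "other", 1.1, 1.0
        units.append(
            GroundTruthUnit(
                unit_id=f"u{i:03d}",
                baseline_rate=base,
                stim_gain=sgain,
                cue_gain=1.1,
                predim_attend_gain=pgain,
                drug_gain=drug,
                attention_effect=att,
                gain_variance=gv,
                p2t_us=p2t,
                cell_class="narrow" if narrow else "broad",
                cluster_label="N1" if narrow else "B1",
                response_type=resp,
            )
        )
    return units


def generate_session(
    task: TaskConfig,
    units: Sequence[GroundTruthUnit],
    seed: int | None = None,
    microsaccade_rate: float = 1.5,
    with_eyes: bool = True,
    with_waveforms: bool = True,
) -> SessionData:
    """Generate a complete synthetic recording session."""
    seed = _require_seed(seed if seed is not None else task.seed)
    if len(units) < 1:
        raise ValueError("at least one unit required")
    ss = np.random.SeedSequence(seed)
    s_trials, s_spikes, s_waves, s_eyes = (int(c.generate_state(1)[0]) for c in ss.spawn(4))

    trials = generate_trials(task, seed=s_trials)
    spikes = generate_spikes(trials, units, seed=s_spikes)
    waveforms = (
        generate_waveforms(units, noise_sd=0.02, seed=s_waves)
        if with_waveforms
        else pd.DataFrame()
    )
    eyes = (
        generate_eye_traces(trials, microsaccade_rate=microsaccade_rate, seed=s_eyes)
        if with_eyes
        else []
    )
    hits = trials[trials.outcome == "hit"]
    rts = pd.DataFrame(
        {
            "trial_id": hits.trial_id,
            "attention": hits.attention,
            "drug": hits.drug,
            "rt_ms": hits.t_response
            - hits.apply(lambda r: [r.t_dim1, r.t_dim2, r.t_dim3][int(r.dimming_order) - 1], axis=1),
        }
    )
    return SessionData(trials, spikes, waveforms, eyes, rts, list(units), task, seed)
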