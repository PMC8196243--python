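"""Tabular I/O, trial filtering and epoch extraction.

All analysis windows are half-open ``[start, end)`` in ms relative to their
anchor event; all times are ms from trial start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EyeTrace, SessionData

__all__ = [
    "EpochWindow",
    "EPOCH_WINDOWS",
    "filter_trials",
    "excluded_conditions",
    "epoch_rates",
    "write_session",
    "read_trials",
    "read_spikes",
    "read_waveforms",
    "read_eyes",
]


@dataclass(frozen=True)
class EpochWindow:
    """Analysis window anchored to a trial event, half-open [start, end)."""

    name: str
    anchor: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError(f"epoch {self.name}: end must exceed start")

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


EPOCH_WINDOWS: dict[str, EpochWindow] = {
    "post_stim": EpochWindow("post_stim", "t_stimulus_on", 100.0, 400.0),
    "post_cue": EpochWindow("post_cue", "t_cue_on", 100.0, 400.0),
    "pre_dim": EpochWindow("pre_dim", "t_dim1", -500.0, 0.0),
    # pre-stimulus baseline window used for response typing
    "baseline": EpochWindow("baseline", "t_stimulus_on", -300.0, 0.0),
}


def filter_trials(trials: pd.DataFrame, n_block_start_excluded: int = 6) -> pd.DataFrame:
    """Correct trials with the first trials of every block removed.

    ``within_block_index`` is 1-based, so a block of 36 all-correct trials
    retains 30.
    """
    if "within_block_index" not in trials.columns:
        raise ValueError("trials table lacks within_block_index (block index required)")
    keep = (trials["outcome"] == "hit") & (trials["within_block_index"] > n_block_start_excluded)
    return trials.loc[keep].reset_index(drop=True)


def excluded_conditions(trials: pd.DataFrame, min_trials: int = 10) -> pd.DataFrame:
    """Conditions (attention x motion x drug) with fewer than ``min_trials``
    surviving trials; a non-empty result excludes the session/unit from
    condition-resolved analyses."""
    counts = (
        trials.groupby(["attention", "motion", "drug"], observed=True)
        .size()
        .rename("n_trials")
        .reset_index()
    )
    return counts[counts.n_trials < min_trials].reset_index(drop=True)


def epoch_rates(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    windows: dict[str, EpochWindow] | None = None,
    unit_ids: list | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Spike counts and rates per (unit, trial, epoch).

    Counts use half-open windows; trials lacking the anchor event (NaN) are
    dropped for that epoch only.  Trials with zero spikes contribute rows
    with count 0.  Spikes on trials absent from the (possibly filtered)
    trial table are ignored unless ``strict``.
    """
    if windows is None:
        windows = EPOCH_WINDOWS
    if unit_ids is None:
        unit_ids = sorted(spikes["unit_id"].unique())
    if strict:
        missing = set(spikes["trial_id"].unique()) - set(trials["trial_id"])
        if missing:
            raise ValueError(f"spikes reference unknown trials: {sorted(missing)[:5]} ...")
    spikes = spikes[spikes["trial_id"].isin(set(trials["trial_id"]))]

    frames = []
    for win in windows.values():
        if win.anchor not in trials.columns:
            raise ValueError(f"anchor event {win.anchor!r} missing from trials table")
        tt = trials[["trial_id", win.anchor]].dropna()
        anchor = tt.set_index("trial_id")[win.anchor]
        sp = spikes[spikes["trial_id"].isin(anchor.index)]
        rel = sp["spike_time_ms"].to_numpy() - anchor.reindex(sp["trial_id"]).to_numpy()
        in_win = (rel >= win.start_ms) & (rel < win.end_ms)
        counts = (
            sp.loc[in_win]
            .groupby(["unit_id", "trial_id"], observed=True)
            .size()
            .rename("spike_count")
        )
        grid = pd.MultiIndex.from_product([unit_ids, anchor.index], names=["unit_id", "trial_id"])
        counts = counts.reindex(grid, fill_value=0).reset_index()
        counts["epoch"] = win.name
        counts["duration_s"] = win.duration_s
        counts["rate"] = counts["spike_count"] / win.duration_s
        frames.append(counts)
    out = pd.concat(frames, ignore_index=True)
    cols = ["attention", "motion", "drug", "outcome"]
    have = [c for c in cols if c in trials.columns]
    return out.merge(trials[["trial_id"] + have], on="trial_id", how="left")


# ---------------------------------------------------------------------------
# CSV round-trip


def write_session(session: SessionData, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["trials"] = outdir / "trials.csv"
    session.trials.to_csv(paths["trials"], index=False)
    paths["spikes"] = outdir / "spikes.csv"
    session.spikes.to_csv(paths["spikes"], index=False)
    if len(session.waveforms):
        paths["waveforms"] = outdir / "waveforms.csv"
        session.waveforms.to_csv(paths["waveforms"], index=False)
    if session.eyes:
        paths["eyes"] = outdir / "eyes.csv"
        rows = []
        for tr in session.eyes:
            rows.append(
                pd.DataFrame(
                    {"trial_id": tr.trial_id, "t_ms": tr.t_ms, "x_deg": tr.x_deg, "y_deg": tr.y_deg}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(paths["eyes"], index=False)
        paths["eye_events"] = outdir / "eye_events_truth.csv"
        ev = [
            dict(trial_id=tr.trial_id, onset_ms=o, amplitude_deg=a, direction_rad=d)
            for tr in session.eyes
            for (o, a, d) in tr.injected
        ]
        pd.DataFrame(ev, columns=["trial_id", "onset_ms", "amplitude_deg", "direction_rad"]).to_csv(
            paths["eye_events"], index=False
        )
    paths["rts"] = outdir / "rts.csv"
    session.rts.to_csv(paths["rts"], index=False)
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(session.ground_truth_dict(), fh, indent=1)
    return paths


def read_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_spikes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_waveforms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_eyes(path: str | Path, truth_path: str | Path | None = None) -> list[EyeTrace]:
    df = pd.read_csv(path)
    truth: dict[int, list] = {}
    if truth_path is not None and Path(truth_path).exists():
        tdf = pd.read_csv(truth_path)
        for tr in tdf.itertuples(index=False):
            truth.setdefault(tr.trial_id, []).append(
                (tr.onset_ms, tr.amplitude_deg, tr.direction_rad)
            )
    traces = []
    for tid, g in df.groupby("trial_id"):
        traces.append(
            EyeTrace(
                int(tid),
                g["t_ms"].to_numpy(),
                g["x_deg"].to_numpy(),
                g["y_deg"].to_numpy(),
                truth.get(tid, []),
            )
        )
    return traces
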