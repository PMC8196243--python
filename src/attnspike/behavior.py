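"""Behavioral analyses: signal detection, reaction times, error rates and
microsaccades.

Microsaccade detection follows the velocity-threshold approach: 2-D eye
velocity from a 5-point moving-window derivative, an elliptic threshold at
``lambda`` times a median-based velocity SD per axis, and a minimum event
duration in samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .synthetic import EyeTrace

__all__ = [
    "dprime",
    "guessing_hit_rate",
    "normalize_rts",
    "rt_anova",
    "error_rate_tests",
    "Microsaccade",
    "detect_microsaccades",
]


def dprime(hit_rate: float, fa_rate: float, n_clip: int | None = None) -> float:
    """Signal-detection d' = Phi^-1(hit) - Phi^-1(fa).

    Rates of exactly 0 or 1 are infinite unless ``n_clip`` is given, in
    which case they are clipped to 1/(2N) from the boundary.
    """
    rates = []
    for r in (hit_rate, fa_rate):
        if not (0 <= r <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if r in (0.0, 1.0):
            if n_clip is None:
                raise ValueError("rate of 0 or 1 is degenerate; provide n_clip")
            eps = 1.0 / (2 * n_clip)
            r = eps if r == 0.0 else 1.0 - eps
        rates.append(r)
    return float(st.norm.ppf(rates[0]) - st.norm.ppf(rates[1]))


def guessing_hit_rate(n_dimming_events: int = 3) -> float:
    """Hit probability of releasing at one uniformly guessed dimming event
    when the target event is itself uniform over the sequence."""
    if n_dimming_events < 1:
        raise ValueError("need at least one dimming event")
    return 1.0 / n_dimming_events


def simulate_guessing_hit_rate(n_dimming_events: int, n_trials: int, seed: int) -> float:
    """Monte-Carlo check of the guessing model."""
    rng = np.random.default_rng(seed)
    target = rng.integers(0, n_dimming_events, n_trials)
    guess = rng.integers(0, n_dimming_events, n_trials)
    return float(np.mean(target == guess))


def normalize_rts(rts: pd.DataFrame, min_trials: int = 5) -> pd.DataFrame:
    """Divide each RT by its session's grand mean (across all attention and
    drug conditions).  Sessions with fewer than ``min_trials`` trials are
    excluded.  Requires a ``session`` column."""
    if "session" not in rts.columns:
        raise ValueError("rts table needs a session column")
    out = []
    for sess, g in rts.groupby("session"):
        if len(g) < min_trials:
            continue
        g = g.copy()
        g["rt_norm"] = g["rt_ms"] / g["rt_ms"].mean()
        out.append(g)
    if not out:
        return rts.iloc[0:0].assign(rt_norm=[])
    return pd.concat(out, ignore_index=True)


def rt_anova(normalized: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-factor (attention x drug) ANOVA on single-trial normalized RTs,
    plus rank-sum post hocs on the drug contrast within each attention
    level."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("rt_norm ~ C(attention) * C(drug)", data=normalized).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    sse = tab.loc["Residual", "sum_sq"]
    tab["eta2p"] = tab["sum_sq"] / (tab["sum_sq"] + sse)
    tab.loc["Residual", "eta2p"] = np.nan

    posthoc = []
    for att, g in normalized.groupby("attention", observed=True):
        a = g.loc[g["drug"] == "off", "rt_norm"]
        b = g.loc[g["drug"] == "on", "rt_norm"]
        if len(a) > 1 and len(b) > 1:
            z, p = st.ranksums(a, b)
            posthoc.append(dict(attention=att, z=z, p=p, n_off=len(a), n_on=len(b)))
    return tab, pd.DataFrame(posthoc)


def error_rate_tests(counts: np.ndarray) -> dict:
    """Pearson chi-square (1 df, uncorrected) on a 2x2 drug x correct/error
    table; fixation breaks must already be removed."""
    import warnings

    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if counts.sum() == 0:
        raise ValueError("empty table")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    if (expected < 5).any():
        warnings.warn("expected cell count < 5; chi-square approximation unstable", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = float(np.nansum(np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)))
    p = float(st.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return dict(chi2=chi2, p=p, df=1, expected=expected)


@dataclass
class Microsaccade:
    trial_id: int
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity: float
    direction_rad: float


def _velocity(x: np.ndarray, dt_s: float) -> np.ndarray:
    """5-point moving-window derivative (deg/s); endpoints padded with 0."""
    v = np.zeros_like(x)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
    return v


def detect_microsaccades(
    trace: EyeTrace,
    lam: float = 6.0,
    min_duration_samples: int = 3,
    fs_hz: float = 250.0,
) -> tuple[list[Microsaccade], float]:
    """Velocity-threshold microsaccade detection on one trial.

    Returns (events, rate in Hz); the rate divides the event count by the
    analyzed trace duration.
    """
    x, y, t = trace.x_deg, trace.y_deg, trace.t_ms
    if x.size < 10:
        raise ValueError("trace too short")
    dt_s = 1.0 / fs_hz
    vx = _velocity(x, dt_s)
    vy = _velocity(y, dt_s)
    events: list[Microsaccade] = []
    thresholds = []
    for v in (vx, vy):
        sd = np.sqrt(np.median(v**2) - np.median(v) ** 2)
        if sd <= 0:
            sd = np.std(v) if np.std(v) > 0 else 1e-9
        thresholds.append(lam * sd)
    crit = (vx / thresholds[0]) ** 2 + (vy / thresholds[1]) ** 2 > 1.0
    # contiguous supra-threshold runs of sufficient duration
    idx = np.flatnonzero(crit)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        for s, e in zip(starts, ends):
            if e - s + 1 < min_duration_samples:
                continue
            dx = x[e] - x[s]
            dy = y[e] - y[s]
            amp = float(np.hypot(dx, dy))
            pv = float(np.max(np.hypot(vx[s : e + 1], vy[s : e + 1])))
            events.append(
                Microsaccade(
                    trial_id=trace.trial_id,
                    onset_ms=float(t[s]),
                    offset_ms=float(t[e]),
                    amplitude_deg=amp,
                    peak_velocity=pv,
                    direction_rad=float(np.arctan2(dy, dx)),
                )
            )
    duration_s = x.size * dt_s
    return events, len(events) / duration_s
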