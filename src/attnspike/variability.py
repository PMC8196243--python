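"""Trial-to-trial rate variability: Fano factor and gain-variance fits.

Spike counts in a fixed window are modeled as negative-binomial with
variance mu + sigma2_g * mu^2, i.e. Poisson counts modulated by a
trial-wise multiplicative gain with mean 1 and variance sigma2_g.  The
gain-variance term is fit directly (by maximum likelihood in the (mu,
sigma2_g) parameterization) and is only reported when the sample variance
exceeds the sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import minimize_scalar

__all__ = [
    "fano_factor",
    "GainFit",
    "fit_gain_variance",
    "gain_fits_by_group",
    "variability_anova",
]


def fano_factor(counts: np.ndarray) -> float:
    """Sample variance / sample mean of spike counts; NaN for mean 0."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        return np.nan
    m = counts.mean()
    if m == 0:
        return np.nan
    return float(counts.var(ddof=1) / m)


@dataclass
class GainFit:
    mu: float
    gain_variance: float
    valid: bool
    n_trials: int
    method: str = "mle"


def _nb_negloglik(log_s2g: float, counts: np.ndarray, mu: float) -> float:
    s2g = np.exp(log_s2g)
    r = 1.0 / s2g
    p = r / (r + mu)
    return -float(np.sum(st.nbinom.logpmf(counts, r, p)))


def fit_gain_variance(counts: np.ndarray, min_trials: int = 10) -> GainFit:
    """Maximum-likelihood negative-binomial fit of the gain variance.

    The mean parameter's MLE is the sample mean, so the fit reduces to a 1-D
    optimization of sigma2_g.  Not attempted (valid=False) when the sample
    variance is below the sample mean; falls back to the moment estimator
    (var - mean) / mean^2 when the likelihood optimization fails.
    """
    counts = np.asarray(counts)
    if counts.size < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    mu = float(counts.mean())
    var = float(counts.var(ddof=1))
    n = counts.size
    if var < mu or mu == 0:
        return GainFit(mu=mu, gain_variance=np.nan, valid=False, n_trials=n, method="gated")
    moment = (var - mu) / mu**2
    try:
        lo = np.log(max(moment / 50.0, 1e-8))
        hi = np.log(max(moment * 50.0, 1e-6))
        res = minimize_scalar(
            _nb_negloglik, bounds=(lo, hi), args=(counts, mu), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(res.message)
        return GainFit(mu=mu, gain_variance=float(np.exp(res.x)), valid=True, n_trials=n)
    except Exception:
        return GainFit(mu=mu, gain_variance=float(moment), valid=True, n_trials=n, method="moment")


def gain_fits_by_group(counts_table: pd.DataFrame, min_trials: int = 10) -> pd.DataFrame:
    """Condition-averaged gain-variance estimates per unit.

    Fits each stimulus condition separately, then averages the fitted
    sigma2_g over the 2 attend-RF conditions and, separately, over the 4
    attend-away conditions, per drug state.  Expects columns unit_id,
    attention, motion, drug, spike_count.
    """
    tbl = counts_table.copy()
    tbl["att_group"] = np.where(tbl["attention"] == "RF", "attend_RF", "attend_away")
    rows = []
    for (unit_id, att_group, drug), g in tbl.groupby(["unit_id", "att_group", "drug"], observed=True):
        fits = []
        for _, cond in g.groupby(["attention", "motion"], observed=True):
            c = cond["spike_count"].to_numpy()
            if c.size < min_trials:
                continue
            fits.append(fit_gain_variance(c, min_trials=min_trials))
        valid = [f for f in fits if f.valid]
        rows.append(
            dict(
                unit_id=unit_id,
                att_group=att_group,
                drug=drug,
                mu=float(np.mean([f.mu for f in fits])) if fits else np.nan,
                gain_variance=float(np.mean([f.gain_variance for f in valid])) if valid else np.nan,
                valid=len(valid) > 0,
                n_conditions_valid=len(valid),
                n_trials=int(sum(f.n_trials for f in fits)),
            )
        )
    return pd.DataFrame(rows)


def variability_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "unit_id",
    within: list[str] | None = None,
    between: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Repeated-measures / mixed ANOVA on a variability measure.

    Returns a dict with a two-way repeated-measures table over the within
    factors (attention group x drug) and, when a between grouping is given,
    a mixed between-within table.  Units lacking a complete within-cell set
    are dropped; empty input yields empty tables.
    """
    import pingouin as pg

    if within is None:
        within = ["att_group", "drug"]
    out: dict[str, pd.DataFrame] = {}
    data = table.dropna(subset=[dv])
    if data.empty:
        return {"within": pd.DataFrame(), "mixed": pd.DataFrame()}
    # keep subjects with complete within-design cells
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    complete = data.groupby(subject)[within].apply(lambda g: len(g.drop_duplicates()) == n_cells)
    data = data[data[subject].isin(complete[complete].index)]
    if data[subject].nunique() < 2:
        return {"within": pd.DataFrame(), "mixed": pd.DataFrame()}
    out["within"] = pg.rm_anova(
        data=data, dv=dv, within=within, subject=subject, detailed=True
    ).rename(columns={"np2": "eta2p", "p_unc": "p", "p-unc": "p", "ng2": "eta2g"})
    if between is not None:
        sub = data.groupby([subject, between, within[0]], observed=True)[dv].mean().reset_index()
        counts = sub.groupby(between, observed=True)[subject].nunique()
        if (counts >= 2).all() and len(counts) >= 2:
            out["mixed"] = pg.mixed_anova(
                data=sub, dv=dv, within=within[0], subject=subject, between=between
            ).rename(columns={"np2": "eta2p", "p_unc": "p", "p-unc": "p"})
        else:
            out["mixed"] = pd.DataFrame()
    else:
        out["mixed"] = pd.DataFrame()
    return out
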