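"""Per-unit and population quantification of attention and drug effects.

Implements the ideal-observer attentional modulation (AUROC with the
Mann-Whitney pair-count correspondence), the drug modulation index
DrugMI = (rate_no_drug - rate_drug) / (rate_no_drug + rate_drug), Cohen's D'
for attention, the three-factor ANOVA gate used to flag attention- and
drug-modulated units, response-type classification, peak-normalized
population histograms, Benjamini-Hochberg FDR adjustment and the population
level tests (paired/one-sample t with effect sizes, mixed between-within
ANOVA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "auroc",
    "auroc_flip",
    "cohens_dprime",
    "drug_mi",
    "drug_mi_unit",
    "anova3",
    "anova_gate",
    "classify_response_type",
    "compute_psth",
    "population_histogram",
    "fdr_adjust",
    "paired_t_with_effect",
    "one_sample_t_with_effect",
    "mixed_anova",
    "population_tests",
    "unit_metrics",
]


# ---------------------------------------------------------------------------
# elementary per-unit metrics


def auroc(rf: np.ndarray, away: np.ndarray) -> float:
    """P(rf > away) + 0.5 P(rf = away) over all trial pairs.

    Equivalent to the Mann-Whitney U statistic divided by n1*n2.
    """
    rf = np.asarray(rf, dtype=float)
    away = np.asarray(away, dtype=float)
    if rf.size < 2 or away.size < 2:
        return np.nan
    ranks = st.rankdata(np.concatenate([rf, away]))
    r1 = ranks[: rf.size].sum()
    u1 = r1 - rf.size * (rf.size + 1) / 2.0
    return float(u1 / (rf.size * away.size))


def auroc_flip(nodrug: np.ndarray, drug: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip paired AUROCs (x -> 1-x) for units whose no-drug AUROC < 0.5.

    The flip decision uses the no-drug value only (strict inequality) and is
    applied to both members of the pair.
    """
    nodrug = np.asarray(nodrug, dtype=float)
    drug = np.asarray(drug, dtype=float)
    flip = nodrug < 0.5
    return np.where(flip, 1.0 - nodrug, nodrug), np.where(flip, 1.0 - drug, drug)


def cohens_dprime(rf: np.ndarray, away: np.ndarray) -> float:
    """Standardized attend-RF vs attend-away mean rate difference.

    Pooled SD uses n-1 weighting; positive sign iff the attend-RF mean is
    larger.  NaN when the pooled SD is 0.
    """
    rf = np.asarray(rf, dtype=float)
    away = np.asarray(away, dtype=float)
    if rf.size < 2 or away.size < 2:
        return np.nan
    v1, v2 = rf.var(ddof=1), away.var(ddof=1)
    pooled = np.sqrt(((rf.size - 1) * v1 + (away.size - 1) * v2) / (rf.size + away.size - 2))
    if pooled == 0:
        return np.nan
    return float((rf.mean() - away.mean()) / pooled)


def drug_mi(rate_nodrug: float, rate_drug: float) -> float:
    """(no drug - drug) / (no drug + drug); NaN when both rates are 0."""
    if rate_nodrug < 0 or rate_drug < 0:
        raise ValueError("rates must be >= 0")
    denom = rate_nodrug + rate_drug
    if denom == 0:
        return np.nan
    return (rate_nodrug - rate_drug) / denom


def drug_mi_unit(rates: pd.DataFrame, epoch: str) -> float:
    """Unit-level DrugMI for one epoch.

    One MI per (attention, motion) stimulus condition (6 in the full
    design), computed from condition-mean rates with and without drug, then
    averaged across conditions.
    """
    sub = rates[rates["epoch"] == epoch]
    mis = []
    for _, g in sub.groupby(["attention", "motion"], observed=True):
        m = g.groupby("drug", observed=True)["rate"].mean()
        if "off" not in m.index or "on" not in m.index:
            continue
        mi = drug_mi(m["off"], m["on"])
        if not np.isnan(mi):
            mis.append(mi)
    return float(np.mean(mis)) if mis else np.nan


# ---------------------------------------------------------------------------
# three-factor ANOVA


def _balanced_anova3(y, levels_a, levels_b, levels_c) -> pd.DataFrame | None:
    """Closed-form fixed-effects 3-way ANOVA for a balanced design.

    Returns None when the design is not balanced.
    """
    cells = {}
    for yi, a, b, c in zip(y, levels_a, levels_b, levels_c):
        cells.setdefault((a, b, c), []).append(yi)
    la = sorted(set(levels_a))
    lb = sorted(set(levels_b))
    lc = sorted(set(levels_c))
    if len(cells) != len(la) * len(lb) * len(lc):
        return None
    sizes = {k: len(v) for k, v in cells.items()}
    n = next(iter(sizes.values()))
    if n < 2 or any(s != n for s in sizes.values()):
        return None
    m = np.array([[[np.mean(cells[(a, b, c)]) for c in lc] for b in lb] for a in la])
    mu = m.mean()
    ma = m.mean(axis=(1, 2))
    mb = m.mean(axis=(0, 2))
    mc = m.mean(axis=(0, 1))
    mab = m.mean(axis=2)
    mac = m.mean(axis=1)
    mbc = m.mean(axis=0)
    A, B, C = len(la), len(lb), len(lc)
    ss = {
        "attention": B * C * n * np.sum((ma - mu) ** 2),
        "drug": A * C * n * np.sum((mb - mu) ** 2),
        "motion": A * B * n * np.sum((mc - mu) ** 2),
        "attention:drug": C * n * np.sum((mab - ma[:, None] - mb[None, :] + mu) ** 2),
        "attention:motion": B * n * np.sum((mac - ma[:, None] - mc[None, :] + mu) ** 2),
        "drug:motion": A * n * np.sum((mbc - mb[:, None] - mc[None, :] + mu) ** 2),
    }
    resid_abc = (
        m
        - mab[:, :, None]
        - mac[:, None, :]
        - mbc[None, :, :]
        + ma[:, None, None]
        + mb[None, :, None]
        + mc[None, None, :]
        - mu
    )
    ss["attention:drug:motion"] = n * np.sum(resid_abc**2)
    sse = sum(
        np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in cells.values()
    )
    dfe = A * B * C * (n - 1)
    dfs = {
        "attention": A - 1,
        "drug": B - 1,
        "motion": C - 1,
        "attention:drug": (A - 1) * (B - 1),
        "attention:motion": (A - 1) * (C - 1),
        "drug:motion": (B - 1) * (C - 1),
        "attention:drug:motion": (A - 1) * (B - 1) * (C - 1),
    }
    rows = []
    mse = sse / dfe
    for eff, ssv in ss.items():
        dfv = dfs[eff]
        f = (ssv / dfv) / mse if mse > 0 else np.nan
        p = st.f.sf(f, dfv, dfe) if np.isfinite(f) else np.nan
        rows.append(
            dict(effect=eff, ss=ssv, df=dfv, F=f, p=p, eta2p=ssv / (ssv + sse) if ssv + sse > 0 else np.nan)
        )
    rows.append(dict(effect="residual", ss=sse, df=dfe, F=np.nan, p=np.nan, eta2p=np.nan))
    return pd.DataFrame(rows)


def anova3(data: pd.DataFrame, dv: str = "rate") -> pd.DataFrame:
    """Fixed-effects attention x drug x motion ANOVA on trial values.

    Balanced designs use an exact closed form; unbalanced designs fall back
    to Type-II sums of squares via statsmodels.
    """
    y = data[dv].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero-variance response; ANOVA degenerate")
    out = _balanced_anova3(y, data["attention"], data["drug"], data["motion"])
    if out is not None:
        return out
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = data.groupby(["attention", "drug", "motion"], observed=True).size()
    expected = data["attention"].nunique() * data["drug"].nunique() * data["motion"].nunique()
    if len(counts) < expected or counts.min() == 0:
        raise ValueError("empty condition cell; unit excluded from ANOVA gate")
    model = smf.ols(f"{dv} ~ C(attention) * C(drug) * C(motion)", data=data).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    sse = tab.loc["Residual", "sum_sq"]
    rows = []
    rename = {
        "C(attention)": "attention",
        "C(drug)": "drug",
        "C(motion)": "motion",
        "C(attention):C(drug)": "attention:drug",
        "C(attention):C(motion)": "attention:motion",
        "C(drug):C(motion)": "drug:motion",
        "C(attention):C(drug):C(motion)": "attention:drug:motion",
        "Residual": "residual",
    }
    for name, r in tab.iterrows():
        eff = rename.get(name, name)
        eta = r.sum_sq / (r.sum_sq + sse) if eff != "residual" else np.nan
        rows.append(
            dict(effect=eff, ss=r.sum_sq, df=int(r.df), F=r.F, p=r["PR(>F)"], eta2p=eta)
        )
    return pd.DataFrame(rows)


def anova_gate(
    rates: pd.DataFrame, epoch: str = "pre_dim", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-unit significance flags from the pre-dimming 3-factor ANOVA.

    A unit is attention-modulated when the attention main effect or any
    interaction involving attention is significant; drug-modulated
    analogously for drug.
    """
    sub = rates[rates["epoch"] == epoch]
    rows = []
    for unit_id, g in sub.groupby("unit_id"):
        try:
            tab = anova3(g)
        except ValueError as exc:
            rows.append(
                dict(unit_id=unit_id, excluded=True, reason=str(exc), attention_modulated=False, drug_modulated=False)
            )
            continue
        p = tab.set_index("effect")["p"]
        att = bool(
            (p["attention"] < alpha)
            or (p["attention:drug"] < alpha)
            or (p["attention:motion"] < alpha)
            or (p["attention:drug:motion"] < alpha)
        )
        dr = bool(
            (p["drug"] < alpha)
            or (p["attention:drug"] < alpha)
            or (p["drug:motion"] < alpha)
            or (p["attention:drug:motion"] < alpha)
        )
        rows.append(
            dict(
                unit_id=unit_id,
                excluded=False,
                reason="",
                attention_modulated=att,
                drug_modulated=dr,
                p_attention=p["attention"],
                p_drug=p["drug"],
                p_attention_drug=p["attention:drug"],
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response types, histograms, FDR


def classify_response_type(
    baseline: float,
    transient: float,
    predim_rf: float,
    change_threshold: float = 0.20,
    zero_baseline_floor: float = 0.5,
) -> str:
    """Response-type rules on baseline / stimulus-transient / pre-dimming
    attend-RF rates (spikes/s).

    visuo-attention: >= 20% stimulus change, pre-dim >= 120% of baseline and
    >= transient; visual: >= 20% stimulus change and pre-dim at least 20%
    below the transient; attention: stimulus change < 20%, pre-dim >= 120%
    of baseline and above the transient; otherwise "other".  Zero baselines
    are floored so percentage changes stay defined.
    """
    b = max(baseline, zero_baseline_floor)
    stim_change = abs(transient - b) / b
    visual_response = stim_change >= change_threshold
    if visual_response and predim_rf >= (1 + change_threshold) * b and predim_rf >= transient:
        return "visuo-attention"
    if visual_response and predim_rf <= (1 - change_threshold) * transient:
        return "visual"
    if (not visual_response) and predim_rf >= (1 + change_threshold) * b and predim_rf > transient:
        return "attention"
    return "other"


def compute_psth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    align: str,
    window_ms: tuple[float, float],
    binwidth_ms: float = 20.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Trial-averaged firing-rate histograms per unit aligned to an event.

    Returns (bin_centers_ms, DataFrame unit_id x bins in spikes/s).
    """
    tt = trials[["trial_id", align]].dropna()
    anchor = tt.set_index("trial_id")[align]
    edges = np.arange(window_ms[0], window_ms[1] + binwidth_ms / 2, binwidth_ms)
    centers = (edges[:-1] + edges[1:]) / 2
    sp = spikes[spikes["trial_id"].isin(anchor.index)]
    rel = sp["spike_time_ms"].to_numpy() - anchor.reindex(sp["trial_id"]).to_numpy()
    n_trials = len(tt)
    rows = {}
    for unit_id, idx in sp.groupby("unit_id").groups.items():
        h, _ = np.histogram(rel[sp.index.get_indexer(idx)], bins=edges)
        rows[unit_id] = h / n_trials / (binwidth_ms / 1000.0)
    psth = pd.DataFrame.from_dict(rows, orient="index", columns=[f"b{i}" for i in range(len(centers))])
    psth.index.name = "unit_id"
    return centers, psth


def population_histogram(psths: pd.DataFrame) -> pd.DataFrame:
    """Peak-normalize each unit's PSTH, then average across units.

    Returns a frame with columns mean and sem per bin.  All-zero units are
    excluded with a warning.
    """
    import warnings

    mat = psths.to_numpy(dtype=float)
    peaks = mat.max(axis=1)
    keep = peaks > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} all-zero unit(s) excluded from population histogram", stacklevel=2)
    mat = mat[keep] / peaks[keep, None]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    return pd.DataFrame({"mean": mean, "sem": sem})


def fdr_adjust(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# population statistics


def _t_ci(mean: float, se: float, df: int, conf: float = 0.95) -> tuple[float, float]:
    tcrit = st.t.ppf(0.5 + conf / 2.0, df)
    return mean - tcrit * se, mean + tcrit * se


def paired_t_with_effect(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided paired t-test with Cohen's D_z and CI of the mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        # no variability in the paired differences: t-test degenerates; a
        # uniformly zero difference is reported as no effect
        t, p = 0.0, 1.0
        dz = 0.0 if d.mean() == 0 else np.inf
    else:
        t, p = st.ttest_rel(x, y)
        dz = d.mean() / sd
    lo, hi = _t_ci(d.mean(), sd / np.sqrt(n) if sd > 0 else 0.0, n - 1)
    return dict(t=float(t), p=float(p), n=n, mean_diff=float(d.mean()), dz=float(dz), ci_low=lo, ci_high=hi)


def one_sample_t_with_effect(x: np.ndarray, popmean: float = 0.0) -> dict:
    """Two-sided one-sample t-test with Cohen's D and CI of the mean."""
    x = np.asarray(x, dtype=float)
    n = x.size
    t, p = st.ttest_1samp(x, popmean)
    sd = x.std(ddof=1)
    d = (x.mean() - popmean) / sd if sd > 0 else np.nan
    lo, hi = _t_ci(x.mean(), sd / np.sqrt(n), n - 1)
    return dict(t=float(t), p=float(p), n=n, mean=float(x.mean()), cohens_d=float(d), ci_low=lo, ci_high=hi)


def mixed_anova(long: pd.DataFrame, dv: str, within: str, between: str, subject: str) -> pd.DataFrame:
    """Classical between-within (split-plot) ANOVA with partial eta squared."""
    import pingouin as pg

    tab = pg.mixed_anova(data=long, dv=dv, within=within, between=between, subject=subject)
    return tab.rename(columns={"np2": "eta2p", "p_unc": "p", "p-unc": "p"})


def population_tests(metrics: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Group-level tests on unit metrics.

    Per group: paired t on no-drug vs drug AUROC (Cohen's D_z + CI) and
    one-sample t of DrugMI against 0 (Cohen's D + CI).  Expects columns
    ``auroc_nodrug``, ``auroc_drug``, ``drug_mi`` and the grouping column.
    Degenerate groups (< 2 complete units) are skipped.
    """
    rows = []
    for grp, g in metrics.groupby(grouping, observed=True):
        pair = g[["auroc_nodrug", "auroc_drug"]].dropna()
        if len(pair) >= 2:
            res = paired_t_with_effect(pair["auroc_nodrug"].to_numpy(), pair["auroc_drug"].to_numpy())
            rows.append(dict(group=grp, test="auroc_paired_t", **res))
        mi = g["drug_mi"].dropna().to_numpy()
        if mi.size >= 2:
            res = one_sample_t_with_effect(mi)
            rows.append(dict(group=grp, test="drugmi_one_sample_t", **res))
    return pd.DataFrame(rows)


def unit_metrics(
    rates: pd.DataFrame,
    epochs: tuple[str, ...] = ("post_stim", "post_cue", "pre_dim"),
) -> pd.DataFrame:
    """Per-unit x epoch metrics table: AUROC and Cohen's D' by drug state
    (attend-away conditions pooled) and the condition-averaged DrugMI."""
    rows = []
    for unit_id, g in rates.groupby("unit_id"):
        for epoch in epochs:
            ge = g[g["epoch"] == epoch]
            row = dict(unit_id=unit_id, epoch=epoch)
            for drug, suffix in (("off", "nodrug"), ("on", "drug")):
                gd = ge[ge["drug"] == drug]
                rf = gd.loc[gd["attention"] == "RF", "rate"].to_numpy()
                away = gd.loc[gd["attention"] != "RF", "rate"].to_numpy()
                row[f"auroc_{suffix}"] = auroc(rf, away)
                row[f"cohens_dprime_{suffix}"] = cohens_dprime(rf, away)
            row["drug_mi"] = drug_mi_unit(ge, epoch)
            rows.append(row)
    df = pd.DataFrame(rows)
    for epoch in epochs:
        mask = df["epoch"] == epoch
        flipped = auroc_flip(
            df.loc[mask, "auroc_nodrug"].to_numpy(), df.loc[mask, "auroc_drug"].to_numpy()
        )
        df.loc[mask, "auroc_nodrug_flipped"] = flipped[0]
        df.loc[mask, "auroc_drug_flipped"] = flipped[1]
    return df
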