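"""Two-stage spiking network: sensory populations feeding a winner-take-all
integration stage, with graded NMDA-conductance blockade in small neuron
subgroups.

The integration stage holds two decision populations (D1 = "attend RF",
D2 = "attend away") coupled through a shared inhibitory pool; recurrent
excitation mixes fast AMPA and slow, voltage-dependent (Mg2+ gated) NMDA
conductances.  Two sensory populations receive a common fluctuating
stimulus and project feedforward to their decision population; feedback
from the integration stage closes the loop, and spatial attention is
modeled as a reduction of the feedback gain onto the "attend away" branch.

In each decision population, 3 subgroups of 10 neurons have their incoming
NMDA conductance scaled by 0.6, 0.75 and 0.9 (40/25/10% reduction); the
remaining neurons are unaffected (scale 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metrics import auroc, drug_mi, paired_t_with_effect, one_sample_t_with_effect

__all__ = [
    "NetworkConfig",
    "NetworkRun",
    "simulate",
    "run_batch",
    "evaluate_attentional_auroc",
    "evaluate_drug_mi",
    "NMDA_SCALING_LEVELS",
]

NMDA_SCALING_LEVELS = (1.0, 0.9, 0.75, 0.6)

# population indices
SE1, SE2, SI, D1, D2, DI = range(6)
_EXC_POPS = (SE1, SE2, D1, D2)


@dataclass
class NetworkConfig:
    """All constants of the two-stage network (units: ms, mV, nS, pF, pA)."""

    # population sizes
    n_sensory: int = 100
    n_sensory_inh: int = 50
    n_decision: int = 80
    n_decision_inh: int = 60
    n_affected_per_group: int = 10

    # LIF neurons
    c_m_exc: float = 500.0
    g_leak_exc: float = 25.0
    c_m_inh: float = 200.0
    g_leak_inh: float = 20.0
    v_leak: float = -70.0
    v_thresh: float = -50.0
    v_reset: float = -55.0
    t_ref_exc: float = 2.0
    t_ref_inh: float = 1.0

    # synaptic kinetics
    tau_ampa: float = 2.0
    tau_nmda_decay: float = 100.0
    tau_nmda_rise: float = 2.0
    alpha_nmda: float = 0.5
    tau_gaba: float = 5.0
    e_exc: float = 0.0
    e_inh: float = -70.0
    mg_conc: float = 1.0

    # recurrent coupling in the integration stage (total nS from a fully
    # active presynaptic population, before 1/N normalization)
    g_d_self_nmda: float = 250.0
    g_d_self_ampa: float = 60.0
    g_d_cross_ampa: float = 20.0
    g_d_to_inh_ampa: float = 150.0
    g_d_to_inh_nmda: float = 300.0
    g_inh_to_d_gaba: float = 700.0
    g_inh_self_gaba: float = 300.0

    # sensory stage
    g_se_self_ampa: float = 0.0
    g_se_to_inh_ampa: float = 150.0
    g_sinh_to_se_gaba: float = 150.0

    # feedforward / feedback between stages
    g_ff_ampa: float = 250.0
    g_ff_nmda: float = 150.0
    g_fb_ampa: float = 250.0
    g_fb_nmda: float = 0.0
    feedback_bias: float = 0.9  # fractional reduction of D2 -> SE2 feedback

    # external drive (pA) and white-noise amplitude (pA*sqrt(ms))
    i_ext_exc: float = 490.0
    i_ext_decision: float | None = 540.0
    i_ext_inh: float = 290.0
    noise_sigma: float = 350.0

    # stimulus
    i_stim: float = 200.0
    stim_onset: float = 500.0
    stim_ramp_ms: float = 200.0
    stim_fluct_sd: float = 0.35
    stim_fluct_tau: float = 20.0

    # per-neuron NMDA scaling of affected subgroups
    nmda_scaling_levels: tuple[float, ...] = NMDA_SCALING_LEVELS

    duration: float = 2000.0
    dt: float = 0.05
    rate_window: tuple[float, float] = (700.0, 2000.0)  # stimulus period minus transient
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt > 0.1:
            raise ValueError("dt must be <= 0.1 ms")
        for s in self.nmda_scaling_levels:
            if not (0 < s <= 1):
                raise ValueError("nmda scaling must lie in (0, 1]")
        if 3 * self.n_affected_per_group >= self.n_decision:
            raise ValueError("affected subgroups must leave unaffected neurons")


@dataclass
class NetworkRun:
    rates: pd.DataFrame  # per-neuron mean rate in the analysis window
    pop_rate_traces: pd.DataFrame  # population rate vs time (coarse bins)
    spikes: pd.DataFrame | None
    seed: int
    config: NetworkConfig = field(repr=False)

    def subgroup_rates(self, pop: str, scaling: float) -> np.ndarray:
        sel = (self.rates["population"] == pop) & (self.rates["nmda_scale"] == scaling)
        return self.rates.loc[sel, "rate"].to_numpy()


def _build_arrays(cfg: NetworkConfig):
    sizes = [cfg.n_sensory, cfg.n_sensory, cfg.n_sensory_inh, cfg.n_decision, cfg.n_decision, cfg.n_decision_inh]
    n_total = sum(sizes)
    pop_of = np.concatenate([np.full(s, p, dtype=np.int64) for p, s in enumerate(sizes)])
    offsets = np.cumsum([0] + sizes)

    is_exc = np.isin(pop_of, _EXC_POPS)
    c_m = np.where(is_exc, cfg.c_m_exc, cfg.c_m_inh)
    g_leak = np.where(is_exc, cfg.g_leak_exc, cfg.g_leak_inh)
    t_ref = np.where(is_exc, cfg.t_ref_exc, cfg.t_ref_inh)

    # per-neuron incoming-NMDA scaling: subgroups of the decision populations
    nmda_scale = np.ones(n_total)
    n_grp = cfg.n_affected_per_group
    reduced = [s for s in cfg.nmda_scaling_levels if s < 1.0]
    for pop in (D1, D2):
        start = offsets[pop]
        for gi, s in enumerate(reduced):
            nmda_scale[start + gi * n_grp : start + (gi + 1) * n_grp] = s

    # weight matrices: conductance per postsynaptic neuron per unit of summed
    # presynaptic gating, normalized by presynaptic population size
    wa = np.zeros((6, 6))
    wn = np.zeros((6, 6))
    wg = np.zeros((6, 6))

    def set_w(mat, post, pre, g_total):
        mat[post, pre] = g_total / sizes[pre]

    # sensory stage
    set_w(wa, SE1, SE1, cfg.g_se_self_ampa)
    set_w(wa, SE2, SE2, cfg.g_se_self_ampa)
    set_w(wa, SI, SE1, cfg.g_se_to_inh_ampa)
    set_w(wa, SI, SE2, cfg.g_se_to_inh_ampa)
    set_w(wg, SE1, SI, cfg.g_sinh_to_se_gaba)
    set_w(wg, SE2, SI, cfg.g_sinh_to_se_gaba)
    set_w(wg, SI, SI, cfg.g_inh_self_gaba)

    # feedforward and biased feedback
    set_w(wa, D1, SE1, cfg.g_ff_ampa)
    set_w(wa, D2, SE2, cfg.g_ff_ampa)
    set_w(wn, D1, SE1, cfg.g_ff_nmda)
    set_w(wn, D2, SE2, cfg.g_ff_nmda)
    set_w(wa, SE1, D1, cfg.g_fb_ampa)
    set_w(wa, SE2, D2, cfg.g_fb_ampa * (1.0 - cfg.feedback_bias))
    set_w(wn, SE1, D1, cfg.g_fb_nmda)
    set_w(wn, SE2, D2, cfg.g_fb_nmda * (1.0 - cfg.feedback_bias))

    # integration stage
    for d_self, d_other in ((D1, D2), (D2, D1)):
        set_w(wn, d_self, d_self, cfg.g_d_self_nmda)
        set_w(wa, d_self, d_self, cfg.g_d_self_ampa)
        set_w(wa, d_self, d_other, cfg.g_d_cross_ampa)
        set_w(wa, DI, d_self, cfg.g_d_to_inh_ampa)
        set_w(wn, DI, d_self, cfg.g_d_to_inh_nmda)
        set_w(wg, d_self, DI, cfg.g_inh_to_d_gaba)
    set_w(wg, DI, DI, cfg.g_inh_self_gaba)

    i_ext = np.where(is_exc, cfg.i_ext_exc, cfg.i_ext_inh)
    if cfg.i_ext_decision is not None:
        i_ext[np.isin(pop_of, (D1, D2))] = cfg.i_ext_decision
    return sizes, offsets, pop_of, c_m, g_leak, t_ref, nmda_scale, wa, wn, wg, i_ext


def _kernel_source():
    """LIF integration loop, JIT-compiled on first use."""
    import numba

    @numba.njit(cache=False, fastmath=True)
    def run(
        n_steps, dt, pop_of, c_m, g_leak, t_ref, nmda_scale, wa, wn, wg, i_ext,
        v_leak, v_thresh, v_reset, tau_ampa, tau_nmda_decay, tau_nmda_rise,
        alpha_nmda, tau_gaba, e_exc, e_inh, mg_conc, noise_sigma,
        i_stim, stim_start_step, stim_ramp_steps, stim_sd, stim_tau,
        win_lo_step, win_hi_step, seed, record, rec_bin_steps,
    ):
        np.random.seed(seed)
        n = pop_of.size
        v = v_leak + np.random.uniform(0.0, 5.0, n)
        refr = np.zeros(n)
        s_a = np.zeros(n)
        x_n = np.zeros(n)
        s_n = np.zeros(n)
        s_g = np.zeros(n)
        counts = np.zeros(n, dtype=np.int64)
        dec_a = np.exp(-dt / tau_ampa)
        dec_x = np.exp(-dt / tau_nmda_rise)
        dec_g = np.exp(-dt / tau_gaba)
        z1 = 0.0
        z2 = 0.0
        ou_a = np.exp(-dt / stim_tau)
        ou_b = stim_sd * np.sqrt(1.0 - ou_a * ou_a)
        noise_scale = noise_sigma / np.sqrt(dt)
        n_bins = n_steps // rec_bin_steps + 1
        pop_traces = np.zeros((6, n_bins))
        max_spk = 4_000_000 if record else 1
        spk_t = np.zeros(max_spk, dtype=np.float32)
        spk_i = np.zeros(max_spk, dtype=np.int32)
        n_spk = 0

        sum_a = np.zeros(6)
        sum_n = np.zeros(6)
        sum_g = np.zeros(6)
        for step in range(n_steps):
            z1 = ou_a * z1 + ou_b * np.random.normal()
            z2 = ou_a * z2 + ou_b * np.random.normal()
            stim_on = step >= stim_start_step
            stim_amp = 1.0
            if stim_on and stim_ramp_steps > 0 and step < stim_start_step + stim_ramp_steps:
                stim_amp = (step - stim_start_step) / stim_ramp_steps

            for p in range(6):
                sum_a[p] = 0.0
                sum_n[p] = 0.0
                sum_g[p] = 0.0
            for i in range(n):
                p = pop_of[i]
                sum_a[p] += s_a[i]
                sum_n[p] += s_n[i]
                sum_g[p] += s_g[i]

            for i in range(n):
                p = pop_of[i]
                g_a = 0.0
                g_n = 0.0
                g_gab = 0.0
                for q in range(6):
                    g_a += wa[p, q] * sum_a[q]
                    g_n += wn[p, q] * sum_n[q]
                    g_gab += wg[p, q] * sum_g[q]
                vi = v[i]
                b_mg = 1.0 / (1.0 + mg_conc * np.exp(-0.062 * vi) / 3.57)
                i_syn = -(g_a + nmda_scale[i] * b_mg * g_n) * (vi - e_exc) - g_gab * (vi - e_inh)
                i_in = i_ext[i] + i_syn + noise_scale * np.random.normal()
                if stim_on:
                    if p == 0:
                        i_in += stim_amp * i_stim * (1.0 + z1)
                    elif p == 1:
                        i_in += stim_amp * i_stim * (1.0 + z2)
                if refr[i] > 0.0:
                    refr[i] -= dt
                    v[i] = v_reset
                else:
                    v[i] = vi + dt * (-g_leak[i] * (vi - v_leak) + i_in) / c_m[i]
                    if v[i] >= v_thresh:
                        v[i] = v_reset
                        refr[i] = t_ref[i]
                        s_a[i] += 1.0
                        x_n[i] += 1.0
                        s_g[i] += 1.0
                        if win_lo_step <= step < win_hi_step:
                            counts[i] += 1
                        pop_traces[p, step // rec_bin_steps] += 1.0
                        if record and n_spk < max_spk:
                            spk_t[n_spk] = step * dt
                            spk_i[n_spk] = i
                            n_spk += 1

            for i in range(n):
                s_a[i] *= dec_a
                x_n[i] *= dec_x
                s_g[i] *= dec_g
                s_n[i] += dt * (-s_n[i] / tau_nmda_decay + alpha_nmda * x_n[i] * (1.0 - s_n[i]))
                if s_n[i] > 1.0:
                    s_n[i] = 1.0

        return counts, pop_traces, spk_t[:n_spk], spk_i[:n_spk]

    return run


_KERNEL = None


def _kernel():
    global _KERNEL
    if _KERNEL is None:
        _KERNEL = _kernel_source()
    return _KERNEL


POP_NAMES = ["SE1", "SE2", "SI", "D1", "D2", "DI"]


def simulate(cfg: NetworkConfig, seed: int | None = None, record_spikes: bool = False) -> NetworkRun:
    """Run one network realization; deterministic given (config, seed)."""
    seed = int(seed if seed is not None else (cfg.seed if cfg.seed is not None else 0))
    sizes, offsets, pop_of, c_m, g_leak, t_ref, nmda_scale, wa, wn, wg, i_ext = _build_arrays(cfg)
    n_steps = int(round(cfg.duration / cfg.dt))
    rec_bin_steps = max(int(round(10.0 / cfg.dt)), 1)  # 10 ms population-rate bins
    counts, traces, spk_t, spk_i = _kernel()(
        n_steps, cfg.dt, pop_of, c_m, g_leak, t_ref, nmda_scale, wa, wn, wg, i_ext,
        cfg.v_leak, cfg.v_thresh, cfg.v_reset, cfg.tau_ampa, cfg.tau_nmda_decay,
        cfg.tau_nmda_rise, cfg.alpha_nmda, cfg.tau_gaba, cfg.e_exc, cfg.e_inh,
        cfg.mg_conc, cfg.noise_sigma, cfg.i_stim, int(round(cfg.stim_onset / cfg.dt)),
        int(round(cfg.stim_ramp_ms / cfg.dt)), cfg.stim_fluct_sd, cfg.stim_fluct_tau,
        int(round(cfg.rate_window[0] / cfg.dt)), int(round(cfg.rate_window[1] / cfg.dt)),
        seed % (2**31 - 1), record_spikes, rec_bin_steps,
    )
    win_s = (cfg.rate_window[1] - cfg.rate_window[0]) / 1000.0
    rates = pd.DataFrame(
        {
            "neuron": np.arange(pop_of.size),
            "population": [POP_NAMES[p] for p in pop_of],
            "nmda_scale": nmda_scale,
            "rate": counts / win_s,
        }
    )
    # sanity: refractory period bounds attainable rates
    max_rate = 1000.0 / min(cfg.t_ref_exc, cfg.t_ref_inh)
    if (rates["rate"] > max_rate).any():
        raise RuntimeError("numerical instability: rate exceeds refractory bound")
    bin_ms = rec_bin_steps * cfg.dt
    tr = pd.DataFrame(traces.T, columns=POP_NAMES)
    for p, name in enumerate(POP_NAMES):
        tr[name] = tr[name] / sizes[p] / (bin_ms / 1000.0)
    tr.insert(0, "t_ms", np.arange(len(tr)) * bin_ms)
    spikes = (
        pd.DataFrame({"neuron": spk_i, "t_ms": spk_t}) if record_spikes else None
    )
    return NetworkRun(rates=rates, pop_rate_traces=tr, spikes=spikes, seed=seed, config=cfg)


def run_batch(cfg: NetworkConfig, n_runs: int, seed: int) -> list[NetworkRun]:
    """Run the network ``n_runs`` times with distinct child seeds."""
    ss = np.random.SeedSequence(seed)
    return [simulate(cfg, seed=int(s.generate_state(1)[0])) for s in ss.spawn(n_runs)]


def evaluate_attentional_auroc(runs: list[NetworkRun]) -> pd.DataFrame:
    """Per-run attentional AUROC between matched 10-neuron subgroups.

    For each NMDA scaling level, the AUROC contrasts the stimulus-period
    rates of that level's subgroup in the attend-RF population (D1) against
    the matched subgroup of the attend-away population (D2); for the
    unaffected level the first ``n_affected_per_group`` unaffected neurons
    are used.  Includes a paired t-test of each reduced level against the
    unaffected level across runs.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    rows = []
    n_grp = runs[0].config.n_affected_per_group
    for ridx, run in enumerate(runs):
        for s in runs[0].config.nmda_scaling_levels:
            r1 = run.subgroup_rates("D1", s)[:n_grp]
            r2 = run.subgroup_rates("D2", s)[:n_grp]
            rows.append(dict(run=ridx, nmda_scale=s, auroc=auroc(r1, r2)))
    df = pd.DataFrame(rows)
    wide = df.pivot(index="run", columns="nmda_scale", values="auroc")
    tests = []
    for s in sorted(c for c in wide.columns if c < 1.0):
        res = paired_t_with_effect(wide[s].to_numpy(), wide[1.0].to_numpy())
        tests.append(dict(nmda_scale=s, **res))
    df.attrs["paired_tests"] = pd.DataFrame(tests)
    return df


def evaluate_drug_mi(runs: list[NetworkRun]) -> pd.DataFrame:
    """Per-run rate modulation index of affected vs unaffected subgroups.

    MI = (rate_unaffected - rate_reduced) / (rate_unaffected + rate_reduced)
    using subgroup-mean stimulus-period rates in the attend-RF population;
    runs with zero summed rate are skipped.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    n_grp = runs[0].config.n_affected_per_group
    rows = []
    for ridx, run in enumerate(runs):
        bench = float(np.mean(run.subgroup_rates("D1", 1.0)[:n_grp]))
        for s in runs[0].config.nmda_scaling_levels:
            if s >= 1.0:
                continue
            reduced = float(np.mean(run.subgroup_rates("D1", s)))
            if bench + reduced == 0:
                continue
            rows.append(dict(run=ridx, nmda_scale=s, mi=drug_mi(bench, reduced)))
    df = pd.DataFrame(rows)
    tests = []
    for s, g in df.groupby("nmda_scale"):
        res = one_sample_t_with_effect(g["mi"].to_numpy())
        tests.append(dict(nmda_scale=s, median_mi=float(g["mi"].median()), **res))
    df.attrs["tests"] = pd.DataFrame(tests)
    return df
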