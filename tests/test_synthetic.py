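import numpy as np
import pandas as pd
import pytest

from attnspike.spike_io import EPOCH_WINDOWS, epoch_rates, filter_trials
from attnspike.synthetic import (
    GroundTruthUnit,
    TaskConfig,
    generate_eye_traces,
    generate_session,
    generate_spikes,
    generate_trials,
    generate_waveforms,
)


class TestTaskConfig:
    def test_block_structure_invariant(self):
        TaskConfig()  # 3*2*3*2 == 36

    def test_inconsistent_block_length_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(block_length_min=40)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(trials_per_condition=5)


class TestGroundTruthUnit:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthUnit("u", baseline_rate=0.0)

    def test_drug_gain_range(self):
        with pytest.raises(ValueError):
            GroundTruthUnit("u", 5.0, drug_gain=1.5)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            generate_trials(TaskConfig())


@pytest.fixture(scope="module")
def gen_trials():
    return generate_trials(TaskConfig(trials_per_condition=12), seed=5)


class TestTrials:
    @pytest.fixture()
    def trials(self, gen_trials):
        return gen_trials

    def test_min_correct_trials_per_condition(self, trials):
        hits = trials[trials.outcome == "hit"]
        counts = hits.groupby(["attention", "motion", "drug"]).size()
        assert counts.min() >= 12

    def test_event_times_increasing(self, trials):
        ev = ["t_fixation_on", "t_stimulus_on", "t_cue_on", "t_dim1", "t_dim2", "t_dim3", "t_response"]
        for row in trials[ev].itertuples(index=False):
            t = [v for v in row if not np.isnan(v)]
            assert all(b > a for a, b in zip(t, t[1:]))

    def test_timing_draws_in_intervals(self, trials):
        ok = trials.dropna(subset=["t_cue_on"])
        delay = ok.t_cue_on - ok.t_stimulus_on
        assert delay.between(300, 1400).all()
        ok = trials.dropna(subset=["t_dim1"])
        gap = ok.t_dim1 - ok.t_cue_on
        assert gap.between(600, 1750).all()

    def test_drug_constant_within_block(self, trials):
        assert (trials.groupby("block_id")["drug"].nunique() == 1).all()

    def test_dims_absent_when_not_reached(self, trials):
        order1 = trials[(trials.dimming_order == 1) & (trials.outcome == "hit")]
        assert order1.t_dim2.isna().all() and order1.t_dim3.isna().all()

    def test_seed_determinism(self):
        task = TaskConfig(trials_per_condition=10)
        a = generate_trials(task, seed=9)
        b = generate_trials(task, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSpikes:
    def test_poisson_limit_variance_over_mean(self):
        # sigma2_g = 0, flat gains -> counts Poisson, Fano -> 1
        task = TaskConfig(trials_per_condition=60)
        unit = GroundTruthUnit("u", 20.0, stim_gain=1, cue_gain=1, predim_attend_gain=1)
        trials = generate_trials(task, seed=2)
        spikes = generate_spikes(trials, [unit], seed=3)
        rates = epoch_rates(spikes, trials, {"pre_dim": EPOCH_WINDOWS["pre_dim"]})
        counts = rates["spike_count"].to_numpy()
        ff = counts.var(ddof=1) / counts.mean()
        assert ff == pytest.approx(1.0, abs=0.15)

    def test_gain_variance_moment_identity(self):
        # var = mu + s2g mu^2 checked against the Monte-Carlo moments
        rng = np.random.default_rng(7)
        s2g, mu, n = 0.2, 10.0, 10_000
        gains = rng.gamma(1 / s2g, s2g, n)
        counts = rng.poisson(gains * mu)
        est = (counts.var(ddof=1) - counts.mean()) / counts.mean() ** 2
        assert est == pytest.approx(s2g, abs=0.02)

    def test_generator_matches_moment_identity(self):
        task = TaskConfig(trials_per_condition=45)
        unit = GroundTruthUnit(
            "u", 20.0, stim_gain=1, cue_gain=1, predim_attend_gain=1, gain_variance=0.2
        )
        trials = generate_trials(task, seed=11)
        spikes = generate_spikes(trials, [unit], seed=12)
        rates = epoch_rates(spikes, trials, {"pre_dim": EPOCH_WINDOWS["pre_dim"]})
        counts = rates["spike_count"].to_numpy()
        est = (counts.var(ddof=1) - counts.mean()) / counts.mean() ** 2
        assert est == pytest.approx(0.2, abs=0.06)

    def test_epoch_rate_scaling(self):
        # planted multiplicative structure appears in epoch means
        task = TaskConfig(trials_per_condition=40)
        unit = GroundTruthUnit(
            "u", 10.0, stim_gain=2.0, cue_gain=1.0, predim_attend_gain=1.5,
            attention_effect=1.4, drug_gain=0.7,
        )
        trials = generate_trials(task, seed=21)
        spikes = generate_spikes(trials, [unit], seed=22)
        rates = epoch_rates(spikes, trials)
        predim = rates[rates.epoch == "pre_dim"]
        m = predim.groupby(["attention", "drug"])["rate"].mean()
        base = m[("away1", "off")]
        assert m[("RF", "off")] / base == pytest.approx(1.4, rel=0.1)
        assert m[("away1", "on")] / base == pytest.approx(0.7, rel=0.1)
        assert base == pytest.approx(15.0, rel=0.1)  # 10 * predim gain 1.5

    def test_requires_unit(self):
        trials = generate_trials(TaskConfig(trials_per_condition=10), seed=1)
        with pytest.raises(ValueError):
            generate_spikes(trials, [], seed=1)


class TestWaveformGeneration:
    def test_p2t_planted_within_one_sample(self):
        from attnspike.synthetic import NATIVE_WAVEFORM_DT_US
        from attnspike.waveforms import peak_to_trough

        units = [
            GroundTruthUnit(f"u{p}", 5.0, p2t_us=float(p))
            for p in (172, 199, 240, 383, 500)
        ]
        wf = generate_waveforms(units, n_samples=48)
        for u in units:
            row = wf[wf.unit_id == u.unit_id].drop(columns="unit_id").to_numpy()[0]
            p2t = peak_to_trough(row, NATIVE_WAVEFORM_DT_US)
            assert abs(p2t - u.p2t_us) <= 5.4

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            generate_waveforms([GroundTruthUnit("u", 5.0, p2t_us=500.0)], n_samples=16)


@pytest.fixture(scope="module")
def eye_trials():
    return generate_trials(TaskConfig(trials_per_condition=25), seed=3)


class TestEyeTraces:
    @pytest.fixture()
    def trials(self, eye_trials):
        return eye_trials

    def test_zero_rate_zero_events(self, trials):
        traces = generate_eye_traces(trials, microsaccade_rate=0.0, seed=4)
        assert sum(len(t.injected) for t in traces) == 0

    def test_sampling_rate(self, trials):
        traces = generate_eye_traces(trials, seed=4)
        tr = traces[0]
        assert np.allclose(np.diff(tr.t_ms), 4.0)

    def test_injected_count_poisson_mean(self, trials):
        traces = generate_eye_traces(trials, microsaccade_rate=2.0, seed=5)
        durations = np.array([t.t_ms.size / 250.0 for t in traces])
        counts = np.array([len(t.injected) for t in traces])
        # rate recovery within sampling error (refractory spacing loses a few)
        assert counts.sum() / durations.sum() == pytest.approx(2.0, rel=0.15)


class TestSessionDeterminism:
    def test_identical_seed_identical_output(self):
        task = TaskConfig(trials_per_condition=10)
        units = [GroundTruthUnit("u", 10.0)]
        a = generate_session(task, units, seed=77, with_eyes=False)
        b = generate_session(task, units, seed=77, with_eyes=False)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        pd.testing.assert_frame_equal(a.waveforms, b.waveforms)
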