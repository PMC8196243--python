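import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from attnspike.metrics import (
    anova3,
    anova_gate,
    auroc,
    auroc_flip,
    classify_response_type,
    cohens_dprime,
    drug_mi,
    drug_mi_unit,
    fdr_adjust,
    mixed_anova,
    one_sample_t_with_effect,
    paired_t_with_effect,
    population_histogram,
    population_tests,
    unit_metrics,
)


def brute_force_auroc(rf, away):
    wins = sum((a > b) + 0.5 * (a == b) for a in rf for b in away)
    return wins / (len(rf) * len(away))


class TestAuroc:
    def test_hand_example(self):
        assert auroc([2, 3, 4], [1, 2, 3]) == pytest.approx((6 + 0.5 * 2) / 9)

    def test_identical_distributions(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert auroc(x, x) == 0.5

    def test_full_separation(self):
        assert auroc([10, 11, 12], [1, 2, 3]) == 1.0
        assert auroc([1, 2, 3], [10, 11, 12]) == 0.0

    def test_too_few_trials_missing(self):
        assert np.isnan(auroc([1.0], [2.0, 3.0]))

    @given(
        stn.lists(stn.integers(0, 20), min_size=2, max_size=50),
        stn.lists(stn.integers(0, 20), min_size=2, max_size=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, rf, away):
        assert auroc(rf, away) == pytest.approx(brute_force_auroc(rf, away), abs=1e-12)


class TestAurocFlip:
    def test_below_half_flipped(self):
        nd, d = auroc_flip([0.4], [0.45])
        assert nd[0] == pytest.approx(0.6) and d[0] == pytest.approx(0.55)

    def test_above_half_unchanged(self):
        nd, d = auroc_flip([0.6], [0.55])
        assert nd[0] == 0.6 and d[0] == 0.55

    def test_exactly_half_unchanged(self):
        nd, d = auroc_flip([0.5], [0.3])
        assert nd[0] == 0.5 and d[0] == 0.3


class TestDrugMi:
    def test_equal_rates_zero(self):
        assert drug_mi(10.0, 10.0) == 0.0

    def test_zero_drug_rate_one(self):
        assert drug_mi(5.0, 0.0) == 1.0

    def test_hand_value(self):
        assert drug_mi(30.0, 21.0) == pytest.approx(9 / 51)

    def test_both_zero_missing(self):
        assert np.isnan(drug_mi(0.0, 0.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            drug_mi(-1.0, 1.0)

    @given(stn.floats(0.01, 100), stn.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_bounds(self, a, b):
        mi = drug_mi(a, b)
        assert -1.0 <= mi <= 1.0
        assert drug_mi(b, a) == pytest.approx(-mi)

    def test_condition_averaging(self):
        rows = []
        for att in ("RF", "away1"):
            for mot in ("dir1", "dir2"):
                for drug, rate in (("off", 30.0), ("on", 21.0)):
                    for rep in range(3):
                        rows.append(
                            dict(epoch="pre_dim", attention=att, motion=mot, drug=drug, rate=rate)
                        )
        assert drug_mi_unit(pd.DataFrame(rows), "pre_dim") == pytest.approx(9 / 51)


class TestCohensDprime:
    def test_equal_means_zero(self):
        assert cohens_dprime([1, 2, 3], [3, 2, 1]) == 0.0

    def test_direct_formula(self):
        rng = np.random.default_rng(0)
        rf = rng.normal(12, 4, 5000)
        away = rng.normal(10, 4, 5000)
        assert cohens_dprime(rf, away) == pytest.approx(0.5, abs=0.05)

    def test_estimator_recovery(self):
        rng = np.random.default_rng(1)
        est = [
            cohens_dprime(rng.normal(0.8, 1, 60), rng.normal(0.0, 1, 60)) for _ in range(1000)
        ]
        assert np.mean(est) == pytest.approx(0.8, abs=0.03)

    def test_zero_pooled_sd_missing(self):
        assert np.isnan(cohens_dprime([1.0, 1.0], [1.0, 1.0]))


def _balanced_design(rng, att_effect=1.0, drug_effect=1.0, n=20, base=10.0):
    rows = []
    for att in ("RF", "away1", "away2"):
        for drug in ("off", "on"):
            for mot in ("dir1", "dir2"):
                mu = base
                if att == "RF":
                    mu *= att_effect
                if drug == "on":
                    mu *= drug_effect
                for r in rng.normal(mu, 3.0, n):
                    rows.append(dict(unit_id="u", epoch="pre_dim", attention=att, drug=drug, motion=mot, rate=r))
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        data = _balanced_design(rng, att_effect=1.3)
        fast = anova3(data).set_index("effect")
        # force the statsmodels path by unbalancing with a duplicated row set
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.ols("rate ~ C(attention) * C(drug) * C(motion)", data=data).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        for eff, name in [("attention", "C(attention)"), ("drug", "C(drug)"), ("attention:drug", "C(attention):C(drug)")]:
            assert fast.loc[eff, "F"] == pytest.approx(ref.loc[name, "F"], rel=1e-8)

    def test_gate_detects_planted_attention(self):
        # attention flag fires on the planted effect; the drug main effect
        # stays at its nominal false-alarm rate (the combined drug flag pools
        # 4 tests at alpha=0.05, so its null rate is ~18% by construction)
        rng = np.random.default_rng(3)
        att_hits, drug_main_fp = 0, 0
        for i in range(40):
            data = _balanced_design(rng, att_effect=1.5, n=60)
            out = anova_gate(data)
            att_hits += bool(out.attention_modulated.iloc[0])
            drug_main_fp += bool(out.p_drug.iloc[0] < 0.05)
        assert att_hits >= 38
        assert drug_main_fp <= 7

    def test_zero_variance_excluded(self):
        data = _balanced_design(np.random.default_rng(4), n=5)
        data["rate"] = 1.0
        out = anova_gate(data)
        assert out.excluded.iloc[0]

    def test_unbalanced_falls_back(self):
        rng = np.random.default_rng(5)
        data = _balanced_design(rng, att_effect=2.0, n=12)
        data = data.drop(index=data.index[:3])
        tab = anova3(data)
        assert np.isfinite(tab.set_index("effect").loc["attention", "p"])


class TestResponseTypes:
    def test_visual(self):
        assert classify_response_type(10, 20, 12) == "visual"

    def test_visuo_attention(self):
        assert classify_response_type(10, 15, 16) == "visuo-attention"

    def test_attention(self):
        assert classify_response_type(10, 11, 13) == "attention"

    def test_other(self):
        assert classify_response_type(10, 11, 10) == "other"

    def test_zero_baseline_floor(self):
        # floored at 0.5 spikes/s: transient 1.0 is a 100% change
        assert classify_response_type(0.0, 1.0, 0.3) == "visual"


class TestPopulationHistogram:
    def test_single_unit_peak_one(self):
        psth = pd.DataFrame([[1.0, 4.0, 2.0]], index=["u"])
        out = population_histogram(psth)
        assert out["mean"].max() == 1.0
        assert (out["sem"] == 0).all()

    def test_identical_units_zero_sem(self):
        psth = pd.DataFrame([[1.0, 4.0, 2.0]] * 2, index=["a", "b"])
        out = population_histogram(psth)
        assert np.allclose(out["sem"], 0.0)

    def test_scale_invariance(self):
        shape = np.array([1.0, 3.0, 2.0])
        psth = pd.DataFrame([shape * 10, shape * 100], index=["a", "b"])
        out = population_histogram(psth)
        np.testing.assert_allclose(out["mean"], shape / 3.0)

    def test_all_zero_unit_excluded(self):
        psth = pd.DataFrame([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0]], index=["a", "z"])
        with pytest.warns(UserWarning):
            out = population_histogram(psth)
        assert out["mean"].max() == 1.0


class TestFdr:
    def test_step_up_thresholds(self):
        reject, _ = fdr_adjust([0.01, 0.02, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, adj = fdr_adjust([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_p_unchanged(self):
        _, adj = fdr_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        _, adj = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPopulationTests:
    def test_planted_drugmi_effect_size(self):
        rng = np.random.default_rng(1)
        res = [
            one_sample_t_with_effect(rng.normal(0.15, 0.17, 37))["cohens_d"] for _ in range(400)
        ]
        assert np.mean(res) == pytest.approx(0.15 / 0.17, abs=0.05)

    def test_paired_t_type_one_error(self):
        rng = np.random.default_rng(2)
        hits = sum(
            paired_t_with_effect(rng.normal(size=50), rng.normal(size=50))["p"] < 0.05
            for _ in range(1000)
        )
        assert hits / 1000 == pytest.approx(0.05, abs=0.02)

    def test_groups_table(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "cell_class": ["narrow"] * 30 + ["broad"] * 30,
                "auroc_nodrug": rng.uniform(0.5, 0.9, 60),
                "auroc_drug": rng.uniform(0.5, 0.9, 60),
                "drug_mi": rng.normal(0.15, 0.1, 60),
            }
        )
        out = population_tests(df, "cell_class")
        assert set(out.group) == {"narrow", "broad"}
        assert set(out.test) == {"auroc_paired_t", "drugmi_one_sample_t"}

    def test_mixed_anova_runs(self):
        rng = np.random.default_rng(4)
        rows = []
        for u in range(40):
            grp = "narrow" if u < 20 else "broad"
            for drug in ("off", "on"):
                rows.append(dict(unit_id=u, grp=grp, drug=drug, auroc=rng.uniform(0.4, 0.9)))
        tab = mixed_anova(pd.DataFrame(rows), "auroc", "drug", "grp", "unit_id")
        assert "eta2p" in tab.columns and len(tab) >= 3


class TestUnitMetricsIntegration:
    def test_planted_effects_recovered(self, small_rates):
        m = unit_metrics(small_rates)
        predim = m[m.epoch == "pre_dim"].set_index("unit_id")
        assert predim.loc["att_drug", "auroc_nodrug"] > 0.65
        assert predim.loc["att_drug", "drug_mi"] > 0.05
        assert abs(predim.loc["flat", "auroc_nodrug"] - 0.5) < 0.12
        assert abs(predim.loc["flat", "drug_mi"]) < 0.05
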