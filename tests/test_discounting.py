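import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datedelay.discounting import (ConvergenceWarning, DiscountModelSpec,
                                   choice_probability, date_premium,
                                   hdi, hierarchical_fit, loo_compare,
                                   retest_reliability, screening_rule,
                                   subjective_value)
from datedelay.simulate import (ParticipantParams, draw_participants,
                                simulate_choices, simulate_dataset)
from datedelay.geometry import build_block_plan


class TestSubjectiveValue:
    def test_immediate_reward_keeps_face_value(self):
        assert subjective_value(35, 0, {"k": 0.1}) == 35.0
        assert subjective_value(35, 0, {"beta": 0.9, "delta": 0.99},
                                "quasi_hyperbolic") == 35.0

    def test_hyperbolic_example(self):
        # 35 euro at 29 days, k = 0.01 per day: 35/1.29
        assert subjective_value(35, 29, {"k": 0.01}) == \
            pytest.approx(27.13, abs=0.01)

    def test_zero_rate_is_identity(self):
        assert subjective_value(50, 100, {"k": 0.0}) == 50.0
        assert subjective_value(50, 100, {"k": 0.0}, "exponential") == 50.0
        assert subjective_value(50, 100, {"beta": 1.0, "delta": 1.0},
                                "quasi_hyperbolic") == 50.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            subjective_value(-1, 10, {"k": 0.1})
        with pytest.raises(ValueError):
            subjective_value(10, 10, {"k": -0.1})
        with pytest.raises(ValueError):
            subjective_value(10, 10, {"beta": 1.5, "delta": 0.9},
                             "quasi_hyperbolic")

    @given(k=st.floats(1e-4, 1.0), a=st.floats(1.0, 100.0),
           d1=st.floats(0.0, 200.0), extra=st.floats(0.5, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_delay(self, k, a, d1, extra):
        for form, params in [("hyperbolic", {"k": k}),
                             ("exponential", {"k": k}),
                             ("quasi_hyperbolic", {"beta": 0.9,
                                                   "delta": 0.995})]:
            v1 = subjective_value(a, d1, params, form)
            v2 = subjective_value(a, d1 + extra, params, form)
            assert v2 < v1

    @given(k=st.floats(1e-6, 1e-3), d=st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_hyperbolic_matches_exponential_for_small_kd(self, k, d):
        if k * d < 1e-2:
            h = subjective_value(100, d, {"k": k})
            e = subjective_value(100, d, {"k": k}, "exponential")
            assert abs(h - e) / e < 1e-3


class TestChoiceProbability:
    def test_equal_values_coin_flip(self):
        assert choice_probability(10, 10, 2.0) == 0.5

    def test_zero_sensitivity_coin_flip(self):
        assert choice_probability(3, 97, 0.0) == 0.5

    def test_logistic_closed_form(self):
        assert choice_probability(10, 20, 1.0) == \
            pytest.approx(1 / (1 + np.exp(-10)))

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            choice_probability(1, 2, -1.0)


class TestHdi:
    def test_point_mass(self):
        assert hdi(np.full(200, 3.0)) == (3.0, 3.0)

    def test_uniform_length(self):
        rng = np.random.default_rng(0)
        lo, hi = hdi(rng.random(1_000_000))
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_matches_analytic(self):
        rng = np.random.default_rng(1)
        lo, hi = hdi(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_symmetric_sample_matches_equal_tailed(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200_000)
        lo, hi = hdi(x)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.03)
        assert hi == pytest.approx(qhi, abs=0.03)

    def test_multimodal_warns_but_returns_interval(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-6, 0.3, 5000),
                            rng.normal(6, 0.3, 5000)])
        with pytest.warns(UserWarning, match="multimodal"):
            lo, hi = hdi(x)
        assert lo < hi


class TestScreeningRule:
    @pytest.mark.parametrize("lo,hi,include", [
        (0.1, 1.5, True),
        (-0.1, 0.4, False),   # includes 0
        (2.5, 3.0, False),    # entirely above 2
        (-1.0, -0.2, False),  # entirely below 0
        (0.01, 1.99, True),
    ])
    def test_cases(self, lo, hi, include):
        assert screening_rule(lo, hi) is include

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            screening_rule(1.0, 0.5)


class TestRetestReliability:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        r, n = retest_reliability(x, x)
        assert r == pytest.approx(1.0) and n == 10

    def test_negated_vector(self):
        x = np.arange(10.0)
        r, _ = retest_reliability(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            retest_reliability(np.ones(5), np.arange(5.0))

    def test_fisher_interval_coverage(self):
        """r for bivariate-normal rho=0.7, n=31 lands in the Fisher-z range."""
        rng = np.random.default_rng(7)
        inside = 0
        reps = 200
        for _ in range(reps):
            z = rng.multivariate_normal([0, 0], [[1, .7], [.7, 1]], size=31)
            r, _ = retest_reliability(z[:, 0], z[:, 1])
            inside += 0.45 < r < 0.87
        assert inside / reps >= 0.95

    def test_outlier_removal_drops_pair(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        y = x + rng.normal(0, 0.2, 30)
        x[0], y[0] = 8.0, -8.0
        r_raw, n_raw = retest_reliability(x, y)
        r_clean, n_clean = retest_reliability(x, y, remove_outliers=True)
        assert n_clean < n_raw and r_clean > r_raw


class TestDatePremium:
    def test_identical_conditions_centred_on_zero(self):
        rng = np.random.default_rng(0)
        lnk = rng.normal(-5, 1, 20)
        tab = pd.DataFrame({"participant": range(20), "lnk_delay": lnk,
                            "lnk_date": lnk})
        res = date_premium(tab, seed=1)
        assert abs(res.mean) < 0.01
        assert 0.3 < res.p_less_zero < 0.7

    def test_consistent_negative_shift_is_certain(self):
        rng = np.random.default_rng(1)
        lnk = rng.normal(-5, 1, 20)
        tab = pd.DataFrame({"participant": range(20), "lnk_delay": lnk,
                            "lnk_date": lnk - 0.45 + rng.normal(0, 0.02, 20)})
        res = date_premium(tab, seed=1)
        assert res.p_less_zero > 0.999
        assert res.hdi_low < res.differences.mean() < res.hdi_high

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({"participant": range(15),
                            "lnk_delay": rng.normal(-5, 1, 15),
                            "lnk_date": rng.normal(-5.4, 1, 15)})
        swapped = tab.rename(columns={"lnk_delay": "lnk_date",
                                      "lnk_date": "lnk_delay"})
        a = date_premium(tab, seed=3)
        b = date_premium(swapped, seed=3)
        assert np.allclose(a.differences, -b.differences)

    def test_missing_condition_dropped(self):
        tab = pd.DataFrame({"participant": range(5),
                            "lnk_delay": [-5, -5, np.nan, -5, -6],
                            "lnk_date": [-5.5, -5.2, -5, -5.9, -6.1]})
        res = date_premium(tab, seed=0)
        assert len(res.differences) == 4


@pytest.fixture(scope="module")
def small_fit(small_choices):
    choices, _ = small_choices
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return hierarchical_fit(choices, seed=31, chains=2, warmup=300,
                                draws=300)


class TestHierarchicalFit:
    def test_deterministic_for_seed(self, small_choices):
        choices, _ = small_choices
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            a = hierarchical_fit(choices, seed=3, chains=1, warmup=100,
                                 draws=100)
            b = hierarchical_fit(choices, seed=3, chains=1, warmup=100,
                                 draws=100)
        assert np.array_equal(a.theta, b.theta)

    def test_recovers_individual_ordering(self, small_choices, small_fit):
        _, parts = small_choices
        from scipy.stats import spearmanr
        true = [p.lnk_delay for p in parts]
        est = small_fit.participant_table().lnk_delay
        assert spearmanr(true, est).statistic > 0.7

    def test_premium_antisymmetry_in_table(self, small_fit):
        tab = small_fit.participant_table()
        assert np.allclose(tab.premium, tab.lnk_date - tab.lnk_delay)

    def test_quasi_hyperbolic_form_fits_and_ranks(self, small_choices):
        """The beta-delta form still orders participants by impulsivity."""
        choices, parts = small_choices
        from scipy.stats import spearmanr
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = hierarchical_fit(choices,
                                   DiscountModelSpec("quasi_hyperbolic"),
                                   seed=9, chains=1, warmup=250, draws=250)
        assert fit.theta.shape[-1] == 4
        true = [p.lnk_delay for p in parts]
        est = fit.participant_table().lnk_delay
        assert spearmanr(true, est).statistic > 0.6

    def test_requires_both_conditions(self, small_choices):
        choices, _ = small_choices
        only_delay = choices[choices.condition == "delay"]
        with pytest.raises(ValueError, match="condition"):
            hierarchical_fit(only_delay, seed=0, chains=1, warmup=10,
                             draws=10)

    def test_switch_point_brackets_estimate(self, item_bank):
        """A deterministic chooser's k must fall between the implied rates of
        the items around their switch point."""
        from datedelay.simulate import implied_discount_rates
        k_true = 0.012
        p = ParticipantParams(0, np.log(k_true), 0.0, inv_temp=1e6)
        plan = build_block_plan(27, "delay", seed=0)
        frames = []
        for pid in range(4):  # clones stabilise the hierarchy
            ch = simulate_choices(p, item_bank, plan, seed=pid)
            ch["participant"] = pid
            frames.append(ch)
        choices = pd.concat(frames, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = hierarchical_fit(choices, seed=5, chains=2, warmup=400,
                                   draws=400)
        ks = np.sort(implied_discount_rates(item_bank))
        k_lo = ks[ks < k_true].max()
        k_hi = ks[ks > k_true].min()
        est = np.exp(fit.participant_table().lnk_delay.iloc[0])
        assert k_lo <= est <= k_hi

    def test_shrinkage_toward_group_mean_with_fewer_trials(self, item_bank):
        """A two-sided responder far from the group mean shrinks toward it
        as their trials are removed."""
        plan = build_block_plan(27, "delay", seed=1)
        d_full_all, d_thin_all = [], []
        for rep in range(3):
            parts = draw_participants(9, seed=40 + rep)
            target = ParticipantParams(9, lnk_delay=-6.5,
                                       date_premium_true=-0.4, inv_temp=0.6)
            frames = [simulate_choices(p, item_bank, plan, seed=100 * rep + i)
                      for i, p in enumerate(parts)]
            cht = simulate_choices(target, item_bank, plan,
                                   seed=100 * rep + 99)
            full = pd.concat(frames + [cht], ignore_index=True)
            thin = full[(full.participant != 9) | (full.trial % 27 == 5)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                f_full = hierarchical_fit(full, seed=2, chains=2,
                                          warmup=300, draws=300)
                f_thin = hierarchical_fit(thin, seed=2, chains=2,
                                          warmup=300, draws=300)
            est_f = f_full.participant_table().set_index("participant")
            est_t = f_thin.participant_table().set_index("participant")
            d_full_all.append(abs(est_f.lnk_delay[9]
                                  - f_full.mu[..., 0].mean()))
            d_thin_all.append(abs(est_t.lnk_delay[9]
                                  - f_thin.mu[..., 0].mean()))
        assert np.mean(d_thin_all) < np.mean(d_full_all)
        assert sum(t < f for t, f in zip(d_thin_all, d_full_all)) >= 2

    def test_one_sided_chooser_stays_finite(self, item_bank):
        """An all-LLR chooser has an unbounded MLE; the hierarchical prior
        keeps the estimate finite and near the group."""
        plan = build_block_plan(27, "delay", seed=1)
        parts = draw_participants(7, seed=44)
        extreme = ParticipantParams(7, lnk_delay=-12.0,
                                    date_premium_true=0.0, inv_temp=1e3)
        frames = [simulate_choices(p, item_bank, plan, seed=70 + i)
                  for i, p in enumerate(parts)]
        che = simulate_choices(extreme, item_bank, plan, seed=99)
        assert che.choice_llr.dropna().eq(1.0).all()
        choices = pd.concat(frames + [che], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = hierarchical_fit(choices, seed=3, chains=2, warmup=300,
                                   draws=300)
        tab = fit.participant_table().set_index("participant")
        mu = fit.mu[..., 0].mean()
        sigma = fit.sigma[..., 0].mean()
        assert np.isfinite(tab.lnk_delay[7])
        assert abs(tab.lnk_delay[7] - mu) < 4 * sigma


class TestLooCompare:
    def test_model_against_itself_zero_difference(self, small_fit):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = loo_compare({"a": small_fit, "b": small_fit})
        assert tab["elpd_diff"].iloc[1] == 0.0

    def test_mismatched_observations_rejected(self, small_choices, small_fit):
        choices, _ = small_choices
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            other = hierarchical_fit(choices[choices.participant < 4],
                                     seed=0, chains=1, warmup=50, draws=50)
            with pytest.raises(ValueError, match="observations"):
                loo_compare({"a": small_fit, "b": other})

    def test_hyperbolic_beats_exponential_on_hyperbolic_data(self):
        """Generating form ranks at least as well in most replicates."""
        wins = 0
        reps = 10
        for r in range(reps):
            ds = simulate_dataset(10, seed=300 + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fh = hierarchical_fit(ds["choices"],
                                      DiscountModelSpec("hyperbolic"),
                                      seed=r, chains=2, warmup=250, draws=250)
                fe = hierarchical_fit(ds["choices"],
                                      DiscountModelSpec("exponential"),
                                      seed=r, chains=2, warmup=250, draws=250)
                tab = loo_compare({"hyperbolic": fh, "exponential": fe})
            wins += tab.index[0] == "hyperbolic"
        assert wins >= 8
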