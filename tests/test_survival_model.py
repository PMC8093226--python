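"""BCR labeling, z-normalization, elastic-net Cox fitting, scoring,
threshold learning, the published six-feature model and the combined
clinical model."""

import numpy as np
import pandas as pd
import pytest

from histotyping.io_core import ValidationError
from histotyping.survival_model import (
    PUBLISHED_MODEL_HAZARD_RATIOS,
    CoxEnModel,
    apply_zscore,
    bcr_label,
    breslow_log_partial_likelihood,
    fit_elasticnet_cox,
    fit_zscore,
    histotyping_plus,
    learn_threshold,
    published_model,
    risk_score,
)


class TestBcrLabel:
    def test_second_elevated_test_defines_the_event(self):
        assert bcr_label([(1, 0.1), (2, 0.3), (3, 0.4)]) == (3, 1)

    def test_elevated_tests_need_not_be_consecutive(self):
        assert bcr_label([(1, 0.3), (2, 0.15), (3, 0.25)]) == (3, 1)

    def test_all_low_censors_at_last_test(self):
        assert bcr_label([(1, 0.1), (2, 0.2), (5, 0.15)]) == (5, 0)

    def test_single_elevated_test_censors(self):
        assert bcr_label([(1, 0.3), (4, 0.1)]) == (4, 0)

    def test_exactly_0_2_is_not_elevated(self):
        assert bcr_label([(1, 0.2), (2, 0.2), (3, 0.2)]) == (3, 0)

    def test_no_qualifying_test_excludes_patient(self):
        with pytest.raises(ValidationError, match="excluded"):
            bcr_label([(0.01, 0.1)])  # < 30 days post-surgery


class TestZscore:
    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(3, 7, size=(50, 4)),
                         columns=list("abcd"))
        mu, sigma = fit_zscore(X)
        Z = apply_zscore(X, mu, sigma)
        np.testing.assert_allclose(Z.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(ddof=1), 1, atol=1e-9)

    def test_validation_uses_training_parameters(self):
        rng = np.random.default_rng(1)
        X_tr = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X_va = pd.DataFrame(rng.normal(5, 2, size=(30, 2)), columns=["a", "b"])
        mu, sigma = fit_zscore(X_tr)
        Z_va = apply_zscore(X_va, mu, sigma)
        assert abs(Z_va["a"].mean()) > 1  # not re-centered on itself

    def test_constant_column_flagged_and_excluded(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        mu, sigma = fit_zscore(X)
        assert np.isnan(sigma["c"])
        assert list(apply_zscore(X, mu, sigma).columns) == ["a"]


def _simulate_cox(n, beta, seed, censor_frac=0.3, shape=1.5, scale=8.0):
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    eta = X.to_numpy() @ np.asarray(beta)
    T = scale * (-np.log(rng.uniform(size=n)) / np.exp(eta)) ** (1 / shape)
    C = rng.uniform(0, np.quantile(T, 1 - censor_frac) * 2, size=n)
    event = (T <= C).astype(int)
    return X, np.minimum(T, C), event


class TestElasticNetCox:
    def test_infinite_penalty_shrinks_everything_to_zero(self):
        X, t, e = _simulate_cox(120, [0.8, 0.0, -0.8], seed=0)
        m = fit_elasticnet_cox(X, t, e, seed=0, lambdas=[1e6])
        assert np.all(m.beta == 0.0)

    def test_support_recovery_on_planted_signal(self):
        recovered = 0
        for seed in range(3):
            beta = np.zeros(20)
            beta[[2, 7, 13]] = [0.8, -0.8, 0.8]
            X, t, e = _simulate_cox(300, beta, seed=seed)
            m = fit_elasticnet_cox(X, t, e, seed=seed)
            if {2, 7, 13} <= set(np.nonzero(m.beta)[0]):
                recovered += 1
        assert recovered == 3

    def test_ridge_limit_keeps_all_features(self):
        X, t, e = _simulate_cox(150, [0.5, -0.5, 0.3, 0.0, 0.0], seed=1)
        m = fit_elasticnet_cox(X, t, e, alpha=0.0, seed=1)
        assert np.all(m.beta != 0.0)

    def test_too_few_events_rejected(self):
        X, t, _ = _simulate_cox(30, [0.5], seed=2)
        with pytest.raises(ValidationError):
            fit_elasticnet_cox(X, t, np.zeros(30, dtype=int))

    def test_refit_recovers_own_coefficients(self):
        # proportional-hazards self-consistency at n = 1000
        from lifelines import CoxPHFitter

        beta = np.array([0.6, -0.4, 0.0, 0.3, 0.0, -0.2])
        X, t, e = _simulate_cox(1000, beta, seed=3)
        df = X.copy()
        df["time"], df["event"] = t, e
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(cph.params_[X.columns], beta, atol=0.15)

    def test_breslow_likelihood_matches_lifelines_on_untied_data(self):
        from lifelines import CoxPHFitter

        X, t, e = _simulate_cox(80, [0.5, -0.3], seed=4)
        df = X.copy()
        df["time"], df["event"] = t, e
        cph = CoxPHFitter().fit(df, "time", "event")
        beta_hat = cph.params_[X.columns].to_numpy()
        ll = breslow_log_partial_likelihood(beta_hat, X.to_numpy(), t, e)
        assert ll == pytest.approx(cph.log_likelihood_, rel=1e-6)


class TestRiskScore:
    def _model(self, threshold=None):
        m = CoxEnModel(feature_names=["a", "b"], beta=np.array([0.7, -0.3]),
                       threshold=threshold)
        m.mu = np.array([10.0, 2.0])
        m.sigma = np.array([4.0, 1.0])
        return m

    def test_training_mean_scores_at_half(self):
        lp, score, _ = risk_score(self._model(), {"a": 10.0, "b": 2.0})
        assert lp[0] == 0.0
        assert score[0] == 0.5

    def test_monotone_in_positive_weight_feature(self):
        m = self._model()
        _, s1, _ = risk_score(m, {"a": 10.0, "b": 2.0})
        _, s2, _ = risk_score(m, {"a": 14.0, "b": 2.0})
        assert s2[0] > s1[0]

    def test_score_exactly_at_threshold_is_low_risk(self):
        m = self._model(threshold=0.5)
        _, score, cat = risk_score(m, {"a": 10.0, "b": 2.0})
        assert score[0] == 0.5
        assert cat[0] == "low"

    def test_missing_feature_named_in_error(self):
        with pytest.raises(ValidationError, match="'b'"):
            risk_score(self._model(), pd.DataFrame({"a": [1.0]}))

    def test_unset_normalization_rejected(self):
        m = CoxEnModel(feature_names=["a"], beta=np.array([1.0]))
        with pytest.raises(ValidationError):
            risk_score(m, {"a": 0.0})

    def test_json_round_trip(self, tmp_path):
        m = self._model(threshold=0.62)
        m.lam = 0.031
        m.to_json(tmp_path / "model.json")
        back = CoxEnModel.from_json(tmp_path / "model.json")
        assert back.feature_names == m.feature_names
        np.testing.assert_allclose(back.beta, m.beta)
        np.testing.assert_allclose(back.mu, m.mu)
        assert back.threshold == 0.62 and back.lam == 0.031


class TestLearnThreshold:
    def _clustered(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        low = rng.uniform(0.1, 0.35, n // 2)
        high = rng.uniform(0.65, 0.9, n // 2)
        scores = np.concatenate([low, high])
        t_low = rng.exponential(8.0, n // 2)
        t_high = rng.exponential(2.0, n // 2)
        time = np.concatenate([t_low, t_high])
        event = (rng.uniform(size=n) < 0.8).astype(int)
        return scores, time, event

    def test_separated_clusters_split_between_them(self):
        scores, time, event = self._clustered()
        thr = learn_threshold(scores, time, event)
        # the cut falls in (or at the edge of) the gap between the clusters
        assert 0.3 <= thr <= 0.7
        high = scores > thr
        assert abs(int(high.sum()) - len(scores) // 2) <= 5

    def test_sign_reversal_mirrors_the_partition(self):
        scores, time, event = self._clustered(seed=1)
        thr = learn_threshold(scores, time, event)
        thr_neg = learn_threshold(-scores, time, event)
        np.testing.assert_array_equal(scores > thr, ~(-scores > thr_neg))

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValidationError):
            learn_threshold(np.full(50, 0.5), np.arange(1, 51.0),
                            np.ones(50, dtype=int))

    def test_null_scores_do_not_validate(self):
        """Thresholds learned on pure-noise training scores should not
        produce significant validation splits."""
        from lifelines.statistics import logrank_test

        nonsig = 0
        n_sims = 50
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            scores = rng.uniform(size=n)
            time = rng.exponential(5.0, n)
            event = (rng.uniform(size=n) < 0.7).astype(int)
            half = n // 2
            thr = learn_threshold(scores[:half], time[:half], event[:half])
            high = scores[half:] > thr
            if high.sum() == 0 or (~high).sum() == 0:
                nonsig += 1
                continue
            res = logrank_test(time[half:][high], time[half:][~high],
                               event[half:][high], event[half:][~high])
            if res.p_value > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_sims


class TestPublishedModel:
    def test_six_features_with_log_hazard_weights(self):
        m = published_model()
        assert len(m.feature_names) == 6
        assert m.beta[m.feature_names.index("shape:median:distance_ratio")] == \
            pytest.approx(np.log(1.100), abs=1e-12)

    def test_hazard_ratios_round_trip(self):
        m = published_model()
        for name, hr in PUBLISHED_MODEL_HAZARD_RATIOS.items():
            assert m.hazard_ratios[name] == pytest.approx(hr, abs=1e-9)

    def test_scoring_requires_reference_normalization(self):
        m = published_model()
        x = {name: 0.0 for name in m.feature_names}
        with pytest.raises(ValidationError):
            risk_score(m, x)
        mu = pd.Series(0.0, index=m.feature_names)
        sigma = pd.Series(1.0, index=m.feature_names)
        m.set_normalization(mu, sigma)
        _, score, _ = risk_score(m, x)
        assert score[0] == 0.5


class TestHistotypingPlus:
    def _cohort(self, seed=0, n=250):
        rng = np.random.default_rng(seed)
        score_signal = rng.normal(size=n)
        psa_signal = rng.normal(size=n)
        eta = 0.7 * score_signal + 0.6 * psa_signal
        T = 8.0 * (-np.log(rng.uniform(size=n)) / np.exp(eta)) ** (1 / 1.5)
        C = rng.uniform(0, np.quantile(T, 0.9) * 2, size=n)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
        clinical = pd.DataFrame(
            {
                "grade_group": rng.integers(1, 6, size=n),
                "psa_preop": np.exp(np.log(7) + 0.5 * psa_signal),
                "time": time,
                "event": event,
            }
        )
        scores = 1 / (1 + np.exp(-score_signal))
        return scores, clinical, time, event

    def test_design_has_four_grade_dummies_before_selection(self):
        scores, clinical, time, event = self._cohort()
        model, design = histotyping_plus(scores, clinical, time, event, seed=0)
        dummies = [c for c in design.columns if c.startswith("grade_group_")]
        assert len(dummies) == 4
        assert set(dummies) == {f"grade_group_{g}" for g in (2, 3, 4, 5)}

    def test_psa_enters_as_log2(self):
        scores, clinical, time, event = self._cohort(seed=1)
        _, design = histotyping_plus(scores, clinical, time, event, seed=1)
        doubled = clinical.copy()
        doubled["psa_preop"] *= 2.0
        _, design2 = histotyping_plus(scores, doubled, time, event, seed=1)
        np.testing.assert_allclose(
            design2["log2_psa"] - design["log2_psa"], 1.0, atol=1e-12
        )

    def test_absent_grade_group_drops_its_dummy(self):
        scores, clinical, time, event = self._cohort(seed=2)
        clinical = clinical.copy()
        clinical.loc[clinical["grade_group"] == 5, "grade_group"] = 4
        _, design = histotyping_plus(scores, clinical, time, event, seed=2)
        assert "grade_group_5" not in design.columns

    def test_combined_model_beats_score_alone_when_psa_informative(self):
        from histotyping.evaluation import harrell_cindex

        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            scores, clinical, time, event = self._cohort(seed=10 + seed, n=300)
            half = 150
            model, design = histotyping_plus(
                scores[:half], clinical.iloc[:half], time[:half], event[:half],
                seed=seed,
            )
            va = pd.DataFrame(
                {
                    "histotyping_score": scores[half:],
                    "log2_psa": np.log2(clinical["psa_preop"][half:]),
                }
            )
            for g in (2, 3, 4, 5):
                if f"grade_group_{g}" in model.feature_names:
                    va[f"grade_group_{g}"] = (
                        clinical["grade_group"][half:] == g
                    ).astype(float).to_numpy()
            _, combined, _ = risk_score(model, va)
            c_comb = harrell_cindex(combined, time[half:], event[half:])
            c_score = harrell_cindex(scores[half:], time[half:], event[half:])
            if c_comb >= c_score:
                wins += 1
        assert wins >= 6
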