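"""Effect estimation: exact estimator identities, oracle comparisons on
confounded data, and bootstrap interval semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ehrcf.features import CodeMatrix, log_transform
from ehrcf.structure import EdgeVoteGraph, TieredGraph
from ehrcf.effects import (
    PotentialOutcomeFrame, binarize_treatment, adjustment_set, hurdle_design,
    fit_propensity, effect_iptw, effect_ps_matching, effect_stratification,
    bootstrap_ci, estimate_effect, CausalEffectEstimator,
)
from ehrcf.synthetic import confounded_spec, simulate_cohort, true_effect


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_counts_to_indicator(self):
        assert binarize_treatment([0, 1, 5]).tolist() == [0, 1, 1]

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="no exposed"):
            binarize_treatment([0, 0, 0])

    def test_log_transformed_column_rejected(self):
        m = log_transform(CodeMatrix(pd.DataFrame({"a": [0, 3, 7]})))
        with pytest.raises(ValueError):
            binarize_treatment(m.values["a"])


class TestAdjustmentSet:
    def _votes(self, edges):
        nodes = sorted({n for e in edges for n in e})
        return EdgeVoteGraph(nodes=nodes,
                             tiers={n: 2 for n in nodes},
                             votes={e: 10 for e in edges}, K=10)

    def test_textbook_confounder(self):
        v = self._votes([("c", "t"), ("c", "y"), ("t", "y")])
        assert adjustment_set(v, "t", "y") == ["c"]

    def test_no_confounders_empty_set(self):
        v = self._votes([("t", "y")])
        assert adjustment_set(v, "t", "y") == []

    def test_missing_treatment_raises(self):
        v = self._votes([("t", "y")])
        with pytest.raises(KeyError):
            adjustment_set(v, "zz", "y")

    def test_ground_truth_graph_yields_generator_confounders(self):
        spec = confounded_spec()
        g = TieredGraph(spec.node_names, spec.tier_of,
                        directed=set(spec.edges()))
        got = adjustment_set(g, "cvd_late_effects", "adrd")
        assert got == ["diabetes", "hypertension"]


class TestPropensityFit:
    def test_intercept_only_scores_equal_treated_fraction(self):
        T = np.r_[np.ones(30), np.zeros(70)].astype(int)
        m = fit_propensity(np.empty((100, 0)), T)
        assert np.allclose(m.scores, 0.3)

    def test_independent_covariate_coefficient_near_zero(self, rng):
        n = 10_000
        x = rng.normal(size=(n, 1))
        T = (rng.random(n) < 0.4).astype(int)
        m = fit_propensity(x, T)
        assert abs(m.coef[0]) < 0.1

    def test_separation_handled_with_penalty(self):
        x = np.r_[np.ones(40), np.zeros(40)].reshape(-1, 1)
        T = np.r_[np.ones(40), np.zeros(40)].astype(int)
        with pytest.warns(UserWarning, match="separation?"):
            m = fit_propensity(x, T)
        assert (m.scores >= 0.01).all() and (m.scores <= 0.99).all()

    def test_monotone_in_single_strong_covariate(self, rng):
        n = 4000
        x = rng.normal(size=n)
        T = (rng.random(n) < expit(2 * x)).astype(int)
        m = fit_propensity(x.reshape(-1, 1), T)
        order = np.argsort(x)
        assert (np.diff(m.scores[order]) >= -1e-12).all()

    def test_overfit_guard(self):
        with pytest.raises(ValueError, match="overfit"):
            fit_propensity(np.random.default_rng(0).normal(size=(30, 20)),
                           np.r_[np.ones(15), np.zeros(15)].astype(int))


# ---------------------------------------------------------------------------
# exact identities
# ---------------------------------------------------------------------------

def _randomized_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    T = (rng.random(n) < 0.5).astype(int)
    return T, rng


class TestEstimatorIdentities:
    def test_perfect_effect_under_randomization(self):
        T, _ = _randomized_frame()
        frame = PotentialOutcomeFrame(T, T.copy(), np.empty((len(T), 0)))
        model = fit_propensity(frame.X, frame.T)
        for fn in (effect_iptw, effect_ps_matching, effect_stratification):
            assert fn(frame, model, "ate") == pytest.approx(1.0)

    def test_constant_outcome_gives_exact_zero_for_all(self):
        T, _ = _randomized_frame()
        Y = np.ones_like(T)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(len(T), 2))
        frame = PotentialOutcomeFrame(T, Y, X)
        model = fit_propensity(X, T)
        for estimand in ("ate", "att", "atc"):
            assert effect_iptw(frame, model, estimand) == 0.0
            assert effect_ps_matching(frame, model, estimand) == 0.0
            assert effect_stratification(frame, model, estimand) == 0.0

    def test_hajek_invariant_to_weight_rescaling(self, rng):
        n = 500
        T = (rng.random(n) < 0.4).astype(int)
        Y = (rng.random(n) < 0.3).astype(int)
        e = np.clip(rng.random(n), 0.05, 0.95)
        # direct self-normalized computation with weights scaled by c
        for c in (1.0, 7.3, 1e-4):
            w1, w0 = c * T / e, c * (1 - T) / (1 - e)
            scaled = (w1 @ Y) / w1.sum() - (w0 @ Y) / w0.sum()
            frame = PotentialOutcomeFrame(T, Y, np.empty((n, 0)))
            model = fit_propensity(frame.X, T)
            model.scores = e
            assert effect_iptw(frame, model, "ate") == pytest.approx(
                scaled, abs=1e-12)

    def test_randomized_iptw_equals_difference_of_means(self, rng):
        n = 600
        T = (rng.random(n) < 0.5).astype(int)
        Y = (rng.random(n) < 0.4 + 0.2 * T).astype(int)
        frame = PotentialOutcomeFrame(T, Y, np.empty((n, 0)))
        model = fit_propensity(frame.X, T)
        model.scores = np.full(n, 0.5)
        dom = Y[T == 1].mean() - Y[T == 0].mean()
        assert effect_iptw(frame, model, "ate") == pytest.approx(dom,
                                                                 abs=1e-12)

    def test_horvitz_thompson_flag_differs_on_finite_samples(self, rng):
        n = 300
        T = (rng.random(n) < 0.4).astype(int)
        Y = (rng.random(n) < 0.5).astype(int)
        e = np.clip(rng.random(n), 0.2, 0.8)
        frame = PotentialOutcomeFrame(T, Y, np.empty((n, 0)))
        model = fit_propensity(frame.X, T)
        model.scores = e
        hajek = effect_iptw(frame, model, "ate", normalize=True)
        ht = effect_iptw(frame, model, "ate", normalize=False)
        assert hajek != ht

    def test_constant_score_stratification_is_difference_of_means(self, rng):
        n = 400
        T = (rng.random(n) < 0.5).astype(int)
        Y = (rng.random(n) < 0.3 + 0.3 * T).astype(int)
        frame = PotentialOutcomeFrame(T, Y, np.empty((n, 0)))
        model = fit_propensity(frame.X, T)  # intercept-only: constant score
        dom = Y[T == 1].mean() - Y[T == 0].mean()
        assert effect_stratification(frame, model, "ate") == pytest.approx(dom)

    def test_empty_arm_raises(self):
        T = np.ones(10, dtype=int)
        frame_kwargs = dict(Y=np.zeros(10, dtype=int),
                            X=np.empty((10, 0)))
        frame = PotentialOutcomeFrame(T=T, **frame_kwargs)
        model = fit_propensity(frame.X, frame.T)
        with pytest.raises(ZeroDivisionError):
            effect_iptw(frame, model, "ate")


# ---------------------------------------------------------------------------
# oracle comparisons
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def confounded_frame():
    spec = confounded_spec(n_subjects=20_000, seed=7)
    c = simulate_cohort(spec)
    T = binarize_treatment(c.data["cvd_late_effects"].to_numpy())
    Y = c.data.outcome.to_numpy()
    X = hurdle_design(c.data, ["diabetes", "hypertension"])
    frame = PotentialOutcomeFrame(T, Y, X.to_numpy(),
                                  covariates=list(X.columns))
    oracle = true_effect(spec, "cvd_late_effects", mc_reps=300_000,
                         seed=1).true_ate
    return frame, oracle


class TestOracleRecovery:
    def test_all_strategies_beat_naive(self, confounded_frame):
        frame, oracle = confounded_frame
        naive = (frame.Y[frame.T == 1].mean()
                 - frame.Y[frame.T == 0].mean())
        model = fit_propensity(frame.X, frame.T)
        for fn in (effect_iptw, effect_stratification):
            est = fn(frame, model, "ate")
            assert abs(est - oracle) < abs(naive - oracle)

    def test_iptw_within_003_of_oracle(self, confounded_frame):
        frame, oracle = confounded_frame
        est = estimate_effect(frame, "ate", "iptw")
        assert abs(est - oracle) <= 0.03

    def test_homogeneous_effects_make_estimands_agree(self, confounded_frame):
        frame, _ = confounded_frame
        model = fit_propensity(frame.X, frame.T)
        vals = [effect_iptw(frame, model, e) for e in ("ate", "att", "atc")]
        assert max(vals) - min(vals) < 0.06

    def test_null_effect_matching_near_zero(self, rng):
        n = 5000
        x = rng.normal(size=n)
        T = (rng.random(n) < expit(x)).astype(int)
        Y = (rng.random(n) < 0.3).astype(int)  # independent of T
        frame = PotentialOutcomeFrame(T, Y, x.reshape(-1, 1))
        model = fit_propensity(frame.X, frame.T)
        assert abs(effect_ps_matching(frame, model, "ate")) < 0.05

    def test_matching_beats_naive_with_continuous_confounder(self, rng):
        n = 20_000
        x = rng.normal(size=n)
        T = (rng.random(n) < expit(x)).astype(int)
        Y = (rng.random(n) < expit(-1 + x + T)).astype(int)
        oracle = (expit(-1 + x + 1).mean() - expit(-1 + x).mean())
        frame = PotentialOutcomeFrame(T, Y, x.reshape(-1, 1))
        model = fit_propensity(frame.X, frame.T)
        naive = Y[T == 1].mean() - Y[T == 0].mean()
        est = effect_ps_matching(frame, model, "ate")
        assert abs(est - oracle) < abs(naive - oracle)

    def test_consistency_error_shrinks_with_n(self):
        """Median |IPTW - oracle| decreases from n=2k to n=32k."""
        oracle = true_effect(confounded_spec(), "cvd_late_effects",
                             mc_reps=200_000, seed=2).true_ate
        med = {}
        for n in (2000, 32_000):
            errs = []
            for s in range(3):
                spec = confounded_spec(n_subjects=n, seed=300 + s)
                c = simulate_cohort(spec)
                T = binarize_treatment(c.data["cvd_late_effects"].to_numpy())
                X = hurdle_design(c.data, ["diabetes", "hypertension"])
                frame = PotentialOutcomeFrame(T, c.data.outcome.to_numpy(),
                                              X.to_numpy())
                errs.append(abs(estimate_effect(frame, "ate", "iptw")
                                - oracle))
            med[n] = np.median(errs)
        assert med[32_000] < med[2000]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_constant_estimator_zero_width_interval(self):
        frame = PotentialOutcomeFrame(np.r_[np.ones(5), np.zeros(5)].astype(int),
                                      np.zeros(10, dtype=int),
                                      np.empty((10, 0)))
        est = bootstrap_ci(lambda f: 0.42, frame, B=50, seed=0)
        assert est.ci_low == est.ci_high == pytest.approx(0.42)

    def test_interval_is_empirical_percentiles_of_draws(self, rng):
        n = 300
        T = (rng.random(n) < 0.5).astype(int)
        Y = (rng.random(n) < 0.3 + 0.2 * T).astype(int)
        frame = PotentialOutcomeFrame(T, Y, np.empty((n, 0)))

        def naive(f):
            return f.Y[f.T == 1].mean() - f.Y[f.T == 0].mean()

        est = bootstrap_ci(naive, frame, B=100, level=0.95, seed=5)
        lo, hi = np.percentile(est.bootstrap_draws, [2.5, 97.5])
        assert est.ci_low == pytest.approx(lo)
        assert est.ci_high == pytest.approx(hi)
        assert est.B == 100
        assert est.ci_low <= est.point <= est.ci_high

    def test_deterministic_given_seed(self, rng):
        n = 200
        T = (rng.random(n) < 0.5).astype(int)
        Y = (rng.random(n) < 0.5).astype(int)
        frame = PotentialOutcomeFrame(T, Y, np.empty((n, 0)))
        fn = lambda f: f.Y[f.T == 1].mean() - f.Y[f.T == 0].mean()
        a = bootstrap_ci(fn, frame, B=40, seed=9)
        b = bootstrap_ci(fn, frame, B=40, seed=9)
        assert np.array_equal(a.bootstrap_draws, b.bootstrap_draws)

    def test_excessive_failures_abort(self):
        frame = PotentialOutcomeFrame(np.r_[np.ones(5), np.zeros(5)].astype(int),
                                      np.zeros(10, dtype=int),
                                      np.empty((10, 0)))
        calls = {"n": 0}

        def flaky(f):
            calls["n"] += 1
            if calls["n"] == 1:
                return 0.0  # the observed point estimate succeeds
            raise RuntimeError("replicate failure")

        with pytest.raises(RuntimeError, match="bootstrap"):
            bootstrap_ci(flaky, frame, B=20, seed=0)

    def test_estimator_facade_end_to_end(self, confounded_frame):
        frame, oracle = confounded_frame
        ce = CausalEffectEstimator(estimand="ate", strategy="iptw", B=30,
                                   seed=3)
        ce.fit(pd.DataFrame(frame.X, columns=frame.covariates), frame.Y,
               treatment=frame.T)
        assert ce.estimate_.ci_low <= ce.point_ <= ce.estimate_.ci_high
        assert abs(ce.point_ - oracle) < 0.05
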