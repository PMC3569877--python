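import warnings

import numpy as np
import pandas as pd
import pytest

import splinemlm as sm
from splinemlm.mlm_core import CovarianceNotPD, individual_moments
from splinemlm.effects import vech_indices

from conftest import SMALL_FIXED, SMALL_G, SMALL_MAP, SMALL_WEIGHT, small_generator
from oracles import brute_force_loglik, random_tiny_instance


def _fixed_dict(gspec):
    out = {}
    for s in gspec.specs:
        fe = gspec.fixed_effects[s.response_name]
        out[f"{s.response_name}:intercept"] = fe[0]
        for l in range(1, s.n_splines + 1):
            out[f"{s.response_name}:slope{l}"] = fe[l]
    return out


class TestLogLikelihood:
    def test_single_standard_normal_observation(self):
        spec = sm.SplineSpec("y", 0.0, (), 10.0)
        mspec = sm.ModelSpec(responses=(spec,))
        data = sm.LongData(
            pd.DataFrame(
                {"individual": [0], "time": [3.0], "response": ["y"], "value": [1.7]}
            )
        )
        # G = 0, R = 1, mean equal to the observation: density at the mode
        ll = sm.log_likelihood(
            mspec, data, {"y:intercept": 1.7, "y:slope1": 0.0}, np.zeros((2, 2)), [[1.0]]
        )
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_brute_force_oracle_on_tiny_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(10):
            mspec, data, fixed, G, R = random_tiny_instance(rng)
            ll = sm.log_likelihood(mspec, data, fixed, G, R)
            assert ll == pytest.approx(brute_force_loglik(mspec, data, fixed, G, R), abs=1e-10)

    def test_duplicating_individuals_doubles_loglik(self):
        gspec = small_generator(5, seed=3)
        data, _ = sm.generate(gspec)
        mspec = gspec.model_spec()
        fixed = _fixed_dict(gspec)
        ll1 = sm.log_likelihood(mspec, data, fixed, SMALL_G, gspec.R_true)
        df2 = data.df.copy()
        df2["individual"] = df2["individual"] + 1000
        doubled = sm.LongData(pd.concat([data.df, df2], ignore_index=True))
        ll2 = sm.log_likelihood(mspec, doubled, fixed, SMALL_G, gspec.R_true)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_non_pd_covariance_is_recoverable_failure(self):
        gspec = small_generator(4, seed=5)
        data, _ = sm.generate(gspec)
        bad_R = np.array([[1.0, 9.0], [9.0, 1.0]])  # not PD
        with pytest.raises(CovarianceNotPD):
            sm.log_likelihood(gspec.model_spec(), data, _fixed_dict(gspec), SMALL_G, bad_R)


class TestDataValidation:
    def test_duplicate_measurement_rejected(self):
        df = pd.DataFrame(
            {
                "individual": [0, 0],
                "time": [9.0, 9.0],
                "response": ["y", "y"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            sm.LongData(df)

    def test_time_varying_covariate_rejected(self):
        df = pd.DataFrame(
            {
                "individual": [0, 0],
                "time": [9.0, 10.0],
                "response": ["y", "y"],
                "value": [1.0, 2.0],
                "age": [30.0, 31.0],
            }
        )
        with pytest.raises(ValueError, match="time-constant"):
            sm.LongData(df)

    def test_unobserved_response_rejected_and_prebaseline_named(self):
        gspec = small_generator(3, seed=1)
        data, _ = sm.generate(gspec)
        extra = sm.SplineSpec("bmi", 8.0, (20.0,), 44.0)
        bad = sm.ModelSpec(responses=(SMALL_WEIGHT, SMALL_MAP, extra))
        with pytest.raises(ValueError, match="never observed"):
            sm.fit(bad, data, compute_gamma=False, maxiter=5)
        df = data.df.copy()
        df.loc[df.index[0], "time"] = 3.0  # before baseline week 8
        with pytest.raises(ValueError, match="individual"):
            sm.fit(gspec.model_spec(), sm.LongData(df), compute_gamma=False, maxiter=5)


class TestFit:
    def test_univariate_recovery_matches_mixedlm(self):
        """Random-intercept/slope model: our ML fit agrees with statsmodels
        MixedLM (reml=False) on the same data."""
        import statsmodels.api as smapi

        spec = sm.SplineSpec("y", 0.0, (), 10.0)
        rng = np.random.default_rng(3)
        G = np.array([[4.0, 0.5], [0.5, 0.3]])
        L = np.linalg.cholesky(G)
        rows = []
        for k in range(300):
            t = np.sort(rng.choice(np.arange(11), size=6, replace=False)).astype(float)
            u = L @ rng.standard_normal(2)
            y = 2.0 + 1.0 * t + u[0] + u[1] * t + rng.normal(0, 1.0, t.size)
            rows.extend(
                {"individual": k, "time": tt, "response": "y", "value": yy}
                for tt, yy in zip(t, y)
            )
        data = sm.LongData(pd.DataFrame(rows))
        f = sm.fit(sm.ModelSpec(responses=(spec,)), data)
        df = data.df
        X = np.column_stack([np.ones(len(df)), df["time"]])
        mf = smapi.MixedLM(df["value"], X, groups=df["individual"], exog_re=X).fit(
            reml=False
        )
        assert f.deviance == pytest.approx(-2 * mf.llf, abs=1e-4)
        np.testing.assert_allclose(f.beta, mf.fe_params.values, atol=1e-4)
        np.testing.assert_allclose(f.G, mf.cov_re.values, atol=2e-4)
        assert f.R[0, 0] == pytest.approx(mf.scale, abs=1e-4)
        np.testing.assert_allclose(f.fixed_se, mf.bse_fe.values, atol=1e-4)

    def test_constrained_entries_exactly_zero(self, small_restricted_fit):
        f = small_restricted_fit
        pos = {e: i for i, e in enumerate(f.effects)}
        for a, b in f.constraints.pairs:
            i, j = sorted((pos[x] for x in (a, b)))
            assert f.G[i, j] == 0.0
            # Gamma rows/cols for constrained entries are zero
            from splinemlm.effects import vech_position

            k = vech_position(len(f.effects), i, j)
            assert np.all(f.gamma[k] == 0.0) and np.all(f.gamma[:, k] == 0.0)

    def test_deviance_monotone_under_constraints(self, small_fit, small_restricted_fit):
        assert small_restricted_fit.deviance >= small_fit.deviance

    def test_row_order_and_relabelling_invariance(self):
        gspec = small_generator(60, seed=9)
        data, _ = sm.generate(gspec)
        mspec = gspec.model_spec()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = sm.fit(mspec, data, compute_gamma=False)
            shuffled = data.df.sample(frac=1.0, random_state=4).reset_index(drop=True)
            f2 = sm.fit(mspec, sm.LongData(shuffled), compute_gamma=False)
            relabelled = data.df.copy()
            relabelled["individual"] = relabelled["individual"].map(
                lambda k: f"w{k:03d}"
            )
            f3 = sm.fit(mspec, sm.LongData(relabelled), compute_gamma=False)
        assert f2.deviance == pytest.approx(f1.deviance, abs=1e-6)
        assert f3.deviance == pytest.approx(f1.deviance, abs=1e-6)
        np.testing.assert_allclose(f2.G, f1.G, atol=1e-6)
        np.testing.assert_allclose(f3.G, f1.G, atol=1e-6)

    def test_serialisation_roundtrip(self, small_fit):
        f2 = sm.FittedMLM.from_json(small_fit.to_json())
        np.testing.assert_allclose(f2.G, small_fit.G)
        np.testing.assert_allclose(f2.gamma, small_fit.gamma)
        assert f2.deviance == small_fit.deviance
        assert f2.effects == small_fit.effects
        assert f2.constraints.pairs == small_fit.constraints.pairs


class TestMarginalMoments:
    def test_model_implied_moments_match_simulation(self, small_fit):
        """Mean and covariance of an individual's stacked vector match
        empirical moments of many simulated individuals sharing one
        schedule (CLT tolerance)."""
        schedule = {"weight": np.array([10.0, 20.0, 30.0]), "map": np.array([10.0, 30.0, 40.0])}
        mean, cov = individual_moments(small_fit, schedule)
        rng = np.random.default_rng(77)
        n = 100_000
        U = rng.multivariate_normal(np.zeros(6), small_fit.G, size=n)
        from splinemlm.spline_basis import evaluate_basis

        pos = 0
        sim = np.empty((n, 6))
        col = 0
        for s in small_fit.spec.responses:
            t = schedule[s.response_name]
            basis = evaluate_basis(s, t)
            fe = small_fit.beta[pos : pos + 1 + s.n_splines]
            mu = fe[0] + basis @ fe[1:]
            u = U[:, pos : pos + 1 + s.n_splines]
            sim[:, col : col + t.size] = mu + u[:, :1] + u[:, 1:] @ basis.T
            pos += 1 + s.n_splines
            col += t.size
        # occasion residuals: shared visit at weeks 10 and 30 (cols 0&3, 2&4)
        R = small_fit.R
        for wcol, mcol in ((0, 3), (2, 4)):
            e = rng.multivariate_normal(np.zeros(2), R, size=n)
            sim[:, wcol] += e[:, 0]
            sim[:, mcol] += e[:, 1]
        for c in (1, 5):
            r = 0 if c == 1 else 1
            sim[:, c] += rng.normal(0, np.sqrt(R[r, r]), size=n)
        # CLT tolerances: SE(mean) ~ sd/sqrt(n), SE(cov entry) ~ sqrt(2)*var/sqrt(n)
        sd_max = np.sqrt(np.max(np.diag(cov)))
        np.testing.assert_allclose(sim.mean(axis=0), mean, atol=5 * sd_max / np.sqrt(n))
        np.testing.assert_allclose(
            np.cov(sim.T), cov, atol=6 * np.sqrt(2) * sd_max**2 / np.sqrt(n)
        )


class TestLRT:
    def test_deviance_arithmetic_worked_examples(self):
        res = sm.lrt_from_deviances(984211.981, 984228.987, 4)
        assert res.chi2 == pytest.approx(17.006, abs=1e-9)
        assert round(res.p, 3) == 0.002
        res8 = sm.lrt_from_deviances(984211.981, 984277.574, 8)
        assert res8.p < 0.001
        res0 = sm.lrt_from_deviances(100.0, 100.0, 1)
        assert res0.chi2 == 0.0 and res0.p == 1.0

    def test_negative_chi2_warns_and_p_one(self):
        with pytest.warns(UserWarning, match="non-convergence"):
            res = sm.lrt_from_deviances(100.0, 99.0, 2)
        assert res.p == 1.0

    def test_df_equals_constraint_cardinality(self, small_fit, small_restricted_fit):
        res = sm.lrt(small_fit, small_restricted_fit)
        assert res.df == len(small_restricted_fit.constraints)
        assert res.chi2 >= 0.0
        assert 0.0 <= res.p <= 1.0

    def test_mismatched_models_rejected(self, small_fit, small_restricted_fit):
        with pytest.raises(ValueError, match="strictly"):
            sm.lrt(small_restricted_fit, small_fit)  # wrong nesting order
        gspec = small_generator(20, seed=33)
        other_data, _ = sm.generate(gspec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            other = sm.fit(
                gspec.model_spec(
                    constraints=sm.precedence((SMALL_WEIGHT, SMALL_MAP), "map", "weight")
                ),
                other_data,
                compute_gamma=False,
            )
        with pytest.raises(ValueError, match="different data"):
            sm.lrt(small_fit, other)


class TestRandomEffectPrediction:
    def test_blups_are_shrunken_relative_to_G(self, small_dataset, small_fit):
        """The empirical covariance of predicted individual effects
        understates the model-estimated G (shrinkage towards zero), so G —
        not the predictions — must be used for population associations."""
        _, data, _ = small_dataset
        U = sm.predict_random_effects(small_fit, data)
        emp = U.to_numpy().var(axis=0, ddof=1)
        model_var = np.diag(small_fit.G)
        assert np.all(emp <= model_var * 1.02 + 1e-8)
        # and strictly attenuated for the slope effects (least information)
        assert emp[1] < 0.9 * model_var[1]

    def test_blups_track_true_effects(self, small_dataset, small_fit):
        _, data, truth = small_dataset
        U = sm.predict_random_effects(small_fit, data)
        true_w0 = truth.set_index("individual")["weight:intercept"]
        r = np.corrcoef(U["weight:intercept"].to_numpy(), true_w0.loc[U.index].to_numpy())[0, 1]
        assert r > 0.9
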