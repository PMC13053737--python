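"""Two-slope LGCM: age basis, likelihood correctness, LRT behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from cotwin import ModelSpec, SimConfig, age_basis, build_design, fit_lgcm, fit_model, lrt, simulate_cohort
from cotwin.growth import ConvergenceError, _profile_nll


def _frame(cohort):
    return cohort.analysis_frame()


class TestAgeBasis:
    @pytest.mark.parametrize(
        "age,expected",
        [(75.0, (0.0, 0.0, 0.0)), (65.0, (-1.0, -1.0, 0.0)), (85.0, (1.0, 0.0, 1.0)), (42.0, (-3.3, -3.3, 0.0))],
    )
    def test_known_points(self, age, expected):
        t, s1, s2 = age_basis(age)
        assert (t, s1, s2) == pytest.approx(expected)

    @given(st.floats(min_value=30.0, max_value=110.0))
    @settings(max_examples=50, deadline=None)
    def test_spline_identities(self, age):
        t, s1, s2 = age_basis(age)
        assert s1 <= 0.0 <= s2
        assert s1 + s2 == pytest.approx(t)
        assert s1 * s2 == 0.0


class TestDesign:
    def test_block_shapes_one_pair(self):
        frame = pd.DataFrame(
            {
                "pair_id": ["A"] * 4,
                "person_id": ["a1", "a1", "a2", "a2"],
                "age_years": [70.0, 75.0, 71.0, 82.0],
                "sex_male": 1.0,
                "y": [50.0, 52.0, 49.0, 51.0],
            }
        )
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], random_pair=("1",), random_individual=("1",))
        blocks = build_design(frame, spec)
        assert blocks.y.shape == (1, 4)
        assert blocks.X.shape == (1, 4, 3)
        assert blocks.Zi.shape == (1, 4, 2)
        # members occupy disjoint individual-effect columns
        assert blocks.Zi[0, :2, 0].tolist() == [1.0, 1.0]
        assert blocks.Zi[0, 2:, 1].tolist() == [1.0, 1.0]
        # age 75 sits exactly on the knot
        assert blocks.X[0, 1, 1] == 0.0 and blocks.X[0, 1, 2] == 0.0

    def test_singleton_block(self):
        frame = pd.DataFrame(
            {
                "pair_id": ["A"],
                "person_id": ["a1"],
                "age_years": [70.0],
                "y": [50.0],
            }
        )
        spec = ModelSpec(outcome="y", fixed=["1"], random_pair=("1",), random_individual=("1",))
        blocks = build_design(frame, spec)
        assert blocks.n_pairs == 1 and blocks.n_persons == 1
        assert blocks.Zp[0, 0, 0] == 1.0 and blocks.Zi[0, 0, 0] == 1.0

    def test_row_shuffle_leaves_likelihood_unchanged(self, flat_cohort):
        cohort, _, _ = flat_cohort
        frame = _frame(cohort)
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2", "sex_male"], pair_cov="diag", individual_cov="diag")
        b1 = build_design(frame, spec)
        b2 = build_design(frame.sample(frac=1.0, random_state=3), spec)
        theta = np.array([np.log(3.0), np.log(3.0), np.log(2.0)])
        assert _profile_nll(theta, b1) == pytest.approx(_profile_nll(theta, b2), rel=1e-10)

    def test_rank_deficient_design_rejected(self, flat_cohort):
        cohort, _, _ = flat_cohort
        from cotwin.growth import add_age_basis

        frame = add_age_basis(_frame(cohort))
        frame["dup"] = frame["s1"]
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "dup"])
        with pytest.raises(ValueError, match="rank"):
            build_design(frame, spec)

    def test_empty_design_rejected(self):
        frame = pd.DataFrame({"pair_id": ["A"], "person_id": ["a"], "age_years": [70.0], "y": [np.nan]})
        with pytest.raises(ValueError, match="empty"):
            build_design(frame, ModelSpec(outcome="y", fixed=["1"]))


class TestLikelihood:
    def test_block_likelihood_equals_dense_assembly(self, flat_cohort):
        """Pair-block likelihood equals one dense covariance over everything."""
        cohort, _, _ = flat_cohort
        frame = _frame(cohort)
        # small instance: first 8 pairs
        keep = frame["pair_id"].isin(sorted(frame["pair_id"].unique())[:8])
        frame = frame[keep]
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], pair_cov="diag", individual_cov="diag")
        blocks = build_design(frame, spec)
        theta = np.array([np.log(3.3), np.log(2.1), np.log(1.7)])
        nll = _profile_nll(theta, blocks)

        frame = frame.sort_values(["pair_id", "person_id", "age_years"], kind="mergesort")
        y = frame["y"].to_numpy()
        from cotwin.growth import add_age_basis, design_matrix

        frame = add_age_basis(frame)
        X = design_matrix(frame, spec.fixed)
        sp, si, sr = np.exp(theta) ** 2
        n = len(frame)
        V = np.zeros((n, n))
        pair = frame["pair_id"].to_numpy()
        person = frame["person_id"].to_numpy()
        for i in range(n):
            for j in range(n):
                if pair[i] == pair[j]:
                    V[i, j] += sp
                    if person[i] == person[j]:
                        V[i, j] += si
                        if i == j:
                            V[i, j] += sr
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        ll = -0.5 * (np.linalg.slogdet(V)[1] + r @ Vi @ r + n * np.log(2 * np.pi))
        assert -nll == pytest.approx(ll, rel=1e-10)

    def test_noise_free_interpolation(self):
        """With variances driven to zero, estimates hit the generating betas."""
        rng = np.random.default_rng(5)
        rows = []
        beta = {"1": 47.0, "s1": 4.4, "s2": 9.9}
        for p in range(30):
            for m in range(2):
                for age in (65.0 + rng.uniform(0, 5), 72.0, 80.0, 86.0 + rng.uniform(0, 3)):
                    t = (age - 75) / 10
                    rows.append(
                        {
                            "pair_id": f"P{p}",
                            "person_id": f"P{p}_{m}",
                            "age_years": age,
                            "y": beta["1"] + beta["s1"] * min(t, 0) + beta["s2"] * max(t, 0),
                        }
                    )
        frame = pd.DataFrame(rows)
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], pair_cov="diag", individual_cov="diag")
        fit = fit_lgcm(build_design(frame, spec), allow_fallback=False)
        assert fit.params["1"] == pytest.approx(47.0, abs=1e-6)
        assert fit.params["s1"] == pytest.approx(4.4, abs=1e-6)
        assert fit.params["s2"] == pytest.approx(9.9, abs=1e-6)

    def test_matches_brute_force_dense_optimizer(self):
        """ML optimum equals a derivative-free dense-covariance maximization."""
        cfg = SimConfig(
            n_pairs_mz=4, n_pairs_dz=6, n_waves=2, dropout=0.0,
            pair_sd=(3.0, 0.0, 0.0), individual_sd=(3.0, 0.0, 0.0), residual_sd=3.0,
        )
        cohort, _ = simulate_cohort(cfg, 31)
        frame = _frame(cohort)
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], pair_cov="diag", individual_cov="diag")
        fit = fit_lgcm(build_design(frame, spec), allow_fallback=False)

        from cotwin.growth import add_age_basis, design_matrix

        frame = frame.sort_values(["pair_id", "person_id", "age_years"], kind="mergesort")
        fb = add_age_basis(frame)
        X = design_matrix(fb, spec.fixed)
        y = fb["y"].to_numpy()
        pair = fb["pair_id"].to_numpy()
        person = fb["person_id"].to_numpy()
        n = len(fb)
        same_pair = pair[:, None] == pair[None, :]
        same_person = person[:, None] == person[None, :]

        def dense_nll(theta):
            sp, si, sr = np.exp(2 * theta)
            V = sp * same_pair + si * same_person + sr * np.eye(n)
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e10
            Vi = np.linalg.inv(V)
            A = X.T @ Vi @ X
            beta = np.linalg.solve(A, X.T @ Vi @ y)
            r = y - X @ beta
            return 0.5 * (logdet + r @ Vi @ r + n * np.log(2 * np.pi))

        best = np.inf
        for start in ([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], np.log([3.0, 3.0, 3.0])):
            res = optimize.minimize(dense_nll, np.asarray(start, float), method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, rel=1e-4)

    def test_likelihood_matches_statsmodels_mixedlm(self, flat_cohort):
        """Our log-likelihood function agrees with MixedLM at its optimum."""
        sm = pytest.importorskip("statsmodels.formula.api")
        cohort, _, _ = flat_cohort
        frame = _frame(cohort)
        keep = frame["pair_id"].isin(sorted(frame["pair_id"].unique())[:120])
        frame = frame[keep].copy()
        from cotwin.growth import add_age_basis

        frame = add_age_basis(frame)
        model = sm.mixedlm(
            "y ~ s1 + s2 + sex_male",
            frame,
            groups=frame["pair_id"],
            re_formula="1",
            vc_formula={"person": "0 + C(person_id)"},
        )
        mfit = model.fit(reml=False, method="lbfgs")
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2", "sex_male"], pair_cov="diag", individual_cov="diag")
        blocks = build_design(frame, spec)
        sigma2 = mfit.scale
        theta = 0.5 * np.log(np.array([
            float(mfit.cov_re.iloc[0, 0]) * sigma2 if False else float(mfit.cov_re.iloc[0, 0]),
            float(mfit.vcomp[0]),
            sigma2,
        ]))
        # MixedLM reports cov_re/vcomp on the outcome scale already
        nll = _profile_nll(theta, blocks)
        assert -nll == pytest.approx(mfit.llf, abs=5e-3)
        ours = fit_lgcm(blocks, allow_fallback=False)
        assert ours.loglik >= mfit.llf - 1e-3
        for term, sm_name in (("1", "Intercept"), ("s1", "s1"), ("s2", "s2"), ("sex_male", "sex_male")):
            assert ours.params[term] == pytest.approx(mfit.params[sm_name], abs=2e-2)

    def test_outcome_scaling_equivariance(self, flat_cohort):
        cohort, _, _ = flat_cohort
        frame = _frame(cohort)
        keep = frame["pair_id"].isin(sorted(frame["pair_id"].unique())[:80])
        frame = frame[keep].copy()
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], pair_cov="diag", individual_cov="diag")
        f1 = fit_lgcm(build_design(frame, spec), allow_fallback=False)
        frame["y"] = 2.0 * frame["y"]
        f2 = fit_lgcm(build_design(frame, spec), allow_fallback=False)
        assert np.allclose(f2.params.to_numpy(), 2.0 * f1.params.to_numpy(), rtol=1e-3, atol=1e-4)
        assert f2.sigma2 == pytest.approx(4.0 * f1.sigma2, rel=1e-2)


class TestLRT:
    def test_identical_fits_statistic_zero(self, flat_cohort):
        cohort, _, _ = flat_cohort
        frame = _frame(cohort)
        spec0 = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], pair_cov="diag", individual_cov="diag")
        spec1 = ModelSpec(outcome="y", fixed=["1", "s1", "s2", "sex_male"], pair_cov="diag", individual_cov="diag")
        f0 = fit_model(frame, spec0)
        f1 = fit_model(frame, spec1)
        stat, df, p = lrt(f0, f1)
        assert df == 1 and stat >= 0.0
        import dataclasses

        same, _, p_same = lrt(f0, dataclasses.replace(f0, n_params=f0.n_params + 1))
        assert same == pytest.approx(0.0, abs=1e-6)
        assert p_same == pytest.approx(1.0)

    def test_added_covariate_never_decreases_loglik(self, flat_cohort):
        cohort, _, cfg = flat_cohort
        frame = _frame(cohort)
        frame["ses_z"] = (frame[cfg.ses_name] - cfg.ses_mean) / cfg.ses_sd
        base = fit_model(frame, ModelSpec(outcome="y", fixed=["1", "s1", "s2", "sex_male"], pair_cov="diag", individual_cov="diag"))
        full = fit_model(
            frame,
            ModelSpec(outcome="y", fixed=["1", "s1", "s2", "sex_male", "ses_z", "ses_z:s1", "ses_z:s2"],
                      pair_cov="diag", individual_cov="diag"),
        )
        stat, df, p = lrt(base, full)
        assert df == 3
        assert stat >= -1e-6
        # the generating direct effect is large, so the LRT must reject
        assert p < 1e-6

    def test_non_nested_rejected(self, flat_cohort):
        cohort, _, _ = flat_cohort
        frame = _frame(cohort)
        spec = ModelSpec(outcome="y", fixed=["1", "s1", "s2"], pair_cov="diag", individual_cov="diag")
        f = fit_model(frame, spec)
        with pytest.raises(ValueError, match="nested"):
            lrt(f, f)

    def test_slope2_twice_slope1_recovered(self):
        """A cohort generated with slope 2 = 2 x slope 1 yields that ratio."""
        cfg = SimConfig(
            n_pairs_mz=300, n_pairs_dz=700, n_waves=4, dropout=0.0,
            mu_slope1=5.0, mu_slope2=10.0,
            pair_sd=(3.5, 0.0, 0.0), individual_sd=(3.5, 0.0, 0.0),
        )
        cohort, _ = simulate_cohort(cfg, 17)
        fit = fit_model(
            cohort.analysis_frame(),
            ModelSpec(outcome="y", fixed=["1", "s1", "s2", "sex_male"], pair_cov="diag", individual_cov="diag"),
        )
        ratio = fit.params["s2"] / fit.params["s1"]
        se = ratio * np.sqrt((fit.se["s1"] / fit.params["s1"]) ** 2 + (fit.se["s2"] / fit.params["s2"]) ** 2)
        assert abs(ratio - 2.0) < 3 * se
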