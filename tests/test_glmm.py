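"""Mixed-model likelihood, optimizer, and reporting checks."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mobrisk import glmm
from mobrisk.glmm import GlmmSpec, fit, logistic_irls, marginal_loglik, report_or
from mobrisk.simulate import simulate_panel_direct


@pytest.fixture(scope="module")
def tiny_groups():
    """4 groups x 6 observations, 2 covariates, moderate effects."""
    rng = np.random.default_rng(7)
    n_g, n_t = 4, 6
    pid = np.repeat(np.arange(n_g), n_t)
    X = np.column_stack([np.ones(n_g * n_t), rng.standard_normal(n_g * n_t)])
    beta = np.array([-0.5, 0.8])
    sigma = 0.7
    u = rng.normal(0, sigma, n_g)
    y = (rng.random(n_g * n_t) < 1 / (1 + np.exp(-(X @ beta + u[pid])))).astype(float)
    return X, y, pid, n_g, beta, sigma


def grid_loglik(X, y, pid, n_g, beta, sigma, n_points=20001, half_width=10.0):
    """Brute-force trapezoid integration over the random intercept."""
    grid = np.linspace(-half_width * sigma, half_width * sigma, n_points)
    total = 0.0
    for g in range(n_g):
        m = pid == g
        eta = X[m] @ beta
        vals = (y[m][:, None] * (eta[:, None] + grid[None, :])).sum(axis=0) - np.logaddexp(
            0.0, eta[:, None] + grid[None, :]
        ).sum(axis=0)
        dens = np.exp(-0.5 * (grid / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(np.exp(vals) * dens, grid))
    return total


class TestMarginalLoglik:
    def test_sigma_zero_equals_plain_logistic(self, tiny_groups):
        X, y, pid, n_g, beta, _ = tiny_groups
        ll = marginal_loglik(beta, -np.inf, X, y, pid, n_g)
        direct = float(np.sum(y * (X @ beta) - np.logaddexp(0, X @ beta)))
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_matches_grid_integration(self, tiny_groups):
        X, y, pid, n_g, beta, sigma = tiny_groups
        ll = marginal_loglik(beta, np.log(sigma), X, y, pid, n_g, n_nodes=25)
        oracle = grid_loglik(X, y, pid, n_g, beta, sigma)
        assert ll == pytest.approx(oracle, rel=1e-8)

    def test_single_group_three_obs_grid(self):
        X = np.column_stack([np.ones(3), np.array([-1.0, 0.0, 1.0])])
        y = np.array([0.0, 1.0, 1.0])
        pid = np.zeros(3, dtype=int)
        beta = np.array([0.3, -0.9])
        sigma = 1.3
        ll = marginal_loglik(beta, np.log(sigma), X, y, pid, 1)
        oracle = grid_loglik(X, y, pid, 1, beta, sigma)
        assert ll == pytest.approx(oracle, rel=1e-8)

    def test_coin_flip_model(self):
        n = 40
        X = np.ones((n, 1))
        y = np.repeat([0.0, 1.0], n // 2)
        pid = np.arange(n) % 5
        ll = marginal_loglik(np.zeros(1), -np.inf, X, y, pid, 5)
        assert ll == pytest.approx(n * np.log(0.5), rel=1e-12)

    def test_non_finite_parameters_rejected(self, tiny_groups):
        X, y, pid, n_g, beta, _ = tiny_groups
        with pytest.raises(ValueError):
            marginal_loglik(np.array([np.nan, 0.0]), 0.0, X, y, pid, n_g)

    def test_node_count_stability(self, tiny_groups):
        X, y, pid, n_g, beta, sigma = tiny_groups
        ll25 = marginal_loglik(beta, np.log(sigma), X, y, pid, n_g, n_nodes=25)
        ll51 = marginal_loglik(beta, np.log(sigma), X, y, pid, n_g, n_nodes=51)
        assert abs(ll25 - ll51) < 1e-6

    def test_gradient_matches_finite_differences(self, tiny_groups):
        X, y, pid, n_g, beta, sigma = tiny_groups
        _, grad = marginal_loglik(beta, np.log(sigma), X, y, pid, n_g, return_grad=True)
        eps = 1e-6
        for j in range(len(beta)):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += eps
            bm[j] -= eps
            num = (
                marginal_loglik(bp, np.log(sigma), X, y, pid, n_g)
                - marginal_loglik(bm, np.log(sigma), X, y, pid, n_g)
            ) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-5, abs=1e-8)
        num_s = (
            marginal_loglik(beta, np.log(sigma) + eps, X, y, pid, n_g)
            - marginal_loglik(beta, np.log(sigma) - eps, X, y, pid, n_g)
        ) / (2 * eps)
        assert grad[-1] == pytest.approx(num_s, rel=1e-5, abs=1e-8)


class TestFit:
    @pytest.fixture(scope="class")
    def medium_panel(self):
        return simulate_panel_direct(
            60, 20, beta={"homestay_within": 0.8, "homestay_between": 0.4},
            sigma_u=0.8, intercept=-2.0, seed=11,
        )

    @pytest.fixture(scope="class")
    def medium_fit(self, medium_panel):
        spec = GlmmSpec(
            outcome="outcome",
            fixed_terms=("homestay_within", "homestay_between", "weeks_since_baseline"),
        )
        return fit(spec, medium_panel)

    def test_matches_lme4_glmer(self, medium_panel, medium_fit, tmp_path):
        """Independent oracle: R lme4 glmer with 25-node adaptive quadrature."""
        csv = tmp_path / "panel.csv"
        medium_panel.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(outcome ~ homestay_within + homestay_between +
                       weeks_since_baseline + (1|participant_id),
                       data=d, family=binomial, nAGQ=25)
            co <- summary(m)$coefficients
            cat(co[,1], co[,2], sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_se, r_sigma, r_ll = vals[:4], vals[4:8], vals[8], vals[9]
        np.testing.assert_allclose(medium_fit.beta, r_beta, atol=2e-4)
        np.testing.assert_allclose(medium_fit.se, r_se, atol=2e-3)
        assert medium_fit.sigma_u == pytest.approx(r_sigma, abs=2e-3)
        assert medium_fit.loglik == pytest.approx(r_ll, abs=1e-4)

    def test_sigma_zero_limit_reproduces_plain_logistic(self):
        pnl = simulate_panel_direct(40, 15, sigma_u=0.0, intercept=-1.0, seed=3)
        spec = GlmmSpec(outcome="outcome", fixed_terms=("homestay_within",))
        f = fit(spec, pnl)
        X = np.column_stack([np.ones(len(pnl)), pnl["homestay_within"]])
        plain = logistic_irls(X, pnl["outcome"].to_numpy(dtype=float))
        assert f.sigma_u < 0.1
        np.testing.assert_allclose(f.beta, plain, atol=1e-3)

    def test_duplicating_groups_keeps_beta_shrinks_se(self, medium_panel, medium_fit):
        """Cloning every participant under a new id exactly squares the
        marginal likelihood: estimates unchanged, SEs shrink by 1/sqrt(2)."""
        clone = medium_panel.copy()
        clone["participant_id"] = clone["participant_id"] + 10_000
        doubled = pd.concat([medium_panel, clone], ignore_index=True)
        spec = GlmmSpec(
            outcome="outcome",
            fixed_terms=("homestay_within", "homestay_between", "weeks_since_baseline"),
        )
        f2 = fit(spec, doubled)
        np.testing.assert_allclose(f2.beta, medium_fit.beta, atol=5e-4)
        np.testing.assert_allclose(f2.se, medium_fit.se / np.sqrt(2), rtol=0.02)

    def test_vcov_properties(self, medium_fit):
        v = medium_fit.vcov
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert (np.linalg.eigvalsh(v) > -1e-10).all()
        np.testing.assert_allclose(medium_fit.se, np.sqrt(np.diag(v)))

    def test_logistic_irls_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(400), rng.standard_normal((400, 2))])
        y = (rng.random(400) < 1 / (1 + np.exp(-(X @ [0.3, -0.7, 1.1])))).astype(float)
        ours = logistic_irls(X, y)
        theirs = sm.Logit(y, X).fit(disp=0).params
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_separation_triggers_penalized_refit(self):
        rng = np.random.default_rng(5)
        n = 120
        pid = np.repeat(np.arange(12), 10)
        x = rng.standard_normal(n)
        y = (x > 0).astype(float)  # perfectly separated
        pnl = pd.DataFrame({"participant_id": pid, "outcome": y, "x": x})
        spec = GlmmSpec(outcome="outcome", fixed_terms=("x",), penalty=0.5)
        f = fit(spec, pnl)
        assert f.penalized
        assert np.all(np.abs(f.beta) < 20)
        report_or(f)  # penalized fits are reportable

    def test_fewer_than_two_groups_rejected(self):
        pnl = pd.DataFrame(
            {"participant_id": ["a"] * 6, "outcome": [0, 1, 0, 1, 0, 1], "x": np.arange(6.0)}
        )
        with pytest.raises(ValueError, match="2 groups"):
            fit(GlmmSpec(outcome="outcome", fixed_terms=("x",)), pnl)


class TestReportOr:
    def _fake_fit(self, beta, se):
        k = len(beta)
        return glmm.GlmmFit(
            terms=[f"b{i}" for i in range(k)], beta=np.array(beta), se=np.array(se),
            vcov=np.diag(np.array(se) ** 2), sigma_u=0.5, loglik=-10.0,
            converged=True, penalized=False, n_groups=5, n_obs=50,
        )

    def test_null_coefficient(self):
        rep = report_or(self._fake_fit([0.0], [0.2]))
        assert rep["aor"].iloc[0] == pytest.approx(1.0)
        assert rep["ci_low"].iloc[0] * rep["ci_high"].iloc[0] == pytest.approx(1.0)

    def test_published_homestay_row(self):
        """beta 0.69 (0.281) -> aOR 1.99, CI (1.15, 3.46)."""
        rep = report_or(self._fake_fit([0.69], [0.281]))
        assert rep["aor"].iloc[0] == pytest.approx(1.99, abs=0.005)
        assert rep["ci_low"].iloc[0] == pytest.approx(1.15, abs=0.005)
        assert rep["ci_high"].iloc[0] == pytest.approx(3.45, abs=0.01)

    def test_published_ideation_row(self):
        """beta -0.02 (0.148) -> aOR 0.98, CI (0.73, 1.31)."""
        rep = report_or(self._fake_fit([-0.02], [0.148]))
        assert rep["aor"].iloc[0] == pytest.approx(0.98, abs=0.005)
        assert rep["ci_low"].iloc[0] == pytest.approx(0.73, abs=0.005)
        assert rep["ci_high"].iloc[0] == pytest.approx(1.31, abs=0.005)

    def test_refuses_unconverged(self):
        f = self._fake_fit([0.1], [0.1])
        f.converged = False
        with pytest.raises(ValueError, match="refusing"):
            report_or(f)


class TestLagScan:
    def test_constant_features_lags_agree(self):
        """When features never change week to week, all lags coincide."""
        rng = np.random.default_rng(8)
        n_p, n_w = 40, 12
        pid = np.repeat(np.arange(n_p), n_w)
        week = np.tile(np.arange(n_w), n_p)
        const = np.repeat(rng.standard_normal(n_p), n_w)
        wk = pd.DataFrame(
            {
                "participant_id": pid, "week_index": week,
                "homestay_within": const, "entropy_within": 0.0, "distance_within": 0.0,
                "homestay_between": const, "entropy_between": 0.0, "distance_between": 0.0,
            }
        )
        y = (rng.random(n_p) < 0.3).astype(int)
        outcomes = pd.DataFrame(
            {
                "participant_id": np.arange(n_p), "week_index": 6,
                "event_flag": y, "ideation_flag": np.nan, "responded": 0,
            }
        )
        spec = GlmmSpec(
            outcome="outcome",
            fixed_terms=("homestay_within", "weeks_since_baseline"),
        )
        scan = glmm.lag_scan(wk, outcomes, lags=(0, 1), spec=spec)
        assert scan["error"].eq("").all()
        # lag panels span slightly different week ranges (lag-1 loses week 0),
        # so agreement is close but not exact
        assert scan["estimate"].iloc[0] == pytest.approx(scan["estimate"].iloc[1], rel=0.02)

    def test_reversed_direction_runs_ols(self):
        rng = np.random.default_rng(9)
        n_p, n_w = 30, 10
        pid = np.repeat(np.arange(n_p), n_w)
        week = np.tile(np.arange(n_w), n_p)
        wk = pd.DataFrame(
            {
                "participant_id": pid, "week_index": week,
                "homestay_within": rng.standard_normal(n_p * n_w),
                "entropy_within": rng.standard_normal(n_p * n_w),
                "distance_within": rng.standard_normal(n_p * n_w),
                "homestay_between": 0.0, "entropy_between": 0.0, "distance_between": 0.0,
            }
        )
        outcomes = pd.DataFrame(
            {
                "participant_id": rng.integers(0, n_p, 8),
                "week_index": rng.integers(0, n_w - 1, 8),
                "event_flag": 1, "ideation_flag": np.nan, "responded": 0,
            }
        ).drop_duplicates(["participant_id", "week_index"])
        scan = glmm.lag_scan(wk, outcomes, direction="reversed")
        assert set(scan["term"]) == {"homestay_within", "entropy_within", "distance_within"}
        assert scan["estimate"].notna().all()
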