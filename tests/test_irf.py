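"""Orthogonalized IRFs, bootstrap bands, the ordering sweep, sign tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadvar as dv
from dyadvar.errors import EstimationError, StabilityError
from dyadvar.irf import SignTable, _theta_curves, cholesky_factor
from dyadvar.panel import MonthlyPanel


def _model(coefs, sigma, m_names=None, resid_rows=20):
    coefs = np.asarray(coefs, float)
    if coefs.ndim == 2:
        coefs = coefs[None]
    m = coefs.shape[1]
    return dv.VARModel(
        variables=m_names or [f"v{i}" for i in range(m)],
        p=coefs.shape[0],
        intercepts=np.zeros(m),
        coef_matrices=coefs,
        residuals=np.zeros((resid_rows, m)),
        sigma=np.asarray(sigma, float),
        dyad_ids=["d1"],
        dyad_row_counts=np.array([resid_rows]),
    )


class TestCholesky:
    def test_identity(self):
        np.testing.assert_array_equal(cholesky_factor(np.eye(3)).matrix, np.eye(3))

    def test_known_two_by_two(self):
        p = cholesky_factor(np.array([[4.0, 2.0], [2.0, 3.0]])).matrix
        np.testing.assert_allclose(p, [[2.0, 0.0], [1.0, np.sqrt(2.0)]])
        np.testing.assert_allclose(p @ p.T, [[4.0, 2.0], [2.0, 3.0]])

    def test_first_column_is_covariances_over_s1(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        sigma = a @ a.T + 5 * np.eye(5)
        p = cholesky_factor(sigma).matrix
        s1 = np.sqrt(sigma[0, 0])
        assert p[0, 0] == pytest.approx(s1)
        np.testing.assert_allclose(p[1:, 0], sigma[1:, 0] / s1)
        assert np.all(np.diag(p) > 0)

    def test_singular_covariance_rejected(self):
        with pytest.raises(EstimationError):
            cholesky_factor(np.array([[1.0, 1.0], [1.0, 1.0]]))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_reconstruction_property(self, seed, m):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((m, m))
        sigma = a @ a.T + m * np.eye(m)
        p = cholesky_factor(sigma).matrix
        np.testing.assert_allclose(p @ p.T, sigma, atol=1e-10)
        assert np.allclose(p, np.tril(p)) and np.all(np.diag(p) > 0)


class TestComputeIRF:
    def test_default_horizon_is_ten_steps(self, model4):
        assert dv.compute_irf(model4[0]).horizon == 10

    def test_null_dynamics_gives_unit_impact_only(self):
        irfs = dv.compute_irf(_model(np.zeros((2, 2)), np.eye(2)), horizon=5)
        np.testing.assert_array_equal(irfs.point[0], np.eye(2))
        assert np.all(irfs.point[1:] == 0)

    def test_matches_closed_form_matrix_powers(self, model4):
        model, _ = model4
        irfs = dv.compute_irf(model, horizon=10)
        p_mat = cholesky_factor(model.sigma).matrix
        b = model.coef_matrices[0]
        for h in range(11):
            np.testing.assert_allclose(
                irfs.point[h], np.linalg.matrix_power(b, h) @ p_mat, atol=1e-10
            )

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_shocked_minus_baseline_simulation(self, p):
        """Independent oracle: difference two noise-free trajectories."""
        rng = np.random.default_rng(42)
        coefs = rng.uniform(-0.3, 0.3, (p, 3, 3))
        a = rng.standard_normal((3, 3))
        sigma = a @ a.T + 3 * np.eye(3)
        model = _model(coefs, sigma)
        assert model.stable
        irfs = dv.compute_irf(model, horizon=10)
        p_mat = np.linalg.cholesky(sigma)
        for j in range(3):
            base = [np.zeros(3) for _ in range(p)]
            shocked = [x.copy() for x in base]
            shocked[-1] = shocked[-1] + p_mat[:, j]  # one-time orthogonalized shock
            diffs = [shocked[-1] - base[-1]]
            for _ in range(10):
                nb = sum(coefs[k] @ base[-1 - k] for k in range(p))
                ns = sum(coefs[k] @ shocked[-1 - k] for k in range(p))
                base.append(nb)
                shocked.append(ns)
                diffs.append(ns - nb)
            for h in range(11):
                np.testing.assert_allclose(irfs.point[h, :, j], diffs[h], atol=1e-10)

    def test_matches_statsmodels_orthogonalized_irf(self, cohort4):
        from statsmodels.tsa.api import VAR as StatsmodelsVAR
        _, panel = cohort4
        one = MonthlyPanel(["d"], ["boy"], panel.months, panel.variables,
                           panel.values[:1], panel.encoding)
        mine = dv.compute_irf(dv.fit_var(one, 1), horizon=10)
        ref = StatsmodelsVAR(one.values[0]).fit(1, trend="c").irf(10)
        np.testing.assert_allclose(mine.point, ref.orth_irfs, atol=1e-10)

    def test_unstable_model_rejected(self):
        with pytest.raises(StabilityError):
            dv.compute_irf(_model([[1.05, 0.0], [0.0, 0.3]], np.eye(2)))

    def test_stable_curves_decay(self, model4):
        irfs = dv.compute_irf(model4[0], horizon=60)
        assert np.abs(irfs.point[60]).max() < 1e-6


class TestBootstrap:
    def test_zero_residuals_give_zero_width_bands(self):
        # deterministic trajectories from two starting points: a perfect fit
        a = np.array([[0.6, 0.2], [-0.1, 0.5]])
        starts = [np.array([5.0, -3.0]), np.array([-2.0, 4.0]), np.array([1.0, 7.0])]
        series = []
        for s in starts:
            x = [s]
            for _ in range(9):
                x.append(a @ x[-1])
            series.append(np.stack(x))
        panel = MonthlyPanel(["d1", "d2", "d3"], ["boy"] * 3, np.arange(10),
                             ["v0", "v1"], np.stack(series), "duration_seconds")
        model = dv.fit_var(panel, 1)
        assert np.abs(model.residuals).max() < 1e-10
        out = dv.bootstrap_irf_ci(model, panel, reps=25, seed=0)
        np.testing.assert_allclose(out.lower, out.point, atol=1e-8)
        np.testing.assert_allclose(out.upper, out.point, atol=1e-8)

    def test_band_ordering_and_significance_flags(self, model4):
        model, panel = model4
        out = dv.bootstrap_irf_ci(model, panel, reps=50, seed=1)
        assert np.all(out.lower <= out.point + 1e-12)
        assert np.all(out.point <= out.upper + 1e-12)
        r = out.pair(panel.variables[0], panel.variables[0])
        assert 0 in r.significant_at  # own impact = residual sd > 0

    def test_scaling_noise_scales_point_and_bands(self):
        """Doubling the innovation sd doubles IRFs and band widths."""
        kw = dict(n_dyads_per_group=5, months=range(0, 20),
                  variables=["Crawl", "Babble"],
                  coupling_by_group={"boy": 0.4 * np.eye(2), "girl": 0.4 * np.eye(2)})
        p1 = dv.generate_cohort(dv.GeneratorConfig(seed=5, innovation_cov=np.eye(2), **kw))
        p2 = dv.generate_cohort(dv.GeneratorConfig(seed=5, innovation_cov=4 * np.eye(2), **kw))
        np.testing.assert_allclose(p2.values, 2 * p1.values, atol=1e-12)
        m1, m2 = dv.fit_var(p1, 1), dv.fit_var(p2, 1)
        o1 = dv.bootstrap_irf_ci(m1, p1, reps=30, seed=3)
        o2 = dv.bootstrap_irf_ci(m2, p2, reps=30, seed=3)
        np.testing.assert_allclose(o2.point, 2 * o1.point, atol=1e-8)
        np.testing.assert_allclose(o2.upper - o2.lower, 2 * (o1.upper - o1.lower), atol=1e-8)

    def test_invalid_parameters_rejected(self, model4):
        model, panel = model4
        with pytest.raises(ValueError):
            dv.bootstrap_irf_ci(model, panel, reps=1)
        with pytest.raises(ValueError):
            dv.bootstrap_irf_ci(model, panel, level=0)


class TestConservativeSweep:
    def test_two_variable_sweep_unrolls_to_last_position_orderings(self):
        cfg = dv.GeneratorConfig(n_dyads_per_group=6, months=range(0, 15), seed=8,
                                 variables=["Crawl", "Babble"])
        panel = dv.generate_cohort(cfg)
        sweep = dv.conservative_irf_sweep(panel, reps=40, seed=9)
        assert sweep.orderings == [["Babble", "Crawl"], ["Crawl", "Babble"]]
        # impulse effects of each variable must come from its last-position run
        model = dv.fit_var(panel, 1)
        for var, order in zip(["Crawl", "Babble"], sweep.orderings):
            direct = dv.bootstrap_irf_ci(model, panel, reps=40, seed=9, order=order)
            for resp in panel.variables:
                got = sweep.pair(var, resp)
                want = direct.pair(var, resp)
                np.testing.assert_allclose(got.mean, want.mean, atol=1e-12)
                np.testing.assert_allclose(got.lower, want.lower, atol=1e-12)

    def test_coefficients_identical_across_orderings(self, cohort4):
        # the sweep itself verifies refits match to 1e-10 and raises otherwise
        _, panel = cohort4
        sweep = dv.conservative_irf_sweep(panel, reps=2, seed=0)
        assert len(sweep.orderings) == panel.m
        for order in sweep.orderings:
            assert order[-1] in panel.variables

    def test_sweep_runs_one_ordering_per_variable_on_26_codes(self):
        panel = dv.generate_cohort(dv.GeneratorConfig(seed=2)).subset_group("boy")
        sweep = dv.conservative_irf_sweep(panel, reps=2, seed=1)
        assert len(sweep.orderings) == 26
        assert all(o[-1] == v for o, v in zip(sweep.orderings, panel.variables))


class TestSignTable:
    def test_all_blank_without_significance(self):
        cfg = dv.GeneratorConfig(n_dyads_per_group=4, months=range(0, 12), seed=3,
                                 variables=["Crawl", "Babble"],
                                 coupling_by_group={"boy": np.zeros((2, 2)),
                                                    "girl": np.zeros((2, 2))})
        panel = dv.generate_cohort(cfg)
        sweep = dv.conservative_irf_sweep(panel, reps=30, seed=4)
        # force insignificance by inflating the bands
        sweep.lower = sweep.lower - 100.0
        sweep.upper = sweep.upper + 100.0
        table = dv.build_sign_table(sweep)
        assert (table.cells.to_numpy() == "").all()

    def test_window_outside_horizon_rejected(self, model4):
        model, panel = model4
        sweep = dv.conservative_irf_sweep(panel, reps=5, seed=0, horizon=4)
        with pytest.raises(ValueError):
            dv.build_sign_table(sweep, window=(1, 9))

    def test_study_layout_subsets(self):
        panel = dv.generate_cohort(dv.GeneratorConfig(seed=6)).subset_group("girl")
        sweep = dv.conservative_irf_sweep(panel, reps=5, seed=7)
        table = dv.build_sign_table(
            sweep, impulse_set=dv.MATERNAL_CODES, response_set=dv.INFANT_CODES
        )
        assert table.cells.shape == (15, 11)

    def test_bracket_rendering_dialect(self):
        idx, cols = ["Reach"], ["Points to Object"]
        def t(sign):
            return SignTable(pd.DataFrame(sign, index=idx, columns=cols), (1, 3))
        combined = dv.render_bracket_table(
            duration_tables={"boy": t(""), "girl": t("+")},
            occurrence_tables={"boy": t("-"), "girl": t("")},
        )
        assert combined.loc["Reach", "Points to Object"] == "+G[-B]"
        blank = dv.render_bracket_table({"boy": t("")}, {"boy": t("")})
        assert blank.loc["Reach", "Points to Object"] == ""
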