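"""Designs, screening effects and the second-order response surface."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavopk import (
    DesignMatrix,
    FactorDef,
    ResponseSurfaceModel,
    box_behnken,
    estimate_main_effects,
    plackett_burman,
    rank_effects,
    results_from_coefficients,
)
from flavopk.doe import DegenerateDesignError, _lenth_pse
from flavopk.presets import BBD_FACTORS, PBD_FACTORS


# ---------------------------------------------------------------- coding

class TestFactorCoding:
    def test_decode_maps_coded_levels_to_actual_settings(self):
        nozzle = FactorDef("Nozzle Voltage", "V", 700, 1100, 1500)
        assert nozzle.decode(1) == 1500
        assert nozzle.decode(0) == 1100
        assert FactorDef("Nebulizer", "psi", 40, 50, 60).decode(-1) == 40

    def test_round_trip_on_asymmetric_range(self):
        # center deliberately not the midpoint: coding must be piecewise
        f = FactorDef("x", "u", 0.0, 1.0, 10.0)
        for actual in (0.0, 0.25, 1.0, 3.7, 10.0):
            assert f.decode(f.code(actual)) == pytest.approx(actual, abs=1e-12)
        assert f.code(0.5) == pytest.approx(-0.5)
        assert f.code(5.5) == pytest.approx(0.5)

    def test_out_of_range_raises(self):
        f = FactorDef("x", "u", 0, 5, 10)
        with pytest.raises(ValueError):
            f.code(11)
        with pytest.raises(ValueError):
            f.decode(1.5)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            FactorDef("x", "u", 10, 5, 0)


# ---------------------------------------------------------------- designs

class TestPlackettBurman:
    def test_balance_and_orthogonality(self):
        d = plackett_burman(PBD_FACTORS)
        X = d.non_center
        assert X.shape == (12, 11)
        # six +1 and six -1 in every column; any two columns orthogonal
        assert (X.sum(axis=0) == 0).all()
        G = X.T @ X
        assert np.array_equal(G, 12 * np.eye(11))

    def test_center_rows_appended_and_flagged(self):
        d = plackett_burman(PBD_FACTORS, n_center=3)
        assert d.n_runs == 15
        assert d.center_flags.sum() == 3
        assert (d.runs[d.center_flags] == 0).all()
        assert d.n_real_factors == 7 and d.n_columns == 11

    def test_too_many_factors_rejected(self):
        factors = [FactorDef(f"f{i}", "u", 0, 1, 2) for i in range(12)]
        with pytest.raises(DegenerateDesignError):
            plackett_burman(factors)


class TestBoxBehnken:
    def test_seventeen_runs_with_five_centers(self, bbd17):
        assert bbd17.n_runs == 17
        assert bbd17.center_flags.sum() == 5

    def test_every_edge_run_has_exactly_one_zero(self, bbd17):
        non_center = bbd17.non_center
        assert non_center.shape == (12, 3)
        assert ((non_center == 0).sum(axis=1) == 1).all()
        # all 12 edge midpoints distinct, columns balanced
        assert len({tuple(r) for r in non_center}) == 12
        assert (bbd17.runs.sum(axis=0) == 0).all()

    def test_wrong_factor_count_rejected(self):
        with pytest.raises(ValueError):
            box_behnken(PBD_FACTORS[:2])

    def test_few_centers_warns(self):
        with pytest.warns(UserWarning):
            box_behnken(BBD_FACTORS, n_center=1)


# ------------------------------------------------------------- main effects

def _two_by_two():
    f = [FactorDef("A", "u", 0, 1, 2), FactorDef("B", "u", 0, 1, 2)]
    runs = np.array([[-1, -1], [1, -1], [-1, 1], [1, 1]], float)
    return DesignMatrix(f, runs, ["r1", "r2", "r3", "r4"], np.zeros(4, bool))


class TestMainEffects:
    def test_constant_response_gives_zero_effects(self):
        d = plackett_burman(PBD_FACTORS, n_center=2)
        t = estimate_main_effects(d, np.full(14, 5.0))
        assert np.allclose(t.effects, 0) and np.allclose(t.dummy_effects, 0)

    def test_hand_computed_factorial_effect(self):
        # 2^2 factorial: effect of A = 2((10+12)-(6+8))/4 = 4
        t = estimate_main_effects(_two_by_two(), np.array([6.0, 10, 8, 12]))
        assert t.effects[0] == pytest.approx(4.0)
        assert t.effects[1] == pytest.approx(2.0)

    def test_sign_matches_level_mean_difference(self):
        t = estimate_main_effects(_two_by_two(), np.array([10.0, 6, 12, 8]))
        assert t.effects[0] < 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=12, max_size=12))
    def test_effect_equals_twice_ols_coefficient(self, y):
        """On a balanced two-level design E(Xi) is exactly 2x the OLS slope
        of the coded column."""
        d = plackett_burman(PBD_FACTORS)
        y = np.asarray(y)
        t = estimate_main_effects(d, y)
        X = np.column_stack([np.ones(12), d.non_center])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(t.effects, 2 * beta[1:8], atol=1e-8)

    def test_single_level_column_rejected(self):
        f = [FactorDef("A", "u", 0, 1, 2), FactorDef("B", "u", 0, 1, 2)]
        runs = np.array([[1, -1], [1, 1], [1, -1], [1, 1]], float)
        d = DesignMatrix(f, runs, list("abcd"), np.zeros(4, bool))
        with pytest.raises(DegenerateDesignError):
            estimate_main_effects(d, np.arange(4.0))


class TestRankEffects:
    def test_lenth_pse_definition(self):
        """PSE = 1.5 * median of |effects| surviving the 2.5*s0 trim."""
        eff = np.array([0.1, -0.2, 0.15, 8.0, -0.12, 0.18, 0.25, -0.3, 0.2,
                        0.11, -0.16])
        s0 = 1.5 * np.median(np.abs(eff))
        trimmed = np.abs(eff)[np.abs(eff) < 2.5 * s0]
        assert _lenth_pse(eff) == pytest.approx(1.5 * np.median(trimmed))

    def test_dominant_effect_ranks_first_with_floor_p(self):
        d = plackett_burman(PBD_FACTORS)
        y = 1000.0 * d.non_center[:, 2]  # single huge factor, others inert
        t = rank_effects(d, estimate_main_effects(d, y), method="dummy-variance")
        assert t.ranks[2] == 1
        assert t.p_values[2] <= np.finfo(float).tiny

    def test_active_factors_detected_in_monte_carlo(self):
        """Two active factors (effect 10), five inert, noise sd 1: the
        active pair should reach p < 0.05 in >= 90% of seeded replicates."""
        d = plackett_burman(PBD_FACTORS)
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            y = 5.0 * d.non_center[:, 0] + 5.0 * d.non_center[:, 1] + \
                rng.normal(0, 1.0, 12)
            t = rank_effects(d, estimate_main_effects(d, y), method="lenth")
            hits += (t.p_values[0] < 0.05) and (t.p_values[1] < 0.05)
        assert hits / n_rep >= 0.90

    def test_center_replicate_method(self):
        d = plackett_burman(PBD_FACTORS, n_center=4)
        rng = np.random.default_rng(7)
        y = np.r_[10 * d.non_center[:, 0], np.zeros(4)] + rng.normal(0, 1, 16)
        t = rank_effects(d, estimate_main_effects(d, y),
                         method="center-replicates", response=y)
        assert t.ranks[0] == 1
        assert t.p_values[0] < 0.05

    def test_threshold_reported(self):
        d = plackett_burman(PBD_FACTORS)
        t = rank_effects(d, estimate_main_effects(d, np.arange(12.0)))
        assert t.threshold is not None and t.threshold > 0


# ------------------------------------------------------- quadratic surface

class TestQuadraticFit:
    def test_noise_free_coefficients_recovered_exactly(self, bbd17, rng):
        true = np.concatenate([[100.0], rng.normal(0, 10, 9)])
        from flavopk.doe import _quadratic_model_matrix

        X, _ = _quadratic_model_matrix(bbd17.runs)
        res = ResponseSurfaceModel(bbd17, X @ true).fit()
        assert np.allclose(res.params, true, atol=1e-8)
        assert res.r2 == pytest.approx(1.0)

    def test_published_model_round_trip(self, published_surface):
        """Noise-free responses generated from the published coefficient set
        refit to exactly those coefficients."""
        res = published_surface
        assert res.b0 == pytest.approx(2398.0, abs=1e-8)
        assert res.linear == pytest.approx([-328.12, 121.5, 325.37], abs=1e-8)
        assert res.quadratic == pytest.approx([35.87, -23.38, -74.63], abs=1e-8)
        assert res.interaction == pytest.approx([-45.0, -52.75, 10.5], abs=1e-8)

    def test_residuals_orthogonal_to_model_matrix(self, bbd17, rng):
        y = rng.normal(1000, 100, 17)
        res = ResponseSurfaceModel(bbd17, y).fit()
        prods = res.model.exog.T @ res.resid
        assert np.all(np.abs(prods) < 1e-6 * max(1.0, np.abs(y).sum()))

    def test_prediction_at_center_equals_intercept(self, bbd17, rng):
        res = ResponseSurfaceModel(bbd17, rng.normal(0, 1, 17)).fit()
        assert res.predict(np.zeros(3)) == pytest.approx(res.b0)

    def test_too_few_runs_rejected(self, rng):
        d = box_behnken(BBD_FACTORS, n_center=5)
        small = DesignMatrix(d.factors, d.runs[:9], d.run_ids[:9],
                             d.center_flags[:9])
        with pytest.raises(DegenerateDesignError):
            ResponseSurfaceModel(small, rng.normal(0, 1, 9))

    def test_coefficient_recovery_within_sampling_error(self, bbd17):
        """With noise sd sigma, each estimate should fall within 4 standard
        errors of truth in >= 95% of seeded replicates."""
        from flavopk.doe import _quadratic_model_matrix

        X, _ = _quadratic_model_matrix(bbd17.runs)
        true = np.array([2398, -328, 121, 325, 36, -23, -75, -45, -53, 10.0])
        sigma = 50.0
        cov = sigma**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        ok = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            y = X @ true + rng.normal(0, sigma, 17)
            res = ResponseSurfaceModel(bbd17, y).fit()
            ok += bool(np.all(np.abs(res.params - true) < 4 * se))
        assert ok / n_rep >= 0.95


class TestAnova:
    def test_sum_of_squares_identity(self, bbd17, rng):
        y = rng.normal(2000, 150, 17)
        res = ResponseSurfaceModel(bbd17, y).fit()
        an = res.anova()
        total = np.sum((y - y.mean()) ** 2)
        assert an["ss_regression"] + an["ss_lack_of_fit"] + an["ss_pure_error"] \
            == pytest.approx(total)
        assert an["ss_residual"] == pytest.approx(
            an["ss_lack_of_fit"] + an["ss_pure_error"]
        )
        assert an["df_pure_error"] == 4  # five center replicates

    def test_identical_center_replicates_flagged(self, bbd17, rng):
        y = rng.normal(2000, 150, 17)
        y[bbd17.center_flags] = 1234.5
        an = ResponseSurfaceModel(bbd17, y).fit().anova()
        assert an["ss_pure_error"] == 0.0
        assert an["f_undefined"]

    def test_lack_of_fit_p_matches_f_quadrature(self, bbd17, rng):
        """p for (F, df1, df2) agrees with numerical integration of the
        F density to 1e-6."""
        from scipy.integrate import quad
        from scipy.stats import f as fdist

        y = rng.normal(2000, 150, 17)
        an = ResponseSurfaceModel(bbd17, y).fit().anova()
        F, d1, d2 = an["f_lack_of_fit"], an["df_lack_of_fit"], an["df_pure_error"]
        tail, _ = quad(lambda x: fdist.pdf(x, d1, d2), F, np.inf)
        assert an["p_lack_of_fit"] == pytest.approx(tail, abs=1e-6)


class TestStationaryPoint:
    def test_published_model_saddle_outside_region(self, published_surface):
        """The zero-gradient point of the published surface sits far outside
        the design cube and is a saddle; frozen against an independent
        linear-solve + eigenvalue oracle."""
        sp = published_surface.stationary_point()
        assert sp.coded_point == pytest.approx(
            [4.19851088, -1.30643767, 0.60418703], abs=1e-6
        )
        assert sp.classification == "saddle"
        assert not sp.inside_region
        # gradient residual at the stationary point
        g = published_surface.linear + published_surface.hessian @ sp.coded_point
        assert np.linalg.norm(g) < 1e-8

    def test_concave_bowl_maximum_at_origin(self, bbd17):
        res = results_from_coefficients(
            bbd17, 10.0, (0, 0, 0), (-1, -1, -1), (0, 0, 0)
        )
        sp = res.stationary_point()
        assert sp.coded_point == pytest.approx([0, 0, 0], abs=1e-10)
        assert sp.classification == "maximum"
        assert sp.inside_region
        assert sp.constrained_optimum_coded == pytest.approx([0, 0, 0], abs=1e-10)

    def test_gradient_residual_invariant_random_quadratics(self, bbd17, rng):
        for _ in range(100):
            res = results_from_coefficients(
                bbd17, rng.normal(), rng.normal(size=3),
                rng.normal(size=3) + np.sign(rng.normal(size=3)) * 0.5,
                rng.normal(size=3),
            )
            sp = res.stationary_point()
            if sp.coded_point is None:
                continue
            g = res.linear + res.hessian @ sp.coded_point
            assert np.linalg.norm(g) < 1e-8


class TestConstrainedOptimum:
    def test_published_model_optimum_at_printed_settings(self, published_surface):
        sp = published_surface.stationary_point()
        assert sp.constrained_optimum_coded == pytest.approx([-1, 1, 1])
        neb, sgt, nv = sp.constrained_optimum_actual
        assert (neb, sgt, nv) == (40.0, 400.0, 1500.0)
        assert sp.predicted_response_at_optimum == pytest.approx(3219.1, abs=1e-6)

    def test_matches_grid_oracle_on_random_quadratics(self, bbd17, rng):
        """Face/edge/vertex enumeration agrees with a 0.01-step grid search
        in value (within the grid's own resolution bound)."""
        g = np.arange(-1, 1.0001, 0.01)
        x1, x2, x3 = np.meshgrid(g, g, g, indexing="ij", sparse=True)
        for _ in range(100):
            res = results_from_coefficients(
                bbd17, rng.normal(), rng.normal(size=3) * 3,
                rng.normal(size=3) * 2, rng.normal(size=3),
            )
            sp = res.stationary_point()
            b0, (b1, b2, b3) = res.b0, res.linear
            (b11, b22, b33), (b12, b13, b23) = res.quadratic, res.interaction
            y = (b0 + b1 * x1 + b2 * x2 + b3 * x3
                 + b11 * x1**2 + b22 * x2**2 + b33 * x3**2
                 + b12 * x1 * x2 + b13 * x1 * x3 + b23 * x2 * x3)
            grid_best = float(y.max())
            assert sp.predicted_response_at_optimum >= grid_best - 1e-9
            # grid can undershoot the exact optimum by at most the gradient
            # bound over half a step; a generous linear bound suffices
            lip = np.abs(res.linear).sum() + 3 * np.abs(res.hessian).sum()
            assert sp.predicted_response_at_optimum - grid_best <= lip * 0.01

    def test_summary_mentions_optimum(self, published_surface):
        s = published_surface.summary()
        assert "constrained optimum" in s
        assert "1500" in s
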