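"""Quadratic fit, ANOVA decomposition and standardized-effect ranking."""

import numpy as np
import pytest

from sorbopt import (
    DesignTable,
    anova,
    build_bbd,
    effects_grid,
    fit_quadratic,
    predict,
    standardized_effects,
)
from sorbopt.datasets import (
    PB_FACTORS,
    PB_REFERENCE_COEFFICIENTS,
    PB_REFERENCE_PREDICTED,
)
from sorbopt.errors import SingularDesignError, ValidationError
from sorbopt.rsm import quadratic_basis


class TestFitQuadratic:
    def test_recovers_published_coefficients(self, pb_model):
        # 2-dp rounding of the responses propagates at most +/-0.005 into
        # any coefficient (each is a mean of <=15 responses over 4-8 runs)
        assert np.all(np.abs(pb_model.coefficients - PB_REFERENCE_COEFFICIENTS) <= 0.005)

    def test_residual_structure(self, pb_model):
        assert pb_model.residual_df == 5
        assert pb_model.residual_ss == pytest.approx(18.63, abs=0.02)

    def test_predictions_match_published_column(self, pb_model, pb_design):
        got = predict(pb_model, pb_design.coded)
        assert np.all(np.abs(got - PB_REFERENCE_PREDICTED) <= 0.01)

    def test_exact_interpolation_of_noiseless_data(self):
        design = build_bbd(PB_FACTORS, n_center=3)
        truth = np.array([80.0, 5.0, -2.0, 7.0, -10.0, -3.0, -2.0, -1.0, -2.5, 0.5])
        y = quadratic_basis(design.coded) @ truth
        model, summary = fit_quadratic(design.with_responses(y))
        assert np.allclose(model.coefficients, truth, atol=1e-9)
        assert model.residual_ss == pytest.approx(0.0, abs=1e-16)
        assert summary.r_squared == pytest.approx(1.0)

    def test_fit_summary_consistency(self, pb_fit, pb_design):
        model, summary = pb_fit
        y = pb_design.responses
        sst = ((y - y.mean()) ** 2).sum()
        assert summary.r_squared == pytest.approx(1 - model.residual_ss / sst)
        assert summary.adj_r_squared <= summary.r_squared
        assert np.allclose(summary.fitted + summary.residuals, y)

    def test_missing_responses_rejected(self):
        with pytest.raises(ValidationError):
            fit_quadratic(build_bbd(PB_FACTORS))

    def test_singular_design_names_columns(self, pb_design):
        coded = pb_design.coded.copy()
        coded[:, 2] = coded[:, 1]  # dose collinear with temperature
        broken = DesignTable(
            factors=pb_design.factors, coded=coded, responses=pb_design.responses
        )
        with pytest.raises(SingularDesignError, match="dose"):
            fit_quadratic(broken)


class TestAnova:
    def test_published_rows(self, pb_model, pb_design):
        table = anova(pb_model, pb_design)
        expect = {  # published ANOVA of this fit
            "Model": (9, 1288.60, 38.44),
            "Linear": (3, 754.96, 67.55),
            "pH": (1, 297.77, 79.93),
            "temperature": (1, 38.02, 10.21),
            "dose": (1, 419.17, 112.52),
            "Square": (3, 505.27, 45.21),
            "2-Way Interaction": (3, 28.38, 2.54),
        }
        for source, (df, ss, f) in expect.items():
            row = table[source]
            assert row.df == df
            assert row.adj_ss == pytest.approx(ss, rel=5e-3)
            assert row.f == pytest.approx(f, rel=5e-3)
        assert table["Error"].adj_ss == pytest.approx(18.63, rel=5e-3)
        assert table["Total"].adj_ss == pytest.approx(1307.23, rel=5e-3)

    def test_sum_of_squares_identities(self, pb_model, pb_design):
        t = anova(pb_model, pb_design)
        rtol = 1e-8
        assert t["Total"].adj_ss == pytest.approx(
            t["Model"].adj_ss + t["Error"].adj_ss, rel=rtol
        )
        assert t["Error"].adj_ss == pytest.approx(
            t["Lack-of-Fit"].adj_ss + t["Pure Error"].adj_ss, rel=rtol
        )
        # orthogonal groups decompose into their members
        assert t["Linear"].adj_ss == pytest.approx(
            sum(t[n].adj_ss for n in ("pH", "temperature", "dose")), rel=rtol
        )
        assert t["2-Way Interaction"].adj_ss == pytest.approx(
            sum(t[n].adj_ss for n in ("pH*temperature", "pH*dose", "temperature*dose")),
            rel=rtol,
        )
        assert t["Model"].adj_ss == pytest.approx(
            t["Linear"].adj_ss + t["Square"].adj_ss + t["2-Way Interaction"].adj_ss,
            rel=rtol,
        )
        for row in t.rows.values():
            if row.df > 0 and row.adj_ms is not None:
                assert row.adj_ms == pytest.approx(row.adj_ss / row.df, rel=rtol)

    def test_main_effect_ss_closed_form(self, pb_model, pb_design):
        # 12 edge runs at +/-1 give sum x_i^2 = 8, so SS(main effect) = 8 b^2
        t = anova(pb_model, pb_design)
        for i, name in enumerate(("pH", "temperature", "dose")):
            b = pb_model.coefficients[1 + i]
            assert t[name].adj_ss == pytest.approx(8.0 * b**2, rel=1e-8)

    def test_degrees_of_freedom_split(self, pb_model, pb_design):
        t = anova(pb_model, pb_design)
        assert (t["Error"].df, t["Lack-of-Fit"].df, t["Pure Error"].df) == (5, 3, 2)
        assert t["Total"].df == 14

    def test_noiseless_data_reports_infinite_f(self):
        design = build_bbd(PB_FACTORS, n_center=3)
        y = quadratic_basis(design.coded) @ PB_REFERENCE_COEFFICIENTS
        design = design.with_responses(y)
        model, _ = fit_quadratic(design)
        t = anova(model, design)
        assert t["Error"].adj_ss == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(t["Model"].f)

    def test_no_replicates_omits_lack_of_fit(self, pb_design):
        # drop two of the three centre replicates (fixture rows 9 and 11)
        keep = np.delete(np.arange(15), [8, 10])
        design = DesignTable(
            factors=pb_design.factors,
            coded=pb_design.coded[keep],
            responses=pb_design.responses[keep],
        )
        model, _ = fit_quadratic(design)
        t = anova(model, design)
        assert "Lack-of-Fit" not in t and "Pure Error" not in t


class TestStandardizedEffects:
    def test_published_ranking(self, pb_model):
        order = standardized_effects(pb_model).order()
        assert order[:7] == [
            "pH*pH", "dose", "pH",
            "temperature*temperature", "temperature", "dose*dose", "pH*dose",
        ]

    def test_t_squared_equals_anova_f(self, pb_model, pb_design):
        t_table = anova(pb_model, pb_design)
        for row in standardized_effects(pb_model).rows:
            assert row.t**2 == pytest.approx(t_table[row.term].f, rel=1e-8)

    def test_threshold_is_t_critical(self, pb_model):
        from scipy import stats

        eff = standardized_effects(pb_model, alpha=0.05)
        assert eff.threshold == pytest.approx(stats.t.ppf(0.975, 5))

    def test_null_interaction_rarely_flagged(self):
        # truth with zero pH*temperature effect; at alpha=0.05 the term
        # should be non-significant in >= 90% of replicates
        from sorbopt import SurfaceTruth, generate_bbd_responses

        truth_coef = PB_REFERENCE_COEFFICIENTS.copy()
        truth_coef[7] = 0.0  # pH*temperature
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            table = generate_bbd_responses(
                SurfaceTruth(truth_coef, sigma=1.93), PB_FACTORS, rng=rng
            )
            model, _ = fit_quadratic(table)
            eff = {r.term: r for r in standardized_effects(model, alpha=0.05).rows}
            hits += not eff["pH*temperature"].significant
        assert hits >= 0.9 * n_rep

    def test_zero_residual_variance_gives_infinite_t(self):
        design = build_bbd(PB_FACTORS, n_center=3)
        y = quadratic_basis(design.coded) @ PB_REFERENCE_COEFFICIENTS
        model, _ = fit_quadratic(design.with_responses(y))
        eff = standardized_effects(model)
        assert eff.threshold is None
        assert all(np.isinf(r.t) for r in eff.rows)


class TestEffectsGrid:
    def test_slice_maximum_matches_analytic_stationary_point(self, pb_model):
        # hold dose at 0: the (pH, T) slice is strictly concave with an
        # interior stationary point solving the 2x2 linear system
        b = pb_model.coefficients
        H = np.array([[2 * b[4], b[7]], [b[7], 2 * b[5]]])
        stat = np.linalg.solve(H, -b[1:3])
        grid = np.linspace(-1, 1, 201)
        frame = effects_grid(pb_model, held_factor="dose", held_value=0.0, grid=grid)
        ij = np.unravel_index(np.argmax(frame.to_numpy()), frame.shape)
        assert grid[ij[0]] == pytest.approx(stat[0], abs=0.01)
        assert grid[ij[1]] == pytest.approx(stat[1], abs=0.01)

    def test_single_point_grid_equals_predict(self, pb_model):
        frame = effects_grid(pb_model, held_factor=2, held_value=0.5, grid=np.array([0.3]))
        assert frame.iloc[0, 0] == pytest.approx(predict(pb_model, [0.3, 0.3, 0.5]))

    def test_corners_present(self, pb_model):
        grid = np.array([-1.0, 1.0])
        frame = effects_grid(pb_model, held_factor=0, held_value=0.0, grid=grid)
        for i, ti in enumerate(grid):
            for j, dj in enumerate(grid):
                assert frame.iloc[i, j] == pytest.approx(predict(pb_model, [0.0, ti, dj]))
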