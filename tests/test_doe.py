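"""Design encoding, OLS fit, ANOVA, R² suite and optimisation."""

import numpy as np
import pandas as pd
import pytest

from pelletcoat import doe
from pelletcoat.doe import FactorLevels


# ---------------------------------------------------------------- encoding

@pytest.mark.parametrize(
    "levels, expected",
    [
        (("Kollidon VA64", 5.0, "1:1"), (1, -1, -1, 1, 0)),
        (("Kollicoat Protect", 2.5, "2:1"), (-1, 0, 1, 0, 1)),
        (("Kollicoat Protect", 1.0, "3:1"), (-1, 1, 0, -1, -1)),
    ],
)
def test_encode_run_contrast_coding(levels, expected):
    assert tuple(doe.encode_run(levels)) == pytest.approx(expected)


def test_encode_run_accepts_aliases():
    coded = doe.encode_run(("KollidonVA64", 5, 1))
    assert tuple(coded) == pytest.approx((1, -1, -1, 1, 0))


def test_encode_run_rejects_unknown_levels():
    with pytest.raises(ValueError, match="polymer"):
        doe.encode_run(("Eudragit", 1.0, "1:1"))
    with pytest.raises(ValueError, match="concentration"):
        doe.encode_run(("Kollidon VA64", 4.0, "1:1"))
    with pytest.raises(ValueError, match="ratio"):
        doe.encode_run(("Kollidon VA64", 1.0, "5:1"))


def test_contrast_columns_sum_to_zero_over_full_factorial():
    coded = np.array([doe.encode_run(lv) for lv in doe.full_factorial()])
    assert coded.shape == (18, 5)
    assert np.allclose(coded.sum(axis=0), 0.0)


# ------------------------------------------------------------ design matrix

def test_design_matrix_shape_and_rank(design_table):
    X = doe.build_design_matrix(design_table)
    assert X.shape == (20, 12)
    assert np.linalg.matrix_rank(X) == 12


def test_replicate_runs_share_identical_rows(design_table):
    X = doe.build_design_matrix(design_table)
    idx = design_table.index[design_table["run_id"].isin([2, 9])]
    assert np.array_equal(X[idx[0]], X[idx[1]])


def test_single_run_matrix():
    one = pd.DataFrame(
        {"run_id": [1], "polymer": ["Kollidon VA64"],
         "concentration_pct": [1.0], "ratio": ["1:1"]}
    )
    assert doe.build_design_matrix(one).shape == (1, 12)


def test_rank_deficient_run_set_reports_aliased_columns():
    # constant concentration makes B2 (and dependents) inestimable
    runs = pd.DataFrame(
        {
            "run_id": range(1, 14),
            "polymer": ["Kollidon VA64", "Kollicoat Protect"] * 6 + ["Kollidon VA64"],
            "concentration_pct": [1.0] * 13,
            "ratio": (["1:1", "2:1", "3:1"] * 5)[:13],
        }
    )
    with pytest.raises(ValueError, match="aliased"):
        doe.build_design_matrix(runs)


# -------------------------------------------------------------------- fit

def test_fit_reproduces_published_coefficients(fitted_model, reference_coefficients):
    for term, ref in reference_coefficients.items():
        assert fitted_model.coefficients[term] == pytest.approx(ref, abs=0.05), term


def test_fit_matches_statsmodels_ols(design_table, fitted_model):
    sm = pytest.importorskip("statsmodels.api")
    X = doe.build_design_matrix(design_table)
    y = design_table["coated_surface_pct"].to_numpy(float)
    res = sm.OLS(y, X).fit()
    assert np.allclose(fitted_model.beta, res.params, atol=1e-10)
    assert np.allclose(fitted_model.hat_diagonals,
                       res.get_influence().hat_matrix_diag, atol=1e-10)


def test_fit_requires_more_runs_than_parameters(design_table):
    with pytest.raises(ValueError, match="underdetermined"):
        doe.fit_model(design_table.head(12))


def test_noise_free_synthetic_fit_recovers_generating_model(
    design_table, reference_coefficients
):
    from pelletcoat.synthetic import SimulationSpec, gen_doe_response

    spec = SimulationSpec(reference_coefficients, noise_sd=0.0)
    table = gen_doe_response(design_table.drop(columns="coated_surface_pct"), spec)
    refit = doe.fit_model(table)
    for term, ref in reference_coefficients.items():
        assert refit.coefficients[term] == pytest.approx(ref, abs=1e-8)


def test_residual_identities(fitted_model):
    assert fitted_model.residuals.sum() == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(fitted_model.X.T @ fitted_model.residuals, 0.0, atol=1e-8)
    assert fitted_model.hat_diagonals.sum() == pytest.approx(12.0)
    assert np.all((fitted_model.hat_diagonals > 0)
                  & (fitted_model.hat_diagonals < 1))


def test_refit_on_fitted_values_is_exact(fitted_model, design_table):
    fitted = fitted_model.X @ fitted_model.beta
    table = design_table.copy()
    table["coated_surface_pct"] = fitted
    refit = doe.fit_model(table)
    assert np.allclose(refit.beta, fitted_model.beta, atol=1e-10)


# ------------------------------------------------------------------ ANOVA

def test_anova_significance_pattern(fitted_model):
    rows = {r.term: r for r in doe.anova(fitted_model)}
    p_values = {t: rows[t].p_value for t in ("A", "B", "C", "AB", "BC")}
    assert all(p < 0.05 for p in p_values.values())
    assert min(p_values, key=p_values.get) == "C"
    assert rows["model"].p_value < 1e-4


def test_anova_partial_ss_matches_refit_oracle(fitted_model, design_table):
    """Extra SS for B equals SSE(model without B1, B2) - SSE(full)."""
    X = doe.build_design_matrix(design_table)
    y = design_table["coated_surface_pct"].to_numpy(float)
    keep = [j for j in range(12) if j not in (2, 3)]
    beta_r, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    sse_reduced = float(((y - X[:, keep] @ beta_r) ** 2).sum())
    rows = {r.term: r for r in doe.anova(fitted_model)}
    assert rows["B"].sum_sq == pytest.approx(sse_reduced - fitted_model.sse,
                                             rel=1e-10)


def test_anova_partial_ss_matches_quadratic_form(fitted_model):
    """Independent route: SS_g = b_g' [ (X'X)^-1 ]_gg^-1 b_g."""
    X, beta = fitted_model.X, fitted_model.beta
    xtx_inv = np.linalg.inv(X.T @ X)
    for term, cols in doe.TERM_GROUPS.items():
        cols = list(cols)
        bg = beta[cols]
        block = xtx_inv[np.ix_(cols, cols)]
        ss = float(bg @ np.linalg.solve(block, bg))
        row = {r.term: r for r in doe.anova(fitted_model)}[term]
        assert row.sum_sq == pytest.approx(ss, rel=1e-9)


def test_anova_zero_coefficient_term_in_noise_free_design(design_table):
    """A term absent from the generating model gets F ~ 0 (exact fit)."""
    from pelletcoat.synthetic import SimulationSpec, gen_doe_response

    coefs = {"intercept": 50.0, "A": 5.0, "C1": -20.0, "C2": 8.0}
    table = gen_doe_response(
        design_table.drop(columns="coated_surface_pct"),
        SimulationSpec(coefs, noise_sd=0.0),
    )
    rows = {r.term: r for r in doe.anova(doe.fit_model(table))}
    assert rows["B"].sum_sq == pytest.approx(0.0, abs=1e-10)
    assert rows["B"].p_value == pytest.approx(1.0)
    assert rows["C"].p_value == 0.0  # exact-fit sentinel


# --------------------------------------------------------------- R² suite

def test_r_squared_suite_published_values(fitted_model):
    r2, adj, pred, press = doe.r_squared_suite(fitted_model)
    assert r2 == pytest.approx(0.9914, abs=0.001)
    assert adj == pytest.approx(0.9795, abs=0.002)
    assert pred == pytest.approx(0.9484, abs=0.003)
    assert pred < adj < r2


def test_press_equals_explicit_leave_one_out(fitted_model, design_table):
    y = design_table["coated_surface_pct"].to_numpy(float)
    X = doe.build_design_matrix(design_table)
    press = 0.0
    for i in range(len(y)):
        keep = [j for j in range(len(y)) if j != i]
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        press += (y[i] - X[i] @ beta) ** 2
    _, _, _, press_hat = doe.r_squared_suite(fitted_model)
    assert press_hat == pytest.approx(press, rel=1e-9)


# ------------------------------------------------------- predict & optimise

def test_prediction_from_published_coefficients(reference_coefficients):
    model = doe.CodedModel.from_coefficients(reference_coefficients)
    run7 = doe.predict(model, ("Kollidon VA64", 5.0, "1:1"))
    assert run7 == pytest.approx(19.96, abs=1e-9)
    assert round(run7, 1) == 20.0
    best = doe.predict(model, ("Kollicoat Protect", 1.0, "3:1"))
    assert best == pytest.approx(96.90, abs=1e-9)


def test_prediction_zero_model():
    model = doe.CodedModel.from_coefficients({})
    assert doe.predict(model, ("Kollicoat Protect", 2.5, "2:1")) == 0.0


def test_optimize_selects_low_concentration_high_ratio(fitted_model):
    ranking = doe.optimize(fitted_model, threshold_pct=90.0)
    combos = {(r.polymer, r.concentration_pct, r.ratio)
              for r in ranking.itertuples()}
    assert ("Kollicoat Protect", 1.0, "3:1") in combos
    assert ("Kollicoat Protect", 1.0, "2:1") in combos
    assert (ranking["predicted_pct"] >= 90.0).all()


def test_optimize_cost_tiebreak_prefers_lower_ratio(fitted_model):
    with_tb = doe.optimize(fitted_model, threshold_pct=90.0, tie_break=True)
    assert with_tb.iloc[0]["ratio"] == "2:1"
    assert with_tb.iloc[0]["concentration_pct"] == 1.0
    without = doe.optimize(fitted_model, threshold_pct=90.0, tie_break=False)
    assert without.iloc[0]["ratio"] == "3:1"


def test_optimize_unreachable_threshold_returns_empty(fitted_model):
    assert doe.optimize(fitted_model, threshold_pct=101.0).empty


def test_optimize_no_tiebreak_equals_exhaustive_sort(fitted_model):
    ranking = doe.optimize(fitted_model, threshold_pct=0.0, tie_break=False)
    assert len(ranking) == 18
    preds = sorted(
        (doe.predict(fitted_model, lv) for lv in doe.full_factorial()),
        reverse=True,
    )
    assert np.allclose(ranking["predicted_pct"].to_numpy(), preds)


# --------------------------------------------------------------- table IO

def test_validate_design_table_rejects_bad_responses(design_table):
    bad = design_table.copy()
    bad.loc[0, "coated_surface_pct"] = 140.0
    with pytest.raises(ValueError, match="percentages"):
        doe.validate_design_table(bad)


def test_validate_design_table_rejects_duplicate_run_ids(design_table):
    bad = design_table.copy()
    bad.loc[1, "run_id"] = bad.loc[0, "run_id"]
    with pytest.raises(ValueError, match="duplicate"):
        doe.validate_design_table(bad)
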