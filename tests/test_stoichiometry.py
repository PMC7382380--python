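import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nuetrace as nt
from conftest import grid_tls_slope


@pytest.mark.parametrize(
    "pts, slope, intercept",
    [
        ([(0, 0), (1, 1), (2, 2)], 1.0, 0.0),
        ([(0, 0), (1, 2), (2, 1), (3, 3)], 1.0, 0.0),  # S_nn = S_cc = 5, S_nc = 4
        ([(0, 1), (2, 0), (4, -1)], -0.5, 1.0),
    ],
    ids=["collinear-positive", "symmetric-cross", "collinear-negative"],
)
def test_fit_orthogonal_known_lines(pts, slope, intercept):
    x, y = zip(*pts)
    f = nt.fit_orthogonal(x, y)
    assert f.slope == pytest.approx(slope, abs=1e-12)
    assert f.intercept == pytest.approx(intercept, abs=1e-12)
    # line passes through the centroid
    assert f.intercept == pytest.approx(f.centroid_c - f.slope * f.centroid_n, abs=1e-9)


def test_fit_orthogonal_degenerate_isotropic():
    with pytest.raises(nt.DegenerateFitError, match="major axis undefined"):
        nt.fit_orthogonal([0, 1, 0, 1], [0, 1, 1, 0])


def test_fit_orthogonal_too_few_points():
    with pytest.raises(nt.DegenerateFitError, match="at least 3"):
        nt.fit_orthogonal([0, 1], [0, 1])


def test_fit_orthogonal_horizontal_and_vertical():
    f = nt.fit_orthogonal([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
    assert f.slope == 0.0
    h = nt.dsc(1.0, 6.5, f)
    assert h.flagged and h.dsc == pytest.approx(1.5)
    fv = nt.fit_orthogonal([5.0, 5.0, 5.0, 5.0], [0, 1, 2, 3])
    assert fv.is_vertical
    v = nt.dsc(5.2, 1.0, fv)
    assert v.flagged
    assert v.dsc == pytest.approx(5.2 - fv.centroid_n)


def test_fit_matches_grid_oracle_random_sets():
    """TLS slope equals brute-force orthogonal-SSE minimisation over angles."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        m = rng.integers(4, 13)
        slope = rng.uniform(-5, 5)
        x = rng.uniform(0, 10, m)
        y = slope * x + rng.normal(0, 1.0, m)
        f = nt.fit_orthogonal(x, y)
        assert f.slope == pytest.approx(grid_tls_slope(x, y), abs=1e-3)


def test_axis_swap_covariance():
    """Fitting (C, N) instead of (N, C) maps the same line: slope' = 1/slope."""
    rng = np.random.default_rng(7)
    x = rng.uniform(2, 6, 40)
    y = -4.0 * x + 70.7 + rng.normal(0, 0.5, 40)
    f = nt.fit_orthogonal(x, y)
    g = nt.fit_orthogonal(y, x)
    assert g.slope == pytest.approx(1.0 / f.slope, rel=1e-9)
    # same line: the swapped intercept maps back consistently
    assert g.intercept == pytest.approx(-f.intercept / f.slope, rel=1e-6)


CONTROL_LINE = nt.StoichiometryFit(
    slope=-4.0, intercept=70.7, centroid_n=4.0, centroid_c=54.7,
    n_points=0, ss_orthogonal=0.0,
)


def test_dsc_worked_examples_control_line():
    """Against C = 70.7 − 4 N: (4.0, 56.0) → +0.3153, (4.0, 53.0) → −0.4123."""
    above = nt.dsc(4.0, 56.0, CONTROL_LINE)
    assert above.diff_c == pytest.approx(1.3)
    assert above.diff_n == pytest.approx(0.325)
    assert above.dsc == pytest.approx(1.3 / math.sqrt(17.0))
    assert above.dsc == pytest.approx(0.3153, abs=1e-4)
    below = nt.dsc(4.0, 53.0, CONTROL_LINE)
    assert below.dsc == pytest.approx(-1.7 / math.sqrt(17.0))
    assert below.dsc == pytest.approx(-0.4123, abs=1e-4)
    on_line = nt.dsc(4.0, 70.7 - 16.0, CONTROL_LINE)
    assert on_line.dsc == 0.0


@given(
    b=st.floats(-10.0, 10.0).filter(lambda v: abs(v) > 1e-3),
    a=st.floats(-100.0, 100.0),
    n0=st.floats(0.0, 10.0),
    c0=st.floats(0.0, 100.0),
)
def test_dsc_equals_signed_projection(b, a, n0, c0):
    """Altitude formula ≡ signed scalar projection onto the unit normal."""
    fit = nt.StoichiometryFit(b, a, 0.0, a, 0, 0.0)
    v = nt.dsc(n0, c0, fit)
    expected = nt.signed_distance(n0, c0, fit)
    assert v.dsc == pytest.approx(expected, abs=1e-9 * max(1.0, abs(expected)))
    if b < 0 and v.dsc != 0.0:
        assert math.copysign(1, v.diff_n) == math.copysign(1, v.diff_c)
        assert not v.flagged


def test_dsc_sign_disagreement_flagged_for_positive_slope():
    fit = nt.StoichiometryFit(2.0, 0.0, 0.0, 0.0, 0, 0.0)
    v = nt.dsc(1.0, 3.0, fit)  # above a positive line: diff_c > 0, diff_n < 0
    assert v.flagged
    assert v.dsc > 0  # sign taken from diff_c


def test_mean_signed_dsc_of_fitted_points_is_zero(default_sim):
    """The TLS line passes through the centroid along the major axis."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.uniform(2, 6, 30)
        y = -4.0 * x + 70.0 + rng.normal(0, 0.8, 30)
        res = nt.OrthogonalRegression(x, y).fit()
        vals = res.dsc()
        assert abs(vals["dsc"].mean()) < 1e-9 * max(1.0, np.abs(vals["dsc"]).max())
    ds, _ = default_sim
    seeds = ds.seeds()
    seeds = seeds[seeds["dw_mg"] >= 1.0]
    tab = nt.dsc_table(seeds, mode="per_experiment")
    for _, grp in tab.groupby(["experiment", "condition"]):
        assert abs(grp["dsc"].mean()) < 1e-9


def test_dsc_translation_invariance():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 5, 20)
    y = -3.0 * x + 60 + rng.normal(0, 1, 20)
    f1 = nt.fit_orthogonal(x, y)
    f2 = nt.fit_orthogonal(x + 2.5, y - 7.0)
    d1 = nt.dsc(x, y, f1)["dsc"]
    d2 = nt.dsc(x + 2.5, y - 7.0, f2)["dsc"]
    np.testing.assert_allclose(d1, d2, atol=1e-9)


def test_condition_shifts_table():
    fits = pd.DataFrame(
        {
            "experiment": ["1", "1", "2", "2", "3"],
            "condition": ["control", "lowN", "control", "lowN", "lowN"],
            "slope": [-4.0, -4.6, -4.2, -4.8, -5.0],
            "intercept": [70.0, 68.0, 71.0, 75.0, 60.0],
        }
    )
    with pytest.warns(UserWarning, match="no control"):
        per_exp, summary = nt.condition_shifts(fits)
    assert len(per_exp) == 2  # experiment 3 excluded
    row = summary.set_index("condition").loc["lowN"]
    assert row["delta_slope_mean"] == pytest.approx(-0.6)
    assert row["delta_intercept_mean"] == pytest.approx((-2.0 + 4.0) / 2)
    assert row["delta_intercept_sd"] == pytest.approx(math.sqrt(18.0))
    assert row["n_experiments"] == 2


def test_condition_shifts_identical_fits_zero_delta():
    fits = pd.DataFrame(
        {
            "experiment": ["1", "1"],
            "condition": ["control", "dark"],
            "slope": [-4.0, -4.0],
            "intercept": [70.7, 70.7],
        }
    )
    per_exp, _ = nt.condition_shifts(fits)
    assert per_exp["delta_slope"].iloc[0] == 0.0
    assert per_exp["delta_intercept"].iloc[0] == 0.0


def test_response_vectors_345_triangle():
    means = pd.DataFrame(
        {
            "genotype": ["g1", "g1"],
            "condition": ["control", "drought"],
            "n_pct": [4.0, 4.5],
            "c_pct": [54.7, 53.5],
        }
    )
    vectors, _ = nt.response_vectors(means)
    v = vectors.iloc[0]
    assert (v["delta_n"], v["delta_c"]) == pytest.approx((0.5, -1.2))
    assert v["length"] == pytest.approx(1.3)


def test_response_vectors_zero_vector_flagged():
    means = pd.DataFrame(
        {
            "genotype": ["g1", "g1"],
            "condition": ["control", "dark"],
            "n_pct": [4.0, 4.0],
            "c_pct": [54.7, 54.7],
        }
    )
    vectors, _ = nt.response_vectors(means)
    assert vectors.iloc[0]["zero_vector"]
    assert np.isnan(vectors.iloc[0]["angle_deg"])


def test_response_vectors_heterogeneity_labels():
    """Opposite ΔN% signs ⇒ heterogeneous; aligned vectors ⇒ homogeneous."""
    means = pd.DataFrame(
        {
            "genotype": ["g1", "g2", "g1", "g2", "g1", "g2"],
            "condition": ["control"] * 2 + ["lowN"] * 2 + ["dark"] * 2,
            "n_pct": [4.0, 4.1, 3.4, 3.5, 4.5, 3.5],
            "c_pct": [54.7, 54.5, 56.0, 55.9, 53.5, 55.5],
        }
    )
    _, homog = nt.response_vectors(means)
    h = homog.set_index("condition")
    assert not h.loc["lowN", "heterogeneous"]
    assert h.loc["dark", "heterogeneous"]


def test_response_vectors_missing_control_skipped():
    means = pd.DataFrame(
        {
            "genotype": ["g1", "g2"],
            "condition": ["control", "lowN"],
            "n_pct": [4.0, 3.4],
            "c_pct": [54.7, 56.0],
        }
    )
    with pytest.warns(UserWarning, match="no control mean"):
        vectors, _ = nt.response_vectors(means)
    assert vectors.empty


def test_results_summary_mentions_line():
    res = nt.OrthogonalRegression([0, 1, 2, 4], [1, -3, -7, -15]).fit()
    text = res.summary()
    assert "slope" in text and "intercept" in text
    assert res.nobs == 4
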