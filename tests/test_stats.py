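import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carpalign.observers import ObserverProfile, make_observer_pool, simulate_session
from carpalign.phantom import sample_cohort
from carpalign.stats import (
    ReliabilityCategory,
    bland_altman,
    classify_reliability,
    compare_variants,
    icc_2_1,
    inter_observer_icc,
    intra_observer_icc,
    paired_t_test,
    session_error_sd_for_mean_abs_diff,
    simulate_two_session_icc,
    spearman_correlation,
)
from carpalign.volume import BoneLabel


def anova_icc_oracle(m: np.ndarray) -> float:
    """Brute-force two-way ANOVA ICC(2,1): explicit sums of squares."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / m.size
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_perfect_agreement_and_example_matrix():
    assert icc_2_1([[1, 1], [2, 2], [3, 3]]).icc == pytest.approx(1.0)
    m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    res = icc_2_1(m)
    assert res.icc < 1.0
    assert res.icc == pytest.approx(anova_icc_oracle(m), abs=1e-12)
    assert res.recompute() == pytest.approx(res.icc, abs=1e-12)


def test_icc_matches_anova_oracle_on_random_matrices():
    rng = np.random.default_rng(17)
    for _ in range(100):
        m = rng.normal(0, 5, size=(5, 3)) + rng.normal(0, 3, size=(5, 1))
        assert icc_2_1(m).icc == pytest.approx(anova_icc_oracle(m), abs=1e-9)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(23)
    for _ in range(10):
        m = rng.normal(0, 4, size=(6, 3)) + rng.normal(0, 2, size=(6, 1))
        df = pd.DataFrame(
            {
                "t": np.repeat(np.arange(6), 3),
                "r": np.tile(np.arange(3), 6),
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
        ref_icc = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(m).icc == pytest.approx(ref_icc, abs=1e-9)


def test_icc_degenerate_matrix_rejected():
    with pytest.raises(ValueError, match="zero total variance"):
        icc_2_1(np.full((4, 3), 2.5))
    with pytest.raises(ValueError, match=">= 2"):
        icc_2_1(np.ones((1, 3)))


def test_icc_absolute_agreement_invariances():
    rng = np.random.default_rng(31)
    m = rng.normal(0, 5, size=(8, 3)) + rng.normal(0, 4, size=(8, 1))
    base = icc_2_1(m).icc
    assert icc_2_1(m + 7.5).icc == pytest.approx(base, abs=1e-9)
    shifted = m.copy()
    shifted[:, 0] += 50.0  # systematic rater offset hurts absolute agreement
    assert icc_2_1(shifted).icc < base


def test_icc_converges_to_variance_component_ratio():
    rng = np.random.default_rng(5)
    n = 10_000
    sb, sr, se = 11.0, 0.0, 4.0
    truth = rng.normal(0, sb, size=(n, 1))
    rater = rng.normal(0, sr, size=(1, 3))
    ratings = truth + rater + rng.normal(0, se, size=(n, 3))
    expected = sb**2 / (sb**2 + sr**2 + se**2)
    assert abs(icc_2_1(ratings).icc - expected) < 0.01


@pytest.mark.parametrize(
    "value, expected",
    [
        (0.4, ReliabilityCategory.POOR),
        (0.5, ReliabilityCategory.MODERATE),
        (0.6, ReliabilityCategory.MODERATE),
        (0.75, ReliabilityCategory.MODERATE),
        (0.755, ReliabilityCategory.GOOD),
        (0.76, ReliabilityCategory.GOOD),
        (0.8, ReliabilityCategory.GOOD),
        (0.9, ReliabilityCategory.GOOD),
        (0.95, ReliabilityCategory.EXCELLENT),
    ],
)
def test_reliability_categories(value, expected):
    assert classify_reliability(value) is expected


def test_session_error_calibration_closed_form():
    s = session_error_sd_for_mean_abs_diff(5.0)
    assert s == pytest.approx(5.0 * np.sqrt(np.pi) / 2.0)
    # verify the calibration empirically
    rng = np.random.default_rng(3)
    d = rng.normal(0, s, 200_000) - rng.normal(0, s, 200_000)
    assert np.abs(d).mean() == pytest.approx(5.0, abs=0.05)


def test_five_degree_session_difference_gives_icc_086():
    """Between-wrist SD 11 deg + 5 deg mean absolute session difference
    lands the test-retest ICC at 0.86."""
    res = simulate_two_session_icc(10_000, 11.0, 5.0, seed=42)
    assert round(res.icc, 2) == pytest.approx(0.86, abs=0.01)


def test_inter_observer_known_variance_components():
    """sigma_b^2=121, sigma_r^2=0, sigma_e^2=16 -> ICC ~ 121/137."""
    rng = np.random.default_rng(7)
    n = 8000
    ratings = rng.normal(0, 11.0, size=(n, 1)) + rng.normal(0, 4.0, size=(n, 3))
    assert abs(icc_2_1(ratings).icc - 121.0 / 137.0) < 0.01


def test_intra_observer_perfect_with_zero_noise():
    zero = {k: {b: 0.0 for b in BoneLabel} for k in ("summation", "stripped")}
    cohort = sample_cohort(6, seed=2)
    pool = make_observer_pool(2, 2, seed=1, noise_sd=zero)
    from carpalign.drr import assign_rotations
    from carpalign.observers import MeasurementTable

    log = assign_rotations([ph.wrist_id for ph in cohort], seed=3)
    table = MeasurementTable.concat(
        [
            simulate_session(cohort, None, pool, s, seed=4, rotation_log=log)
            for s in (1, 2)
        ]
    )
    out = intra_observer_icc(table)
    assert np.allclose(out["icc_mean"], 1.0)
    assert np.allclose(out["icc_sd"], 0.0)


def test_intra_observer_requires_both_sessions():
    cohort = sample_cohort(4, seed=2)
    pool = make_observer_pool(1, 1, seed=1)
    from carpalign.observers import MeasurementTable

    table = simulate_session(cohort, None, pool, 1, seed=4)
    with pytest.raises(ValueError, match="missing a session"):
        intra_observer_icc(table)


def test_inter_observer_groups_reported_separately():
    cohort = sample_cohort(6, seed=3)
    pool = make_observer_pool(3, 3, seed=2)
    table = simulate_session(cohort, None, pool, 1, seed=6)
    out = inter_observer_icc(table)
    assert set(out["instructed"].unique()) == {True, False}
    # uninstructed group is pooled per bone across preferred variants
    uninstructed = out[~out["instructed"] & (out["bone"] != "radius")]
    assert set(uninstructed["variant"]) == {"preferred"}


def test_bland_altman_oracle_and_outlier_flag():
    res = bland_altman([(10.0, 12.0), (20.0, 18.0), (30.0, 33.0)])
    diffs = np.array([-2.0, 2.0, -3.0])
    assert res.mean_diff == pytest.approx(diffs.mean())
    assert res.sd_diff == pytest.approx(diffs.std(ddof=1))
    assert res.limits[0] == pytest.approx(diffs.mean() - 1.96 * diffs.std(ddof=1))
    assert res.outlier_indices == ()
    flagged = bland_altman([(10.0, 12.0), (20.0, 18.0), (30.0, 33.0), (50.0, 25.0)])
    assert flagged.outlier_indices == (3,)
    same = bland_altman([(5.0, 5.0)] * 3)
    assert same.mean_diff == 0.0 and same.sd_diff == 0.0 and not same.outlier_indices
    with pytest.raises(ValueError, match="at least 3"):
        bland_altman([(1.0, 2.0), (3.0, 4.0)])


def test_bland_altman_coverage_is_95_percent():
    rng = np.random.default_rng(11)
    n = 20_000
    a = rng.normal(50, 10, n)
    b = a + rng.normal(1.0, 3.0, n)
    res = bland_altman(np.column_stack([a, b]), outlier_threshold=1e9)
    diff = a - b
    inside = np.mean((diff > res.limits[0]) & (diff < res.limits[1]))
    assert inside == pytest.approx(0.95, abs=0.01)


def test_paired_t_contract():
    assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 30)
    b = a + 1.0 + rng.normal(0, 0.5, 30)
    t, p = paired_t_test(a, b)
    d = a - b
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    from scipy import stats as sps

    p_oracle = 2 * sps.t.sf(abs(t_oracle), len(d) - 1)
    assert t == pytest.approx(t_oracle, abs=1e-6)
    assert p == pytest.approx(p_oracle, abs=1e-6)
    with pytest.raises(ValueError):
        paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="zero-variance"):
        paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def test_spearman_contract():
    assert spearman_correlation([1, 2, 3, 4], [10, 20, 25, 90])[0] == pytest.approx(1.0)
    assert spearman_correlation([1, 2, 3, 4], [9, 7, 3, 1])[0] == pytest.approx(-1.0)
    rng = np.random.default_rng(6)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    rho, _ = spearman_correlation(x, y)
    # brute-force rank formula with average ranks
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-9)
    with pytest.raises(ValueError, match="constant"):
        spearman_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_compare_variants_recovers_constructed_offset():
    """A cohort whose capitate tangent is built 11 degrees dorsal of its
    axial axis shows exactly that offset, and it is significant."""
    cohort = sample_cohort(30, seed=12)
    rows = []
    for ph in cohort:
        for variant in ("axial", "tangential"):
            rows.append(
                {
                    "wrist_id": ph.wrist_id,
                    "bone": "capitate",
                    "variant": variant,
                    "angle_deg": ph.truth_angle(BoneLabel.CAPITATE, variant),
                }
            )
    out = compare_variants(pd.DataFrame(rows))
    row = out.iloc[0]
    assert row["mean_offset"] == pytest.approx(-11.0, abs=1e-9)
    assert row["significant"]


def test_compare_variants_identical_is_not_significant():
    df = pd.DataFrame(
        {
            "wrist_id": ["w0", "w0", "w1", "w1", "w2", "w2"],
            "bone": "lunate",
            "variant": ["axial", "tangential"] * 3,
            "angle_deg": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
        }
    )
    out = compare_variants(df)
    assert out.iloc[0]["p"] == pytest.approx(1.0)
    assert not out.iloc[0]["significant"]


@given(st.floats(-0.99, 0.99))
@settings(derandomize=True, max_examples=40)
def test_category_boundaries_are_total(v):
    assert classify_reliability(v) in ReliabilityCategory
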