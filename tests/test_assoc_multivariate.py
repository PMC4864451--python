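"""Canonical-correlation association, loadings, and top-k re-testing."""

import numpy as np
import pandas as pd
import pytest

from _oracles import r2_ftest_pvalue
from conftest import make_gm
from shapeqt.assoc_multivariate import (
    MultivariateResult,
    cca_snp_test,
    retest_subset,
    run_multivariate_screen,
    top_k_modes,
)
from shapeqt.assoc_univariate import fit_linear
from shapeqt.shape_model import build_ssm, gpa_align, mode_scores

MODE_SDS = 0.012 * 0.78 ** (np.arange(12) / 2.0)


def _scores(rng, n=929, effect_mode=None, beta=0.0, g=None):
    y = rng.normal(size=(n, 12)) * MODE_SDS
    if effect_mode is not None:
        y[:, effect_mode - 1] += beta * g
    return y


def test_matches_regression_r2_oracle():
    rng = np.random.default_rng(0)
    for i in range(30):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(size=(n, 12))
        res = cca_snp_test(g, y)
        assert res.p_value == pytest.approx(r2_ftest_pvalue(g, y), abs=1e-10)
        assert 0.0 <= res.canonical_correlation <= 1.0
        assert res.wilks_lambda == pytest.approx(
            1 - res.canonical_correlation**2, abs=1e-12
        )


def test_matches_oracle_with_covariates():
    rng = np.random.default_rng(1)
    n = 300
    c = rng.normal(size=(n, 2))
    g = rng.binomial(2, 0.4, n).astype(float) + 0.0
    y = rng.normal(size=(n, 6)) + c @ rng.normal(size=(2, 6)) * 0.2
    res = cca_snp_test(g, y, covariates=c)
    assert res.p_value == pytest.approx(r2_ftest_pvalue(g, y, c), abs=1e-10)
    assert res.df == (6, n - 2 - 1 - 6)


def test_single_mode_equals_univariate_squared_t():
    rng = np.random.default_rng(2)
    n = 250
    g = rng.binomial(2, 0.3, n).astype(float)
    y = (0.004 * g + rng.normal(0, 0.01, n))[:, None]
    res = cca_snp_test(g, y)
    uni = fit_linear(y[:, 0], g)
    assert res.f_stat == pytest.approx(uni.t**2, rel=1e-10)
    assert res.p_value == pytest.approx(uni.p, abs=1e-12)


def test_loadings_square_sum_to_one_on_pca_scores(small_cohort):
    """On training-set PCA scores (empirically uncorrelated columns) the
    structure correlations coincide with normalised weights."""
    aligned, _ = gpa_align(small_cohort.landmarks)
    model = build_ssm(aligned)
    scores = mode_scores(model, aligned)
    g = small_cohort.genotypes.calls[:, 0].astype(float)
    res = cca_snp_test(g, scores)
    assert np.sum(res.loadings**2) == pytest.approx(1.0, abs=1e-6)


def test_effect_mode_gets_largest_loading():
    rng = np.random.default_rng(3)
    hits = 0
    reps = 200
    for _ in range(reps):
        g = rng.binomial(2, 0.48, 929).astype(float)
        y = _scores(rng, effect_mode=5, beta=-0.0029, g=g)
        res = cca_snp_test(g, y)
        hits += int(res.modes[int(np.argmax(np.abs(res.loadings)))] == 5)
    assert hits / reps > 0.95


def test_top_k_selection_from_printed_loading_rows():
    """The published absolute-loading rows must select the published
    3-mode subsets."""
    def mk(name, loadings):
        return MultivariateResult(
            name, tuple(range(1, 13)), 929, 0.1, 0.99, 1.0, (12, 900), 0.02,
            np.array(loadings),
        )

    rs5009270 = mk(
        "rs5009270",
        [0.12, 0.22, 0.37, 0.46, 0.01, 0.03, 0.01, 0.29, 0.64, 0.26, 0.14, 0.02],
    )
    assert top_k_modes(rs5009270, 3) == [3, 4, 9]
    rs4836732 = mk(
        "rs4836732",
        [0.06, 0.04, 0.01, 0.34, 0.66, 0.02, 0.04, 0.39, 0.12, 0.26, 0.20, 0.42],
    )
    assert top_k_modes(rs4836732, 3) == [5, 8, 12]
    # ties break toward the lower mode index; k = p returns every mode
    tied = mk("t", [0.5, 0.5, 0.5, 0.1] + [0.0] * 8)
    assert top_k_modes(tied, 2) == [1, 2]
    assert top_k_modes(rs5009270, 12) == list(range(1, 13))
    with pytest.raises(ValueError):
        top_k_modes(rs5009270, 13)


def test_retest_full_subset_is_identity():
    rng = np.random.default_rng(4)
    g = rng.binomial(2, 0.3, 300).astype(float)
    y = pd.DataFrame(
        rng.normal(size=(300, 5)), columns=[f"mode{k}" for k in range(1, 6)]
    )
    full = cca_snp_test(g, y)
    again = retest_subset(g, y, [1, 2, 3, 4, 5])
    assert again.p_value == pytest.approx(full.p_value, abs=1e-12)
    sub = retest_subset(g, y, [2, 5])
    assert sub.modes == (2, 5)
    assert sub.df[0] == 2
    # any subset explains at most the full model's variance
    assert sub.canonical_correlation**2 <= full.canonical_correlation**2 + 1e-12
    with pytest.raises(KeyError):
        retest_subset(g, y, [9])


def test_reduced_model_gains_power_for_sparse_effect():
    rng = np.random.default_rng(5)
    wins = 0
    reps = 100
    for _ in range(reps):
        g = rng.binomial(2, 0.48, 929).astype(float)
        y = _scores(rng, effect_mode=5, beta=-0.0022, g=g)
        full = cca_snp_test(g, y)
        sub = retest_subset(g, y, top_k_modes(full, 3))
        wins += int(sub.p_value <= full.p_value)
    assert wins / reps > 0.8


def test_selection_inflation_under_null_is_reported():
    """Re-testing a data-selected subset on the same data inflates type-I
    error; quantify the inflation (it must exceed the nominal rate)."""
    rng = np.random.default_rng(6)
    reps = 150
    rej = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = rng.normal(size=(300, 12))
        full = cca_snp_test(g, y)
        sub = retest_subset(g, y, top_k_modes(full, 3))
        rej += int(sub.p_value <= 0.05)
    rate = rej / reps
    assert rate > 0.05  # anti-conservative, as expected
    assert rate < 0.8


def test_dominant_coding_rejected_without_override():
    rng = np.random.default_rng(7)
    g = (rng.binomial(2, 0.3, 200) > 0).astype(float)
    y = rng.normal(size=(200, 3))
    with pytest.raises(ValueError, match="additive"):
        cca_snp_test(g, y, coding="dominant")
    res = cca_snp_test(g, y, coding="dominant", allow_any_coding=True)
    assert res.coding == "dominant"


def test_errors_name_the_problem():
    rng = np.random.default_rng(8)
    g = rng.binomial(2, 0.3, 100).astype(float)
    y = rng.normal(size=(100, 3))
    y[:, 2] = y[:, 1]  # collinear
    with pytest.raises(ValueError, match="collinear"):
        cca_snp_test(g, y)
    with pytest.raises(ValueError, match="constant"):
        cca_snp_test(np.ones(100), rng.normal(size=(100, 3)))
    with pytest.raises(ValueError, match="too small"):
        cca_snp_test(g[:10], rng.normal(size=(10, 9)))


def test_screen_null_familywise_control():
    """41 null SNPs at the 0.05/41 Bonferroni threshold: the full-model
    screen should almost always make zero discoveries."""
    rng = np.random.default_rng(9)
    reps = 120
    clean = 0
    n = 400
    for _ in range(reps):
        y = pd.DataFrame(
            rng.normal(size=(n, 12)) * MODE_SDS,
            columns=[f"mode{k}" for k in range(1, 13)],
        )
        gm = make_gm(
            {f"rs{j}": rng.binomial(2, 0.3, n).astype(np.int8) for j in range(41)}
        )
        full, _, _ = run_multivariate_screen(gm, y, k=3)
        thr = full.attrs["bonferroni_threshold"]
        clean += int((full["p"] > thr).all())
    se = np.sqrt(0.05 * 0.95 / reps)
    assert clean / reps >= 0.95 - 3 * se


def test_screen_ranks_injected_effects_first():
    rng = np.random.default_rng(10)
    reps = 40
    top3_ok = 0
    n = 929
    for _ in range(reps):
        gm = make_gm(
            {f"rs{j}": rng.binomial(2, 0.35, n).astype(np.int8) for j in range(12)}
        )
        y = rng.normal(size=(n, 12)) * MODE_SDS
        for snp_j, mode in ((0, 3), (1, 5), (2, 9)):
            y[:, mode - 1] += -0.004 * gm.calls[:, snp_j]
        scores = pd.DataFrame(y, columns=[f"mode{k}" for k in range(1, 13)])
        full, topk, loads = run_multivariate_screen(gm, scores, k=3)
        top3_ok += int(set(full["snp"][:3]) == {"rs0", "rs1", "rs2"})
    assert top3_ok / reps > 0.9


def test_screen_deterministic(small_cohort):
    aligned, _ = gpa_align(small_cohort.landmarks)
    model = build_ssm(aligned)
    scores = mode_scores(model, aligned)
    a = run_multivariate_screen(small_cohort.genotypes, scores, k=3)
    b = run_multivariate_screen(small_cohort.genotypes, scores, k=3)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
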