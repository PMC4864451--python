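"""Linear-model SNP association and the max(T) permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exhaustive_perm_pvalue, mc_power_additive, simple_ols
from conftest import make_gm
from shapeqt.assoc_univariate import (
    NotEstimableError,
    PermutationPlan,
    UnivariateResult,
    bonferroni_threshold,
    fit_linear,
    genotype_mean_scores,
    maxT_permutation,
    power_additive,
)
from shapeqt.genotypes import code_genotype, read_ped_map, write_ped_map


def test_fit_matches_closed_form_simple_regression():
    """Without covariates or missing data the fit must agree with the
    textbook closed form to numerical precision."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = 50
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.02 * g + rng.normal(0, 0.1, n)
        res = fit_linear(y, g)
        beta, se, t, p = simple_ols(y, g)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)


def test_exact_fit_underflows():
    g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1, 2, 1])
    y = 0.5 * g
    res = fit_linear(y, g)
    assert res.beta == pytest.approx(0.5, abs=1e-12)
    assert res.p < 1e-30


def test_missing_data_complete_case():
    rng = np.random.default_rng(1)
    n = 100
    g = rng.binomial(2, 0.4, n).astype(float)
    y = rng.normal(size=n)
    g_miss = g.copy()
    g_miss[:10] = np.nan
    res = fit_linear(y, g_miss)
    ref = fit_linear(y[10:], g[10:])
    assert res.n == 90
    assert res.t == pytest.approx(ref.t, abs=1e-12)


def test_not_estimable_errors():
    rng = np.random.default_rng(2)
    y = rng.normal(size=30)
    with pytest.raises(NotEstimableError, match="constant"):
        fit_linear(y, np.ones(30))
    # all-heterozygote SNP under dominant coding is constant
    dom = code_genotype(np.ones(30, dtype=np.int8), "dominant")
    with pytest.raises(NotEstimableError, match="constant"):
        fit_linear(y, dom)
    g = rng.binomial(2, 0.3, 30).astype(float)
    c = np.column_stack([g, g])  # collinear with genotype
    with pytest.raises(NotEstimableError, match="rank-deficient"):
        fit_linear(y, g, c)


def test_null_t_statistics_are_small():
    rng = np.random.default_rng(3)
    n = 10_000
    exceed = 0
    for _ in range(200):
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(size=n)
        _, _, t, _ = simple_ols(y, g)
        exceed += abs(t) >= 4
    assert exceed <= 1


def test_covariate_adjustment_changes_estimate():
    rng = np.random.default_rng(4)
    n = 500
    g = rng.binomial(2, 0.3, n).astype(float)
    age = rng.normal(60, 10, n)
    y = 0.01 * g + 0.005 * (age - 60) + rng.normal(0, 0.05, n)
    raw = fit_linear(y, g)
    adj = fit_linear(y, g, age[:, None])
    assert adj.se < raw.se  # age explains residual variance


# --- max(T) permutations ------------------------------------------------------

def test_sampled_emp1_matches_exhaustive_rank_p():
    """n=7 toy data: 100,000 sampled permutations vs all 7! relabelings."""
    rng = np.random.default_rng(5)
    y = rng.normal(size=7)
    calls = np.array([0, 1, 2, 0, 1, 2, 1], dtype=np.int8)
    gm = make_gm({"rs_toy": calls})
    plan = PermutationPlan(n_perm=100_000, seed=1)
    tab = maxT_permutation(y[:, None], gm, plan=plan)
    p_ex = exhaustive_perm_pvalue(y, calls.astype(float))
    assert abs(tab["emp1"][0] - p_ex) < 0.01
    # family of one: familywise == pointwise exactly
    assert tab["emp2"][0] == tab["emp1"][0]


def test_emp_conventions_and_family_ordering():
    rng = np.random.default_rng(6)
    n = 120
    y = rng.normal(size=(n, 5))
    gm = make_gm({"rs1": rng.binomial(2, 0.4, n).astype(np.int8)})
    tab = maxT_permutation(y, gm, plan=PermutationPlan(n_perm=500, seed=0))
    assert ((tab["emp1"] > 0) & (tab["emp1"] <= 1)).all()
    assert (tab["emp1"] <= tab["emp2"] + 1e-12).all()
    # observed t/p agree with the direct fit
    for _, row in tab.iterrows():
        ref = fit_linear(y[:, row["mode"] - 1], gm.calls[:, 0].astype(float))
        assert row["t"] == pytest.approx(ref.t, abs=1e-10)
        assert row["p"] == pytest.approx(ref.p, abs=1e-10)
        assert row["beta"] == pytest.approx(ref.beta, abs=1e-12)


def test_freedman_lane_reduces_to_plain_shuffle_without_covariates():
    rng = np.random.default_rng(7)
    n = 60
    y = rng.normal(size=(n, 3))
    gm = make_gm({"rs1": rng.binomial(2, 0.3, n).astype(np.int8)})
    a = maxT_permutation(
        y, gm, plan=PermutationPlan(n_perm=300, seed=9, covariate_scheme="freedman_lane")
    )
    b = maxT_permutation(
        y, gm, plan=PermutationPlan(n_perm=300, seed=9, covariate_scheme="raw_label_swap")
    )
    assert np.allclose(a["emp1"], b["emp1"])
    assert np.allclose(a["t"], b["t"])


def test_permutation_schemes_with_covariates_agree_on_null():
    rng = np.random.default_rng(8)
    n = 150
    c = rng.normal(size=(n, 2))
    y = rng.normal(size=(n, 4)) + c @ np.array([[0.3] * 4, [0.2] * 4])
    gm = make_gm({"rs1": rng.binomial(2, 0.4, n).astype(np.int8)})
    fl = maxT_permutation(
        y, gm, covariates=c,
        plan=PermutationPlan(n_perm=2000, seed=1, covariate_scheme="freedman_lane"),
    )
    raw = maxT_permutation(
        y, gm, covariates=c,
        plan=PermutationPlan(n_perm=2000, seed=1, covariate_scheme="raw_label_swap"),
    )
    assert np.allclose(fl["t"], raw["t"], atol=1e-10)  # same observed stats
    assert np.abs(fl["emp1"] - raw["emp1"]).max() < 0.06


def test_emp1_superuniform_under_null():
    rng = np.random.default_rng(9)
    n_rej = 0
    reps = 150
    for i in range(reps):
        y = rng.normal(size=(100, 1))
        gm = make_gm({"rs1": rng.binomial(2, 0.3, 100).astype(np.int8)})
        tab = maxT_permutation(y, gm, plan=PermutationPlan(n_perm=499, seed=i))
        n_rej += int(tab["emp1"][0] <= 0.1)
    se = np.sqrt(0.1 * 0.9 / reps)
    assert n_rej / reps <= 0.1 + 3 * se + 1 / 500


def test_shared_family_corrects_over_all_snps():
    rng = np.random.default_rng(10)
    n = 200
    y = rng.normal(size=(n, 3))
    gm = make_gm(
        {f"rs{j}": rng.binomial(2, 0.3, n).astype(np.int8) for j in range(4)}
    )
    plan = PermutationPlan(n_perm=500, seed=3, family="all_snps_and_modes")
    tab = maxT_permutation(y, gm, plan=plan)
    assert len(tab) == 12
    assert (tab["emp1"] <= tab["emp2"] + 1e-12).all()
    per_snp = maxT_permutation(
        y, gm, plan=PermutationPlan(n_perm=500, seed=3)
    )
    # the larger family is at least as stringent on average
    assert tab["emp2"].mean() >= per_snp["emp2"].mean() - 0.05


def test_dominant_invariance_to_allele_labels(tmp_path, small_cohort):
    """Relabelled PED alleles must produce identical dominant-model t's,
    since the minor allele is re-derived from the data."""
    gm = small_cohort.genotypes
    write_ped_map(gm, tmp_path / "a.ped", tmp_path / "a.map")
    txt = (tmp_path / "a.ped").read_text().replace("A", "T").replace("G", "C")
    (tmp_path / "b.ped").write_text(txt)
    gm2 = read_ped_map(tmp_path / "b.ped", tmp_path / "a.map")
    y = small_cohort.true_scores[:, 2]
    snp = gm.snp_ids[0]
    t1 = fit_linear(y, code_genotype(gm.column(snp), "dominant")).t
    t2 = fit_linear(y, code_genotype(gm2.column(snp), "dominant")).t
    assert t1 == pytest.approx(t2, abs=1e-12)


# --- per-genotype means and dominance heuristic -------------------------------

def test_genotype_mean_scores_flags_dominance():
    rng = np.random.default_rng(11)
    n, beta, sd = 929, 0.005, 0.0073
    flagged_dom = 0
    flagged_add = 0
    reps = 200
    for _ in range(reps):
        g = rng.binomial(2, 0.4, n)
        y_dom = beta * (g > 0) + rng.normal(0, sd, n)
        y_add = beta / 2 * g + rng.normal(0, sd, n)
        flagged_dom += genotype_mean_scores(y_dom, g)["dominant_flag"]
        flagged_add += genotype_mean_scores(y_add, g)["dominant_flag"]
    assert flagged_dom / reps > 0.9
    assert flagged_add / reps < 0.1


def test_genotype_mean_scores_edge_cases():
    out = genotype_mean_scores(np.ones(6), np.array([0, 0, 1, 1, 2, 2]))
    assert out["means"] == {0: 1.0, 1: 1.0, 2: 1.0}
    out = genotype_mean_scores(np.arange(4.0), np.array([0, 0, 1, 1]))
    assert out["means"][2] is None and out["dominant_flag"] is False


# --- Bonferroni and analytic power --------------------------------------------

def test_bonferroni_thresholds():
    assert bonferroni_threshold(492) == pytest.approx(0.05 / 492)
    assert bonferroni_threshold(492) < 1.02e-4  # reported as "< 0.0001"
    assert bonferroni_threshold(41) == pytest.approx(0.05 / 41)
    assert 1.2e-3 < bonferroni_threshold(41) < 1.25e-3  # "< 0.001"
    assert bonferroni_threshold(1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_threshold(0)


def test_power_null_equals_alpha_and_monotonicity():
    assert power_additive(929, 0.25, 0.0, 1.0) == pytest.approx(0.05, abs=1e-12)
    base = power_additive(500, 0.2, 0.002, 0.01)
    assert power_additive(1000, 0.2, 0.002, 0.01) > base
    assert power_additive(500, 0.2, 0.003, 0.01) > base
    assert power_additive(500, 0.4, 0.002, 0.01) > base
    with pytest.raises(ValueError):
        power_additive(500, 0.7, 0.002, 0.01)


def test_power_matches_monte_carlo():
    rng = np.random.default_rng(12)
    n, maf, beta, sd = 400, 0.25, 0.002, 0.01
    analytic = power_additive(n, maf, beta, sd)
    mc = mc_power_additive(n, maf, beta, sd, 0.05, 5000, rng)
    assert abs(analytic - mc) < 0.02
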