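"""Univariate SNP–mode association with max(T) permutation correction.

Each retained shape-mode score is regressed on a coded genotype
(additive 0/1/2 or dominant 0/1 minor-allele copies) plus optional
covariates.  Asymptotic p-values come from the usual t-test on the
genotype slope.  Empirical significance uses max(T) permutations:
for every permutation the |t| statistic is recomputed for each test in
the family, giving a pointwise empirical p (EMP1) and a familywise
empirical p corrected over the family via the per-permutation maximum
(EMP2).  Both use the (r + 1) / (N + 1) convention, which can never be
exactly zero.

Two permutation schemes are available when covariates are present:

* ``freedman_lane`` (default): permute the residuals of the scores on
  the covariates, add back the covariate fit, and re-fit the full
  model.  This keeps the covariate structure intact under the null.
* ``raw_label_swap``: permute the raw score vectors across subjects,
  the behaviour of a plain phenotype-shuffling ``--mperm`` run.

Without covariates the two schemes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix, code_genotype


class NotEstimableError(ValueError):
    """Raised when a design matrix is rank deficient (e.g. constant genotype)."""


@dataclass(frozen=True)
class UnivariateResult:
    snp_id: str
    mode: int  # 1-based
    coding: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    emp1: float | None = None
    emp2: float | None = None
    covariates: str = "none"


@dataclass(frozen=True)
class PermutationPlan:
    """How to run max(T) permutations.

    ``family`` controls what EMP2 corrects over: ``modes_within_snp``
    runs an independent permutation batch per SNP with the family being
    that SNP's modes (the per-SNP ``--mperm`` behaviour);
    ``all_snps_and_modes`` shares permutations across every (SNP, mode)
    test and corrects over all of them.
    """

    n_perm: int = 100_000
    seed: int = 0
    family: str = "modes_within_snp"
    covariate_scheme: str = "freedman_lane"

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.family not in ("modes_within_snp", "all_snps_and_modes"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.covariate_scheme not in ("freedman_lane", "raw_label_swap"):
            raise ValueError(f"unknown covariate scheme {self.covariate_scheme!r}")


def _as_matrix(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[1] == 0:
        return None
    return c


def fit_linear(
    scores: np.ndarray,
    genotype: np.ndarray,
    covariates=None,
    snp_id: str = "",
    mode: int = 0,
    coding: str = "additive",
    covariate_label: str = "none",
) -> UnivariateResult:
    """OLS of a mode score on [intercept, coded genotype, covariates].

    Complete-case: subjects with a missing genotype, score or covariate
    are dropped for this test only.  The genotype slope, its SE, the
    t statistic (n - k df) and the two-sided asymptotic p are reported.
    """
    y = np.asarray(scores, dtype=float)
    g = np.asarray(genotype, dtype=float)
    c = _as_matrix(covariates)
    ok = np.isfinite(y) & np.isfinite(g)
    if c is not None:
        ok &= np.all(np.isfinite(c), axis=1)
    y, g = y[ok], g[ok]
    c = c[ok] if c is not None else None
    n = y.shape[0]
    p_cov = 0 if c is None else c.shape[1]
    if n < p_cov + 3:
        raise ValueError(f"{snp_id}/mode{mode}: too few complete cases (n={n})")
    if np.ptp(g) == 0:
        raise NotEstimableError(
            f"{snp_id}/mode{mode}: genotype constant after complete-case filtering"
        )
    x = np.column_stack([np.ones(n), g] + ([] if c is None else [c]))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise NotEstimableError(
            f"{snp_id}/mode{mode}: rank-deficient design (collinear covariates)"
        )
    fit = sm.OLS(y, x).fit()
    return UnivariateResult(
        snp_id=snp_id,
        mode=mode,
        coding=coding,
        n=n,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        covariates=covariate_label,
    )


# ---------------------------------------------------------------------------
# max(T) permutation engine
# ---------------------------------------------------------------------------

def _maxt_stats(
    y: np.ndarray,
    g: np.ndarray,
    c: np.ndarray | None,
    n_perm: int,
    rng: np.random.Generator,
    scheme: str,
    block: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed |t| per column of ``y`` plus per-permutation exceedance
    counts (pointwise) and max-statistic exceedance counts (familywise).

    Works in the partialled-out parameterisation: with Z = [1, C],
    g_t = M_Z g, and QX an orthonormal basis of [Z, g], the slope and
    residual sum of squares of the full fit on permuted data reduce to
    inner products of permuted basis vectors with fixed residual
    columns, so each permutation costs one small matrix product.
    """
    n, k = y.shape
    if c is None:
        # Without covariates the two schemes coincide and the statistic
        # depends on the permuted genotype only, so shuffle g directly.
        return _maxt_stats_nocov(y, g, n_perm, rng, block)
    z = np.column_stack([np.ones(n), c])
    qz, _ = np.linalg.qr(z)
    g_t = g - qz @ (qz.T @ g)
    ng2 = float(g_t @ g_t)
    if ng2 < 1e-12:
        raise NotEstimableError("genotype constant (or collinear with covariates)")
    x = np.column_stack([z, g])
    qx, _ = np.linalg.qr(x)
    df = n - x.shape[1]
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    if scheme == "freedman_lane":
        r = y - qz @ (qz.T @ y)
    else:  # raw_label_swap
        r = y.copy()
    r_norm2 = np.sum(r * r, axis=0)

    w = np.column_stack([g_t, qx])  # gathered jointly per permutation

    def t_stats(wp: np.ndarray) -> np.ndarray:
        """wp: (..., n, w) gathered basis; returns (..., k) t statistics."""
        u = np.swapaxes(wp, -1, -2) @ r  # (..., w, k)
        a = u[..., 0, :]
        rss = r_norm2 - np.sum(u[..., 1:, :] ** 2, axis=-2)
        rss = np.maximum(rss, 1e-300)
        beta = a / ng2
        se = np.sqrt(rss / df / ng2)
        return beta / se

    t_obs = t_stats(w)
    abs_obs = np.abs(t_obs)

    exceed_point = np.zeros(k, dtype=np.int64)
    exceed_max = np.zeros(k, dtype=np.int64)
    done = 0
    idx_base = np.arange(n)
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = rng.permuted(np.tile(idx_base, (b, 1)), axis=1)
        wp = w[perm]  # (b, n, w)
        t_perm = np.abs(t_stats(wp))  # (b, k)
        exceed_point += np.sum(t_perm >= abs_obs[None, :], axis=0)
        tmax = t_perm.max(axis=1)
        exceed_max += np.sum(tmax[:, None] >= abs_obs[None, :], axis=0)
        done += b
    emp1 = (exceed_point + 1.0) / (n_perm + 1.0)
    emp2 = (exceed_max + 1.0) / (n_perm + 1.0)
    return t_obs, emp1, emp2


def _maxt_stats_nocov(
    y: np.ndarray,
    g: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    block: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariate-free max(T): t for simple regression of each score column
    on the genotype, under direct shuffles of the genotype vector."""
    n, k = y.shape
    g_t = g - g.mean()
    ng2 = float(g_t @ g_t)
    if ng2 < 1e-12:
        raise NotEstimableError("genotype constant")
    df = n - 2
    r = y - y.mean(axis=0)
    r_norm2 = np.sum(r * r, axis=0)

    def t_stats(gp: np.ndarray) -> np.ndarray:
        a = gp @ r  # (..., k)
        rss = np.maximum(r_norm2 - a * a / ng2, 1e-300)
        return (a / ng2) / np.sqrt(rss / df / ng2)

    t_obs = t_stats(g_t)
    abs_obs = np.abs(t_obs)
    exceed_point = np.zeros(k, dtype=np.int64)
    exceed_max = np.zeros(k, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        gp = rng.permuted(np.tile(g_t, (b, 1)), axis=1)
        t_perm = np.abs(t_stats(gp))
        exceed_point += np.sum(t_perm >= abs_obs[None, :], axis=0)
        exceed_max += np.sum(
            t_perm.max(axis=1)[:, None] >= abs_obs[None, :], axis=0
        )
        done += b
    emp1 = (exceed_point + 1.0) / (n_perm + 1.0)
    emp2 = (exceed_max + 1.0) / (n_perm + 1.0)
    return t_obs, emp1, emp2


def maxT_permutation(
    scores: pd.DataFrame | np.ndarray,
    gm: GenotypeMatrix,
    snps: Sequence[str] | None = None,
    coding: str = "additive",
    covariates=None,
    plan: PermutationPlan | None = None,
    covariate_label: str = "none",
) -> pd.DataFrame:
    """max(T) permutation association of every (SNP, mode) pair.

    Returns a tidy frame with one row per test: snp, mode, coding, n,
    beta, se, t, p (asymptotic), emp1, emp2.  For the
    ``modes_within_snp`` family each SNP gets its own independent
    permutation stream (derived deterministically from the plan seed);
    for ``all_snps_and_modes`` one shared stream covers every test, as
    max(T) across SNPs requires, and subjects must be complete for all
    requested SNPs.
    """
    plan = plan or PermutationPlan()
    if isinstance(scores, pd.DataFrame):
        y_all = scores.to_numpy(dtype=float)
        mode_ids = [int(str(cname).replace("mode", "")) for cname in scores.columns]
    else:
        y_all = np.asarray(scores, dtype=float)
        mode_ids = list(range(1, y_all.shape[1] + 1))
    snps = list(snps) if snps is not None else gm.snp_ids
    missing_snps = [s for s in snps if s not in gm.snp_ids]
    if missing_snps:
        raise KeyError(f"SNPs not in genotype matrix: {missing_snps}")
    c_all = _as_matrix(covariates)

    rows = []
    if plan.family == "modes_within_snp":
        streams = np.random.SeedSequence(plan.seed).spawn(len(snps))
        for snp, ss in zip(snps, streams):
            g_all = code_genotype(gm.column(snp), coding)
            ok = np.isfinite(g_all) & np.all(np.isfinite(y_all), axis=1)
            if c_all is not None:
                ok &= np.all(np.isfinite(c_all), axis=1)
            y, g = y_all[ok], g_all[ok]
            c = c_all[ok] if c_all is not None else None
            t_obs, emp1, emp2 = _maxt_stats(
                y, g, c, plan.n_perm, np.random.default_rng(ss), plan.covariate_scheme
            )
            rows += _result_rows(
                snp, mode_ids, coding, int(ok.sum()), y, g, c, t_obs, emp1, emp2,
                covariate_label,
            )
    else:
        g_mat = np.column_stack(
            [code_genotype(gm.column(s), coding) for s in snps]
        )
        ok = np.all(np.isfinite(g_mat), axis=1) & np.all(np.isfinite(y_all), axis=1)
        if c_all is not None:
            ok &= np.all(np.isfinite(c_all), axis=1)
        y = y_all[ok]
        c = c_all[ok] if c_all is not None else None
        rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
        n = y.shape[0]
        # one shared permutation stream: draw blocks once, evaluate all SNPs
        per_snp = [(snp, g_mat[ok, j]) for j, snp in enumerate(snps)]
        stats_ctx = [
            _SharedCtx(y, g, c, plan.covariate_scheme) for _, g in per_snp
        ]
        t_obs_all = np.column_stack([ctx.t_obs for ctx in stats_ctx])
        abs_obs_all = np.abs(t_obs_all)
        k = y.shape[1]
        exceed_point = np.zeros((k, len(snps)), dtype=np.int64)
        exceed_max = np.zeros((k, len(snps)), dtype=np.int64)
        done = 0
        idx_base = np.arange(n)
        while done < plan.n_perm:
            b = min(256, plan.n_perm - done)
            perm = rng.permuted(np.tile(idx_base, (b, 1)), axis=1)
            t_blocks = [np.abs(ctx.t_for(perm)) for ctx in stats_ctx]  # (b,k) each
            t_all = np.stack(t_blocks, axis=2)  # (b, k, n_snps)
            exceed_point += np.sum(t_all >= abs_obs_all[None], axis=0)
            tmax = t_all.reshape(b, -1).max(axis=1)
            exceed_max += np.sum(
                tmax[:, None, None] >= abs_obs_all[None], axis=0
            )
            done += b
        emp1_all = (exceed_point + 1.0) / (plan.n_perm + 1.0)
        emp2_all = (exceed_max + 1.0) / (plan.n_perm + 1.0)
        for j, (snp, g) in enumerate(per_snp):
            rows += _result_rows(
                snp, mode_ids, coding, n, y, g, c,
                t_obs_all[:, j], emp1_all[:, j], emp2_all[:, j], covariate_label,
            )
    return pd.DataFrame([r.__dict__ for r in rows])


class _SharedCtx:
    """Per-SNP statistic evaluator reused across shared permutation blocks."""

    def __init__(self, y, g, c, scheme):
        n = y.shape[0]
        z = np.ones((n, 1)) if c is None else np.column_stack([np.ones(n), c])
        qz, _ = np.linalg.qr(z)
        g_t = g - qz @ (qz.T @ g)
        self.ng2 = float(g_t @ g_t)
        if self.ng2 < 1e-12:
            raise NotEstimableError("genotype constant within shared family")
        x = np.column_stack([z, g])
        qx, _ = np.linalg.qr(x)
        self.df = n - x.shape[1]
        self.r = y - qz @ (qz.T @ y) if scheme == "freedman_lane" else y.copy()
        self.r_norm2 = np.sum(self.r * self.r, axis=0)
        self.w = np.column_stack([g_t, qx])
        self.t_obs = self._t(self.w)

    def _t(self, wp):
        u = np.swapaxes(wp, -1, -2) @ self.r
        a = u[..., 0, :]
        rss = np.maximum(self.r_norm2 - np.sum(u[..., 1:, :] ** 2, axis=-2), 1e-300)
        return (a / self.ng2) / np.sqrt(rss / self.df / self.ng2)

    def t_for(self, perm):
        return self._t(self.w[perm])


def _result_rows(
    snp, mode_ids, coding, n, y, g, c, t_obs, emp1, emp2, covariate_label
):
    """Recompute beta/se/p from the observed t (closed form) for reporting."""
    n_sub = y.shape[0]
    z = np.ones((n_sub, 1)) if c is None else np.column_stack([np.ones(n_sub), c])
    qz, _ = np.linalg.qr(z)
    g_t = g - qz @ (qz.T @ g)
    ng2 = float(g_t @ g_t)
    r = y - qz @ (qz.T @ y)
    df = n_sub - z.shape[1] - 1
    rows = []
    for j, mode in enumerate(mode_ids):
        beta = float(g_t @ r[:, j]) / ng2
        t = float(t_obs[j])
        se = abs(beta / t) if t != 0 else float("nan")
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append(
            UnivariateResult(
                snp_id=snp, mode=mode, coding=coding, n=n, beta=beta, se=se,
                t=t, p=p, emp1=float(emp1[j]), emp2=float(emp2[j]),
                covariates=covariate_label,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Small analytic helpers
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Familywise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def genotype_mean_scores(
    scores: np.ndarray, calls: np.ndarray, dominance_ratio: float = 0.25
) -> dict:
    """Mean score per genotype class {0, 1, 2 minor-allele copies}.

    Also returns a minor-allele-dominance heuristic flag: raised when
    the heterozygote and minor-homozygote means nearly coincide relative
    to the heterozygote/major-homozygote gap
    (|mean2 - mean1| < ratio * |mean1 - mean0|), suggesting a
    dominant-model re-fit.  Classes with no subjects are reported as
    None and leave the flag unset.
    """
    scores = np.asarray(scores, dtype=float)
    calls = np.asarray(calls)
    means: dict[int, float | None] = {}
    for cls in (0, 1, 2):
        sel = calls == cls
        means[cls] = float(scores[sel].mean()) if sel.any() else None
    flag = False
    if all(means[c] is not None for c in (0, 1, 2)):
        gap01 = abs(means[1] - means[0])
        gap12 = abs(means[2] - means[1])
        flag = gap12 < dominance_ratio * gap01
    return {"means": means, "dominant_flag": flag}


def power_additive(
    n: int, maf: float, beta: float, residual_sd: float, alpha: float = 0.05
) -> float:
    """Analytic power of the two-sided additive slope test.

    Under Hardy–Weinberg the coded genotype has variance 2*maf*(1-maf),
    so the noncentrality of the 1-df F test is
    lambda = n * beta^2 * 2 * maf * (1 - maf) / residual_sd^2.
    """
    if n < 3 or residual_sd <= 0 or not (0.0 < maf <= 0.5):
        raise ValueError("need n >= 3, residual_sd > 0 and maf in (0, 0.5]")
    lam = n * beta**2 * 2.0 * maf * (1.0 - maf) / residual_sd**2
    fcrit = stats.f.isf(alpha, 1, n - 2)
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncf.sf(fcrit, 1, n - 2, lam))
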