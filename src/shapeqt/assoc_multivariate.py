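"""Multivariate (canonical-correlation) SNP association against shape modes.

One coded genotype against the matrix of retained mode scores.  With a
single genotype variable the first (and only) canonical correlation r1
satisfies r1^2 = R^2 of the multiple regression of the genotype on the
modes, Wilks' lambda is 1 - r1^2, and the standard F approximation

    F = ((1 - lambda) / lambda) * ((n - c - 1 - p) / p)

on (p, n - c - 1 - p) degrees of freedom is exact, where p is the
number of modes and c the number of covariates.  Covariates are handled
by residualising both the genotype and every mode on [1, C]
(Frisch–Waugh), with the error degrees of freedom reduced by c.

Per-mode loadings are the correlations of each (residualised) mode with
the canonical phenotype variate.  On PCA scores of the training set,
whose columns are empirically uncorrelated, these coincide up to sign
with the normalised canonical weights, and their squares sum to 1.
Loadings are reported as absolute values; signs are kept internally.

The screen is additive-coding only by default, because only the
additive model is standard for this multivariate test; dominant coding
is accepted via an explicit ``allow_any_coding=True`` override and
flagged in the output.

Re-testing a data-driven top-k mode subset on the same cohort inflates
type-I error under the null; this package reproduces the published
procedure and quantifies (rather than corrects) that inflation in its
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, code_genotype


@dataclass(frozen=True)
class MultivariateResult:
    snp_id: str
    modes: tuple[int, ...]  # 1-based indices of modes used
    n: int
    canonical_correlation: float
    wilks_lambda: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    loadings: np.ndarray  # signed, same order as ``modes``
    coding: str = "additive"
    covariates: str = "none"

    @property
    def abs_loadings(self) -> np.ndarray:
        return np.abs(self.loadings)


def _residualize(a: np.ndarray, qz: np.ndarray) -> np.ndarray:
    return a - qz @ (qz.T @ a)


def cca_snp_test(
    genotype: np.ndarray,
    scores: pd.DataFrame | np.ndarray,
    covariates=None,
    snp_id: str = "",
    coding: str = "additive",
    allow_any_coding: bool = False,
    covariate_label: str = "none",
    mode_ids: Sequence[int] | None = None,
) -> MultivariateResult:
    """Canonical-correlation association of one SNP with all mode scores."""
    if coding != "additive" and not allow_any_coding:
        raise ValueError(
            f"multivariate test supports additive coding only (got {coding!r}); "
            "pass allow_any_coding=True to override"
        )
    if isinstance(scores, pd.DataFrame):
        y = scores.to_numpy(dtype=float)
        ids = tuple(int(str(cname).replace("mode", "")) for cname in scores.columns)
    else:
        y = np.asarray(scores, dtype=float)
        ids = tuple(mode_ids) if mode_ids else tuple(range(1, y.shape[1] + 1))
    g = np.asarray(genotype, dtype=float)
    c = None
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[1] == 0:
            c = None

    ok = np.isfinite(g) & np.all(np.isfinite(y), axis=1)
    if c is not None:
        ok &= np.all(np.isfinite(c), axis=1)
    y, g = y[ok], g[ok]
    c = c[ok] if c is not None else None
    n, p = y.shape
    n_cov = 0 if c is None else c.shape[1]
    if n <= p + n_cov + 2:
        raise ValueError(f"{snp_id}: n={n} too small for p={p} modes, c={n_cov}")
    if np.ptp(g) == 0:
        raise ValueError(f"{snp_id}: genotype constant after complete-case filtering")
    sds = y.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [ids[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"{snp_id}: constant score columns for modes {bad}")

    z = np.ones((n, 1)) if c is None else np.column_stack([np.ones(n), c])
    qz, _ = np.linalg.qr(z)
    g_t = _residualize(g, qz)
    y_t = _residualize(y, qz)

    gram = y_t.T @ y_t
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(y_t, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"{snp_id}: singular mode matrix (modes {ids[i]} and {ids[j]} collinear)"
        )
    b = np.linalg.solve(gram, y_t.T @ g_t)
    yhat = y_t @ b  # canonical phenotype variate
    ss_tot = float(g_t @ g_t)
    ss_fit = float(yhat @ g_t)
    r2 = max(0.0, min(1.0, ss_fit / ss_tot))
    lam = 1.0 - r2
    df1 = p
    df2 = n - n_cov - 1 - p
    f_stat = (r2 / lam) * (df2 / df1) if lam > 0 else float("inf")
    p_value = float(stats.f.sf(f_stat, df1, df2))

    yhat_sd = yhat.std(ddof=1)
    if yhat_sd > 0:
        yc = y_t - y_t.mean(axis=0)
        hc = yhat - yhat.mean()
        loadings = (yc.T @ hc) / (
            (n - 1) * y_t.std(axis=0, ddof=1) * yhat_sd
        )
    else:
        loadings = np.zeros(p)
    return MultivariateResult(
        snp_id=snp_id,
        modes=ids,
        n=n,
        canonical_correlation=float(np.sqrt(r2)),
        wilks_lambda=float(lam),
        f_stat=float(f_stat),
        df=(df1, df2),
        p_value=p_value,
        loadings=np.asarray(loadings),
        coding=coding,
        covariates=covariate_label,
    )


def top_k_modes(result: MultivariateResult, k: int = 3) -> list[int]:
    """Indices (1-based, ascending) of the k largest absolute loadings.

    Ties are broken toward the lower mode index.
    """
    p = len(result.modes)
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} modes in the result")
    order = sorted(
        range(p), key=lambda j: (-abs(result.loadings[j]), result.modes[j])
    )
    return sorted(result.modes[j] for j in order[:k])


def retest_subset(
    genotype: np.ndarray,
    scores: pd.DataFrame | np.ndarray,
    subset: Sequence[int],
    covariates=None,
    snp_id: str = "",
    coding: str = "additive",
    allow_any_coding: bool = False,
    covariate_label: str = "none",
) -> MultivariateResult:
    """Re-run the multivariate test restricted to a subset of modes (1-based)."""
    subset = list(subset)
    if isinstance(scores, pd.DataFrame):
        cols = [f"mode{m}" for m in subset]
        missing = [c for c in cols if c not in scores.columns]
        if missing:
            raise KeyError(f"modes not present in score table: {missing}")
        sub = scores[cols]
        return cca_snp_test(
            genotype, sub, covariates, snp_id, coding, allow_any_coding,
            covariate_label,
        )
    y = np.asarray(scores, dtype=float)
    idx = [m - 1 for m in subset]
    return cca_snp_test(
        genotype, y[:, idx], covariates, snp_id, coding, allow_any_coding,
        covariate_label, mode_ids=subset,
    )


def run_multivariate_screen(
    gm: GenotypeMatrix,
    scores: pd.DataFrame,
    covariates=None,
    snps: Sequence[str] | None = None,
    k: int = 3,
    alpha: float = 0.05,
    covariate_label: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full-model CCA screen, per-SNP loadings, and top-k re-test.

    Returns (full_table, topk_table, loadings_table).  The tables carry
    a Bonferroni threshold of ``alpha / n_snps`` in the attrs dict.
    """
    snps = list(snps) if snps is not None else gm.snp_ids
    full_rows, topk_rows, loading_rows = [], [], []
    for snp in snps:
        g = code_genotype(gm.column(snp), "additive")
        res = cca_snp_test(g, scores, covariates, snp_id=snp,
                           covariate_label=covariate_label)
        meta = gm.snps.set_index("snp").loc[snp]
        maf = float(gm.maf[gm._index(snp)])
        full_rows.append(
            {
                "snp": snp,
                "chrom": meta["chrom"],
                "p": res.p_value,
                "canonical_r": res.canonical_correlation,
                "wilks_lambda": res.wilks_lambda,
                "n": res.n,
                "minor_allele": meta["minor_allele"],
                "maf": maf,
                "covariates": covariate_label,
            }
        )
        loading_rows.append(
            {"snp": snp}
            | {f"mode{m}": abs(v) for m, v in zip(res.modes, res.loadings)}
        )
        subset = top_k_modes(res, k=k)
        sub = retest_subset(g, scores, subset, covariates, snp_id=snp,
                            covariate_label=covariate_label)
        topk_rows.append(
            {
                "snp": snp,
                "chrom": meta["chrom"],
                "p": sub.p_value,
                "modes": ", ".join(str(m) for m in subset),
                "n": sub.n,
                "minor_allele": meta["minor_allele"],
                "maf": maf,
                "covariates": covariate_label,
            }
        )
    full = pd.DataFrame(full_rows).sort_values("p", kind="stable").reset_index(drop=True)
    topk = pd.DataFrame(topk_rows).sort_values("p", kind="stable").reset_index(drop=True)
    loadings = pd.DataFrame(loading_rows)
    thr = alpha / len(snps)
    full.attrs["bonferroni_threshold"] = thr
    topk.attrs["bonferroni_threshold"] = thr
    return full, topk, loadings
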