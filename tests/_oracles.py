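"""Independent oracles used by the test suite.

These are deliberately naive implementations (closed forms, exhaustive
enumeration, direct simulation) kept separate from the package code
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg test p-value (sum of probabilities of
    heterozygote counts no more likely than the observed one, conditional
    on allele counts)."""
    n = n_het + n_hom_minor + n_hom_major
    n_rare = 2 * n_hom_minor + n_het
    if n_rare > n:  # make "rare" the actual minor allele
        n_rare = 2 * n - n_rare
    probs = {}
    # heterozygote count must share parity with the rare-allele count
    start = n_rare % 2
    for het in range(start, n_rare + 1, 2):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        if hom_c < 0:
            continue
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(hom_c + 1)
            + het * math.log(2.0)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        probs[het] = math.exp(logp)
    obs_het = n_het if (2 * n_hom_minor + n_het) <= n else n_het
    p_obs = probs.get(obs_het, 0.0)
    return min(1.0, sum(p for p in probs.values() if p <= p_obs + 1e-12))


def simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple regression: (slope, se, t, two-sided p)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    s2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta, se, t, p


def r2_ftest_pvalue(g: np.ndarray, y: np.ndarray, c: np.ndarray | None = None):
    """Multiple-regression R² F-test p of genotype on phenotype columns,
    with covariates regressed out of both sides first (lstsq throughout)."""
    g = np.asarray(g, float)
    y = np.asarray(y, float)
    n = len(g)
    n_cov = 0
    if c is not None:
        z = np.column_stack([np.ones(n), c])
        n_cov = c.shape[1]
        g = g - z @ np.linalg.lstsq(z, g, rcond=None)[0]
        y = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    p = y.shape[1]
    x = np.column_stack([np.ones(n), y])
    beta = np.linalg.lstsq(x, g, rcond=None)[0]
    resid = g - x @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((g - g.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    df2 = n - n_cov - 1 - p
    f = (r2 / p) / ((1.0 - r2) / df2)
    return float(stats.f.sf(f, p, df2))


def exhaustive_perm_pvalue(y: np.ndarray, g: np.ndarray) -> float:
    """Exhaustive relabeling p for the simple-regression |t|: fraction of
    all n! genotype orderings (identity included) with |t*| >= |t_obs|."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)

    def abs_t(gp: np.ndarray) -> float:
        return abs(simple_ols(y, gp)[2])

    t_obs = abs_t(g)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs_t(g[list(perm)]) >= t_obs - 1e-12:
            count += 1
    return count / total


def sample_two_locus_genotypes(
    n: int, p_a: float, p_b: float, d_prime: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unphased genotypes at two loci from haplotypes with a target D'."""
    if d_prime >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d = d_prime * dmax
    h = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    assert np.all(h >= -1e-12)
    h = np.clip(h, 0, None)
    h /= h.sum()
    haps = rng.choice(4, size=(n, 2), p=h)
    # haplotype 0/1 carry allele A; 0/2 carry allele B
    ca = np.sum(haps <= 1, axis=1).astype(np.int8)
    cb = np.sum((haps == 0) | (haps == 2), axis=1).astype(np.int8)
    return ca, cb


def mc_power_additive(
    n: int,
    maf: float,
    beta: float,
    sd: float,
    alpha: float,
    n_sim: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo power of the two-sided additive slope test (vectorised)."""
    g = rng.binomial(2, maf, size=(n_sim, n)).astype(float)
    y = beta * g + rng.normal(0.0, sd, size=(n_sim, n))
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.sum(gc * gc, axis=1)
    sxy = np.sum(gc * yc, axis=1)
    syy = np.sum(yc * yc, axis=1)
    ok = sxx > 0
    b = sxy[ok] / sxx[ok]
    rss = syy[ok] - b * sxy[ok]
    se = np.sqrt(rss / (n - 2) / sxx[ok])
    t = b / se
    crit = stats.t.isf(alpha / 2, n - 2)
    return float(np.mean(np.abs(t) > crit))
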