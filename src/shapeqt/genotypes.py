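"""Genotype ingestion, QC, coding and LD utilities.

Text PED/MAP is the native interchange format.  Calls are stored as
counts of the dataset-level minor allele in {0, 1, 2}, with -1 for
missing; the minor allele is determined from observed allele
frequencies (ties broken toward the lexicographically smaller allele
label).  Missing genotypes are handled complete-case per test: a
subject is dropped only for the SNPs where its call is missing.

File dialects
-------------
PED:   ``FID IID PAT MAT SEX PHENO a1 a2 a1 a2 ...`` e.g.
       ``F1 S0001 0 0 2 -9 A G A A``
MAP:   ``chrom snp genetic_dist pos`` e.g. ``9 rs4836732 0 119266089``
.gen:  Oxford genotype probabilities, one SNP per row:
       ``chrom snp pos A G 0.95 0.03 0.02 ...`` (one (AA, AB, BB) triple
       per subject, alleles as labelled in columns 4-5)
.raw:  ``FID IID PAT MAT SEX PHENOTYPE rs123_A ...`` with 0/1/2/NA
       allele-count codes (one column per SNP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects × SNPs minor-allele counts with allele labels and MAF."""

    fids: list[str]
    iids: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos, minor_allele, major_allele
    calls: np.ndarray  # (n, m) int8, counts of minor allele, -1 missing
    maf: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        if not np.all(np.isin(calls, [MISSING, 0, 1, 2])):
            raise ValueError("calls must be in {0, 1, 2, missing}")
        if np.any((self.maf < 0) | (self.maf > 0.5 + 1e-12)):
            raise ValueError("maf must lie in [0, 0.5]")
        object.__setattr__(self, "calls", calls)

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp"])

    def column(self, snp: str) -> np.ndarray:
        idx = self._index(snp)
        return self.calls[:, idx]

    def _index(self, snp: str) -> int:
        ids = self.snp_ids
        try:
            return ids.index(snp)
        except ValueError:
            raise KeyError(f"SNP {snp!r} not in genotype matrix") from None

    def subset_subjects(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row subset. MAF and minor-allele labels are kept dataset-level
        (not recomputed), matching the single-MAF-per-SNP reporting style."""
        mask = np.asarray(mask, bool)
        return replace(
            self,
            fids=[f for f, m in zip(self.fids, mask) if m],
            iids=[i for i, m in zip(self.iids, mask) if m],
            calls=self.calls[mask],
        )


@dataclass(frozen=True)
class GenotypeProbabilities:
    """Per-subject per-SNP (p_AA, p_AB, p_BB) triples (AA = allele1 hom)."""

    fids: list[str]
    iids: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos, allele1, allele2
    probs: np.ndarray  # (n, m, 3)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("probs must be (n_subjects, n_snps, 3)")
        if np.any(p < -1e-12):
            raise ValueError("genotype probabilities must be nonnegative")
        if np.any(p.sum(axis=2) > 1.0 + 1e-6):
            raise ValueError("genotype probability triples must sum to at most 1")
        object.__setattr__(self, "probs", p)


def _minor_major(
    count1: int, count2: int, allele1: str, allele2: str
) -> tuple[str, str]:
    """Minor allele from observed counts; ties go to the lexicographically
    smaller label."""
    if count1 < count2 or (count1 == count2 and allele1 < allele2):
        return allele1, allele2
    return allele2, allele1


def _compute_maf(calls: np.ndarray) -> np.ndarray:
    ok = calls >= 0
    denom = 2.0 * ok.sum(axis=0)
    num = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(denom > 0, num / denom, 0.0)
    return maf


def genotype_matrix_from_counts(
    fids: Sequence[str],
    iids: Sequence[str],
    snps: pd.DataFrame,
    counts: np.ndarray,
    allele1: str | Sequence[str] = "A",
    allele2: str | Sequence[str] = "B",
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from allele1-count calls, flipping each SNP so
    calls count the observed minor allele."""
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    a1 = [allele1] * m if isinstance(allele1, str) else list(allele1)
    a2 = [allele2] * m if isinstance(allele2, str) else list(allele2)
    minor = []
    major = []
    calls = counts.copy()
    for j in range(m):
        col = counts[:, j]
        ok = col >= 0
        c1 = int(np.sum(col[ok]))
        c2 = int(2 * ok.sum() - c1)
        mn, mj = _minor_major(c1, c2, a1[j], a2[j])
        if mn == a2[j]:  # calls currently count allele1 -> flip
            calls[ok, j] = 2 - col[ok]
        minor.append(mn)
        major.append(mj)
    snps = snps.copy().reset_index(drop=True)
    snps["minor_allele"] = minor
    snps["major_allele"] = major
    return GenotypeMatrix(
        fids=list(fids),
        iids=list(iids),
        snps=snps,
        calls=calls,
        maf=_compute_maf(calls),
    )


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read standard whitespace-delimited PED + 4-column MAP files."""
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str, "snp": str},
    )
    m = len(map_df)
    fids, iids = [], []
    allele_rows = []
    with Path(ped_path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields "
                    f"({m} SNPs), got {len(parts)}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(fids), m, 2)

    counts = np.zeros((len(fids), m), dtype=np.int8)
    a1_labels, a2_labels = [], []
    for j in range(m):
        snp = map_df.loc[j, "snp"]
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(f"SNP {snp}: more than 2 alleles observed: {observed}")
        if len(observed) == 0:
            observed = ["A"]  # all-missing SNP: placeholder labels
        a1 = observed[0]
        a2 = observed[1] if len(observed) > 1 else observed[0]
        missing = np.any(col == "0", axis=1)
        counts[:, j] = np.sum(col == a1, axis=1).astype(np.int8)
        counts[missing, j] = MISSING
        a1_labels.append(a1)
        a2_labels.append(a2)

    snps = map_df[["snp", "chrom", "pos"]].copy()
    return genotype_matrix_from_counts(
        fids, iids, snps, counts, allele1=a1_labels, allele2=a2_labels
    )


def write_ped_map(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    with Path(map_path).open("w") as fh:
        for _, row in gm.snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")
    minor = list(gm.snps["minor_allele"])
    major = list(gm.snps["major_allele"])
    with Path(ped_path).open("w") as fh:
        for i in range(gm.n_subjects):
            fields = [gm.fids[i], gm.iids[i], "0", "0", "0", "-9"]
            for j in range(gm.n_snps):
                c = gm.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [major[j], major[j]]
                elif c == 1:
                    fields += [minor[j], major[j]]
                else:
                    fields += [minor[j], minor[j]]
            fh.write(" ".join(fields) + "\n")


def read_gen(
    gen_path: str | Path, sample_ids: Sequence[str]
) -> GenotypeProbabilities:
    """Read Oxford-style .gen probability rows (one SNP per line)."""
    snp_rows = []
    prob_cols = []
    n = len(sample_ids)
    with Path(gen_path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + 3 * n:
                raise ValueError(
                    f".gen line {lineno}: expected {5 + 3 * n} fields, got {len(parts)}"
                )
            snp_rows.append(parts[:5])
            prob_cols.append(np.array(parts[5:], dtype=float).reshape(n, 3))
    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "snp", "pos", "allele1", "allele2"]
    )
    snps["pos"] = snps["pos"].astype(int)
    snps = snps[["snp", "chrom", "pos", "allele1", "allele2"]]
    probs = np.stack(prob_cols, axis=1) if prob_cols else np.zeros((n, 0, 3))
    ids = list(sample_ids)
    return GenotypeProbabilities(fids=ids, iids=ids, snps=snps, probs=probs)


def read_raw(raw_path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a .raw-style coded file; returns (subject table, calls, snp ids)."""
    df = pd.read_csv(raw_path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    calls = df[snp_cols].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    snp_ids = [c.rsplit("_", 1)[0] for c in snp_cols]
    return df[[c for c in meta_cols if c in df.columns]], calls, snp_ids


# ---------------------------------------------------------------------------
# Hard-calling and QC
# ---------------------------------------------------------------------------

def hard_call(
    probs: GenotypeProbabilities, threshold: float = 0.9
) -> GenotypeMatrix:
    """Best-guess genotypes from probability triples.

    A genotype is called as the most probable class when that
    probability is at least ``threshold``; otherwise it is missing.
    """
    if not (1.0 / 3.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (1/3, 1]")
    p = probs.probs
    best = np.argmax(p, axis=2)
    pmax = np.max(p, axis=2)
    counts = np.where(pmax >= threshold, best, MISSING).astype(np.int8)
    # counts currently count allele2 copies (AA=0 ... BB=2) -> allele1 counts
    ok = counts >= 0
    a1_counts = counts.copy()
    a1_counts[ok] = 2 - counts[ok]
    snps = probs.snps[["snp", "chrom", "pos"]].copy()
    return genotype_matrix_from_counts(
        probs.fids,
        probs.iids,
        snps,
        a1_counts,
        allele1=list(probs.snps["allele1"]),
        allele2=list(probs.snps["allele2"]),
    )


def maf_filter(gm: GenotypeMatrix, floor: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs with MAF <= floor (strictly greater is kept)."""
    all_missing = np.all(gm.calls == MISSING, axis=0)
    keep = (gm.maf > floor) & ~all_missing
    dropped = [s for s, k in zip(gm.snp_ids, keep) if not k]
    if dropped:
        logger.warning("maf_filter dropped %d SNPs: %s", len(dropped), dropped)
    return replace(
        gm,
        snps=gm.snps.loc[keep].reset_index(drop=True),
        calls=gm.calls[:, keep],
        maf=gm.maf[keep],
    )


def code_genotype(calls: np.ndarray, model: str = "additive") -> np.ndarray:
    """Numeric coding of minor-allele counts; missing becomes NaN.

    additive: 0/1/2 copies; dominant: 0 for no copies, 1 for >= 1 copy.
    """
    calls = np.asarray(calls)
    out = calls.astype(float)
    out[calls == MISSING] = np.nan
    if model == "additive":
        return out
    if model == "dominant":
        return np.where(np.isnan(out), np.nan, (out > 0).astype(float))
    raise ValueError(f"unknown genetic model {model!r}")


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _em_haplotype_freqs(
    ca: np.ndarray, cb: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> np.ndarray:
    """EM haplotype frequencies (AB, Ab, aB, ab) from unphased genotype pairs,
    where A/B denote the minor alleles counted by ``ca``/``cb``.

    Initialised at linkage equilibrium; converged when the observed-data
    log-likelihood changes by less than ``tol``.
    """
    # 3x3 genotype table
    table = np.zeros((3, 3))
    for ga in range(3):
        for gb in range(3):
            table[ga, gb] = np.sum((ca == ga) & (cb == gb))
    n = table.sum()
    p_a = (2 * table[2].sum() + table[1].sum()) / (2 * n)
    p_b = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
    # haplotype order: AB, Ab, aB, ab ("a"/"b" = major alleles)
    h = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    h = np.clip(h, 1e-12, None)
    h /= h.sum()

    def loglik(h: np.ndarray) -> float:
        ll = 0.0
        for ga in range(3):
            for gb in range(3):
                cnt = table[ga, gb]
                if cnt == 0:
                    continue
                if ga == 1 and gb == 1:
                    prob = 2 * h[0] * h[3] + 2 * h[1] * h[2]
                else:
                    prob = _unambiguous_prob(ga, gb, h)
                ll += cnt * np.log(max(prob, 1e-300))
        return ll

    prev = loglik(h)
    for _ in range(max_iter):
        # expected haplotype counts
        counts = np.zeros(4)
        for ga in range(3):
            for gb in range(3):
                cnt = table[ga, gb]
                if cnt == 0:
                    continue
                if ga == 1 and gb == 1:
                    w = h[0] * h[3] / (h[0] * h[3] + h[1] * h[2])
                    counts[0] += cnt * w
                    counts[3] += cnt * w
                    counts[1] += cnt * (1 - w)
                    counts[2] += cnt * (1 - w)
                else:
                    hap1, hap2 = _phase(ga, gb)
                    counts[hap1] += cnt
                    counts[hap2] += cnt
        h = counts / counts.sum()
        h = np.clip(h, 1e-300, None)
        cur = loglik(h)
        if abs(cur - prev) < tol:
            break
        prev = cur
    return h


def _phase(ga: int, gb: int) -> tuple[int, int]:
    """Haplotype pair for an unambiguous two-locus genotype (not both het)."""

    def haps(ga: int, gb: int) -> list[int]:
        a_alleles = [1] * ga + [0] * (2 - ga)  # 1 = minor at locus A
        b_alleles = [1] * gb + [0] * (2 - gb)
        idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
        return [idx[(a_alleles[i], b_alleles[i])] for i in range(2)]

    h = haps(ga, gb)
    return h[0], h[1]


def _unambiguous_prob(ga: int, gb: int, h: np.ndarray) -> float:
    hap1, hap2 = _phase(ga, gb)
    if hap1 == hap2:
        return h[hap1] * h[hap2]
    return 2 * h[hap1] * h[hap2]


def ld_pair(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> tuple[float, float]:
    """(r², D′) between two SNPs, from EM haplotype frequency estimates."""
    ca = gm.column(snp_a)
    cb = gm.column(snp_b)
    ok = (ca >= 0) & (cb >= 0)
    if ok.sum() < 20:
        raise ValueError(
            f"need at least 20 complete genotype pairs for {snp_a}/{snp_b}"
        )
    ca, cb = ca[ok].astype(int), cb[ok].astype(int)
    for snp, c in ((snp_a, ca), (snp_b, cb)):
        if len(set(c.tolist())) == 1:
            raise ValueError(f"SNP {snp} is monomorphic in the complete pairs")
    h = _em_haplotype_freqs(ca, cb)
    p_a = h[0] + h[1]
    p_b = h[0] + h[2]
    d = h[0] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = float(d * d / denom) if denom > 0 else float("nan")
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = float(d / dmax) if dmax > 0 else float("nan")
    return min(r2, 1.0), float(np.clip(d_prime, -1.0, 1.0))


def find_proxies(
    gm: GenotypeMatrix, index_snp: str, threshold: float = 0.85
) -> list[tuple[str, float, float]]:
    """SNPs in LD with the index SNP (r² > threshold OR D′ > threshold),
    sorted by r² descending."""
    gm._index(index_snp)  # raises KeyError if absent
    out = []
    for snp in gm.snp_ids:
        if snp == index_snp:
            continue
        try:
            r2, dp = ld_pair(gm, index_snp, snp)
        except ValueError:
            continue
        if r2 > threshold or abs(dp) > threshold:
            out.append((snp, r2, dp))
    return sorted(out, key=lambda t: -t[1])
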