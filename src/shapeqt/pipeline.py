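"""End-to-end study orchestration.

A study run takes a cohort (simulated, or read from landmark / PED+MAP /
covariate files), builds one shape model per sex stratum actually used
by the SNP→stratum map, computes mode scores, and runs the univariate
max(T) and multivariate CCA screens for each requested covariate set.
Each SNP is tested in exactly one stratum — the population where its
original association was reported — and never consumes subjects from
another stratum.  All outputs are deterministic given the config
(including seeds): a re-run produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc_multivariate import run_multivariate_screen
from .assoc_univariate import PermutationPlan, maxT_permutation
from .genotypes import GenotypeMatrix, read_ped_map
from .shape_model import (
    build_ssm,
    gpa_align,
    ks_normality,
    mode_scores,
    plot_mode_extremes,
    read_landmark_manifest,
    save_model,
)
from .synthetic_data import CohortSpec, GeneticEffectSpec, simulate_cohort

logger = logging.getLogger(__name__)

STRATA = ("mixed", "female", "male")


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    outdir: str = "study_out"
    # either simulate ...
    simulate: dict | None = None  # kwargs for CohortSpec (effects as dicts)
    # ... or read from files
    landmark_manifest: str | None = None
    ped: str | None = None
    map: str | None = None
    covariates: str | None = None
    # analysis settings
    snp_strata: dict[str, str] = field(default_factory=dict)  # snp -> stratum
    snp_coding: dict[str, str] = field(default_factory=dict)  # snp -> model
    variance_threshold: float = 0.95
    covariate_sets: list[list[str]] = field(
        default_factory=lambda: [[], ["age", "bmi"]]
    )
    n_perm: int = 100_000
    perm_seed: int = 0
    perm_family: str = "modes_within_snp"
    covariate_scheme: str = "freedman_lane"
    top_k: int = 3
    sd_multiple: float = 2.5
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: StudyConfig) -> list[str]:
    """Static checks; an empty list means the config is runnable."""
    issues: list[str] = []
    has_files = all(
        p is not None
        for p in (config.landmark_manifest, config.ped, config.map)
    )
    if config.simulate is None and not has_files:
        issues.append("neither 'simulate' nor input file paths are set")
    if config.simulate is not None and has_files:
        issues.append("both 'simulate' and input file paths are set; choose one")
    if not config.snp_strata:
        issues.append("snp_strata is empty: no SNP is assigned a stratum")
    for snp, stratum in config.snp_strata.items():
        if stratum not in STRATA:
            issues.append(f"SNP {snp}: unknown stratum {stratum!r}")
    for snp, coding in config.snp_coding.items():
        if coding not in ("additive", "dominant"):
            issues.append(f"SNP {snp}: unknown coding {coding!r}")
        if snp not in config.snp_strata:
            issues.append(f"SNP {snp}: coding given but no stratum assigned")
    if not (0.0 < config.variance_threshold <= 1.0):
        issues.append("variance_threshold must be in (0, 1]")
    if config.top_k < 1:
        issues.append("top_k must be at least 1")
    for p in (config.landmark_manifest, config.ped, config.map, config.covariates):
        if p is not None and not Path(p).exists():
            issues.append(f"input path does not exist: {p}")
    known_covs = {"age", "bmi", "height", "sex"}
    for cset in config.covariate_sets:
        for name in cset:
            if name not in known_covs:
                issues.append(f"unknown covariate {name!r} in covariate set")
    return issues


def _load_inputs(config: StudyConfig):
    if config.simulate is not None:
        kwargs = dict(config.simulate)
        effects = tuple(
            GeneticEffectSpec(**e) for e in kwargs.pop("effects", [])
        )
        cohort = simulate_cohort(CohortSpec(effects=effects, **kwargs))
        return cohort.landmarks, cohort.genotypes, cohort.covariates
    landmarks = read_landmark_manifest(config.landmark_manifest)
    gm = read_ped_map(config.ped, config.map)
    covar = (
        pd.read_csv(config.covariates, sep="\t")
        if config.covariates is not None
        else None
    )
    return landmarks, gm, covar


def _stratum_mask(stratum: str, covar: pd.DataFrame) -> np.ndarray:
    if stratum == "mixed":
        return np.ones(len(covar), dtype=bool)
    # PED sex coding: 1 = male, 2 = female
    want = 2 if stratum == "female" else 1
    return (covar["sex"].to_numpy() == want)


def run_study(config: StudyConfig) -> dict:
    """Execute a full study; returns a manifest dict of produced outputs."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("loading inputs")
    landmarks, gm, covar = _load_inputs(config)
    if covar is None:
        raise ValueError("covariate table required (sex column drives strata)")
    by_id = {lm.subject_id: lm for lm in landmarks}
    order = [str(i) for i in covar["IID"]]
    missing = [i for i in order if i not in by_id]
    if missing:
        raise ValueError(f"stage landmarks: no landmark file for subjects {missing[:5]}")
    landmarks = [by_id[i] for i in order]

    strata_needed = sorted(set(config.snp_strata.values()))
    scores_by_stratum: dict[str, pd.DataFrame] = {}
    mask_by_stratum: dict[str, np.ndarray] = {}
    models = {}
    for stratum in strata_needed:
        mask = _stratum_mask(stratum, covar)
        n_sub = int(mask.sum())
        if n_sub < 3:
            raise ValueError(
                f"stage ssm[{stratum}]: insufficient subjects for SSM (n={n_sub})"
            )
        logger.info("stratum %s: aligning %d shapes", stratum, n_sub)
        subset = [lm for lm, m in zip(landmarks, mask) if m]
        aligned, _ = gpa_align(subset)
        model = build_ssm(aligned, config.variance_threshold)
        scores = mode_scores(model, aligned)
        models[stratum] = model
        scores_by_stratum[stratum] = scores
        mask_by_stratum[stratum] = mask
        save_model(model, outdir / f"ssm_{stratum}.json")
        scores.rename_axis("IID").reset_index().to_csv(
            outdir / f"scores_{stratum}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        ks_normality(scores).to_csv(
            outdir / f"ks_normality_{stratum}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        for _, row in ks_normality(scores).iterrows():
            if row["pvalue"] < 0.05:
                logger.warning(
                    "stratum %s %s: KS normality p=%.3g", stratum,
                    row["mode"], row["pvalue"],
                )

    snp_meta = gm.snps.set_index("snp")
    covariate_labels = [
        "+".join(cset) if cset else "none" for cset in config.covariate_sets
    ]

    uni_tables = []
    mv_full_tables, mv_topk_tables, mv_loadings = [], [], []
    for cset, clabel in zip(config.covariate_sets, covariate_labels):
        for stratum in strata_needed:
            snps_here = [
                s for s, st in config.snp_strata.items() if st == stratum
            ]
            if not snps_here:
                continue
            mask = mask_by_stratum[stratum]
            scores = scores_by_stratum[stratum]
            gm_sub = gm.subset_subjects(mask)
            cov_sub = (
                covar.loc[mask, cset].to_numpy(dtype=float) if cset else None
            )
            for coding in ("additive", "dominant"):
                snps_coding = [
                    s for s in snps_here
                    if config.snp_coding.get(s, "additive") == coding
                ]
                if not snps_coding:
                    continue
                plan = PermutationPlan(
                    n_perm=config.n_perm,
                    seed=config.perm_seed,
                    family=config.perm_family,
                    covariate_scheme=config.covariate_scheme,
                )
                logger.info(
                    "univariate %s/%s/%s: %d SNPs x %d modes, %d permutations",
                    stratum, clabel, coding, len(snps_coding),
                    scores.shape[1], plan.n_perm,
                )
                tab = maxT_permutation(
                    scores, gm_sub, snps_coding, coding, cov_sub, plan,
                    covariate_label=clabel,
                )
                tab.insert(1, "stratum", stratum)
                tab["chrom"] = [snp_meta.loc[s, "chrom"] for s in tab["snp_id"]]
                tab["minor_allele"] = [
                    snp_meta.loc[s, "minor_allele"] for s in tab["snp_id"]
                ]
                tab["maf"] = [gm.maf[gm._index(s)] for s in tab["snp_id"]]
                uni_tables.append(tab)

            snps_add = [
                s for s in snps_here
                if config.snp_coding.get(s, "additive") == "additive"
            ]
            if snps_add:
                full, topk, loads = run_multivariate_screen(
                    gm_sub, scores, cov_sub, snps_add, k=config.top_k,
                    alpha=config.alpha, covariate_label=clabel,
                )
                for t in (full, topk, loads):
                    t.insert(1, "stratum", stratum)
                mv_full_tables.append(full)
                mv_topk_tables.append(topk)
                mv_loadings.append(loads)

    uni = pd.concat(uni_tables, ignore_index=True)
    uni.to_csv(outdir / "univariate.tsv", sep="\t", index=False,
               float_format="%.6g")
    mv_full = pd.concat(mv_full_tables, ignore_index=True)
    mv_full.to_csv(outdir / "multivariate_full.tsv", sep="\t", index=False,
                   float_format="%.6g")
    mv_topk = pd.concat(mv_topk_tables, ignore_index=True)
    mv_topk.to_csv(outdir / "multivariate_topk.tsv", sep="\t", index=False,
                   float_format="%.6g")
    pd.concat(mv_loadings, ignore_index=True).to_csv(
        outdir / "multivariate_loadings.tsv", sep="\t", index=False,
        float_format="%.6g",
    )

    # mode-extreme outlines for familywise-significant univariate hits
    hits = uni[uni["emp2"] < config.alpha]
    figures = []
    for _, row in hits.iterrows():
        stratum = row["stratum"]
        fig_path = outdir / f"mode_extremes_{stratum}_mode{row['mode']}.svg"
        if not fig_path.exists():
            plot_mode_extremes(
                models[stratum], int(row["mode"]), fig_path, config.sd_multiple
            )
        figures.append(fig_path.name)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_subjects": {s: int(mask_by_stratum[s].sum()) for s in strata_needed},
        "retained_modes": {s: models[s].retained for s in strata_needed},
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
        "figures": sorted(set(figures)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
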