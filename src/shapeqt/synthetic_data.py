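"""Synthetic cohorts with the statistical structure the analysis assumes.

No raw radiograph/genotype data are distributed with this package, so
every downstream stage is exercised against simulated cohorts whose
generating process is known exactly: a fixed femur-like 65-point
template, K orthonormal displacement modes with strictly decreasing
score SDs, Hardy–Weinberg genotypes, small additive or dominant
per-allele effects on individual mode scores, per-coordinate landmark
jitter, and a random similarity transform per subject (so that skipping
Procrustes alignment visibly corrupts the PCA).

Default cohort demography mirrors a hip-osteoarthritis radiograph
cohort: 929 subjects (570 women, 359 men), age 64.1 ± 15.0 years,
BMI 27.4 ± 7.9 kg/m²; default genetic effects are on the order of a few
thousandths of a mode-score unit per allele, the small-to-modest scale
typical of established hip-OA loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, genotype_matrix_from_counts, write_ped_map
from .shape_model import N_COORDS, N_LANDMARKS, LandmarkSet, write_landmarks

DEFAULT_N_MODES = 12
#: Score SD of mode k (1-based): geometric decay, sd_k = 0.012 * 0.78**((k-1)/2).
#: Chosen jointly with the landmark jitter so that (a) 12 modes sit just above
#: a 0.95 cumulative-variance cutoff in the fitted PCA and (b) the default
#: per-allele effects of ~-0.003 give >80% analytic power at n=929.
DEFAULT_MODE_SDS = 0.012 * 0.78 ** (np.arange(DEFAULT_N_MODES) / 2.0)
DEFAULT_LANDMARK_NOISE_SD = 4.8e-4


@dataclass(frozen=True)
class PoseRanges:
    """Per-subject similarity-transform jitter applied to generated landmarks."""

    rotation_deg: float = 10.0
    scale: tuple[float, float] = (0.9, 1.1)
    translation_frac: float = 0.1  # fraction of centroid size


@dataclass(frozen=True)
class GenerativeShapeSpec:
    """Template outline plus orthonormal displacement modes and their SDs."""

    template: np.ndarray  # (65, 2), centred, unit centroid size
    modes: np.ndarray  # (K, 130), rows orthonormal
    mode_sds: np.ndarray  # (K,), strictly decreasing
    landmark_noise_sd: float = DEFAULT_LANDMARK_NOISE_SD
    pose_ranges: PoseRanges = field(default_factory=PoseRanges)

    def __post_init__(self) -> None:
        t = np.asarray(self.template, float)
        m = np.asarray(self.modes, float)
        s = np.asarray(self.mode_sds, float)
        if t.shape != (N_LANDMARKS, 2):
            raise ValueError(f"template must be {N_LANDMARKS}x2, got {t.shape}")
        if m.ndim != 2 or m.shape[1] != N_COORDS:
            raise ValueError(f"modes must be Kx{N_COORDS}, got {m.shape}")
        if m.shape[0] > N_COORDS - 1:
            raise ValueError("at most 129 modes are possible")
        if s.shape != (m.shape[0],):
            raise ValueError("mode_sds length must match number of modes")
        if np.any(s <= 0) or np.any(np.diff(s) >= 0):
            raise ValueError("mode_sds must be positive and strictly decreasing")
        gram = m @ m.T
        if not np.allclose(gram, np.eye(m.shape[0]), atol=1e-8):
            raise ValueError("modes must be mutually orthonormal")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be nonnegative")
        object.__setattr__(self, "template", t)
        object.__setattr__(self, "modes", m)
        object.__setattr__(self, "mode_sds", s)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass(frozen=True)
class GeneticEffectSpec:
    """One SNP with a real effect on one shape mode."""

    snp_id: str
    maf: float
    model: str  # "additive" | "dominant"
    target_mode: int  # 1-based
    beta: float  # score units per coded genotype unit

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5]")
        if self.model not in ("additive", "dominant"):
            raise ValueError(f"{self.snp_id}: unknown genetic model {self.model!r}")
        if self.target_mode < 1:
            raise ValueError(f"{self.snp_id}: target_mode is 1-based")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, demography, genetic effects and the master seed.

    The seed fully determines the output: identical specs produce
    bit-identical cohorts.  Per-subject random draws come from
    deterministic sub-streams so the first subjects are unchanged when
    ``n_subjects`` grows.
    """

    n_subjects: int = 929
    sex_ratio: float = 570 / 929  # fraction female
    age_mean: float = 64.1
    age_sd: float = 15.0
    bmi_mean: float = 27.4
    bmi_sd: float = 7.9
    seed: int = 0
    effects: tuple[GeneticEffectSpec, ...] = ()
    null_snps: int = 38
    null_maf_range: tuple[float, float] = (0.12, 0.48)
    # optional covariate -> mode-score leakage: (covariate, target_mode, beta per SD)
    covariate_effects: tuple[tuple[str, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.null_snps < 0:
            raise ValueError("null_snps must be nonnegative")


@dataclass(frozen=True)
class SimulatedCohort:
    landmarks: list[LandmarkSet]
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame  # FID IID sex age bmi height
    true_scores: np.ndarray  # (n, K), includes genetic effects
    shape_spec: GenerativeShapeSpec


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _control_polygon() -> np.ndarray:
    """Closed femur-like control polygon: medial shaft, lesser trochanter,
    femoral head, saddle, greater trochanter, lateral shaft."""
    head_c = np.array([-0.75, 0.95])
    head_r = 0.62
    pts: list[tuple[float, float]] = [
        (-0.50, -2.20),
        (-0.52, -1.20),
        (-0.55, -0.80),
        (-0.68, -0.50),  # lesser trochanter
        (-0.60, -0.30),
        (-0.72, 0.10),
        (-0.95, 0.40),
    ]
    for ang in (195, 170, 145, 120, 95, 70, 45, 20):  # femoral head arc
        a = np.deg2rad(ang)
        pts.append((head_c[0] + head_r * np.cos(a), head_c[1] + head_r * np.sin(a)))
    pts += [
        (-0.05, 0.85),  # saddle between head and greater trochanter
        (0.35, 1.10),
        (0.60, 1.05),  # greater trochanter
        (0.70, 0.80),
        (0.62, 0.20),
        (0.58, -0.80),
        (0.58, -2.20),
        (0.05, -2.25),
    ]
    return np.array(pts)


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def _outward_normals(pts: np.ndarray) -> np.ndarray:
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    tang = nxt - prv
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    # orient away from the centroid
    outward = np.sign(np.sum(normals * (pts - pts.mean(axis=0)), axis=1))
    outward[outward == 0] = 1.0
    return normals * outward[:, None]


def _similarity_directions(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-transform tangent space at the
    (centred, unit-size) template: x/y translation, rotation, scaling."""
    t = template.ravel()
    tx = np.tile([1.0, 0.0], N_LANDMARKS)
    ty = np.tile([0.0, 1.0], N_LANDMARKS)
    rot = np.column_stack([-template[:, 1], template[:, 0]]).ravel()
    dirs = []
    for v in (tx, ty, t.copy(), rot):
        for b in dirs:
            v = v - (b @ v) * b
        v = v / np.linalg.norm(v)
        dirs.append(v)
    return np.array(dirs)


def _orthonormalize(raw: Sequence[np.ndarray], against: np.ndarray) -> np.ndarray:
    basis = [b for b in against]
    out = []
    for f in raw:
        v = np.asarray(f, float).ravel().copy()
        for b in basis:
            v = v - (b @ v) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-8:
            raise ValueError("mode field is degenerate after orthogonalization")
        v = v / nrm
        basis.append(v)
        out.append(v)
    return np.array(out)


def make_template_femur(n_modes: int = DEFAULT_N_MODES) -> GenerativeShapeSpec:
    """Fixed 65-point proximal-femur-like outline with default modes.

    The first five mode fields are anatomically interpretable
    displacement patterns (femoral head size, neck width, shaft width,
    neck-shaft angle, greater-trochanter height); the remainder are
    smooth bending fields along the outline normal.  All fields are
    Gram–Schmidt-orthonormalised against each other *and* against the
    similarity-transform directions at the template, so the generated
    variance survives Procrustes alignment intact.  Pure function: two
    calls return identical output.
    """
    if not (1 <= n_modes <= N_COORDS - 1):
        raise ValueError("n_modes out of range")
    pts = _resample_closed(_control_polygon(), N_LANDMARKS)
    centroid = pts.mean(axis=0)
    pts = pts - centroid
    size = np.linalg.norm(pts)
    pts = pts / size
    head_c = (np.array([-0.75, 0.95]) - centroid) / size
    head_r = 0.62 / size
    normals = _outward_normals(pts)
    d_head = pts - head_c
    r_head = np.linalg.norm(d_head, axis=1)
    u_head = d_head / np.maximum(r_head[:, None], 1e-9)

    fields: list[np.ndarray] = []
    # 1: femoral head size (radial expansion around the head centre)
    w = np.exp(-(r_head**2) / (2 * (1.3 * head_r) ** 2))
    fields.append((w[:, None] * u_head).ravel())
    # 2: neck width (normal displacement in the neck band)
    neck_c = (np.array([-0.35, 0.45]) - centroid) / size
    d_neck = np.linalg.norm(pts - neck_c, axis=1)
    w = np.exp(-(d_neck**2) / (2 * (1.0 * head_r) ** 2))
    fields.append((w[:, None] * normals).ravel())
    # 3: shaft width (lateral displacement of shaft points)
    shaft_y = (-1.0 - centroid[1]) / size
    w = 1.0 / (1.0 + np.exp((pts[:, 1] - shaft_y) / (0.3 * head_r)))
    sgn = np.sign(pts[:, 0] - np.median(pts[:, 0]))
    fields.append((w * sgn)[:, None].repeat(2, axis=1) @ np.diag([1.0, 0.0]))
    # 4: neck-shaft angle (rotation of head+neck about the neck base)
    pivot = (np.array([-0.15, 0.0]) - centroid) / size
    arm = pts - pivot
    perp = np.column_stack([-arm[:, 1], arm[:, 0]])
    w = np.exp(-(r_head**2) / (2 * (2.0 * head_r) ** 2))
    fields.append((w[:, None] * perp).ravel())
    # 5: greater trochanter height
    troch_c = (np.array([0.50, 1.00]) - centroid) / size
    d_tr = np.linalg.norm(pts - troch_c, axis=1)
    w = np.exp(-(d_tr**2) / (2 * (0.8 * head_r) ** 2))
    fields.append(np.column_stack([np.zeros(N_LANDMARKS), w]).ravel())
    # 6..K: smooth bending fields along the outline normal
    s = np.arange(N_LANDMARKS) / N_LANDMARKS
    freq = 2
    while len(fields) < n_modes:
        phase = 0.7 * len(fields)
        w = np.sin(2 * np.pi * freq * s + phase)
        fields.append((w[:, None] * normals).ravel())
        freq += 1

    fields = [np.asarray(f, float).ravel() for f in fields]
    sim = _similarity_directions(pts)
    modes = _orthonormalize(fields[:n_modes], sim)
    sds = 0.012 * 0.78 ** (np.arange(n_modes) / 2.0)
    return GenerativeShapeSpec(template=pts, modes=modes, mode_sds=sds)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _code(calls: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return calls.astype(float)
    return (calls > 0).astype(float)


def simulate_cohort(
    spec: CohortSpec, shape: GenerativeShapeSpec | None = None
) -> SimulatedCohort:
    """Draw one cohort: landmarks, genotypes, covariates, true mode scores.

    Genotypes are Binomial(2, MAF) per SNP (Hardy–Weinberg).  Mode
    scores are b_k ~ Normal(0, mode_sds[k]^2), plus ``beta * code(g)``
    for targeted modes.  Landmarks are
    ``template + modes^T b + Normal(0, landmark_noise_sd^2)`` followed by
    a random similarity transform per subject drawn from the pose
    ranges.  Covariates come from the stated normals; height is drawn
    per sex (women 162.7 ± 6.2 cm, men 176.2 ± 6.9 cm).
    """
    if shape is None:
        shape = make_template_femur()
    k = shape.n_modes
    for eff in spec.effects:
        if eff.target_mode > k:
            raise ValueError(
                f"{eff.snp_id}: target_mode {eff.target_mode} exceeds K={k}"
            )
    for cov_name, mode, _ in spec.covariate_effects:
        if cov_name not in ("age", "bmi", "height"):
            raise ValueError(f"unknown covariate {cov_name!r}")
        if not (1 <= mode <= k):
            raise ValueError(f"covariate effect target_mode {mode} out of range")

    n = spec.n_subjects
    root = np.random.SeedSequence(spec.seed)
    geno_ss, subj_ss = root.spawn(2)

    # --- genotypes: one sub-stream per SNP (n-invariant per subject) ---
    snp_ids = [e.snp_id for e in spec.effects]
    mafs = [e.maf for e in spec.effects]
    if spec.null_snps > 0:
        lo, hi = spec.null_maf_range
        null_mafs = np.linspace(lo, hi, spec.null_snps)
        for i, m in enumerate(null_mafs):
            snp_ids.append(f"null{i + 1:04d}")
            mafs.append(float(m))
    n_snps = len(snp_ids)
    calls = np.zeros((n, n_snps), dtype=np.int8)
    for j, child in enumerate(geno_ss.spawn(n_snps)):
        rng = np.random.default_rng(child)
        calls[:, j] = rng.binomial(2, mafs[j], size=n)
    snps = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": ["1"] * n_snps,
            "pos": [(j + 1) * 1_000_000 for j in range(n_snps)],
        }
    )
    gm = genotype_matrix_from_counts(
        fids=[f"S{i + 1:04d}" for i in range(n)],
        iids=[f"S{i + 1:04d}" for i in range(n)],
        snps=snps,
        counts=calls,
        allele1="A",
        allele2="G",
    )

    # --- per-subject draws: sex, covariates, scores, noise, pose ---
    template_vec = shape.template.ravel()
    pr = shape.pose_ranges
    rot_max = np.deg2rad(pr.rotation_deg)
    landmarks: list[LandmarkSet] = []
    sex = np.zeros(n, dtype=int)
    age = np.zeros(n)
    bmi = np.zeros(n)
    height = np.zeros(n)
    scores = np.zeros((n, k))
    children = subj_ss.spawn(n)
    for i in range(n):
        rng = np.random.default_rng(children[i])
        is_female = rng.random() < spec.sex_ratio
        sex[i] = 2 if is_female else 1  # PED convention: 1=male, 2=female
        age[i] = rng.normal(spec.age_mean, spec.age_sd)
        bmi[i] = rng.normal(spec.bmi_mean, spec.bmi_sd)
        height[i] = rng.normal(162.7, 6.2) if is_female else rng.normal(176.2, 6.9)
        b = rng.normal(0.0, shape.mode_sds)
        noise = rng.normal(0.0, shape.landmark_noise_sd, size=N_COORDS)
        theta = rng.uniform(-rot_max, rot_max)
        sc = rng.uniform(pr.scale[0], pr.scale[1])
        trans = rng.uniform(-pr.translation_frac, pr.translation_frac, size=2)
        scores[i] = b
        # genetic effects
        for eff in spec.effects:
            jcol = snp_ids.index(eff.snp_id)
            g = gm.calls[i, jcol]
            if g >= 0:
                scores[i, eff.target_mode - 1] += eff.beta * _code(
                    np.array([g]), eff.model
                )[0]
        vec = template_vec + shape.modes.T @ scores[i] + noise
        pts = vec.reshape(N_LANDMARKS, 2)
        c, ssin = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -ssin], [ssin, c]])
        size = np.linalg.norm(pts - pts.mean(axis=0))
        pts = pts @ rot.T * sc + trans * size
        landmarks.append(LandmarkSet(subject_id=f"S{i + 1:04d}", points=pts))

    # optional covariate -> score leakage
    cov_arrays = {"age": age, "bmi": bmi, "height": height}
    for cov_name, mode, beta_per_sd in spec.covariate_effects:
        z = cov_arrays[cov_name]
        z = (z - z.mean()) / z.std(ddof=1)
        scores[:, mode - 1] += beta_per_sd * z

    covariates = pd.DataFrame(
        {
            "FID": gm.fids,
            "IID": gm.iids,
            "sex": sex,
            "age": np.round(age, 2),
            "bmi": np.round(bmi, 2),
            "height": np.round(height, 1),
        }
    )
    return SimulatedCohort(
        landmarks=landmarks,
        genotypes=gm,
        covariates=covariates,
        true_scores=scores,
        shape_spec=shape,
    )


# ---------------------------------------------------------------------------
# On-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write landmarks (one file per subject + manifest), PED/MAP, covariates."""
    outdir = Path(outdir)
    lm_dir = outdir / "landmarks"
    lm_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for lm in cohort.landmarks:
        p = lm_dir / f"{lm.subject_id}.txt"
        write_landmarks(lm, p)
        manifest_rows.append((lm.subject_id, f"landmarks/{lm.subject_id}.txt"))
    manifest = outdir / "landmarks_manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["subject_id", "path"]).to_csv(
        manifest, sep="\t", index=False
    )
    ped = outdir / "cohort.ped"
    map_ = outdir / "cohort.map"
    write_ped_map(cohort.genotypes, ped, map_)
    covar = outdir / "covariates.tsv"
    cohort.covariates.to_csv(covar, sep="\t", index=False)
    return {"manifest": manifest, "ped": ped, "map": map_, "covariates": covar}
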