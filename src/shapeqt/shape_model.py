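"""Point-distribution shape models for 2D landmark outlines.

A statistical shape model (SSM) summarises a set of landmark
configurations as a mean shape plus orthonormal modes of variation
obtained by principal components analysis.  Each subject's shape is
approximated as ``mean + sum_k b_k * mode_k`` and the per-subject mode
scores ``b_k`` serve as quantitative traits downstream.

The workflow is:

1. :func:`gpa_align` — generalized Procrustes analysis removes
   translation, rotation and (optionally) scale from raw landmark sets;
2. :func:`build_ssm` — PCA of the aligned coordinate vectors, retaining
   the smallest number of modes whose cumulative variance fraction
   reaches a threshold (0.95 by default);
3. :func:`project` / :func:`reconstruct` — move between shape space and
   mode-score space;
4. :func:`mode_extremes` — mean ± a multiple of the per-mode SD, for
   visualising what each mode does;
5. :func:`ks_normality` — Kolmogorov–Smirnov check that per-mode scores
   are compatible with a normal distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_LANDMARKS = 65
N_COORDS = 2 * N_LANDMARKS


class DegenerateShapeError(ValueError):
    """Raised when a landmark set has zero centroid size."""


@dataclass(frozen=True)
class LandmarkSet:
    """One subject's ordered 2D landmarks.

    Point order encodes anatomical correspondence across subjects and is
    never permuted.
    """

    subject_id: str
    points: np.ndarray  # (65, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{self.subject_id}: expected {N_LANDMARKS}x2 landmarks, got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"{self.subject_id}: non-finite landmark coordinates")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class AlignedShape:
    """A shape after Procrustes alignment.

    ``vector`` is the flattened (x1, y1, ..., x65, y65) coordinate
    vector in the common frame; ``centroid_size`` is the pre-normalisation
    centroid size (Frobenius norm of the centred configuration), kept so
    that size information is not lost when scale is normalised away.
    """

    subject_id: str
    vector: np.ndarray  # (130,)
    centroid_size: float


@dataclass(frozen=True)
class ShapeModel:
    """Mean shape + orthonormal PCA modes, in descending eigenvalue order."""

    mean: np.ndarray  # (130,)
    modes: np.ndarray  # (130, M), columns orthonormal
    variances: np.ndarray  # (M,), nonincreasing
    retained: int
    variance_fractions: np.ndarray  # (M,)
    scale_normalized: bool = True

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def retained_sds(self) -> np.ndarray:
        return np.sqrt(self.variances[: self.retained])


# ---------------------------------------------------------------------------
# Landmark file I/O (plain tabular text: two header comment lines, x<TAB>y rows)
# ---------------------------------------------------------------------------

def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# subject {lm.subject_id}\n")
        fh.write(f"# n_points {N_LANDMARKS}\n")
        for x, y in lm.points:
            fh.write(f"{x:.10g}\t{y:.10g}\n")


def read_landmarks(path: str | Path) -> LandmarkSet:
    path = Path(path)
    subject_id = path.stem
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# subject"):
                    subject_id = line.split(None, 2)[2]
                continue
            parts = line.split()
            rows.append((float(parts[0]), float(parts[1])))
    return LandmarkSet(subject_id=subject_id, points=np.array(rows))


def read_landmark_manifest(manifest: str | Path) -> list[LandmarkSet]:
    """Read a manifest TSV (columns: subject_id, path) of landmark files."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest.parent / p
        lm = read_landmarks(p)
        out.append(LandmarkSet(subject_id=str(row["subject_id"]), points=lm.points))
    return out


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_and_size(points: np.ndarray, subject_id: str) -> tuple[np.ndarray, float]:
    centred = points - points.mean(axis=0)
    size = float(np.linalg.norm(centred))
    if size < 1e-12:
        raise DegenerateShapeError(
            f"subject {subject_id}: degenerate shape (zero centroid size)"
        )
    return centred, size


def _rotate_to(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of ``points`` onto ``target``."""
    h = points.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, d]) @ vt
    return points @ r


def gpa_align(
    landmarks: Sequence[LandmarkSet],
    tol: float = 1e-10,
    max_iter: int = 100,
    scale: bool = True,
) -> tuple[list[AlignedShape], np.ndarray]:
    """Generalized Procrustes alignment of a set of landmark configurations.

    Each shape is centred, (optionally) scaled to unit centroid size, and
    rotated to the current mean; the mean is recomputed, re-normalised
    and the loop repeats until the mean moves by less than ``tol``.

    Returns the aligned shapes and the converged mean as a 130-vector.
    """
    if len(landmarks) < 2:
        raise ValueError("need at least 2 shapes for Procrustes alignment")
    centred = []
    sizes = []
    for lm in landmarks:
        c, s = _center_and_size(lm.points, lm.subject_id)
        if scale:
            c = c / s
        centred.append(c)
        sizes.append(s)

    mean = centred[0].copy()
    mean /= np.linalg.norm(mean)
    for _ in range(max_iter):
        rotated = [_rotate_to(c, mean) for c in centred]
        new_mean = np.mean(rotated, axis=0)
        new_mean -= new_mean.mean(axis=0)
        nrm = np.linalg.norm(new_mean)
        if nrm < 1e-12:
            raise DegenerateShapeError("degenerate mean shape during GPA")
        new_mean /= nrm
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        centred = rotated
        if shift < tol:
            break

    aligned = [
        AlignedShape(subject_id=lm.subject_id, vector=c.ravel(), centroid_size=s)
        for lm, c, s in zip(landmarks, centred, sizes)
    ]
    return aligned, mean.ravel()


# ---------------------------------------------------------------------------
# PCA shape model
# ---------------------------------------------------------------------------

def build_ssm(
    aligned: Sequence[AlignedShape], variance_threshold: float = 0.95
) -> ShapeModel:
    """PCA of aligned shape vectors with variance-threshold mode retention.

    The sample covariance uses 1/(n-1).  Modes are sorted by descending
    eigenvalue; the retained count is the smallest ``m`` whose cumulative
    variance fraction reaches ``variance_threshold``.  Eigenvector signs
    are fixed by making the largest-magnitude coordinate of each mode
    positive, so output is deterministic across platforms.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    n = len(aligned)
    if n < 3:
        raise ValueError(f"need at least 3 shapes to build an SSM (got {n})")
    x = np.array([a.vector for a in aligned])
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (n - 1)
    total = float(variances.sum())
    scale_ref = float(np.mean(np.sum(x * x, axis=1)))
    if total <= max(scale_ref, 1.0) * 1e-24:
        raise ValueError("zero total variance: all shapes identical")
    m = min(n - 1, N_COORDS)
    variances = variances[:m]
    modes = vt[:m].T  # (130, M)
    # deterministic eigenvector signs
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    modes = modes * signs
    fractions = variances / total
    cum = np.cumsum(fractions)
    retained = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    retained = min(retained, m)
    return ShapeModel(
        mean=mean,
        modes=modes,
        variances=variances,
        retained=retained,
        variance_fractions=fractions,
    )


def project(
    model: ShapeModel, shape: AlignedShape | np.ndarray, n_modes: int | None = None
) -> np.ndarray:
    """Mode scores ``b = modes^T (x - mean)`` for the first ``n_modes`` modes."""
    vec = shape.vector if isinstance(shape, AlignedShape) else np.asarray(shape, float)
    if vec.shape != (model.mean.shape[0],):
        raise ValueError(f"shape vector has wrong dimension {vec.shape}")
    k = model.retained if n_modes is None else n_modes
    if k > model.n_modes:
        raise ValueError(f"requested {k} modes but model has {model.n_modes}")
    return model.modes[:, :k].T @ (vec - model.mean)


def reconstruct(model: ShapeModel, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project` on the retained subspace."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[0]
    if k > model.n_modes:
        raise ValueError(f"got {k} scores but model has {model.n_modes} modes")
    return model.mean + model.modes[:, :k] @ scores


def mode_scores(
    model: ShapeModel, aligned: Sequence[AlignedShape]
) -> pd.DataFrame:
    """Per-subject scores for the retained modes, one column per mode.

    Columns are named ``mode1..modeM`` (1-based, matching how modes are
    reported in association tables).
    """
    rows = np.array([project(model, a) for a in aligned])
    cols = [f"mode{k}" for k in range(1, model.retained + 1)]
    return pd.DataFrame(rows, index=[a.subject_id for a in aligned], columns=cols)


def mode_extremes(
    model: ShapeModel, mode_k: int, sd_multiple: float = 2.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outlines at mean - s*SD, mean, mean + s*SD along one mode (1-based).

    Returns three (65, 2) point arrays, the conventional rendering of
    what a shape mode does.
    """
    if not (1 <= mode_k <= model.retained):
        raise ValueError(f"mode {mode_k} out of range 1..{model.retained}")
    sd = float(np.sqrt(model.variances[mode_k - 1]))
    offset = sd_multiple * sd * model.modes[:, mode_k - 1]
    minus = (model.mean - offset).reshape(-1, 2)
    mean = model.mean.reshape(-1, 2)
    plus = (model.mean + offset).reshape(-1, 2)
    return minus, mean, plus


def ks_normality(scores: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """One-sample KS test of each mode's scores against a fitted normal.

    Parameters are estimated from the scores themselves, which makes the
    test conservative (the Lilliefors effect): p-values are biased
    upwards relative to a test with known parameters.  The test is a
    diagnostic, not a filter.
    """
    if isinstance(scores, pd.DataFrame):
        cols = list(scores.columns)
        data = scores.to_numpy(dtype=float)
    else:
        data = np.asarray(scores, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        cols = [f"mode{k}" for k in range(1, data.shape[1] + 1)]
    n = data.shape[0]
    if n < 8:
        raise ValueError(f"need at least 8 observations for the KS check (got {n})")
    out = []
    for j, name in enumerate(cols):
        col = data[:, j]
        sd = col.std(ddof=1)
        if sd <= 0.0:
            raise ValueError(f"{name}: constant scores, KS test undefined")
        res = stats.kstest(col, "norm", args=(col.mean(), sd))
        out.append((name, res.statistic, res.pvalue))
    return pd.DataFrame(out, columns=["mode", "statistic", "pvalue"])


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: ShapeModel, path: str | Path) -> None:
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "mean": model.mean.tolist(),
        "modes": model.modes.tolist(),
        "variances": model.variances.tolist(),
        "retained": model.retained,
        "variance_fractions": model.variance_fractions.tolist(),
        "scale_normalized": model.scale_normalized,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ShapeModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported shape-model file version")
    return ShapeModel(
        mean=np.array(payload["mean"]),
        modes=np.array(payload["modes"]),
        variances=np.array(payload["variances"]),
        retained=int(payload["retained"]),
        variance_fractions=np.array(payload["variance_fractions"]),
        scale_normalized=bool(payload["scale_normalized"]),
    )


def plot_mode_extremes(
    model: ShapeModel, mode_k: int, path: str | Path, sd_multiple: float = 2.5
) -> None:
    """Write an SVG of mean ± ``sd_multiple`` SD outlines for one mode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    minus, mean, plus = mode_extremes(model, mode_k, sd_multiple)
    fig, ax = plt.subplots(figsize=(4, 5))
    for pts, style, label in (
        (mean, "-", "mean"),
        (plus, "--", f"+{sd_multiple} SD"),
        (minus, ":", f"-{sd_multiple} SD"),
    ):
        closed = np.vstack([pts, pts[:1]])
        ax.plot(closed[:, 0], closed[:, 1], style, label=label)
    ax.set_aspect("equal")
    ax.set_title(f"mode {mode_k}")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, format="svg")
    plt.close(fig)
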