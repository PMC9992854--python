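"""Volumetry and downstream statistics.

Structure volumes are obtained by summing soft probabilities (not hard
voxel counts) and multiplying by the 1 mm^3 voxel volume, which propagates
segmentation uncertainty and some partial-volume information into the
estimates; the intracranial volume (ICV) is the sum of all intracranial
structure volumes including intracranial CSF. Group differences are
quantified with Cohen's d (pooled standard deviation), optionally after
linear correction of the volumes for age, gender and ICV, and aging
trajectories are modelled with a cubic B-spline in age (10 equally spaced
knots) plus linear slice-spacing terms per acquisition direction and a
gender bias, fitted by L-BFGS-B on the residual sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize

__all__ = [
    "VolumeReport",
    "AgingModelSpec",
    "soft_volumes",
    "estimate_icv",
    "hard_dice",
    "cohens_d",
    "covariate_correct",
    "fit_aging_trajectory",
]

VOXEL_VOLUME_MM3 = 1.0  # all segmentations live on the 1 mm isotropic grid


@dataclass
class VolumeReport:
    """Per-structure soft volumes in mm^3, with optional QC keep flags."""

    volumes: dict[str, float]
    icv: float | None = None
    kept: dict[str, bool] = field(default_factory=dict)


def soft_volumes(
    result,
    names: Sequence[str] | None = None,
    tol: float = 1e-4,
) -> VolumeReport:
    """Structure volumes from a :class:`SegmentationResult`: the volume of
    structure k is the sum of its soft probabilities times 1 mm^3. The
    total over all channels equals the voxel count exactly (conservation)."""
    soft = np.asarray(result.soft, dtype=np.float64)
    sums = soft.sum(axis=0)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError("soft probabilities do not sum to 1 per voxel")
    if names is None:
        names = [result.hard.entry(v).name for v in result.label_order]
    vols = soft.reshape(soft.shape[0], -1).sum(axis=1) * VOXEL_VOLUME_MM3
    return VolumeReport(volumes={n: float(v) for n, v in zip(names, vols)})


def estimate_icv(report: VolumeReport, structure_set: Sequence[str]) -> float:
    """Intracranial volume: sum of the volumes of the declared intracranial
    structures. The set must include the intracranial CSF structure;
    background and extracerebral structures must be excluded by the caller's
    choice of set."""
    structure_set = list(structure_set)
    missing = [s for s in structure_set if s not in report.volumes]
    if missing:
        raise ValueError(f"structures {missing} absent from the volume report")
    if not any("csf" in s.lower() for s in structure_set):
        raise ValueError(
            "ICV must include the intracranial CSF structure; none found in the set"
        )
    return float(sum(report.volumes[s] for s in structure_set))


def hard_dice(x: np.ndarray, y: np.ndarray) -> float:
    """Hard Dice overlap 2|X n Y| / (|X| + |Y|) between two voxel sets
    (boolean masks on the same grid). Two empty sets agree perfectly (1)."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("masks must share a grid")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def cohens_d(group_c: Sequence[float], group_ad: Sequence[float]) -> float:
    """Cohen's d effect size |mean_C - mean_AD| / s with the pooled
    standard deviation s^2 = ((n_C-1) s_C^2 + (n_AD-1) s_AD^2) /
    (n_C + n_AD - 2). Values below 0.2 are small, above 0.8 large."""
    c = np.asarray(group_c, dtype=float)
    a = np.asarray(group_ad, dtype=float)
    if c.size < 2 or a.size < 2:
        raise ValueError("each group needs at least 2 samples")
    nc, na = c.size, a.size
    s2 = ((nc - 1) * c.var(ddof=1) + (na - 1) * a.var(ddof=1)) / (nc + na - 2)
    diff = abs(c.mean() - a.mean())
    if s2 == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means; d is infinite")
        return float("inf")
    return float(diff / np.sqrt(s2))


def covariate_correct(
    volumes: Sequence[float],
    covariates: Mapping[str, Sequence[float]],
) -> np.ndarray:
    """Residualize volumes on covariates (e.g. age, gender, ICV) by OLS
    with intercept, re-centred to the grand mean. Raises on a rank-deficient
    design, naming the offending columns."""
    y = np.asarray(volumes, dtype=float)
    names = list(covariates)
    cols = [np.asarray(covariates[n], dtype=float) for n in names]
    for n, c in zip(names, cols):
        if c.shape != y.shape:
            raise ValueError(f"covariate {n!r} length {c.size} != volumes length {y.size}")
    X = np.column_stack([np.ones_like(y)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [n for n, c in zip(names, cols) if np.std(c) == 0]
        if not bad:
            # find columns whose removal restores full rank
            bad = [
                n
                for i, n in enumerate(names)
                if np.linalg.matrix_rank(np.delete(X, i + 1, axis=1)) == rank
            ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid + y.mean()


@dataclass
class AgingModelSpec:
    """Fitted aging model: cubic B-spline in age (10 equally spaced knots)
    + linear slice-spacing terms per acquisition direction + gender bias."""

    knots: np.ndarray  # full (clamped) knot vector
    spline_coef: np.ndarray  # one per basis function
    spacing_coef: np.ndarray  # (3,): sagittal, coronal, axial slopes
    gender_coef: float
    age_range: tuple[float, float]
    converged: bool
    grad_norm: float

    N_KNOTS = 10
    DEGREE = 3

    def design(self, ages, gender, spacing) -> np.ndarray:
        ages = np.clip(np.asarray(ages, dtype=float), *self.age_range)
        B = BSpline.design_matrix(ages, self.knots, self.DEGREE).toarray()
        g = np.broadcast_to(np.asarray(gender, dtype=float), ages.shape)
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), ages.shape + (3,))
        return np.column_stack([B, g, sp])

    def predict(
        self,
        ages,
        gender: float = 0.0,
        spacing: Sequence[float] = (1.0, 1.0, 1.0),
    ) -> np.ndarray:
        """Trajectory at query ages with covariates held at reference
        values (default: gender 0, 1 mm isotropic acquisition)."""
        coef = np.concatenate([self.spline_coef, [self.gender_coef], self.spacing_coef])
        return self.design(ages, gender, spacing) @ coef


def _knot_vector(lo: float, hi: float) -> np.ndarray:
    sites = np.linspace(lo, hi, AgingModelSpec.N_KNOTS)
    k = AgingModelSpec.DEGREE
    return np.concatenate([[lo] * k, sites, [hi] * k])


def fit_aging_trajectory(
    ages: Sequence[float],
    volumes: Sequence[float],
    gender: Sequence[float],
    slice_spacing: Sequence[Sequence[float]],
) -> AgingModelSpec:
    """Fit the aging model by minimizing the residual sum of squares with
    L-BFGS-B. Isotropic scans should report their spacing in all three
    direction columns."""
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(volumes, dtype=float)
    g = np.asarray(gender, dtype=float)
    sp = np.asarray(slice_spacing, dtype=float).reshape(len(ages), 3)
    if ages.size < 50 or np.unique(ages).size < 5:
        raise ValueError("need >= 50 observations spanning >= 5 distinct ages")
    lo, hi = float(ages.min()), float(ages.max())
    if hi - lo <= 0:
        raise ValueError("degenerate age range")
    knots = _knot_vector(lo, hi)
    B = BSpline.design_matrix(np.clip(ages, lo, hi - 1e-9), knots, AgingModelSpec.DEGREE).toarray()
    X = np.column_stack([B, g, sp])

    # precondition: scale columns to unit norm for the quasi-Newton solver
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale

    def f(beta):
        r = Xs @ beta - y
        return 0.5 * float(r @ r), Xs.T @ r

    res = minimize(f, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    beta = res.x / scale
    grad_norm = float(np.linalg.norm(X.T @ (X @ beta - y)))
    if not res.success:
        warnings.warn(f"aging fit did not fully converge; |grad| = {grad_norm:.3g}")
    nb = B.shape[1]
    return AgingModelSpec(
        knots=knots,
        spline_coef=beta[:nb],
        spacing_coef=beta[nb + 1 : nb + 4],
        gender_coef=float(beta[nb]),
        age_range=(lo, hi),
        converged=bool(res.success),
        grad_norm=grad_norm,
    )
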