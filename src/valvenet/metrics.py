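"""Shape-comparison metrics and Green–Lagrange strain fields.

Predicted and reference closed-valve shapes are compared with three
complementary metrics, all in cm:

* mean Euclidean distance — pointwise agreement of matched control points;
* Hausdorff distance — worst-case disagreement between the two surfaces,
  computed on dense surface samples (control points do not lie on the
  surface);
* Procrustes distance — residual RMSD after optimal rigid (translation +
  rotation, no scaling) alignment, isolating shape error from pose error.

Strains are the standard thin-shell membrane measure: with covariant surface
tangents a_alpha (reference) and abar_alpha (deformed), the metric tensors
A_ab = a_a . a_b and Abar_ab give the in-plane Green–Lagrange strain
E = (Abar - A)/2; the maximum in-plane principal strain is the larger
eigenvalue of the generalized problem E v = lambda A v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import pearsonr

from .nurbs import NurbsSurface, sample_surface

__all__ = [
    "MetricsReport",
    "StrainField",
    "mean_euclidean",
    "hausdorff",
    "surface_point_cloud",
    "procrustes",
    "coaptation_stats",
    "max_principal_strain",
]


@dataclass(frozen=True)
class MetricsReport:
    """Corpus-level aggregates: for each shape metric the max/mean/median of
    the per-valve values, plus coaptation RMSE (cm^2) and Pearson R."""

    euclidean: dict
    hausdorff: dict
    procrustes: dict
    coaptation_rmse: float
    coaptation_r: float
    n_valves: int

    @staticmethod
    def aggregate(values: np.ndarray) -> dict:
        return {"max": float(np.max(values)), "mean": float(np.mean(values)),
                "median": float(np.median(values))}


def mean_euclidean(pred_positions: np.ndarray, true_positions: np.ndarray) -> float:
    """Mean over all control points (all leaflets) of the pointwise Euclidean
    distance between predicted and true deformed positions (cm)."""
    pred = np.asarray(pred_positions, float)
    true = np.asarray(true_positions, float)
    if pred.shape != true.shape:
        raise ValueError("position arrays must have matching shapes")
    return float(np.mean(np.linalg.norm(pred.reshape(-1, 3) - true.reshape(-1, 3), axis=1)))


def surface_point_cloud(surfaces: list[NurbsSurface], sampling: tuple[int, int] = (50, 50)) -> np.ndarray:
    """Stacked surface samples on a dense parameter grid, shape (N, 3)."""
    nu, nv = sampling
    if nu < 1 or nv < 1:
        raise ValueError("sampling grid must be non-empty")
    clouds = []
    for surf in surfaces:
        lo_u, hi_u = surf.knots_u.domain
        lo_v, hi_v = surf.knots_v.domain
        xi = np.linspace(lo_u, hi_u, nu)
        eta = np.linspace(lo_v, hi_v, nv)
        clouds.append(sample_surface(surf, xi, eta)["S"].reshape(-1, 3))
    return np.vstack(clouds)


def hausdorff(pred_points: np.ndarray, true_points: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (cm)."""
    pred = np.asarray(pred_points, float).reshape(-1, 3)
    true = np.asarray(true_points, float).reshape(-1, 3)
    if len(pred) == 0 or len(true) == 0:
        raise ValueError("empty point set")
    d1 = directed_hausdorff(pred, true)[0]
    d2 = directed_hausdorff(true, pred)[0]
    return float(max(d1, d2))


def procrustes(pred_points: np.ndarray, true_points: np.ndarray) -> float:
    """Partial Procrustes distance: RMSD after optimal translation and proper
    rotation (no scaling) of the predicted onto the true configuration (cm)."""
    pred = np.asarray(pred_points, float).reshape(-1, 3)
    true = np.asarray(true_points, float).reshape(-1, 3)
    if pred.shape != true.shape:
        raise ValueError("point sets must be matched and equal length")
    if len(pred) < 3:
        raise ValueError("Procrustes alignment needs at least 3 points")
    pc = pred - pred.mean(axis=0)
    tc = true - true.mean(axis=0)
    # Kabsch: optimal proper rotation from the SVD of the cross-covariance
    U, _, Vt = np.linalg.svd(pc.T @ tc)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    aligned = pc @ R
    return float(np.sqrt(np.mean(np.sum((aligned - tc) ** 2, axis=1))))


def coaptation_stats(predicted: np.ndarray, true: np.ndarray) -> tuple[float, float]:
    """(RMSE in cm^2, Pearson correlation R) between predicted and true
    coaptation areas.  R is NaN (flagged) when either vector has zero
    variance."""
    pred = np.asarray(predicted, float).ravel()
    tr = np.asarray(true, float).ravel()
    if len(pred) != len(tr) or len(pred) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    rmse = float(np.sqrt(np.mean((pred - tr) ** 2)))
    if np.std(pred) < 1e-15 or np.std(tr) < 1e-15:
        return rmse, float("nan")
    return rmse, float(pearsonr(pred, tr)[0])


@dataclass(frozen=True)
class StrainField:
    """Maximum in-plane principal Green–Lagrange strain sampled on a parameter
    grid (dimensionless).  Degenerate-metric points are NaN."""

    values: np.ndarray
    xi: np.ndarray
    eta: np.ndarray


def max_principal_strain(reference: NurbsSurface, deformed: NurbsSurface,
                         grid: tuple[int, int] = (30, 30)) -> StrainField:
    """Membrane Green–Lagrange strain of ``deformed`` relative to
    ``reference`` (same parametrization), maximum principal value per grid
    point."""
    if reference.shape != deformed.shape:
        raise ValueError("surfaces must share a parametrization")
    nu, nv = grid
    lo_u, hi_u = reference.knots_u.domain
    lo_v, hi_v = reference.knots_v.domain
    xi = np.linspace(lo_u, hi_u, nu)
    eta = np.linspace(lo_v, hi_v, nv)
    ref = sample_surface(reference, xi, eta, order=1)
    dfm = sample_surface(deformed, xi, eta, order=1)

    def metric(Su, Sv):
        return (np.einsum("uvc,uvc->uv", Su, Su),
                np.einsum("uvc,uvc->uv", Su, Sv),
                np.einsum("uvc,uvc->uv", Sv, Sv))

    A11, A12, A22 = metric(ref["Su"], ref["Sv"])
    B11, B12, B22 = metric(dfm["Su"], dfm["Sv"])
    E11, E12, E22 = 0.5 * (B11 - A11), 0.5 * (B12 - A12), 0.5 * (B22 - A22)
    detA = A11 * A22 - A12 * A12
    ok = detA > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        # M = A^{-1} E; principal strains are the eigenvalues of M
        M11 = (A22 * E11 - A12 * E12) / detA
        M12 = (A22 * E12 - A12 * E22) / detA
        M21 = (A11 * E12 - A12 * E11) / detA
        M22 = (A11 * E22 - A12 * E12) / detA
        tr = M11 + M22
        det = M11 * M22 - M12 * M21
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        lam_max = 0.5 * (tr + disc)
    lam_max = np.where(ok, lam_max, np.nan)
    return StrainField(lam_max, xi, eta)
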