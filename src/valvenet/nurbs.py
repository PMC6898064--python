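"""Tensor-product NURBS surfaces and the control-grid texture representation.

A tri-leaflet valve geometry is carried by three tensor-product NURBS patches.
Each patch is defined by an ``m x n`` grid of 3D control points (cm), positive
weights, open (clamped) knot vectors and polynomial degrees ``(p, q)``.  The
control grid doubles as the learning representation: stacking the x/y/z
coordinates as three channels of an ``m x n`` image ("texture") lets ordinary
convolutions act directly on the exact geometry, with no meshing or sampling
loss — this is the NURBS-aware convolution input.

Conventions (fixed because convolution semantics depend on them):

* parameter domain is ``[0, 1]^2``;
* grid axis 0 (size ``m``) runs along the circumferential parameter, axis 1
  (size ``n``) from the attachment edge to the free edge;
* texture channel order is ``(x, y, z)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotVector",
    "NurbsSurface",
    "ControlGridTensor",
    "open_uniform_knots",
    "basis_functions",
    "basis_matrix",
    "evaluate_surface",
    "surface_derivatives",
    "sample_surface",
    "surface_area",
    "to_texture",
    "from_texture",
    "surface_to_dict",
    "surface_from_dict",
    "save_surface_json",
    "load_surface_json",
    "export_vtk_polydata",
]


@dataclass(frozen=True)
class KnotVector:
    """Open (clamped) knot vector: first and last knots repeated degree+1 times."""

    values: np.ndarray
    degree: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        p = self.degree
        if p < 1:
            raise ValueError(f"degree must be >= 1, got {p}")
        if vals.ndim != 1 or len(vals) < 2 * (p + 1):
            raise ValueError("knot vector too short for degree")
        if np.any(np.diff(vals) < 0):
            raise ValueError("knot vector must be non-decreasing")
        if not (np.allclose(vals[: p + 1], vals[0]) and np.allclose(vals[-p - 1 :], vals[-1])):
            raise ValueError("knot vector must be clamped (open)")

    @property
    def n_basis(self) -> int:
        return len(self.values) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.values[self.degree]), float(self.values[-self.degree - 1])


def open_uniform_knots(n_ctrl: int, degree: int) -> KnotVector:
    """Clamped uniform knot vector on [0, 1] for ``n_ctrl`` basis functions."""
    if n_ctrl <= degree:
        raise ValueError(f"need n_ctrl > degree, got {n_ctrl} <= {degree}")
    n_int = n_ctrl - degree
    interior = np.linspace(0.0, 1.0, n_int + 1)[1:-1]
    vals = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
    return KnotVector(vals, degree)


def _check_range(kv: KnotVector, u: np.ndarray) -> None:
    lo, hi = kv.domain
    tol = 1e-12 * max(1.0, abs(hi - lo))
    if np.any(u < lo - tol) or np.any(u > hi + tol):
        raise ValueError(f"parameter outside knot range [{lo}, {hi}]")


def _bspline_table(t: np.ndarray, p: int, u: np.ndarray) -> np.ndarray:
    """All degree-``p`` B-spline basis values at ``u``; shape (len(u), len(t)-p-1).

    Vectorized bottom-up Cox–de Boor: seed the degree-0 indicator row (with the
    right end of the domain folded into the last non-empty span) and raise the
    degree, treating 0/0 terms as 0.
    """
    u = np.asarray(u, dtype=float)
    nu = len(u)
    n0 = len(t) - 1
    # span index of each u, clamped into the valid range so u == t[-1] lands
    # in the last non-empty span
    hi_span = np.searchsorted(t, t[-1], side="left") - 1
    lo_span = np.searchsorted(t, t[0], side="right") - 1
    span = np.clip(np.searchsorted(t, u, side="right") - 1, lo_span, hi_span)
    N = np.zeros((nu, n0))
    N[np.arange(nu), span] = 1.0
    for k in range(1, p + 1):
        nk = len(t) - k - 1
        left_den = t[k : k + nk] - t[:nk]
        right_den = t[k + 1 : k + 1 + nk] - t[1 : 1 + nk]
        with np.errstate(divide="ignore", invalid="ignore"):
            left = np.where(left_den > 0, (u[:, None] - t[:nk]) / left_den, 0.0)
            right = np.where(right_den > 0, (t[k + 1 : k + 1 + nk] - u[:, None]) / right_den, 0.0)
        N = left * N[:, :nk] + right * N[:, 1 : 1 + nk]
    return N


def basis_matrix(kv: KnotVector, u: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Matrix of the ``deriv``-th derivative of every basis function at ``u``.

    Shape ``(len(u), kv.n_basis)``.  ``deriv=0`` gives the values themselves.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    _check_range(kv, u)
    t, p = kv.values, kv.degree
    if deriv > p:
        return np.zeros((len(u), kv.n_basis))
    # start from the lower-degree table and differentiate up
    B = _bspline_table(t, p - deriv, u)
    for k in range(p - deriv + 1, p + 1):
        nk = len(t) - k - 1
        den_l = t[k : k + nk] - t[:nk]
        den_r = t[k + 1 : k + 1 + nk] - t[1 : 1 + nk]
        with np.errstate(divide="ignore", invalid="ignore"):
            term_l = np.where(den_l > 0, B[:, :nk] / den_l, 0.0)
            term_r = np.where(den_r > 0, B[:, 1 : 1 + nk] / den_r, 0.0)
        B = k * (term_l - term_r)
    return B


def basis_functions(kv: KnotVector, u: float) -> np.ndarray:
    """Values of all ``kv.n_basis`` basis functions at a single parameter."""
    return basis_matrix(kv, np.array([float(u)]))[0]


@dataclass(frozen=True)
class NurbsSurface:
    """Tensor-product NURBS patch.

    ``control_points`` has shape (m, n, 3) in cm, ``weights`` shape (m, n).
    """

    control_points: np.ndarray
    weights: np.ndarray
    knots_u: KnotVector
    knots_v: KnotVector
    name: str = "surface"

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "weights", w)
        if cp.ndim != 3 or cp.shape[2] != 3:
            raise ValueError("control_points must have shape (m, n, 3)")
        m, n = cp.shape[:2]
        if w.shape != (m, n):
            raise ValueError("weights shape must match control grid")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if self.knots_u.n_basis != m or self.knots_v.n_basis != n:
            raise ValueError("knot vectors inconsistent with control grid size")

    @property
    def shape(self) -> tuple[int, int]:
        return self.control_points.shape[:2]

    @property
    def degrees(self) -> tuple[int, int]:
        return self.knots_u.degree, self.knots_v.degree

    def with_control_points(self, cp: np.ndarray, name: str | None = None) -> "NurbsSurface":
        return NurbsSurface(cp, self.weights, self.knots_u, self.knots_v,
                            name if name is not None else self.name)


@dataclass(frozen=True)
class ControlGridTensor:
    """The m x n x 3 texture view of a control grid (channels = x, y, z)."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 3 or d.shape[2] != 3:
            raise ValueError("texture must have shape (m, n, 3)")


def to_texture(surface: NurbsSurface) -> ControlGridTensor:
    return ControlGridTensor(surface.control_points.copy(), provenance=surface.name)


def from_texture(tensor: ControlGridTensor, template: NurbsSurface) -> NurbsSurface:
    if tensor.data.shape != template.control_points.shape:
        raise ValueError(
            f"texture shape {tensor.data.shape} does not match template grid "
            f"{template.control_points.shape}"
        )
    return template.with_control_points(tensor.data.copy())


def _homogeneous_grid_eval(surface: NurbsSurface, Bu: np.ndarray, Bv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted numerator A (nu, nv, 3) and denominator W (nu, nv) for given basis matrices."""
    wc = surface.control_points * surface.weights[:, :, None]
    A = np.einsum("ui,ijc,vj->uvc", Bu, wc, Bv, optimize=True)
    W = Bu @ surface.weights @ Bv.T
    return A, W


def sample_surface(surface: NurbsSurface, xi: np.ndarray, eta: np.ndarray,
                   order: int = 0) -> dict[str, np.ndarray]:
    """Evaluate the surface (and optionally derivatives) on a tensor grid.

    Returns a dict with key "S" of shape (len(xi), len(eta), 3) and, for
    ``order >= 1``, "Su", "Sv"; for ``order == 2`` also "Suu", "Suv", "Svv".
    Derivatives are with respect to the parameters, by the rational quotient
    rule.
    """
    if order < 0 or order > 2:
        raise ValueError("order must be 0, 1 or 2")
    p, q = surface.degrees
    if order > min(p, q):
        raise ValueError(f"derivative order {order} exceeds degrees {surface.degrees}")
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    Bu = {d: basis_matrix(surface.knots_u, xi, d) for d in range(order + 1)}
    Bv = {d: basis_matrix(surface.knots_v, eta, d) for d in range(order + 1)}
    wc = surface.control_points * surface.weights[:, :, None]

    def num(a: int, b: int) -> np.ndarray:
        return np.einsum("ui,ijc,vj->uvc", Bu[a], wc, Bv[b], optimize=True)

    def den(a: int, b: int) -> np.ndarray:
        return Bu[a] @ surface.weights @ Bv[b].T

    W = den(0, 0)
    S = num(0, 0) / W[:, :, None]
    out = {"S": S}
    if order >= 1:
        Wu, Wv = den(1, 0), den(0, 1)
        Su = (num(1, 0) - Wu[:, :, None] * S) / W[:, :, None]
        Sv = (num(0, 1) - Wv[:, :, None] * S) / W[:, :, None]
        out.update(Su=Su, Sv=Sv)
    if order == 2:
        Wuu, Wuv, Wvv = den(2, 0), den(1, 1), den(0, 2)
        Suu = (num(2, 0) - 2 * Wu[:, :, None] * Su - Wuu[:, :, None] * S) / W[:, :, None]
        Svv = (num(0, 2) - 2 * Wv[:, :, None] * Sv - Wvv[:, :, None] * S) / W[:, :, None]
        Suv = (num(1, 1) - Wu[:, :, None] * Sv - Wv[:, :, None] * Su
               - Wuv[:, :, None] * S) / W[:, :, None]
        out.update(Suu=Suu, Suv=Suv, Svv=Svv)
    return out


def evaluate_surface(surface: NurbsSurface, xi: float, eta: float) -> np.ndarray:
    """Single rational surface point S(xi, eta), shape (3,), in cm."""
    return sample_surface(surface, [xi], [eta])["S"][0, 0]


def surface_derivatives(surface: NurbsSurface, xi: float, eta: float,
                        order: int = 1) -> dict[str, np.ndarray]:
    """Partial derivatives at one parameter point (keys Su, Sv[, Suu, Suv, Svv])."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    res = sample_surface(surface, [xi], [eta], order=order)
    return {k: v[0, 0] for k, v in res.items() if k != "S"}


def _span_breaks(kv: KnotVector) -> np.ndarray:
    lo, hi = kv.domain
    vals = kv.values
    interior = vals[(vals > lo) & (vals < hi)]
    return np.unique(np.concatenate([[lo], interior, [hi]]))


def gauss_parameters(kv: KnotVector, quad_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes and weights over every non-empty knot span."""
    if quad_order < 1:
        raise ValueError("quad_order must be >= 1")
    gx, gw = np.polynomial.legendre.leggauss(quad_order)
    breaks = _span_breaks(kv)
    nodes, weights = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        nodes.append(0.5 * (a + b) + half * gx)
        weights.append(half * gw)
    return np.concatenate(nodes), np.concatenate(weights)


def surface_area(surface: NurbsSurface, quad_order: int = 4) -> float:
    """Patch area (cm^2) by per-span Gauss–Legendre quadrature of |S_u x S_v|."""
    xu, wu = gauss_parameters(surface.knots_u, quad_order)
    xv, wv = gauss_parameters(surface.knots_v, quad_order)
    res = sample_surface(surface, xu, xv, order=1)
    jac = np.linalg.norm(np.cross(res["Su"], res["Sv"]), axis=-1)
    area = float(wu @ jac @ wv)
    if area <= 0.0:
        warnings.warn(f"degenerate surface {surface.name!r}: zero area", stacklevel=2)
        return 0.0
    return area


# ---------------------------------------------------------------------------
# serialization


def surface_to_dict(surface: NurbsSurface) -> dict:
    """JSON-ready dict. Control points row-major: axis 0 circumferential."""
    return {
        "degrees": list(surface.degrees),
        "knots_u": surface.knots_u.values.tolist(),
        "knots_v": surface.knots_v.values.tolist(),
        "weights": surface.weights.tolist(),
        "control_points": surface.control_points.tolist(),
        "units": "cm",
        "name": surface.name,
    }


def surface_from_dict(d: dict) -> NurbsSurface:
    p, q = d["degrees"]
    return NurbsSurface(
        np.asarray(d["control_points"], dtype=float),
        np.asarray(d["weights"], dtype=float),
        KnotVector(np.asarray(d["knots_u"], dtype=float), p),
        KnotVector(np.asarray(d["knots_v"], dtype=float), q),
        name=d.get("name", "surface"),
    )


def save_surface_json(surface: NurbsSurface, path) -> None:
    with open(path, "w") as fh:
        json.dump(surface_to_dict(surface), fh, indent=1)


def load_surface_json(path) -> NurbsSurface:
    with open(path) as fh:
        return surface_from_dict(json.load(fh))


def export_vtk_polydata(surfaces, path, samples: int = 30,
                        point_scalars: dict[str, list[np.ndarray]] | None = None) -> None:
    """Write legacy ASCII VTK PolyData of surfaces sampled on a parameter grid.

    ``surfaces`` is an iterable of NurbsSurface; each is sampled on a
    ``samples x samples`` grid and quadrilateral cells are emitted.
    ``point_scalars`` optionally maps a field name to one per-surface array of
    shape (samples, samples) sampled on the same grid.
    """
    surfaces = list(surfaces)
    pts, polys = [], []
    offset = 0
    for surf in surfaces:
        lo_u, hi_u = surf.knots_u.domain
        lo_v, hi_v = surf.knots_v.domain
        xi = np.linspace(lo_u, hi_u, samples)
        eta = np.linspace(lo_v, hi_v, samples)
        S = sample_surface(surf, xi, eta)["S"]
        pts.append(S.reshape(-1, 3))
        for i in range(samples - 1):
            for j in range(samples - 1):
                a = offset + i * samples + j
                polys.append((a, a + 1, a + samples + 1, a + samples))
        offset += samples * samples
    pts = np.vstack(pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvalvenet surfaces\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for x, y, z in pts:
            fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
        fh.write(f"POLYGONS {len(polys)} {5 * len(polys)}\n")
        for quad in polys:
            fh.write("4 " + " ".join(str(i) for i in quad) + "\n")
        if point_scalars:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for fname, arrays in point_scalars.items():
                vals = np.concatenate([np.asarray(a, dtype=float).reshape(-1) for a in arrays])
                if len(vals) != len(pts):
                    raise ValueError(f"scalar field {fname!r} length mismatch")
                fh.write(f"SCALARS {fname} float 1\nLOOKUP_TABLE default\n")
                for v in vals:
                    fh.write(f"{v:.6g}\n")
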