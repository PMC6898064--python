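"""Parametric tri-leaflet valve design.

A surgical bioprosthetic aortic valve is modeled as three identical NURBS
leaflets, each spanning a 120 degree sector around the valve (z) axis, sutured
to a rigid stent along its attachment edge.  Five parameters span the design
space:

``D``
    valve diameter in cm (population average 2.3 cm);
``belly``
    dimensionless belly-curve parameter in [0, 1]: how far the leaflet's belly
    sags radially inward toward the axis;
``free_edge``
    dimensionless free-edge curve parameter in [0, 1]: dip of the free edge
    below the commissures;
``free_edge_height``
    height of the free-edge midline above the annulus, cm;
``commissure_height``
    height of the commissure posts, cm.

Each parameter has a monotone, localized geometric effect, so downstream
latent-space analyses (parameter sweeps, embedding colorings) are meaningful.
Leaflet 0 occupies the angular sector [-60, 60] degrees; leaflets 1 and 2 are
exact rotations by 120 and 240 degrees.  The stent is modeled purely as the
fixed attachment boundary: control points on grid edges i=0, i=m-1 (the
commissure sides) and j=0 (the annulus) are pinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .nurbs import KnotVector, NurbsSurface, open_uniform_knots

__all__ = [
    "ValveDesignParams",
    "ValveGeometry",
    "build_leaflet",
    "build_valve",
    "rotation_z",
    "sample_design_space",
    "DEFAULT_DESIGN_RANGES",
]

#: Default sampling ranges for the geometric design space.  Diameter and
#: heights are anchored to the 2.3 cm average valve diameter.
DEFAULT_DESIGN_RANGES: dict[str, tuple[float, float]] = {
    "diameter": (2.3, 2.3),
    "belly": (0.0, 1.0),
    "free_edge": (0.0, 1.0),
    "free_edge_height": (0.6, 1.2),
    "commissure_height": (1.2, 1.2),
}


@dataclass(frozen=True)
class ValveDesignParams:
    diameter: float = 2.3
    belly: float = 0.5
    free_edge: float = 0.5
    free_edge_height: float = 0.9
    commissure_height: float = 1.2

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not (0.0 <= self.belly <= 1.0 and 0.0 <= self.free_edge <= 1.0):
            raise ValueError("belly and free_edge must lie in [0, 1]")
        if not (0.0 < self.free_edge_height <= self.commissure_height):
            raise ValueError("need 0 < free_edge_height <= commissure_height")

    def as_array(self) -> np.ndarray:
        return np.array([self.diameter, self.belly, self.free_edge,
                         self.free_edge_height, self.commissure_height])

    FIELDS = ("diameter", "belly", "free_edge", "free_edge_height", "commissure_height")

    @classmethod
    def from_array(cls, a) -> "ValveDesignParams":
        return cls(*(float(x) for x in a))


def rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _leaflet_control_grid(params: ValveDesignParams, m: int, n: int) -> np.ndarray:
    """Control grid of the reference (unrotated) leaflet, shape (m, n, 3).

    Axis 0 sweeps the circumferential angle phi_i from -60 to +60 degrees;
    axis 1 goes from the attachment (annulus) row j=0 to the free edge j=n-1.
    The radial coordinate sags inward with the belly parameter, maximally at
    mid-leaflet and at the free edge; the height blends linearly from the
    attachment scallop to the free-edge curve.
    """
    R = params.diameter / 2.0
    b, f = params.belly, params.free_edge
    h, Hc = params.free_edge_height, params.commissure_height
    i = np.arange(m)[:, None]
    j = np.arange(n)[None, :]
    s = i / (m - 1)              # circumferential fraction in [0, 1]
    v = j / (n - 1)              # attachment-to-free-edge fraction
    phi = -np.pi / 3 + 2 * np.pi / 3 * s
    bump = np.sin(np.pi * s)     # 0 at commissures, 1 at mid-leaflet
    r = R * (1.0 - b * bump * v)
    z_att = Hc * (1.0 - bump * (1.0 - h / Hc))
    z_free = h * (1.0 - f * (1.0 - np.abs(2 * s - 1.0)) * 0.2)
    z = z_att * (1.0 - v) + z_free * v
    cp = np.empty((m, n, 3))
    cp[:, :, 0] = r * np.cos(phi)
    cp[:, :, 1] = r * np.sin(phi)
    cp[:, :, 2] = z + 0 * r      # broadcast to (m, n)
    return cp


def build_leaflet(params: ValveDesignParams, grid: tuple[int, int] = (8, 8),
                  degrees: tuple[int, int] = (3, 3)) -> NurbsSurface:
    """Reference leaflet NURBS patch (unit weights, open uniform knots)."""
    m, n = grid
    p, q = degrees
    if m < p + 1 or n < q + 1:
        raise ValueError(f"grid {grid} too small for degrees {degrees}")
    if m < 4 or n < 4:
        raise ValueError("grid must be at least 4 x 4")
    cp = _leaflet_control_grid(params, m, n)
    return NurbsSurface(cp, np.ones((m, n)), open_uniform_knots(m, p),
                        open_uniform_knots(n, q), name="leaflet0")


@dataclass(frozen=True)
class ValveGeometry:
    """Reference (undeformed) valve: three leaflets plus the fixed-edge mask.

    Leaflet k equals leaflet 0 rotated by 2*pi*k/3 about the z axis.
    ``fixed_mask`` is True exactly on attachment-edge control points
    (grid edges i=0, i=m-1 and j=0), shared by all three leaflets.
    """

    leaflets: tuple[NurbsSurface, NurbsSurface, NurbsSurface]
    params: ValveDesignParams
    fixed_mask: np.ndarray

    @property
    def grid(self) -> tuple[int, int]:
        return self.leaflets[0].shape

    def textures(self) -> np.ndarray:
        """Stacked control grids, shape (3, m, n, 3)."""
        return np.stack([lf.control_points for lf in self.leaflets])

    def rotated(self, k: int) -> "ValveGeometry":
        """The same valve rotated by 2*pi*k/3 with leaflets relabeled to match."""
        Rz = rotation_z(2 * np.pi * k / 3)
        leaflets = tuple(
            self.leaflets[(idx - k) % 3].with_control_points(
                self.leaflets[(idx - k) % 3].control_points @ Rz.T,
                name=f"leaflet{idx}")
            for idx in range(3)
        )
        return ValveGeometry(leaflets, self.params, self.fixed_mask)


def build_valve(params: ValveDesignParams, grid: tuple[int, int] = (8, 8),
                degrees: tuple[int, int] = (3, 3)) -> ValveGeometry:
    base = build_leaflet(params, grid, degrees)
    leaflets = []
    for k in range(3):
        Rz = rotation_z(2 * np.pi * k / 3)
        leaflets.append(base.with_control_points(base.control_points @ Rz.T,
                                                 name=f"leaflet{k}"))
    m, n = grid
    mask = np.zeros((m, n), dtype=bool)
    mask[0, :] = mask[-1, :] = True
    mask[:, 0] = True
    return ValveGeometry(tuple(leaflets), params, mask)


def sample_design_space(ranges: dict[str, tuple[float, float]] | None = None,
                        n: int = 1, seed: int = 0,
                        method: str = "lhs") -> list[ValveDesignParams]:
    """Reproducible Latin-hypercube (or uniform) samples of the design space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    full = dict(DEFAULT_DESIGN_RANGES)
    if ranges:
        unknown = set(ranges) - set(full)
        if unknown:
            raise ValueError(f"unknown design parameters: {sorted(unknown)}")
        full.update(ranges)
    lo = np.array([full[k][0] for k in ValveDesignParams.FIELDS])
    hi = np.array([full[k][1] for k in ValveDesignParams.FIELDS])
    if np.any(hi < lo):
        raise ValueError("empty parameter interval")
    if method == "lhs":
        unit = qmc.LatinHypercube(d=len(lo), seed=seed).random(n)
    elif method == "uniform":
        unit = np.random.default_rng(seed).uniform(size=(n, len(lo)))
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    samples = lo + unit * (hi - lo)
    return [ValveDesignParams.from_array(row) for row in samples]
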