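"""Surrogate valve-closure simulator and training-set generation.

This module is a deterministic, fast stand-in for a shell finite-element /
isogeometric valve-closure analysis.  It is NOT a mechanical model: it is a
closed-form displacement law engineered to reproduce the structural features
the learning task depends on, with known ground truth:

* zero displacement on the fixed attachment edges (the sutured stent);
* exact 3-fold rotational symmetry / equivariance;
* displacement magnitude increasing with transvalvular pressure and
  decreasing with effective tissue stiffness x thickness, with a smooth
  saturating response;
* leaflets that never cross the valve axis nor leave their 120 degree sector
  (no interpenetration);
* a coaptation area (cm^2) that grows as the leaflets press toward the
  sector-boundary planes where neighbors meet.

The displacement law: every control point at reference radius r moves radially
inward by

    dr = g(i, j) * S(L) * rho * r,        S(L) = L / (L + L0),

where ``g(i,j) = sin(pi i/(m-1)) * j/(n-1)`` is a modal envelope vanishing on
all attachment edges, ``L = p R / (k_eff t)`` is a dimensionless load with
``k_eff = c0 + c1 c2``, and ``rho < 1`` prevents axis crossing.  Angles and
heights are unchanged, which makes the no-interpenetration and symmetry
properties exact.  A smooth multiplicative perturbation field (amplitude
``noise``) seeded per sample keeps the learning task non-degenerate.  The
interface is the only contract: a real shell solver could be substituted
behind :func:`simulate_closure` without touching the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import h5py
import numpy as np

from .design import (DEFAULT_DESIGN_RANGES, ValveDesignParams, ValveGeometry,
                     build_valve, sample_design_space)
from .nurbs import KnotVector, NurbsSurface, basis_matrix

__all__ = [
    "MaterialProperties",
    "SimulationCondition",
    "DeformedValve",
    "SimulationSample",
    "ValveDataset",
    "simulate_closure",
    "compute_coaptation_area",
    "coaptation_from_displacements",
    "generate_dataset",
    "DEFAULT_MATERIAL_RANGES",
    "DEFAULT_PRESSURE_RANGE",
    "LOAD_SCALE",
    "CONTRACTION_LIMIT",
    "COAPTATION_EPS",
    "MOTION_THRESHOLD",
    "NOISE_AMPLITUDE",
]

#: Saturation constant L0 of the load response (absorbs the mmHg unit).
LOAD_SCALE = 1.0
#: Maximum radial contraction fraction rho; < 1 so no point reaches the axis.
CONTRACTION_LIMIT = 0.95
#: Proximity threshold eps (cm) to a sector-boundary plane for coaptation.
COAPTATION_EPS = 0.05
#: Displacement-magnitude threshold u_c (cm) excluding undisplaced points.
MOTION_THRESHOLD = 0.01
#: Amplitude of the smooth multiplicative perturbation of dr.
NOISE_AMPLITUDE = 0.02

#: Material coefficient ranges (model-scale stiffness units) and leaflet
#: thickness (cm).  Chosen once so that the dimensionless load L spans roughly
#: 1-14 over the corpus, i.e. the saturation S covers 0.5-0.93 and peak
#: displacements are comparable to the sub-centimeter closure displacements of
#: a 2.3 cm valve.
DEFAULT_MATERIAL_RANGES: dict[str, tuple[float, float]] = {
    "c0": (200.0, 600.0),
    "c1": (100.0, 300.0),
    "c2": (0.5, 1.5),
    "thickness": (0.03, 0.07),
}
#: Physiological diastolic transvalvular pressure range, mmHg.
DEFAULT_PRESSURE_RANGE: tuple[float, float] = (70.0, 90.0)


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic leaflet material: coefficients c0, c1, c2 and thickness (cm)."""

    c0: float
    c1: float
    c2: float
    thickness: float

    def __post_init__(self) -> None:
        if min(self.c0, self.c1, self.c2, self.thickness) <= 0:
            raise ValueError("material coefficients and thickness must be positive")

    @property
    def k_eff(self) -> float:
        """Effective stiffness c0 + c1*c2 entering the load."""
        return self.c0 + self.c1 * self.c2

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2, self.thickness])


@dataclass(frozen=True)
class SimulationCondition:
    """Quasi-static closure condition: uniform transvalvular pressure, mmHg."""

    pressure: float

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")


@dataclass(frozen=True)
class DeformedValve:
    """Closed-valve configuration: displacement grids plus coaptation area."""

    valve: ValveGeometry
    displacements: np.ndarray  # (3, m, n, 3), cm
    coaptation_area: float     # cm^2
    material: MaterialProperties | None = None
    condition: SimulationCondition | None = None

    def deformed_leaflets(self) -> list[NurbsSurface]:
        return [
            lf.with_control_points(lf.control_points + self.displacements[k])
            for k, lf in enumerate(self.valve.leaflets)
        ]


@dataclass(frozen=True)
class SimulationSample:
    """One training record.  Design parameters are metadata only — they are
    never fed to the network."""

    reference: np.ndarray      # (3, m, n, 3) leaflet textures, cm
    pressure: float            # mmHg
    material: np.ndarray       # (c0, c1, c2, thickness)
    displacement: np.ndarray   # (3, m, n, 3), cm
    coaptation_area: float     # cm^2
    design_params: np.ndarray  # (5,) metadata


def _smooth_noise_field(shape: tuple[int, int], rng: np.random.Generator,
                        coarse: int = 3) -> np.ndarray:
    """Smooth field in [-1, 1]: bilinear upsampling of a coarse uniform grid."""
    m, n = shape
    coarse_field = rng.uniform(-1.0, 1.0, size=(coarse, coarse))
    xi = np.linspace(0, coarse - 1, m)
    eta = np.linspace(0, coarse - 1, n)
    i0 = np.clip(xi.astype(int), 0, coarse - 2)
    j0 = np.clip(eta.astype(int), 0, coarse - 2)
    fx = (xi - i0)[:, None]
    fy = (eta - j0)[None, :]
    c00 = coarse_field[i0][:, j0]
    c10 = coarse_field[i0 + 1][:, j0]
    c01 = coarse_field[i0][:, j0 + 1]
    c11 = coarse_field[i0 + 1][:, j0 + 1]
    return (c00 * (1 - fx) * (1 - fy) + c10 * fx * (1 - fy)
            + c01 * (1 - fx) * fy + c11 * fx * fy)


def load_saturation(pressure: float, material: MaterialProperties,
                    radius: float) -> float:
    """Saturated dimensionless load S(L) = L/(L+L0), L = p R/(k_eff t)."""
    load = pressure * radius / (material.k_eff * material.thickness)
    return load / (load + LOAD_SCALE)


def simulate_closure(valve: ValveGeometry, material: MaterialProperties,
                     condition: SimulationCondition,
                     noise_seed: int | None = None,
                     noise_amplitude: float = NOISE_AMPLITUDE,
                     coaptation_grid: tuple[int, int] = (480, 36)) -> DeformedValve:
    """Deform a valve to its closed state under pressure.

    With ``noise_seed`` set, a smooth multiplicative perturbation field (one
    field per sample, shared by the three leaflets so exact symmetry is kept)
    scales the radial contraction by ``1 + noise_amplitude * field``.
    """
    if condition.pressure <= 0 or material.thickness <= 0:
        raise ValueError("non-physical simulation inputs")
    m, n = valve.grid
    R = valve.params.diameter / 2.0
    sat = load_saturation(condition.pressure, material, R)
    s = np.arange(m)[:, None] / (m - 1)
    v = np.arange(n)[None, :] / (n - 1)
    envelope = np.sin(np.pi * s) * v
    factor = envelope * sat * CONTRACTION_LIMIT
    if noise_seed is not None and noise_amplitude > 0:
        rng = np.random.default_rng(noise_seed)
        factor = factor * (1.0 + noise_amplitude * _smooth_noise_field((m, n), rng))
    displacements = np.zeros((3, m, n, 3))
    for k, leaflet in enumerate(valve.leaflets):
        cp = leaflet.control_points
        # radial contraction: dr = factor * r, angle and height unchanged
        displacements[k, :, :, 0] = -factor * cp[:, :, 0]
        displacements[k, :, :, 1] = -factor * cp[:, :, 1]
    displacements[:, valve.fixed_mask, :] = 0.0  # exact zeros on the stent
    deformed = DeformedValve(valve, displacements, 0.0, material, condition)
    area = compute_coaptation_area(deformed, sampling=coaptation_grid)
    return DeformedValve(valve, displacements, area, material, condition)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@lru_cache(maxsize=32)
def _cached_basis(knots_bytes: bytes, degree: int, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    kv = KnotVector(np.frombuffer(knots_bytes), degree)
    lo, hi = kv.domain
    pts = lo + (hi - lo) * (np.arange(n_samples) + 0.5) / n_samples
    return basis_matrix(kv, pts, 0), basis_matrix(kv, pts, 1)


def _leaflet_fields(surface: NurbsSurface, n_u: int, n_v: int):
    """Positions and first derivatives on the midpoint sampling grid."""
    Bu0, Bu1 = _cached_basis(surface.knots_u.values.tobytes(), surface.knots_u.degree, n_u)
    Bv0, Bv1 = _cached_basis(surface.knots_v.values.tobytes(), surface.knots_v.degree, n_v)
    cp = surface.control_points
    # unit weights for generated leaflets: plain B-spline tensor contraction
    if np.allclose(surface.weights, 1.0):
        S = np.einsum("ui,ijc,vj->uvc", Bu0, cp, Bv0, optimize=True)
        Su = np.einsum("ui,ijc,vj->uvc", Bu1, cp, Bv0, optimize=True)
        Sv = np.einsum("ui,ijc,vj->uvc", Bu0, cp, Bv1, optimize=True)
        return S, Su, Sv
    from .nurbs import sample_surface
    lo_u, hi_u = surface.knots_u.domain
    lo_v, hi_v = surface.knots_v.domain
    xi = lo_u + (hi_u - lo_u) * (np.arange(n_u) + 0.5) / n_u
    eta = lo_v + (hi_v - lo_v) * (np.arange(n_v) + 0.5) / n_v
    res = sample_surface(surface, xi, eta, order=1)
    return res["S"], res["Su"], res["Sv"]


def compute_coaptation_area(deformed: DeformedValve,
                            eps: float = COAPTATION_EPS,
                            motion_threshold: float = MOTION_THRESHOLD,
                            sampling: tuple[int, int] = (480, 36)) -> float:
    """Coaptation area (cm^2) of a closed valve.

    Integrates the deformed-surface area measure over surface samples that lie
    within ``eps`` of either of the leaflet's two sector-boundary half-planes
    (the planes through the valve axis where neighboring leaflets meet) and
    whose displacement magnitude exceeds ``motion_threshold`` (excluding
    undisplaced attachment/commissure points).  Counted one-sided per leaflet
    and summed over the three leaflets.

    Both windows are C1 smoothstep ramps (widths 0.2*eps and
    0.2*motion_threshold) rather than hard indicators, so on a fixed
    quadrature grid the area responds smoothly and monotonically to the load.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    n_u, n_v = sampling
    if n_u < 1 or n_v < 1:
        raise ValueError("sampling grid must be non-empty")
    w_d = 0.2 * eps
    w_u = 0.2 * motion_threshold
    total = 0.0
    for k, ref_leaflet in enumerate(deformed.valve.leaflets):
        def_leaflet = ref_leaflet.with_control_points(
            ref_leaflet.control_points + deformed.displacements[k])
        S_ref, _, _ = _leaflet_fields(ref_leaflet, n_u, n_v)
        S_def, Su, Sv = _leaflet_fields(def_leaflet, n_u, n_v)
        disp_mag = np.linalg.norm(S_def - S_ref, axis=-1)
        r = np.hypot(S_def[:, :, 0], S_def[:, :, 1])
        phi = np.arctan2(S_def[:, :, 1], S_def[:, :, 0])
        center = 2.0 * np.pi * k / 3.0
        d1 = r * np.abs(np.sin(phi - (center - np.pi / 3.0)))
        d2 = r * np.abs(np.sin(phi - (center + np.pi / 3.0)))
        dist = np.minimum(d1, d2)
        w_near = _smoothstep((eps - dist) / w_d)
        w_moved = _smoothstep((disp_mag - (motion_threshold - w_u)) / w_u)
        dA = np.linalg.norm(np.cross(Su, Sv), axis=-1) / (n_u * n_v)
        total += float(np.sum(w_near * w_moved * dA))
    return total


def coaptation_from_displacements(valve: ValveGeometry, displacements: np.ndarray,
                                  **kwargs) -> float:
    """Re-measure coaptation area from (possibly predicted) displacement grids."""
    return compute_coaptation_area(DeformedValve(valve, np.asarray(displacements, float), 0.0),
                                   **kwargs)


# ---------------------------------------------------------------------------
# dataset generation

SCHEMA_VERSION = "1.0"


class ValveDataset:
    """In-memory training corpus with the HDF5 schema used on disk.

    Arrays: reference (N,3,m,n,3), pressure (N,), material (N,4),
    displacement (N,3,m,n,3), coaptation (N,), design_params (N,5).
    """

    def __init__(self, reference, pressure, material, displacement, coaptation,
                 design_params, grid: tuple[int, int], degrees=(3, 3), seed=0):
        self.reference = np.asarray(reference, dtype=float)
        self.pressure = np.asarray(pressure, dtype=float)
        self.material = np.asarray(material, dtype=float)
        self.displacement = np.asarray(displacement, dtype=float)
        self.coaptation = np.asarray(coaptation, dtype=float)
        self.design_params = np.asarray(design_params, dtype=float)
        self.grid = tuple(grid)
        self.degrees = tuple(degrees)
        self.seed = int(seed)
        n = len(self.pressure)
        for arr in (self.reference, self.material, self.displacement,
                    self.coaptation, self.design_params):
            if len(arr) != n:
                raise ValueError("inconsistent dataset array lengths")

    def __len__(self) -> int:
        return len(self.pressure)

    def __getitem__(self, idx: int) -> SimulationSample:
        return SimulationSample(
            reference=self.reference[idx], pressure=float(self.pressure[idx]),
            material=self.material[idx], displacement=self.displacement[idx],
            coaptation_area=float(self.coaptation[idx]),
            design_params=self.design_params[idx])

    def valve_at(self, idx: int) -> ValveGeometry:
        return build_valve(ValveDesignParams.from_array(self.design_params[idx]),
                           grid=self.grid, degrees=self.degrees)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("inputs/reference", data=self.reference)
            fh.create_dataset("inputs/pressure", data=self.pressure)
            fh.create_dataset("inputs/material", data=self.material)
            fh.create_dataset("targets/displacement", data=self.displacement)
            fh.create_dataset("targets/coaptation", data=self.coaptation)
            fh.create_dataset("meta/design_params", data=self.design_params)
            fh.attrs["schema_version"] = SCHEMA_VERSION
            fh.attrs["units_length"] = "cm"
            fh.attrs["units_pressure"] = "mmHg"
            fh.attrs["seed"] = self.seed
            fh.attrs["grid"] = self.grid
            fh.attrs["degrees"] = self.degrees

    @classmethod
    def load(cls, path) -> "ValveDataset":
        with h5py.File(path, "r") as fh:
            return cls(
                fh["inputs/reference"][:], fh["inputs/pressure"][:],
                fh["inputs/material"][:], fh["targets/displacement"][:],
                fh["targets/coaptation"][:], fh["meta/design_params"][:],
                grid=tuple(int(x) for x in fh.attrs["grid"]),
                degrees=tuple(int(x) for x in fh.attrs["degrees"]),
                seed=int(fh.attrs["seed"]))


def generate_dataset(n: int, seed: int = 0,
                     design_ranges: dict | None = None,
                     material_ranges: dict | None = None,
                     pressure_range: tuple[float, float] = DEFAULT_PRESSURE_RANGE,
                     grid: tuple[int, int] = (8, 8), degrees=(3, 3),
                     noise_amplitude: float = NOISE_AMPLITUDE,
                     coaptation_grid: tuple[int, int] = (480, 36),
                     out=None) -> ValveDataset:
    """Generate ``n`` closure simulations spanning geometry, material and
    pressure ranges; fully reproducible from ``seed``.

    Design parameters are Latin-hypercube sampled; materials and pressure are
    Latin-hypercube sampled jointly; each sample gets its own perturbation
    seed.  With ``out`` set, the corpus is also written as HDF5.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    s_design, s_mat, s_noise = (int(c.generate_state(1)[0] % (2**31))
                                for c in ss.spawn(3))
    designs = sample_design_space(design_ranges, n=n, seed=s_design)

    from scipy.stats import qmc
    mat_full = dict(DEFAULT_MATERIAL_RANGES)
    if material_ranges:
        unknown = set(material_ranges) - set(mat_full)
        if unknown:
            raise ValueError(f"unknown material parameters: {sorted(unknown)}")
        mat_full.update(material_ranges)
    keys = ("c0", "c1", "c2", "thickness")
    lo = np.array([mat_full[k][0] for k in keys] + [pressure_range[0]])
    hi = np.array([mat_full[k][1] for k in keys] + [pressure_range[1]])
    if np.any(hi < lo):
        raise ValueError("empty material/pressure interval")
    unit = qmc.LatinHypercube(d=5, seed=s_mat).random(n)
    mat_press = lo + unit * (hi - lo)
    noise_seeds = np.random.default_rng(s_noise).integers(0, 2**31, size=n)

    m, nn = grid
    reference = np.empty((n, 3, m, nn, 3))
    displacement = np.empty((n, 3, m, nn, 3))
    pressure = np.empty(n)
    material = np.empty((n, 4))
    coaptation = np.empty(n)
    design_arr = np.empty((n, 5))
    for idx, params in enumerate(designs):
        valve = build_valve(params, grid=grid, degrees=degrees)
        mat = MaterialProperties(*mat_press[idx, :4])
        cond = SimulationCondition(pressure=float(mat_press[idx, 4]))
        deformed = simulate_closure(valve, mat, cond,
                                    noise_seed=int(noise_seeds[idx]),
                                    noise_amplitude=noise_amplitude,
                                    coaptation_grid=coaptation_grid)
        reference[idx] = valve.textures()
        displacement[idx] = deformed.displacements
        pressure[idx] = cond.pressure
        material[idx] = mat.as_array()
        coaptation[idx] = deformed.coaptation_area
        design_arr[idx] = params.as_array()
    ds = ValveDataset(reference, pressure, material, displacement, coaptation,
                      design_arr, grid=grid, degrees=degrees, seed=seed)
    if out is not None:
        ds.save(out)
    return ds
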