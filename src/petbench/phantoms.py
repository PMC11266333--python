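"""NEMA phantoms as geometric primitives with materials and activity.

A :class:`PhantomModel` is an ordered list of primitives (cylinder,
sphere, annulus, box); later primitives override earlier ones where they
overlap (priority = list order).  Cylinders and annuli are axis-aligned
with the scanner axis (z); boxes are axis-aligned.  Activity
concentrations are in Bq/mL; all lengths in mm (1 mL = 1000 mm^3).

NEMA dimensions that the performance standard fixes but which are easy
to get wrong are annotated where they appear: the scatter-phantom line
bore sits 45 mm below the cylinder axis, the IEC body phantom spheres
(10-37 mm diameters) sit on a 114.4-mm-diameter circle, and the lung
insert is a 50-mm-diameter low-density cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .materials import Material, get_material

__all__ = [
    "Primitive",
    "PhantomModel",
    "MuMap",
    "make_sensitivity_phantom",
    "make_scatter_phantom",
    "make_iq_phantom",
    "make_point_sources",
    "make_annulus_source",
    "make_flood_source",
    "rasterise_mumap",
    "IQ_SPHERE_DIAMETERS_MM",
]

IQ_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
_IQ_SPHERE_RING_RADIUS_MM = 57.2  # spheres on a 114.4-mm-diameter circle
_LUNG_INSERT_RADIUS_MM = 25.0


@dataclass(frozen=True)
class Primitive:
    """One homogeneous solid: shape + pose + material + activity."""

    shape: str                      # cylinder | sphere | annulus | box
    centre: tuple[float, float, float]
    material: Material
    activity_bq_ml: float = 0.0
    radius: float = 0.0             # sphere / cylinder outer radius
    inner_radius: float = 0.0       # annulus only
    length: float = 0.0             # cylinder / annulus (along z)
    size: tuple[float, float, float] = (0.0, 0.0, 0.0)  # box full extents

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere", "annulus", "box"):
            raise ConfigurationError(f"unknown primitive shape {self.shape!r}")
        if self.activity_bq_ml < 0:
            raise ConfigurationError("activity_bq_ml must be >= 0")
        if self.shape == "annulus" and not 0 <= self.inner_radius < self.radius:
            raise ConfigurationError("annulus requires 0 <= inner_radius < radius")

    # -- geometry ---------------------------------------------------------
    @property
    def volume_ml(self) -> float:
        if self.shape == "sphere":
            v = 4.0 / 3.0 * np.pi * self.radius**3
        elif self.shape == "cylinder":
            v = np.pi * self.radius**2 * self.length
        elif self.shape == "annulus":
            v = np.pi * (self.radius**2 - self.inner_radius**2) * self.length
        else:
            v = float(np.prod(self.size))
        return v / 1000.0  # mm^3 -> mL

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask for points (N, 3) inside the solid."""
        p = pts - np.asarray(self.centre)
        if self.shape == "sphere":
            return np.einsum("ij,ij->i", p, p) <= self.radius**2
        if self.shape == "box":
            h = np.asarray(self.size) / 2.0
            return np.all(np.abs(p) <= h, axis=1)
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        in_z = np.abs(p[:, 2]) <= self.length / 2.0
        if self.shape == "cylinder":
            return (r2 <= self.radius**2) & in_z
        return (r2 <= self.radius**2) & (r2 >= self.inner_radius**2) & in_z

    def ray_intervals(self, origins: np.ndarray, dirs: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Entry/exit parameters of rays with the solid.

        Returns a list of (t0, t1) array pairs (each shape (N,)); empty
        intersections are encoded as t0 > t1.  An annulus may produce two
        intervals per ray.
        """
        o = origins - np.asarray(self.centre)
        d = dirs
        if self.shape == "sphere":
            return [_sphere_interval(o, d, self.radius)]
        if self.shape == "box":
            return [_box_interval(o, d, np.asarray(self.size) / 2.0)]
        outer = _cyl_interval(o, d, self.radius, self.length)
        if self.shape == "cylinder":
            return [outer]
        inner = _cyl_interval(o, d, self.inner_radius, self.length)
        # shell = outer minus inner: up to two sub-intervals
        t0, t1 = outer
        i0, i1 = inner
        has_inner = i0 <= i1
        a0, a1 = t0, np.where(has_inner, np.minimum(t1, i0), t1)
        b0, b1 = np.where(has_inner, np.maximum(t0, i1), 1.0), np.where(has_inner, t1, 0.0)
        return [(a0, a1), (b0, b1)]


_EMPTY = (np.inf, -np.inf)


def _sphere_interval(o, d, r):
    b = np.einsum("ij,ij->i", o, d)
    c = np.einsum("ij,ij->i", o, o) - r * r
    disc = b * b - c
    ok = disc >= 0
    s = np.sqrt(np.where(ok, disc, 0.0))
    t0 = np.where(ok, -b - s, np.inf)
    t1 = np.where(ok, -b + s, -np.inf)
    return t0, t1


def _slab(o1, d1, half):
    """1D slab [-half, half]: interval of t, degenerate dirs handled."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-half - o1) / d1
        tb = (half - o1) / d1
    lo = np.minimum(ta, tb)
    hi = np.maximum(ta, tb)
    parallel = np.abs(d1) < 1e-12
    inside = np.abs(o1) <= half
    lo = np.where(parallel, np.where(inside, -np.inf, np.inf), lo)
    hi = np.where(parallel, np.where(inside, np.inf, -np.inf), hi)
    return lo, hi


def _cyl_interval(o, d, r, length):
    if r <= 0:
        n = len(o)
        return np.full(n, np.inf), np.full(n, -np.inf)
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1]
    c = o[:, 0] ** 2 + o[:, 1] ** 2 - r * r
    axial = a < 1e-16
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - a * c
        ok = (disc >= 0) & ~axial
        s = np.sqrt(np.where(disc > 0, disc, 0.0))
        lo = np.where(ok, (-b - s) / a, np.where(axial & (c <= 0), -np.inf, np.inf))
        hi = np.where(ok, (-b + s) / a, np.where(axial & (c <= 0), np.inf, -np.inf))
    zlo, zhi = _slab(o[:, 2], d[:, 2], length / 2.0)
    return np.maximum(lo, zlo), np.minimum(hi, zhi)


def _box_interval(o, d, half):
    lo = np.full(len(o), -np.inf)
    hi = np.full(len(o), np.inf)
    for ax in range(3):
        l, h = _slab(o[:, ax], d[:, ax], half[ax])
        lo = np.maximum(lo, l)
        hi = np.minimum(hi, h)
    return lo, hi


@dataclass
class PhantomModel:
    """Ordered primitives; later entries take priority in overlaps."""

    primitives: list[Primitive] = field(default_factory=list)
    name: str = "phantom"

    @property
    def active_primitives(self) -> list[Primitive]:
        return [p for p in self.primitives if p.activity_bq_ml > 0]

    @property
    def total_activity_bq(self) -> float:
        """Sum of concentration x volume over primitives (overlaps ignored)."""
        return sum(p.activity_bq_ml * p.volume_ml for p in self.primitives)

    def mu_at(self, pts: np.ndarray, background_mu: float = 0.0) -> np.ndarray:
        """511-keV mu (mm^-1) at points (N, 3).

        Outside every primitive the transport background is vacuum
        (``background_mu = 0``): ambient air attenuates 511-keV photons by
        < 0.5% over the bore and is neglected unless an explicit air
        primitive is added.  Attenuation-map rasterisation passes the air
        coefficient instead.
        """
        mu = np.full(len(pts), background_mu, dtype=float)
        for p in self.primitives:  # later overrides earlier
            mask = p.contains(pts)
            mu[mask] = p.material.mu_511_mm
        return mu

    def material_index_at(self, pts: np.ndarray) -> np.ndarray:
        """Index into ``primitives`` of the governing primitive (-1 = air)."""
        idx = np.full(len(pts), -1, dtype=np.int64)
        for i, p in enumerate(self.primitives):
            idx[p.contains(pts)] = i
        return idx

    def activity_at(self, pts: np.ndarray) -> np.ndarray:
        act = np.zeros(len(pts))
        for p in self.primitives:
            mask = p.contains(pts)
            act[mask] = p.activity_bq_ml
        return act

    def sample_emission_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform positions within active primitives, weighted by
        concentration x volume."""
        active = self.active_primitives
        if not active or n == 0:
            return np.zeros((0, 3))
        weights = np.array([p.activity_bq_ml * p.volume_ml for p in active])
        counts = rng.multinomial(n, weights / weights.sum())
        parts = [_sample_in_primitive(p, k, rng) for p, k in zip(active, counts) if k]
        return np.concatenate(parts) if parts else np.zeros((0, 3))


def _sample_in_primitive(p: Primitive, n: int, rng: np.random.Generator) -> np.ndarray:
    c = np.asarray(p.centre)
    if p.shape == "sphere":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = p.radius * rng.random(n) ** (1.0 / 3.0)
        return c + v * r[:, None]
    if p.shape == "box":
        return c + (rng.random((n, 3)) - 0.5) * np.asarray(p.size)
    # cylinder / annulus: uniform in the (possibly hollow) disc x z
    r2 = rng.uniform(p.inner_radius**2 if p.shape == "annulus" else 0.0,
                     p.radius**2, n)
    r = np.sqrt(r2)
    th = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-p.length / 2.0, p.length / 2.0, n)
    return c + np.column_stack([r * np.cos(th), r * np.sin(th), z])


# ---------------------------------------------------------------------------
# NEMA phantom factories
# ---------------------------------------------------------------------------

def make_sensitivity_phantom(n_sleeves: int, activity_bq: float,
                             radial_offset_mm: float = 0.0) -> PhantomModel:
    """700-mm line source (1 mm ID) in 1..5 concentric 1.25-mm Al sleeves.

    The innermost sleeve has a 3.9-mm inner diameter; each further sleeve
    slides over the previous one, adding 1.25 mm of aluminium wall.
    """
    if not 1 <= n_sleeves <= 5:
        raise ConfigurationError(f"n_sleeves must be in [1, 5], got {n_sleeves}")
    if activity_bq < 0:
        raise ConfigurationError("activity must be >= 0")
    length = 700.0
    line_r = 0.5
    conc = activity_bq / (np.pi * line_r**2 * length / 1000.0) if activity_bq else 0.0
    centre = (radial_offset_mm, 0.0, 0.0)
    prims = []
    r_in = 1.95  # innermost sleeve inner radius (3.9 mm ID)
    for _ in range(n_sleeves):
        prims.append(Primitive("annulus", centre, get_material("aluminium"),
                               radius=r_in + 1.25, inner_radius=r_in, length=length))
        r_in += 1.25
    prims.append(Primitive("cylinder", centre, get_material("water"),
                           activity_bq_ml=conc, radius=line_r, length=length))
    return PhantomModel(prims, name=f"sensitivity_{n_sleeves}sleeves")


def make_scatter_phantom(line_activity_bq: float, include_bed: bool = True) -> PhantomModel:
    """NEMA scatter/count-losses phantom.

    Polyethylene cylinder, 700 mm long, 101.5 mm radius, with the 700-mm
    line source (3.2 mm ID) in its off-centre bore 45 mm below the axis.
    """
    if line_activity_bq < 0:
        raise ConfigurationError("line_activity must be >= 0")
    length = 700.0
    line_r = 1.6
    conc = line_activity_bq / (np.pi * line_r**2 * length / 1000.0) if line_activity_bq else 0.0
    prims = [
        Primitive("cylinder", (0.0, 0.0, 0.0), get_material("polyethylene"),
                  radius=101.5, length=length),
        Primitive("cylinder", (0.0, -45.0, 0.0), get_material("water"),
                  activity_bq_ml=conc, radius=line_r, length=length),
    ]
    if include_bed:
        prims.insert(0, Primitive("box", (0.0, -115.0, 0.0), get_material("carbon_fibre"),
                                  size=(400.0, 15.0, 700.0)))
    return PhantomModel(prims, name="scatter")


def make_iq_phantom(background_bq_ml: float, sphere_bq_ml: float,
                    include_bed: bool = False) -> PhantomModel:
    """IEC body phantom: warm background, six hot spheres, cold lung insert.

    The body is modelled as a 147-mm-radius, 194-mm-long cylinder; the
    spheres (diameters 10-37 mm) sit on a 114.4-mm-diameter circle in the
    central transverse plane, and the 50-mm-diameter lung insert runs
    axially through the centre.
    """
    if background_bq_ml < 0 or sphere_bq_ml < 0:
        raise ConfigurationError("concentrations must be >= 0")
    if sphere_bq_ml > 0 and background_bq_ml == 0:
        raise ConfigurationError(
            "background concentration must be positive to define the "
            "sphere-to-background ratio")
    prims = [
        Primitive("cylinder", (0.0, 0.0, 0.0), get_material("water"),
                  activity_bq_ml=background_bq_ml, radius=147.0, length=194.0),
        Primitive("cylinder", (0.0, 0.0, 0.0), get_material("lung"),
                  radius=_LUNG_INSERT_RADIUS_MM, length=194.0),
    ]
    for j, diam in enumerate(IQ_SPHERE_DIAMETERS_MM):
        ang = 2 * np.pi * j / 6.0
        prims.append(Primitive(
            "sphere",
            (_IQ_SPHERE_RING_RADIUS_MM * np.cos(ang),
             _IQ_SPHERE_RING_RADIUS_MM * np.sin(ang), 0.0),
            get_material("water"), activity_bq_ml=sphere_bq_ml, radius=diam / 2.0))
    if include_bed:
        prims.insert(0, Primitive("box", (0.0, -160.0, 0.0), get_material("carbon_fibre"),
                                  size=(400.0, 15.0, 400.0)))
    model = PhantomModel(prims, name="iq_body")
    model.sbr = round(sphere_bq_ml / background_bq_ml, 1) if background_bq_ml else None
    return model


def make_point_sources(offsets_mm, activity_bq: float = 1.0,
                       fov_radius_mm: float = 350.0,
                       fov_half_length_mm: float = 100.0) -> PhantomModel:
    """0.5-mm-radius spherical sources at the requested (x, y, z) offsets."""
    prims = []
    for pos in offsets_mm:
        pos = tuple(float(v) for v in pos)
        if np.hypot(pos[0], pos[1]) > fov_radius_mm or abs(pos[2]) > fov_half_length_mm:
            raise ConfigurationError(f"point source at {pos} lies outside the FOV")
        r = 0.5
        conc = activity_bq / (4.0 / 3.0 * np.pi * r**3 / 1000.0)
        prims.append(Primitive("sphere", pos, get_material("water"),
                               activity_bq_ml=conc, radius=r))
    return PhantomModel(prims, name="point_sources")


def nema_point_source_offsets() -> list[tuple[float, float, float]]:
    """The six NEMA spatial-resolution positions: radial 10/100/200 mm at
    the axial centre and at +76 mm (three-eighths of the axial FOV)."""
    return [(r, 0.0, z) for z in (0.0, 76.0) for r in (10.0, 100.0, 200.0)]


def make_annulus_source(activity_bq: float = 1.0) -> PhantomModel:
    """Thin annulus source (320 mm radius, 1 mm wall, 200 mm long) used to
    derive geometric normalisation factors."""
    prim = Primitive("annulus", (0.0, 0.0, 0.0), get_material("water"),
                     radius=320.5, inner_radius=319.5, length=200.0,
                     activity_bq_ml=activity_bq / (np.pi * (320.5**2 - 319.5**2) * 200.0 / 1000.0))
    return PhantomModel([prim], name="annulus_source")


def make_flood_source(activity_bq: float = 1.0) -> PhantomModel:
    """Uniform flood cylinder (10 cm radius, 22 cm height) used for the
    crystal-efficiency fan-sums."""
    prim = Primitive("cylinder", (0.0, 0.0, 0.0), get_material("water"),
                     radius=100.0, length=220.0,
                     activity_bq_ml=activity_bq / (np.pi * 100.0**2 * 220.0 / 1000.0))
    return PhantomModel([prim], name="flood_source")


# ---------------------------------------------------------------------------
# Attenuation-map rasterisation
# ---------------------------------------------------------------------------

@dataclass
class MuMap:
    """3D grid of 511-keV linear attenuation (mm^-1)."""

    values: np.ndarray              # (nx, ny, nz)
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]  # centre of voxel (0, 0, 0)

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ConfigurationError("MuMap values must be >= 0")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.values.shape, self.voxel_mm))


def _voxel_centres(dims, voxel_mm):
    voxel = np.asarray(voxel_mm, dtype=float)
    axes = [ (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(dims, voxel) ]
    return axes


def rasterise_mumap(phantom: PhantomModel, dims=(256, 256, 71),
                    voxel_mm=(2.0, 2.0, 3.0)) -> MuMap:
    """Voxelised 511-keV attenuation map (voxel-centre sampling)."""
    values = _rasterise(phantom, dims, voxel_mm, attribute="mu")
    origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(dims, voxel_mm))
    return MuMap(values, tuple(float(v) for v in voxel_mm), origin)


def rasterise_activity(phantom: PhantomModel, dims, voxel_mm) -> np.ndarray:
    """Voxelised activity concentration map (Bq/mL, voxel-centre sampling)."""
    return _rasterise(phantom, dims, voxel_mm, attribute="activity")


def _rasterise(phantom, dims, voxel_mm, attribute):
    if any(n < 1 for n in dims) or any(v <= 0 for v in voxel_mm):
        raise ConfigurationError("dims must be >= 1 and voxel sizes > 0")
    ax, ay, az = _voxel_centres(dims, voxel_mm)
    out = np.zeros(dims, dtype=float)
    air_mu = get_material("air").mu_511_mm
    # slice-wise to bound memory
    xx, yy = np.meshgrid(ax, ay, indexing="ij")
    flat_xy = np.column_stack([xx.ravel(), yy.ravel()])
    for k, z in enumerate(az):
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), z)])
        if attribute == "mu":
            out[:, :, k] = phantom.mu_at(pts, background_mu=air_mu).reshape(
                dims[0], dims[1])
        else:
            out[:, :, k] = phantom.activity_at(pts).reshape(dims[0], dims[1])
    return out
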