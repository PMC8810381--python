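"""Mass, centre of mass and inertia of bristled and membranous wings.

A featherwing-beetle wing is modelled as a composite rigid body: a
petiole and a narrow blade (flat cuticle patches of constant thickness)
plus a fringe of setae (thin rods with a linear mass density that also
absorbs the mass of their secondary outgrowths).  Membranous "substitute"
wings share the same outline — the blade extended by the polyline through
the seta tips — and differ only in membrane thickness.

All geometry lives in the wing-base frame: the patch plane is the local
x–y plane (x spanwise, y chordwise, z normal), rods may point out of it.
Inertia tensors are returned about a caller-chosen reference point in
wing-base axes.

The seta tensor uses the thin-rod formula shifted by the parallel-axis
theorem; patch tensors come from a midpoint quadrature on a square grid
whose boundary cells are clipped against the polygon, which converges to
the exact polygon integrals as the step shrinks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import Frame, segments_intersect
from .units import CUTICLE_DENSITY, SETA_LINEAR_DENSITY

__all__ = [
    "SetaRod",
    "MembranePatch",
    "WingMorphology",
    "MassProperties",
    "seta_mass_properties",
    "membrane_mass_properties",
    "assemble_wing",
    "membranous_substitute",
]

#: default quadrature step, µm.  Deliberately much finer than the coarse
#: 50 µm grid that is adequate for whole-wing totals: a ~30 µm wide petiole
#: needs a step of a few µm to resolve its own moments.
DEFAULT_STEP = 2.0

#: how far (µm) a seta base may sit from the blade boundary
SETA_BASE_TOLERANCE = 5.0


def _as_unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"direction must be a unit vector, |v| = {n!r}")
    return v


@dataclass(frozen=True)
class SetaRod:
    """A seta modelled as a straight thin rod.

    Parameters are in internal units: µm for lengths, µg/µm for the linear
    density (default 0.96 µg/m, which already accounts for the secondary
    outgrowths).
    """

    base: np.ndarray
    direction: np.ndarray
    length: float
    linear_density: float = SETA_LINEAR_DENSITY

    def __post_init__(self):
        object.__setattr__(self, "base", np.asarray(self.base, dtype=float).reshape(3))
        object.__setattr__(self, "direction", _as_unit(self.direction))
        if not self.length > 0:
            raise ValueError("seta length must be positive")
        if not self.linear_density > 0:
            raise ValueError("seta linear density must be positive")

    @classmethod
    def from_tip(cls, base, tip, linear_density: float = SETA_LINEAR_DENSITY) -> "SetaRod":
        base = np.asarray(base, dtype=float).reshape(3)
        tip = np.asarray(tip, dtype=float).reshape(3)
        d = tip - base
        length = float(np.linalg.norm(d))
        if length <= 0:
            raise ValueError("seta tip coincides with its base")
        return cls(base, d / length, length, linear_density)

    @property
    def tip(self) -> np.ndarray:
        return self.base + self.length * self.direction

    @property
    def mass(self) -> float:
        return self.linear_density * self.length


@dataclass(frozen=True)
class MembranePatch:
    """Flat cuticle patch of constant thickness.

    ``boundary`` is an ordered (n, 2) vertex list, µm, of a simple closed
    polygon in the wing-base x–y plane.  Zero-area placeholders are
    permitted so that composites can omit a part, but the quadrature
    rejects them.
    """

    boundary: np.ndarray
    thickness: float
    cuticle_density: float = CUTICLE_DENSITY

    def __post_init__(self):
        b = np.asarray(self.boundary, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
            raise ValueError("boundary must be an (n >= 3, 2) vertex array")
        object.__setattr__(self, "boundary", b)
        if not self.thickness > 0:
            raise ValueError("membrane thickness must be positive")
        if not self.cuticle_density > 0:
            raise ValueError("cuticle density must be positive")
        poly = Polygon(b)
        if not poly.is_valid and poly.convex_hull.area > 0:
            raise ValueError("boundary polygon must be simple (non-self-intersecting)")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary)

    @property
    def area(self) -> float:
        return Polygon(self.boundary).area

    @property
    def surface_density(self) -> float:
        """Mass per unit area, µg/µm²."""
        return self.cuticle_density * self.thickness

    def with_thickness(self, thickness: float) -> "MembranePatch":
        return MembranePatch(self.boundary, thickness, self.cuticle_density)


@dataclass(frozen=True)
class WingMorphology:
    """Composite wing: petiole + blade patches and a fringe of setae.

    ``base_frame`` places the wing-base coordinate system (x spanwise,
    y chordwise, z normal) in the laboratory frame; all component geometry
    is expressed in that local system.
    """

    petiole: MembranePatch
    blade: MembranePatch
    setae: tuple
    base_frame: Frame = field(default_factory=Frame)
    seta_base_tolerance: float = SETA_BASE_TOLERANCE

    def __post_init__(self):
        object.__setattr__(self, "setae", tuple(self.setae))
        blade_poly = self.blade.polygon
        outline = blade_poly if blade_poly.area > 0 else None
        if outline is not None and self.petiole.area > 0:
            outline = unary_union([outline, self.petiole.polygon])
        if outline is not None:
            ring = outline.boundary
            for i, s in enumerate(self.setae):
                d = ring.distance(shapely.points(s.base[0], s.base[1]))
                if d > self.seta_base_tolerance:
                    raise ValueError(
                        f"seta {i} base is {d:.1f} µm from the blade boundary "
                        f"(tolerance {self.seta_base_tolerance} µm)")

    @property
    def wing_length(self) -> float:
        """Maximum in-plane distance of any seta tip or blade vertex from the base origin."""
        r = 0.0
        for patch in (self.petiole, self.blade):
            if patch.area > 0:
                r = max(r, float(np.max(np.linalg.norm(patch.boundary, axis=1))))
        for s in self.setae:
            r = max(r, float(np.linalg.norm(s.tip[:2])))
        return r


def _check_inertia(I: np.ndarray, mass: float) -> None:
    if not np.allclose(I, I.T, atol=1e-9 * max(1.0, abs(I).max())):
        raise ValueError("inertia tensor must be symmetric")
    w = np.linalg.eigvalsh(I)
    tol = 1e-9 * max(1.0, w[-1])
    if w[0] < -tol:
        raise ValueError("inertia tensor must be positive semi-definite")
    # triangle inequality on principal moments
    if w[0] + w[1] < w[2] - tol:
        raise ValueError("principal moments violate the triangle inequality")


@dataclass(frozen=True)
class MassProperties:
    """Mass (µg), centre of mass (µm) and inertia tensor (µg·µm²).

    ``inertia`` is taken about ``ref_point`` in wing-base axes.
    """

    mass: float
    com: np.ndarray
    inertia: np.ndarray
    ref_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float).reshape(3))
        object.__setattr__(self, "inertia", np.asarray(self.inertia, dtype=float).reshape(3, 3))
        object.__setattr__(self, "ref_point", np.asarray(self.ref_point, dtype=float).reshape(3))
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        _check_inertia(self.inertia, self.mass)

    @property
    def izz(self) -> float:
        return float(self.inertia[2, 2])

    @property
    def principal_moments(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.inertia)

    def about(self, new_ref) -> "MassProperties":
        """Inertia about another reference point (parallel-axis theorem, both ways)."""
        new_ref = np.asarray(new_ref, dtype=float).reshape(3)
        I_com = self.inertia - _pa_term(self.mass, self.com - self.ref_point)
        I_new = I_com + _pa_term(self.mass, self.com - new_ref)
        return MassProperties(self.mass, self.com, I_new, new_ref)

    def rotated(self, R: np.ndarray) -> "MassProperties":
        """Mass properties of the same body with all geometry rotated by ``R`` about ref_point."""
        R = np.asarray(R, dtype=float).reshape(3, 3)
        com = self.ref_point + R @ (self.com - self.ref_point)
        return MassProperties(self.mass, com, R @ self.inertia @ R.T, self.ref_point)

    def __add__(self, other: "MassProperties") -> "MassProperties":
        if not np.allclose(self.ref_point, other.ref_point):
            raise ValueError("can only add mass properties sharing a reference point")
        m = self.mass + other.mass
        com = (self.mass * self.com + other.mass * other.com) / m
        return MassProperties(m, com, self.inertia + other.inertia, self.ref_point)


def _pa_term(mass: float, d: np.ndarray) -> np.ndarray:
    """Parallel-axis shift m (|d|² E − d dᵀ)."""
    return mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))


def seta_mass_properties(seta: SetaRod, origin=(0.0, 0.0, 0.0)) -> MassProperties:
    """Thin-rod mass properties about ``origin``.

    The rod tensor about its own centre is (m L²/12)(E − u uᵀ) for unit
    direction u, shifted to ``origin`` by the parallel-axis theorem.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    m = seta.mass
    com = seta.base + 0.5 * seta.length * seta.direction
    u = seta.direction
    I_com = (m * seta.length**2 / 12.0) * (np.eye(3) - np.outer(u, u))
    I = I_com + _pa_term(m, com - origin)
    return MassProperties(m, com, I, origin)


def _patch_cells(poly: Polygon, step: float):
    """Cell centroids and areas for the clipped midpoint quadrature."""
    minx, miny, maxx, maxy = poly.bounds
    nx = max(1, int(np.ceil((maxx - minx) / step)))
    ny = max(1, int(np.ceil((maxy - miny) / step)))
    xs = minx + step * np.arange(nx)
    ys = miny + step * np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    x0 = X.ravel()
    y0 = Y.ravel()
    cells = shapely.box(x0, y0, x0 + step, y0 + step)
    shapely.prepare(poly)
    full = shapely.contains_properly(poly, cells)
    touching = shapely.intersects(poly, cells)
    partial = touching & ~full

    centers_x = [x0[full] + 0.5 * step]
    centers_y = [y0[full] + 0.5 * step]
    areas = [np.full(int(full.sum()), step * step)]
    for cell in cells[partial]:
        clip = poly.intersection(cell)
        if clip.is_empty or clip.area <= 0:
            continue
        c = clip.centroid
        centers_x.append(np.array([c.x]))
        centers_y.append(np.array([c.y]))
        areas.append(np.array([clip.area]))
    return (np.concatenate(centers_x), np.concatenate(centers_y), np.concatenate(areas))


def membrane_mass_properties(patch: MembranePatch, origin=(0.0, 0.0, 0.0),
                             step: float = DEFAULT_STEP) -> MassProperties:
    """Quadrature mass properties of a flat patch about ``origin``.

    Midpoint rule on a square grid of the given step; boundary cells are
    clipped against the polygon so each contributes its exact area at its
    own centroid.  Converges to the exact polygon integrals as step → 0.
    """
    if not step > 0:
        raise ValueError("quadrature step must be positive")
    poly = patch.polygon
    if poly.area <= 0:
        raise ValueError("cannot integrate a degenerate (zero-area) patch")
    origin = np.asarray(origin, dtype=float).reshape(3)
    cx, cy, areas = _patch_cells(poly, step)
    sigma = patch.surface_density
    masses = sigma * areas
    pts = np.column_stack([cx, cy, np.zeros_like(cx)])
    return _point_mass_aggregate(pts, masses, origin)


def _point_mass_aggregate(points: np.ndarray, masses: np.ndarray, origin: np.ndarray) -> MassProperties:
    m = float(masses.sum())
    com = (masses[:, None] * points).sum(axis=0) / m
    r = points - origin
    r2 = np.einsum("ij,ij->i", r, r)
    I = (masses * r2).sum() * np.eye(3) - np.einsum("i,ij,ik->jk", masses, r, r)
    return MassProperties(m, com, I, origin)


def assemble_wing(wing: WingMorphology, step: float = DEFAULT_STEP,
                  origin=(0.0, 0.0, 0.0)) -> MassProperties:
    """Composite wing mass properties: petiole + blade + setae about one origin.

    Zero-area placeholder patches contribute nothing.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    parts = []
    for patch in (wing.petiole, wing.blade):
        if patch.area > 0:
            parts.append(membrane_mass_properties(patch, origin, step))
    for s in wing.setae:
        parts.append(seta_mass_properties(s, origin))
    if not parts:
        raise ValueError("wing has no massive components")
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return total


def membranous_substitute(wing: WingMorphology, thickness: float) -> MembranePatch:
    """Membranous wing of the same outline: blade extended to the seta tips.

    The substitute boundary is the union of the petiole, the blade and the
    region swept between consecutive setae, whose outer margin is the
    polyline through the seta tips (setae are taken in list order, which
    must follow the wing margin).  The cuticle density is inherited from
    the blade, so the substitute mass is exactly linear in ``thickness``.
    """
    if len(wing.setae) < 3:
        raise ValueError("membranous substitute requires at least 3 setae")
    tips = [s.tip[:2] for s in wing.setae]
    bases = [s.base[:2] for s in wing.setae]
    # the tip polyline is the new outer margin; it must not self-intersect
    for i in range(len(tips) - 1):
        for j in range(i + 2, len(tips) - 1):
            if segments_intersect(tips[i], tips[i + 1], tips[j], tips[j + 1]):
                raise ValueError(
                    f"seta tip polyline self-intersects: segment {i}-{i + 1} "
                    f"crosses segment {j}-{j + 1}")
    pieces = []
    for patch in (wing.petiole, wing.blade):
        if patch.area > 0:
            pieces.append(patch.polygon)
    for i in range(len(tips) - 1):
        for tri in ((bases[i], tips[i], tips[i + 1]),
                    (bases[i], tips[i + 1], bases[i + 1])):
            t = Polygon(tri)
            if t.area > 0:
                pieces.append(t)
    outline = unary_union(pieces)
    if outline.geom_type == "MultiPolygon":
        outline = max(outline.geoms, key=lambda g: g.area)
    boundary = np.asarray(outline.exterior.coords)[:-1]
    return MembranePatch(boundary, thickness, wing.blade.cuticle_density)
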