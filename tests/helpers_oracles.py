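"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: inertia comes
from direct point-mass sums over dense deterministic discretizations, and
polygon moments from the closed-form Green's-theorem formulas.
"""
import numpy as np
import shapely


def point_cloud_mass_properties(points, masses, origin):
    """Direct point-mass aggregation: mass, centre of mass, inertia tensor."""
    points = np.asarray(points, dtype=float)
    masses = np.asarray(masses, dtype=float)
    origin = np.asarray(origin, dtype=float)
    m = masses.sum()
    com = (masses[:, None] * points).sum(axis=0) / m
    I = np.zeros((3, 3))
    for k in range(3):
        for l in range(3):
            r = points - origin
            if k == l:
                I[k, l] = (masses * ((r ** 2).sum(axis=1) - r[:, k] * r[:, l])).sum()
            else:
                I[k, l] = -(masses * (r[:, k] * r[:, l])).sum()
    return m, com, I


def rod_point_masses(base, direction, length, lam, n=1_000_000):
    """Midpoint discretization of a thin rod into n equal point masses."""
    base = np.asarray(base, dtype=float)
    direction = np.asarray(direction, dtype=float)
    s = (np.arange(n) + 0.5) / n * length
    pts = base[None, :] + s[:, None] * direction[None, :]
    masses = np.full(n, lam * length / n)
    return pts, masses


def patch_point_masses(boundary, surface_density, n_grid=1000):
    """Deterministic grid discretization of a flat polygon into point masses."""
    poly = shapely.Polygon(np.asarray(boundary, dtype=float))
    minx, miny, maxx, maxy = poly.bounds
    hx = (maxx - minx) / n_grid
    hy = (maxy - miny) / n_grid
    xs = minx + hx * (np.arange(n_grid) + 0.5)
    ys = miny + hy * (np.arange(n_grid) + 0.5)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel())
    x = X.ravel()[inside]
    y = Y.ravel()[inside]
    pts = np.column_stack([x, y, np.zeros_like(x)])
    masses = np.full(x.size, surface_density * hx * hy)
    return pts, masses


def polygon_moments(boundary):
    """Closed-form polygon area, centroid and second moments about the origin.

    Returns (A, cx, cy, Ixx, Iyy, Ixy) with Ixx = ∫ y² dA, Iyy = ∫ x² dA,
    Ixy = ∫ x y dA (Green's theorem over the boundary).
    """
    b = np.asarray(boundary, dtype=float)
    x, y = b[:, 0], b[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * cross.sum()
    cx = ((x + x1) * cross).sum() / (6 * A)
    cy = ((y + y1) * cross).sum() / (6 * A)
    Iyy = ((x ** 2 + x * x1 + x1 ** 2) * cross).sum() / 12.0
    Ixx = ((y ** 2 + y * y1 + y1 ** 2) * cross).sum() / 12.0
    Ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    if A < 0:
        A, Ixx, Iyy, Ixy = -A, -Ixx, -Iyy, -Ixy
    return A, cx, cy, Ixx, Iyy, Ixy


def relative_tensor_error(I_a, I_b):
    """Max elementwise difference between 3×3 tensors, relative to the largest entry."""
    I_a = np.asarray(I_a)
    I_b = np.asarray(I_b)
    scale = max(np.abs(I_a).max(), np.abs(I_b).max())
    return np.abs(I_a - I_b).max() / scale
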