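"""Brute-force geometric oracles, independent of the package's kernels.

Everything here works in the meridional half-plane (u = position along the
division axis, v = distance from it), exploiting the rotational symmetry of
the composite geometry.  Spheroid membership is analytic; spheroid surface
clearance is measured against a dense lattice of points outside the
primitive (KD-tree nearest neighbour), so it shares no code with the
package's point-to-ellipse solver.  Bridge-cylinder margins are plain
arithmetic.
"""

import numpy as np
from scipy.spatial import cKDTree

from karyosim.geometry import BRIDGE_OVERLAP_FRACTION, GeometryFrame

LATTICE = 0.005


class GridOracle:
    def __init__(self, frame: GeometryFrame, spacing: float = LATTICE):
        self.frame = frame
        self.spacing = spacing
        lo, hi = frame.bounding_box()
        us = np.arange(lo[0] - 0.2, hi[0] + 0.2, spacing)
        vs = np.arange(0.0, hi[1] + 0.2, spacing)
        U, V = np.meshgrid(us, vs, indexing="ij")
        self.grid = np.column_stack([U.ravel(), V.ravel()])
        self._outside_trees = {}
        self._inside_trees = {}
        for name in ("mother", "daughter"):
            inside = self._spheroid_inside(name, self.grid[:, 0], self.grid[:, 1])
            self._outside_trees[name] = cKDTree(self.grid[~inside])
            self._inside_trees[name] = cKDTree(self.grid[inside])

    def _spheroid_inside(self, name, u, v):
        s = getattr(self.frame, name)
        return ((u - s.center_x) / s.semi_long) ** 2 + (
            v / s.semi_equatorial
        ) ** 2 <= 1.0

    def _cyl_margin(self, u, v, r):
        b = self.frame.bridge
        if b.half_length <= 0 or b.radius <= 0:
            return -np.inf
        hx = b.half_length * (1.0 + BRIDGE_OVERLAP_FRACTION)
        return min((b.radius - r) - v, (hx + r) - abs(u))

    def spheroid_clearance(self, name, u, v):
        """Distance to the spheroid surface from an interior point, measured
        against the lattice of exterior points (accuracy ~ lattice spacing)."""
        d, _ = self._outside_trees[name].query([u, v])
        return d

    def inside_union(self, u, v):
        """Point membership (r = 0), fully analytic."""
        return (
            self._spheroid_inside("mother", u, v)
            or self._spheroid_inside("daughter", u, v)
            or self._cyl_margin(u, v, 0.0) >= 0.0
        )

    def contains(self, u, v, r):
        """Sphere-fit oracle under the package's per-primitive convention."""
        for name in ("mother", "daughter"):
            if self._spheroid_inside(name, u, v) and (
                self.spheroid_clearance(name, u, v) >= r
            ):
                return True
        return self._cyl_margin(u, v, r) >= 0.0

    def indeterminate(self, u, v, r, tol):
        """True when the query is too close to a decision surface for the
        lattice resolution to call it."""
        margins = [self._cyl_margin(u, v, r)]
        for name in ("mother", "daughter"):
            if self._spheroid_inside(name, u, v):
                d, _ = self._outside_trees[name].query([u, v])
                margins.append(d - r)
            else:
                d, _ = self._inside_trees[name].query([u, v])
                margins.append(-d - r)
        return abs(max(margins)) < tol

    def admissible_points(self, r, buffer):
        """Lattice points that safely admit a sphere of radius r (cached)."""
        if not hasattr(self, "_adm_cache"):
            self._adm_cache = {}
        key = (r, buffer)
        if key in self._adm_cache:
            return self._adm_cache[key]
        ok = np.zeros(len(self.grid), dtype=bool)
        for name in ("mother", "daughter"):
            inside = self._spheroid_inside(name, self.grid[:, 0], self.grid[:, 1])
            d, _ = self._outside_trees[name].query(self.grid[inside])
            sel = np.where(inside)[0][d >= r + buffer]
            ok[sel] = True
        b = self.frame.bridge
        if b.half_length > 0 and b.radius > 0:
            hx = b.half_length * (1.0 + BRIDGE_OVERLAP_FRACTION)
            cyl = (
                (self.grid[:, 1] <= (b.radius - r) - buffer)
                & (np.abs(self.grid[:, 0]) <= (hx + r) - buffer)
            )
            ok |= cyl
        self._adm_cache[key] = self.grid[ok]
        return self._adm_cache[key]

    def nearest_admissible_distance(self, u, v, r, buffer=0.0):
        pts = self.admissible_points(r, buffer)
        return float(np.min(np.hypot(pts[:, 0] - u, pts[:, 1] - v)))


def to_meridional(point):
    x, y, z = point
    return x, float(np.hypot(y, z))
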