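"""Low-level numerical kernels for the composite nuclear geometry.

The dividing nucleus is modelled as the union of three primitives on a common
division axis (x): a mother prolate spheroid, a daughter prolate spheroid and a
connecting cylindrical bridge.  All kernels operate on a packed parameter
vector so they can be compiled with numba and called once per diffusion step:

    params[0] = mother centre x        params[1] = mother semi-axis (long, x)
    params[2] = mother semi-axis (equatorial)
    params[3] = daughter centre x      params[4] = daughter semi-axis (long)
    params[5] = daughter semi-axis (equatorial)
    params[6] = bridge half-length     params[7] = bridge radius
    params[8] = bridge axial half-extent (half-length plus the 1% overlap
                that keeps the union connected at the tip junctions)

Distances are Euclidean in micrometres.  ``point_clearance`` is the signed
distance to the union boundary (positive inside).  Volume exclusion uses a
per-primitive erosion convention: a sphere of radius r fits iff it fits
entirely inside at least one primitive, where for this test the bridge
cylinder is extended axially into each lobe by 2r beyond its 1% connectivity
overlap.  The adaptive extension makes the eroded cylinder meet the eroded
spheroids, so junction passage is possible exactly when the bridge admits
the sphere radially (R > r) -- mirroring the behaviour of the true eroded
union, which a sphere straddling the tangent junction can occupy (see the
geometry module docs).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_PROJ_MARGIN = 1e-9  # projection overshoot so returned points strictly fit


@njit(cache=True)
def _ellipse_closest_ordered(e0, e1, y0, y1):
    """Closest point on the ellipse (x0/e0)^2 + (x1/e1)^2 = 1 to (y0, y1).

    Requires e0 >= e1 > 0 and y0, y1 >= 0.  Root-finding formulation: the
    closest point satisfies x_i = e_i^2 y_i / (t + e_i^2) for the unique root
    t of F(t) = sum (e_i y_i / (t + e_i^2))^2 - 1 on (-e1^2, inf).  F is
    convex and decreasing, so Newton from a right-hand starting point is
    monotone and safe.
    """
    if y1 > 1e-12:
        a0 = e0 * y0
        a1 = e1 * y1
        delta = e0 * e0 - e1 * e1  # >= 0
        # substitute w = t + e1^2 (w > 0), avoiding cancellation at small w;
        # F(w_hi) <= 0 at w_hi, the first Newton step lands left of the root
        # and subsequent iterates increase monotonically (F convex).
        w = math.sqrt(a0 * a0 + a1 * a1)
        for _ in range(100):
            d0 = w + delta
            r0 = a0 / d0
            r1 = a1 / w
            f = r0 * r0 + r1 * r1 - 1.0
            df = -2.0 * (r0 * r0 / d0 + r1 * r1 / w)
            step = f / df
            w_new = w - step
            if w_new <= 0.0:  # safeguard; the root is strictly positive
                w_new = 0.5 * w
            if abs(w_new - w) <= 1e-15 * (1.0 + w):
                w = w_new
                break
            w = w_new
        x0 = e0 * e0 * y0 / (w + delta)
        x1 = e1 * e1 * y1 / w
        return x0, x1
    # y1 == 0: point on the major axis
    denom = e0 * e0 - e1 * e1
    if denom > 0.0 and e0 * y0 < denom:
        # inside the evolute: closest point is off-axis
        x0 = e0 * e0 * y0 / denom
        f = x0 / e0
        x1 = e1 * math.sqrt(max(1.0 - f * f, 0.0))
        return x0, x1
    return e0, 0.0


@njit(cache=True)
def ellipse_signed_distance(a, b, u, v):
    """Signed distance of meridional point (u, v>=0) to the ellipse with
    axial semi-axis a and radial semi-axis b.  Positive inside.

    Returns (signed_distance, foot_u, foot_v).
    """
    au = abs(u)
    if a >= b:
        x0, x1 = _ellipse_closest_ordered(a, b, au, v)
        qu, qv = x0, x1
    else:
        x0, x1 = _ellipse_closest_ordered(b, a, v, au)
        qu, qv = x1, x0
    d = math.hypot(au - qu, v - qv)
    inside = (u / a) * (u / a) + (v / b) * (v / b) <= 1.0
    if u < 0.0:
        qu = -qu
    if inside:
        return d, qu, qv
    return -d, qu, qv


@njit(cache=True)
def fit_margin(params, x, y, z, r):
    """Margin by which a sphere of radius r at (x, y, z) fits in the union.

    Max over primitives of the per-primitive fit margin (distance to the
    primitive surface minus r when inside; minus the distance to the eroded
    primitive when outside).  The bridge cylinder is extended axially by 2r
    for this test, so its eroded axial half-span is params[8] + r.  The
    sphere fits iff the margin is >= 0; at r = 0 this is the signed
    clearance of the point w.r.t. the union.
    """
    v = math.hypot(y, z)
    cm = ellipse_signed_distance(params[1], params[2], x - params[0], v)[0] - r
    cd = ellipse_signed_distance(params[4], params[5], x - params[3], v)[0] - r
    c = cm if cm > cd else cd
    hx = params[8]
    rad = params[7]
    if hx > 0.0 and rad > 0.0:
        er = v - (rad - r)
        ea = abs(x) - (hx + r)
        if er <= 0.0 and ea <= 0.0:
            cb = -er if -er < -ea else -ea
        else:
            cb = -math.hypot(max(er, 0.0), max(ea, 0.0))
        if cb > c:
            c = cb
    return c


@njit(cache=True)
def point_clearance(params, x, y, z):
    """Signed clearance of a point w.r.t. the union of the three primitives.

    Max over primitives of the per-primitive inside-clearance: positive
    distance to the primitive surface when inside it, minus the distance to
    the primitive when outside.
    """
    return fit_margin(params, x, y, z, 0.0)


@njit(cache=True)
def _spheroid_project(a, b, cx, x, y, z, r_eff):
    """Closest point of the r_eff-eroded spheroid to (x, y, z).

    Returns (dist, px, py, pz, ok).  The eroded spheroid is the set of points
    whose distance to the spheroid surface is >= r_eff; its boundary is the
    inner parallel surface, whose foot point shares the surface normal with
    the query point.  A secant refinement along that normal handles the
    curvature correction; where the parallel surface self-intersects (near
    the tips when r_eff exceeds the tip curvature radius b^2/a) we fall back
    to a bisection toward the spheroid centre, which always has maximal
    clearance min(a, b).
    """
    bmin = a if a < b else b
    if bmin <= r_eff * (1.0 + 1e-9) + 1e-15:
        return 1e300, 0.0, 0.0, 0.0, False
    u = x - cx
    v = math.hypot(y, z)
    sc, qu, qv = ellipse_signed_distance(a, b, u, v)
    if sc >= r_eff:
        return 0.0, x, y, z, True
    # outward normal at the foot point
    nu = qu / (a * a)
    nv = qv / (b * b)
    nn = math.hypot(nu, nv)
    nu /= nn
    nv /= nn
    s = r_eff
    pu = qu - s * nu
    pv = qv - s * nv
    ok = False
    prev = -1e300
    for _ in range(16):
        c2 = ellipse_signed_distance(a, b, pu, abs(pv))[0]
        if c2 >= r_eff - 1e-12:
            ok = True
            break
        if c2 <= prev + 1e-14:
            break
        prev = c2
        s += r_eff - c2
        pu = qu - s * nu
        pv = qv - s * nv
    if not ok:
        # bisection along the segment from the query point to the centre
        lo = 0.0
        hi = 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            mu = (1.0 - mid) * u
            mv = (1.0 - mid) * v
            if ellipse_signed_distance(a, b, mu, mv)[0] >= r_eff:
                hi = mid
            else:
                lo = mid
        pu = (1.0 - hi) * u
        pv = (1.0 - hi) * v
    if v > 1e-300:
        ry = y / v
        rz = z / v
    else:
        ry = 1.0
        rz = 0.0
    px = cx + pu
    py = ry * pv
    pz = rz * pv
    dist = math.sqrt((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
    return dist, px, py, pz, True


@njit(cache=True)
def _cylinder_project(ax, rv, x, y, z):
    """Closest point of the eroded bridge cylinder (axial half-extent ax,
    radius rv) to (x, y, z)."""
    if rv <= 1e-15 or ax <= 1e-15:
        return 1e300, 0.0, 0.0, 0.0, False
    v = math.hypot(y, z)
    px = x
    if px > ax:
        px = ax
    elif px < -ax:
        px = -ax
    if v <= rv:
        py = y
        pz = z
    elif v > 1e-300:
        py = y * rv / v
        pz = z * rv / v
    else:
        py = 0.0
        pz = 0.0
    dist = math.sqrt((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
    return dist, px, py, pz, True


@njit(cache=True)
def project_point(params, x, y, z, r):
    """Remap (x, y, z) to the nearest position admitting a sphere of radius r.

    Returns (px, py, pz, ok); ok is False when no primitive can host the
    radius.  Points already fitting the sphere are returned unchanged.
    """
    if fit_margin(params, x, y, z, r) >= 0.0:
        return x, y, z, True
    r_eff = r + _PROJ_MARGIN
    best = 1e300
    bx = x
    by = y
    bz = z
    ok = False
    d, px, py, pz, good = _spheroid_project(
        params[1], params[2], params[0], x, y, z, r_eff
    )
    if good and d < best:
        best = d
        bx, by, bz = px, py, pz
        ok = True
    d, px, py, pz, good = _spheroid_project(
        params[4], params[5], params[3], x, y, z, r_eff
    )
    if good and d < best:
        best = d
        bx, by, bz = px, py, pz
        ok = True
    if params[8] > 0.0 and params[7] > 0.0:
        d, px, py, pz, good = _cylinder_project(
            params[8] + r - _PROJ_MARGIN, params[7] - r_eff, x, y, z
        )
        if good and d < best:
            best = d
            bx, by, bz = px, py, pz
            ok = True
    return bx, by, bz, ok


@njit(cache=True)
def contains_batch(params, pts, r, out):
    for i in range(pts.shape[0]):
        out[i] = fit_margin(params, pts[i, 0], pts[i, 1], pts[i, 2], r) >= 0.0


@njit(cache=True)
def run_single(params_steps, incs, p0, r, rec_slot, labels_out):
    """Advance one particle through all diffusion steps.

    params_steps[i] is the packed geometry at the end of step i (row 0 is the
    initial geometry), incs[i-1] the pre-scaled Gaussian displacement of step
    i.  After each step the compartment label (1 = daughter, x > 0) is stored
    at index rec_slot[i] of labels_out when rec_slot[i] >= 0.

    Per-step order: re-interpolate the boundary and push the particle back
    inside if the boundary moved over it; apply the Gaussian displacement;
    remap to the closest admissible point if outside.  Returns 0 on success
    or the 1-based step index at which no primitive could host the particle.
    """
    x = p0[0]
    y = p0[1]
    z = p0[2]
    if rec_slot[0] >= 0:
        labels_out[rec_slot[0]] = 1 if x > 0.0 else 0
    n_steps = incs.shape[0]
    for i in range(1, n_steps + 1):
        pr = params_steps[i]
        if fit_margin(pr, x, y, z, r) < 0.0:
            x, y, z, ok = project_point(pr, x, y, z, r)
            if not ok:
                return i
        x += incs[i - 1, 0]
        y += incs[i - 1, 1]
        z += incs[i - 1, 2]
        if fit_margin(pr, x, y, z, r) < 0.0:
            x, y, z, ok = project_point(pr, x, y, z, r)
            if not ok:
                return i
        if rec_slot[i] >= 0:
            labels_out[rec_slot[i]] = 1 if x > 0.0 else 0
    return 0


@njit(cache=True)
def run_single_positions(params_steps, incs, p0, r, rec_slot, pos_out):
    """Like run_single but records full positions at the recorded steps."""
    x = p0[0]
    y = p0[1]
    z = p0[2]
    if rec_slot[0] >= 0:
        pos_out[rec_slot[0], 0] = x
        pos_out[rec_slot[0], 1] = y
        pos_out[rec_slot[0], 2] = z
    n_steps = incs.shape[0]
    for i in range(1, n_steps + 1):
        pr = params_steps[i]
        if fit_margin(pr, x, y, z, r) < 0.0:
            x, y, z, ok = project_point(pr, x, y, z, r)
            if not ok:
                return i
        x += incs[i - 1, 0]
        y += incs[i - 1, 1]
        z += incs[i - 1, 2]
        if fit_margin(pr, x, y, z, r) < 0.0:
            x, y, z, ok = project_point(pr, x, y, z, r)
            if not ok:
                return i
        if rec_slot[i] >= 0:
            pos_out[rec_slot[i], 0] = x
            pos_out[rec_slot[i], 1] = y
            pos_out[rec_slot[i], 2] = z
    return 0


def warmup():
    """Trigger JIT compilation of all kernels on a tiny problem."""
    params = np.array([-1.5, 1.0, 0.8, 1.0, 0.5, 0.4, 0.5, 0.2, 0.505])
    point_clearance(params, 0.1, 0.0, 0.0)
    project_point(params, 5.0, 0.0, 0.0, 0.05)
    pts = np.zeros((2, 3))
    out = np.zeros(2, dtype=np.bool_)
    contains_batch(params, pts, 0.0, out)
    steps = np.repeat(params[None, :], 3, axis=0)
    incs = np.zeros((2, 3))
    rec = np.array([0, -1, 1], dtype=np.int64)
    labels = np.zeros(2, dtype=np.int8)
    run_single(steps, incs, np.zeros(3), 0.0, rec, labels)
    pos = np.zeros((2, 3))
    run_single_positions(steps, incs, np.zeros(3), 0.0, rec, pos)
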