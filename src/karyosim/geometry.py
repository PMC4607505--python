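"""Composite nuclear geometry of a dividing yeast nucleus.

During anaphase the budding-yeast nucleus elongates through the bud neck and
is well approximated by two prolate spheroids (mother and daughter lobes)
joined by a narrow cylindrical bridge.  This module represents one time point
of that shape (:class:`GeometryFrame`), an ordered time series for one cell
(:class:`GeometrySeries`), and the geometric queries the Brownian-dynamics
simulator needs: signed clearance to the boundary, sphere containment with
volume exclusion, closest-point remapping, uniform volume sampling, and
Monte-Carlo lobe volumes.

Conventions
-----------
* The division axis is x; the bridge midpoint sits at x = 0 and defines the
  mother/daughter boundary (mother at negative x).
* Spheroid tips touch the bridge ends: ``mother.center_x + mother.semi_long
  = -bridge.half_length`` and symmetrically for the daughter.  The cylinder
  is extended axially into each spheroid by 1% of its half-length so the
  union stays connected at the zero-measure tip junctions.
* Measured tables store full extents (lengths and widths, as read off
  microscopy images); they are halved into semi-axes and radii on load.
* All lengths are in micrometres, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .exceptions import (
    DegenerateGeometryError,
    GeometryFormatError,
    GeometryTooNarrowError,
    GeometryValidationError,
    TimeRangeError,
)

#: Fraction of the bridge half-length by which the cylinder is extended into
#: each spheroid to keep the union connected at the tip junctions.
BRIDGE_OVERLAP_FRACTION = 0.01

_TIP_TOL = 1e-9

#: Canonical column names of the geometry CSV dialect.
GEOMETRY_COLUMNS = (
    "cell_id",
    "time_s",
    "mother_length_um",
    "mother_width_um",
    "daughter_length_um",
    "daughter_width_um",
    "bridge_length_um",
    "bridge_width_um",
)


@dataclass(frozen=True)
class SpheroidSpec:
    """One nuclear lobe: a spheroid of revolution about the division axis.

    ``semi_long`` is the semi-axis along x, ``semi_equatorial`` the semi-axis
    perpendicular to it.  The lobes are prolate in intent, but measured
    widths may transiently exceed lengths, so ``semi_long >=
    semi_equatorial`` is deliberately not enforced.
    """

    center_x: float
    semi_long: float
    semi_equatorial: float

    def __post_init__(self) -> None:
        if self.semi_long <= 0 or self.semi_equatorial <= 0:
            raise GeometryValidationError(
                f"spheroid semi-axes must be positive, got "
                f"({self.semi_long}, {self.semi_equatorial})"
            )

    @property
    def volume(self) -> float:
        """Closed-form spheroid volume (4/3) pi a b^2 in um^3."""
        return 4.0 / 3.0 * np.pi * self.semi_long * self.semi_equatorial**2


@dataclass(frozen=True)
class BridgeSpec:
    """The cylindrical nuclear bridge; ``half_length`` is half the tip-to-tip
    extent and ``radius`` half the measured bridge width."""

    half_length: float
    radius: float

    def __post_init__(self) -> None:
        if self.half_length < 0 or self.radius < 0:
            raise GeometryValidationError(
                f"bridge dimensions must be nonnegative, got "
                f"({self.half_length}, {self.radius})"
            )


@dataclass(frozen=True)
class GeometryFrame:
    """One time point of the two-spheroid-plus-bridge nuclear shape."""

    time: float
    mother: SpheroidSpec
    daughter: SpheroidSpec
    bridge: BridgeSpec

    def __post_init__(self) -> None:
        if not (self.mother.center_x < 0.0 < self.daughter.center_x):
            raise GeometryValidationError(
                "mother lobe must be at negative x, daughter at positive x"
            )
        h = self.bridge.half_length
        if abs(self.mother.center_x + self.mother.semi_long + h) > _TIP_TOL:
            raise GeometryValidationError(
                "mother tip does not touch the bridge end: "
                f"{self.mother.center_x + self.mother.semi_long} != {-h}"
            )
        if abs(self.daughter.center_x - self.daughter.semi_long - h) > _TIP_TOL:
            raise GeometryValidationError(
                "daughter tip does not touch the bridge end: "
                f"{self.daughter.center_x - self.daughter.semi_long} != {h}"
            )

    @classmethod
    def from_extents(
        cls,
        time: float,
        mother_length: float,
        mother_width: float,
        daughter_length: float,
        daughter_width: float,
        bridge_length: float,
        bridge_width: float,
    ) -> "GeometryFrame":
        """Build a frame from measured full extents (image measurements).

        Lengths and widths are halved into semi-axes/radii; lobe centres are
        derived from the tip-contact constraint.
        """
        ma, mb = mother_length / 2.0, mother_width / 2.0
        da, db = daughter_length / 2.0, daughter_width / 2.0
        h, r = bridge_length / 2.0, bridge_width / 2.0
        return cls(
            time=time,
            mother=SpheroidSpec(center_x=-(h + ma), semi_long=ma, semi_equatorial=mb),
            daughter=SpheroidSpec(center_x=h + da, semi_long=da, semi_equatorial=db),
            bridge=BridgeSpec(half_length=h, radius=r),
        )

    def packed(self) -> np.ndarray:
        """Packed parameter vector consumed by the numerical kernels."""
        h = self.bridge.half_length
        return np.array(
            [
                self.mother.center_x,
                self.mother.semi_long,
                self.mother.semi_equatorial,
                self.daughter.center_x,
                self.daughter.semi_long,
                self.daughter.semi_equatorial,
                h,
                self.bridge.radius,
                h * (1.0 + BRIDGE_OVERLAP_FRACTION),
            ]
        )

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) of the union."""
        rad = max(
            self.mother.semi_equatorial,
            self.daughter.semi_equatorial,
            self.bridge.radius,
        )
        lo = np.array(
            [self.mother.center_x - self.mother.semi_long, -rad, -rad]
        )
        hi = np.array(
            [self.daughter.center_x + self.daughter.semi_long, rad, rad]
        )
        return lo, hi


@dataclass(frozen=True)
class GeometrySeries:
    """Ordered geometry frames spanning one cell's anaphase."""

    cell_id: str
    frames: tuple[GeometryFrame, ...]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise GeometryValidationError("a geometry series needs >= 2 frames")
        times = np.array([f.time for f in self.frames])
        if not np.all(np.diff(times) > 0):
            raise GeometryValidationError(
                f"frame times must be strictly increasing, got {times.tolist()}"
            )
        object.__setattr__(self, "frames", tuple(self.frames))

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def duration(self) -> float:
        return self.frames[-1].time - self.frames[0].time

    def param_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, scalar parameter rows) for vectorised interpolation.

        Columns: mother semi_long, mother semi_eq, daughter semi_long,
        daughter semi_eq, bridge half_length, bridge radius.
        """
        times = self.times
        tab = np.array(
            [
                [
                    f.mother.semi_long,
                    f.mother.semi_equatorial,
                    f.daughter.semi_long,
                    f.daughter.semi_equatorial,
                    f.bridge.half_length,
                    f.bridge.radius,
                ]
                for f in self.frames
            ]
        )
        return times, tab


@dataclass(frozen=True)
class GeometryMetrics:
    """Summary morphology metrics of one anaphase geometry series."""

    mother_max_length: float
    mother_max_width: float
    mother_final_volume: float
    daughter_max_length: float
    daughter_max_width: float
    daughter_final_volume: float
    mean_bridge_width: float
    final_volume_ratio: float
    anaphase_duration: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mother_max_length": self.mother_max_length,
            "mother_max_width": self.mother_max_width,
            "mother_final_volume": self.mother_final_volume,
            "daughter_max_length": self.daughter_max_length,
            "daughter_max_width": self.daughter_max_width,
            "daughter_final_volume": self.daughter_final_volume,
            "mean_bridge_width": self.mean_bridge_width,
            "final_volume_ratio": self.final_volume_ratio,
            "anaphase_duration": self.anaphase_duration,
        }


class LobeFractions(NamedTuple):
    """Monte-Carlo lobe volume fractions with their binomial standard error."""

    mother: float
    daughter: float
    se: float


# ---------------------------------------------------------------------------
# file I/O


def load_geometry_table(
    path, dialect: Mapping[str, str] | None = None
) -> dict[str, GeometrySeries]:
    """Read a geometry CSV into one :class:`GeometrySeries` per cell.

    Parameters
    ----------
    path:
        CSV with columns ``cell_id, time_s, mother_length_um,
        mother_width_um, daughter_length_um, daughter_width_um,
        bridge_length_um, bridge_width_um`` (full extents, micrometres).
    dialect:
        Optional mapping from canonical column names to the names actually
        present in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    colmap = {c: c for c in GEOMETRY_COLUMNS}
    if dialect:
        colmap.update(dialect)
    for canonical, actual in colmap.items():
        if actual not in df.columns:
            raise GeometryFormatError(
                f"geometry file {path!s} is missing required column "
                f"{actual!r} (for {canonical!r})"
            )
    df = df.rename(columns={v: k for k, v in colmap.items()})
    out: dict[str, GeometrySeries] = {}
    for cell_id, grp in df.groupby("cell_id", sort=False):
        frames = []
        for row in grp.itertuples(index=False):
            dims = (
                row.mother_length_um,
                row.mother_width_um,
                row.daughter_length_um,
                row.daughter_width_um,
                row.bridge_length_um,
                row.bridge_width_um,
            )
            if any(d <= 0 for d in dims):
                raise GeometryValidationError(
                    f"cell {cell_id}: nonpositive dimension at t={row.time_s}"
                )
            frames.append(GeometryFrame.from_extents(row.time_s, *dims))
        out[str(cell_id)] = GeometrySeries(cell_id=str(cell_id), frames=tuple(frames))
    if not out:
        raise GeometryFormatError(f"geometry file {path!s} contains no rows")
    return out


def load_geometry_series(
    path, dialect: Mapping[str, str] | None = None, cell_id: str | None = None
) -> GeometrySeries:
    """Read a single cell's series; ``cell_id`` selects among multiple cells."""
    table = load_geometry_table(path, dialect)
    if cell_id is not None:
        if cell_id not in table:
            raise GeometryFormatError(
                f"cell {cell_id!r} not found in {path!s}; "
                f"available: {sorted(table)}"
            )
        return table[cell_id]
    if len(table) > 1:
        raise GeometryFormatError(
            f"{path!s} contains {len(table)} cells; pass cell_id to choose one"
        )
    return next(iter(table.values()))


def write_geometry_series(series_set: Iterable[GeometrySeries] | GeometrySeries, path) -> None:
    """Write one or more series in the canonical geometry CSV dialect."""
    if isinstance(series_set, GeometrySeries):
        series_set = [series_set]
    rows = []
    for series in series_set:
        for f in series.frames:
            rows.append(
                {
                    "cell_id": series.cell_id,
                    "time_s": f.time,
                    "mother_length_um": 2 * f.mother.semi_long,
                    "mother_width_um": 2 * f.mother.semi_equatorial,
                    "daughter_length_um": 2 * f.daughter.semi_long,
                    "daughter_width_um": 2 * f.daughter.semi_equatorial,
                    "bridge_length_um": 2 * f.bridge.half_length,
                    "bridge_width_um": 2 * f.bridge.radius,
                }
            )
    pd.DataFrame(rows, columns=list(GEOMETRY_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometric queries


def frame_at(series: GeometrySeries, t: float) -> GeometryFrame:
    """Linearly interpolated geometry at time ``t``.

    Every scalar parameter (semi-axes, bridge half-length and radius) is
    interpolated between the bracketing stored frames; lobe centres are then
    re-derived from the tip-contact constraint.
    """
    times = series.times
    if t < times[0] - _TIP_TOL or t > times[-1] + _TIP_TOL:
        raise TimeRangeError(
            f"t={t} outside series span [{times[0]}, {times[-1]}]"
        )
    t = min(max(t, times[0]), times[-1])
    times_arr, tab = series.param_table()
    vals = [float(np.interp(t, times_arr, tab[:, j])) for j in range(6)]
    ma, mb, da, db, h, r = vals
    return GeometryFrame(
        time=t,
        mother=SpheroidSpec(center_x=-(h + ma), semi_long=ma, semi_equatorial=mb),
        daughter=SpheroidSpec(center_x=h + da, semi_long=da, semi_equatorial=db),
        bridge=BridgeSpec(half_length=h, radius=r),
    )


def clearance(frame: GeometryFrame, point: Sequence[float]) -> float:
    """Signed distance (um) of ``point`` to the union boundary.

    Maximum over the three primitives of the per-primitive inside-clearance:
    positive distance to that primitive's surface when inside it, minus the
    distance to the primitive when outside.  Positive iff the point lies
    strictly inside the union.
    """
    x, y, z = point
    return float(_kernels.point_clearance(frame.packed(), x, y, z))


def contains(frame: GeometryFrame, point: Sequence[float], r: float = 0.0) -> bool:
    """True iff a sphere of radius ``r`` centred at ``point`` fits inside.

    Volume exclusion uses a per-primitive erosion convention: the sphere
    must fit entirely within at least one primitive, where for this test the
    bridge cylinder is extended axially into each lobe by ``2 r`` beyond its
    1% connectivity overlap.  The adaptive extension lets the eroded
    cylinder meet the eroded spheroids, so a finite-size particle can cross
    the lobe/bridge junction exactly when the bridge admits it radially
    (bridge radius > r) — matching the behaviour of the true eroded union,
    which a sphere straddling the tangent junction may occupy.  At ``r = 0``
    this reduces to ``clearance(frame, point) >= 0``, i.e. strict membership.
    """
    if r < 0:
        raise ValueError("particle radius must be nonnegative")
    x, y, z = point
    return bool(_kernels.fit_margin(frame.packed(), x, y, z, r) >= 0.0)


def project_inside(
    frame: GeometryFrame, point: Sequence[float], r: float = 0.0
) -> np.ndarray:
    """Remap ``point`` to the nearest position admitting radius ``r``.

    Points already satisfying :func:`contains` are returned unchanged, making
    the operation idempotent.
    """
    if r < 0:
        raise ValueError("particle radius must be nonnegative")
    x, y, z = point
    px, py, pz, ok = _kernels.project_point(frame.packed(), x, y, z, r)
    if not ok:
        raise GeometryTooNarrowError(
            f"no primitive of the frame at t={frame.time} admits radius {r}"
        )
    return np.array([px, py, pz])


def compartment_of(point: Sequence[float]) -> str:
    """Compartment label by the bridge-midpoint rule: daughter iff x > 0.

    The measure-zero tie x == 0 is assigned to the mother for determinism.
    """
    return "daughter" if point[0] > 0 else "mother"


def sample_uniform(
    frame: GeometryFrame,
    n: int,
    r: float = 0.0,
    rng: np.random.Generator | None = None,
    compartment: str | None = None,
) -> np.ndarray:
    """Uniform positions over the r-accessible volume, by rejection sampling.

    Candidates are drawn uniformly from the bounding box of the union and
    accepted when a sphere of radius ``r`` fits.  ``compartment`` optionally
    restricts samples to the mother or daughter side of the bridge midpoint.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    params = frame.packed()
    lo, hi = frame.bounding_box()
    accepted: list[np.ndarray] = []
    n_drawn = 0
    n_acc = 0
    while n_acc < n:
        batch = max(1024, 2 * (n - n_acc))
        pts = rng.uniform(lo, hi, size=(batch, 3))
        mask = np.empty(batch, dtype=bool)
        _kernels.contains_batch(params, pts, r, mask)
        if compartment == "mother":
            mask &= pts[:, 0] < 0
        elif compartment == "daughter":
            mask &= pts[:, 0] > 0
        good = pts[mask]
        n_drawn += batch
        n_acc += len(good)
        accepted.append(good)
        if n_drawn >= 100_000 and n_acc < 1e-4 * n_drawn:
            raise DegenerateGeometryError(
                f"rejection acceptance rate {n_acc / n_drawn:.2e} below 1e-4 "
                f"for frame at t={frame.time}, r={r}"
            )
    return np.concatenate(accepted)[:n]


def mc_lobe_volumes(
    frame: GeometryFrame, n_samples: int = 100_000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Monte-Carlo (mother, daughter) volumes in um^3.

    Bounding-box sampling: volume = box volume x acceptance rate, split by
    the bridge-midpoint compartment rule.
    """
    if rng is None:
        rng = np.random.default_rng()
    params = frame.packed()
    lo, hi = frame.bounding_box()
    box_vol = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(int(n_samples), 3))
    mask = np.empty(len(pts), dtype=bool)
    _kernels.contains_batch(params, pts, 0.0, mask)
    inside = pts[mask]
    v_mother = box_vol * np.sum(inside[:, 0] <= 0) / n_samples
    v_daughter = box_vol * np.sum(inside[:, 0] > 0) / n_samples
    return float(v_mother), float(v_daughter)


def lobe_volume_fractions(
    frame: GeometryFrame, n_samples: int = 100_000, rng: np.random.Generator | None = None
) -> LobeFractions:
    """Monte-Carlo volume fractions of the two lobes (they sum to 1 exactly).

    Uniform point samples over the union (r = 0) are classified by
    :func:`compartment_of`; the binomial standard error of the daughter
    fraction is reported alongside.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10^4 for a stable MC estimate")
    if rng is None:
        rng = np.random.default_rng()
    pts = sample_uniform(frame, int(n_samples), r=0.0, rng=rng)
    fd = float(np.mean(pts[:, 0] > 0))
    se = float(np.sqrt(max(fd * (1 - fd), 1e-12) / n_samples))
    return LobeFractions(mother=1.0 - fd, daughter=fd, se=se)


def series_metrics(
    series: GeometrySeries,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
) -> GeometryMetrics:
    """Morphology summary of one series: per-frame maxima of lobe extents,
    mean bridge width, final-frame Monte-Carlo lobe volumes and their ratio,
    and the anaphase duration."""
    if rng is None:
        rng = np.random.default_rng()
    frames = series.frames
    v_mother, v_daughter = mc_lobe_volumes(frames[-1], n_samples, rng)
    return GeometryMetrics(
        mother_max_length=max(2 * f.mother.semi_long for f in frames),
        mother_max_width=max(2 * f.mother.semi_equatorial for f in frames),
        mother_final_volume=v_mother,
        daughter_max_length=max(2 * f.daughter.semi_long for f in frames),
        daughter_max_width=max(2 * f.daughter.semi_equatorial for f in frames),
        daughter_final_volume=v_daughter,
        mean_bridge_width=float(np.mean([2 * f.bridge.radius for f in frames])),
        final_volume_ratio=v_daughter / v_mother,
        anaphase_duration=series.duration,
    )
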