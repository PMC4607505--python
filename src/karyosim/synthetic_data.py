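"""Synthetic inputs with the statistical structure the pipeline assumes.

Real inputs to this package are microscopy-derived: per-cell nuclear
geometry time series, tracked plasmid jump tables, and colony-count
quadruples.  This module generates stand-ins for all three so every other
module can be exercised and validated without microscopy data:

* anaphase geometry series in which the daughter lobe grows from near zero,
  the bridge elongates and optionally narrows, and the final daughter volume
  fraction lands in a configurable target interval (default 0.33-0.48, the
  measured range for dividing yeast nuclei);
* planar Brownian jump datasets with a known diffusion coefficient;
* binomial colony counts consistent with a known per-generation loss rate.

The geometry trajectories are smooth monotone interpolants between drawn
endpoint values: an emulation of observed morphology ranges, not a fitted
generative model of nuclear shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import JumpDataset, LossRateInput
from .exceptions import GenerationError
from .geometry import GeometryFrame, GeometrySeries

__all__ = [
    "GeometryGenParams",
    "ColonyCounts",
    "generate_geometry_series",
    "generate_brownian_track",
    "generate_colony_counts",
    "preset_params",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class GeometryGenParams:
    """Ranges (min, max) from which one cell's morphology is drawn.

    All linear dimensions are full extents in um (the same convention as the
    geometry CSV dialect), durations in seconds.  The mother lobe starts at
    its maximum extent and shrinks linearly by ``mother_shrink``; the
    daughter grows from ``daughter_initial_*`` to its drawn final extent via
    a smoothstep ramp (monotone by construction); the bridge elongates via
    the same ramp while its width interpolates linearly from initial to
    final.  Cells are redrawn until the closed-form final daughter volume
    fraction lands inside ``daughter_volume_fraction``.
    """

    mother_length: tuple[float, float] = (2.0, 2.6)
    mother_width: tuple[float, float] = (1.4, 1.9)
    daughter_length: tuple[float, float] = (1.5, 2.2)
    daughter_width: tuple[float, float] = (1.1, 1.7)
    bridge_length_initial: tuple[float, float] = (0.4, 0.8)
    bridge_length_final: tuple[float, float] = (2.0, 3.2)
    bridge_width_initial: tuple[float, float] = (0.35, 0.6)
    bridge_width_final: tuple[float, float] = (0.25, 0.5)
    duration: tuple[float, float] = (480.0, 1200.0)
    frame_spacing: float = 30.0
    daughter_volume_fraction: tuple[float, float] = (0.33, 0.48)
    mother_shrink: float = 0.9
    daughter_initial_length: float = 0.3
    daughter_initial_width: float = 0.24
    max_retries: int = 500

    def __post_init__(self) -> None:
        for name in (
            "mother_length",
            "mother_width",
            "daughter_length",
            "daughter_width",
            "bridge_length_initial",
            "bridge_length_final",
            "bridge_width_initial",
            "bridge_width_final",
            "duration",
            "daughter_volume_fraction",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"range {name} must be positive and ordered")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")


#: Named parameter presets.  ``narrow_bridge`` emulates cells that establish
#: a persistently narrow bridge early in anaphase (strong size exclusion);
#: ``wide_bridge`` emulates cells with a wide bridge throughout (transmission
#: sensitive to the diffusion constant instead).
PRESETS: dict[str, GeometryGenParams] = {
    "default": GeometryGenParams(),
    "narrow_bridge": GeometryGenParams(
        bridge_width_initial=(0.16, 0.22),
        bridge_width_final=(0.12, 0.18),
    ),
    "wide_bridge": GeometryGenParams(
        bridge_width_initial=(0.5, 0.7),
        bridge_width_final=(0.45, 0.65),
    ),
}

PRESET_NAMES = tuple(PRESETS)


def preset_params(name: str) -> GeometryGenParams:
    """Look up a named generator preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    return tau * tau * (3.0 - 2.0 * tau)


def _spheroid_volume(length: float, width: float) -> float:
    return 4.0 / 3.0 * np.pi * (length / 2.0) * (width / 2.0) ** 2


def generate_geometry_series(
    params: GeometryGenParams,
    rng: np.random.Generator,
    cell_id: str = "synthetic",
) -> GeometrySeries:
    """Draw one synthetic anaphase geometry series.

    Endpoint dimensions are drawn uniformly from the configured ranges; the
    draw is rejected (and repeated up to ``params.max_retries`` times) until
    the closed-form final daughter volume fraction — spheroid volumes plus
    half the bridge cylinder each — falls inside the target interval.
    """
    u = rng.uniform
    for _ in range(params.max_retries):
        ml = u(*params.mother_length)
        mw = u(*params.mother_width)
        dl = u(*params.daughter_length)
        dw = u(*params.daughter_width)
        bl0 = u(*params.bridge_length_initial)
        bl1 = u(*params.bridge_length_final)
        bw0 = u(*params.bridge_width_initial)
        bw1 = u(*params.bridge_width_final)
        n_frames = int(rng.integers(
            round(params.duration[0] / params.frame_spacing),
            round(params.duration[1] / params.frame_spacing) + 1,
        ))
        v_bridge = np.pi * (bw1 / 2.0) ** 2 * bl1
        v_m = _spheroid_volume(params.mother_shrink * ml, params.mother_shrink * mw)
        v_d = _spheroid_volume(dl, dw)
        frac = (v_d + v_bridge / 2.0) / (v_m + v_d + v_bridge)
        lo, hi = params.daughter_volume_fraction
        if not lo <= frac <= hi:
            continue
        times = params.frame_spacing * np.arange(n_frames + 1)
        tau = times / times[-1]
        ramp = _smoothstep(tau)
        frames = []
        for t, s, lin in zip(times, ramp, tau):
            shrink = 1.0 - (1.0 - params.mother_shrink) * lin
            frames.append(
                GeometryFrame.from_extents(
                    time=float(t),
                    mother_length=shrink * ml,
                    mother_width=shrink * mw,
                    daughter_length=params.daughter_initial_length
                    + s * (dl - params.daughter_initial_length),
                    daughter_width=params.daughter_initial_width
                    + s * (dw - params.daughter_initial_width),
                    bridge_length=bl0 + s * (bl1 - bl0),
                    bridge_width=bw0 + lin * (bw1 - bw0),
                )
            )
        return GeometrySeries(cell_id=cell_id, frames=tuple(frames))
    raise GenerationError(
        f"could not draw a geometry with daughter volume fraction in "
        f"{params.daughter_volume_fraction} after {params.max_retries} tries"
    )


def generate_geometry_set(
    params: GeometryGenParams,
    n_cells: int,
    rng: np.random.Generator,
    prefix: str = "cell",
) -> list[GeometrySeries]:
    """Draw several independent cells with ids ``<prefix>_1 ...``."""
    return [
        generate_geometry_series(params, rng, cell_id=f"{prefix}_{i + 1}")
        for i in range(n_cells)
    ]


def generate_brownian_track(
    D: float, dt: float, n_steps: int, rng: np.random.Generator
) -> JumpDataset:
    """Planar Brownian jump dataset with known D.

    Gaussian increments with per-axis variance 2 D dt; the squared jump
    magnitudes dx^2 + dy^2 are returned, so the expected mean squared jump
    is 4 D dt (d = 2).
    """
    if D < 0 or dt <= 0 or n_steps < 1:
        raise ValueError("need D >= 0, dt > 0, n_steps >= 1")
    inc = rng.standard_normal((n_steps, 2)) * np.sqrt(2.0 * D * dt)
    return JumpDataset(
        jump_sq_displacements=np.sum(inc**2, axis=1), dt=dt, d=2
    )


@dataclass(frozen=True)
class ColonyCounts:
    """Colony counts of a simulated loss-rate assay (T0 and T1 platings)."""

    t0_selective: int
    t0_nonselective: int
    t1_selective: int
    t1_nonselective: int
    n_generations: float

    def to_loss_rate_input(self) -> LossRateInput:
        return LossRateInput(
            T0=self.t0_selective / self.t0_nonselective,
            T1=self.t1_selective / self.t1_nonselective,
            n_generations=self.n_generations,
        )


def generate_colony_counts(
    true_stability: float,
    true_loss_rate: float,
    n_generations: float,
    plated: int,
    rng: np.random.Generator,
) -> ColonyCounts:
    """Binomial colony counts consistent with a known per-generation loss.

    Each plated cell retains the plasmid with probability ``true_stability``
    at T0 and ``true_stability * (1 - true_loss_rate)^n`` after n
    generations of non-selective outgrowth.
    """
    if not 0 < true_stability <= 1:
        raise ValueError("true_stability must be in (0, 1]")
    if not 0 <= true_loss_rate <= 1:
        raise ValueError("true_loss_rate must be in [0, 1]")
    if plated < 1 or n_generations < 1:
        raise ValueError("plated and n_generations must be >= 1")
    p1 = true_stability * (1.0 - true_loss_rate) ** n_generations
    return ColonyCounts(
        t0_selective=int(rng.binomial(plated, true_stability)),
        t0_nonselective=plated,
        t1_selective=int(rng.binomial(plated, p1)),
        t1_nonselective=plated,
        n_generations=n_generations,
    )
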