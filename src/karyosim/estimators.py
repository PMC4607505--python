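"""Measurement-side estimators.

Formulas used to turn raw experimental observables into model inputs and
readouts: the diffusion coefficient from tracked particle jumps, histogram
bin widths for jump-size distributions, plasmid mitotic stability from colony
counts, the per-generation plasmid loss rate, and binomial confidence
intervals for transmission traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError

__all__ = [
    "JumpDataset",
    "LossRateInput",
    "estimate_diffusion",
    "freedman_diaconis_width",
    "mitotic_stability",
    "plasmid_loss_rate",
    "binomial_ci",
    "two_sample_ttest",
]


@dataclass(frozen=True)
class JumpDataset:
    """Squared displacement magnitudes of a tracked particle at fixed lag.

    ``jump_sq_displacements`` are squared planar jump sizes in um^2 sampled
    every ``dt`` seconds; ``d`` is the tracking dimensionality (2 for a
    single imaging plane).  Jumps recorded near the nuclear membrane are
    assumed to have been excluded upstream, so the estimate is a free
    diffusion coefficient.
    """

    jump_sq_displacements: np.ndarray
    dt: float
    d: int = 2

    def __post_init__(self) -> None:
        arr = np.asarray(self.jump_sq_displacements, dtype=float)
        object.__setattr__(self, "jump_sq_displacements", arr)
        if arr.ndim != 1:
            raise ValueError("jump_sq_displacements must be one-dimensional")
        if np.any(arr < 0):
            raise ValueError("squared displacements must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d not in (1, 2, 3):
            raise ValueError("d must be 1, 2 or 3")


@dataclass(frozen=True)
class LossRateInput:
    """Mitotic stabilities before (T0) and after (T1) n generations of
    non-selective outgrowth."""

    T0: float
    T1: float
    n_generations: float

    def __post_init__(self) -> None:
        if not 0 < self.T0 <= 1:
            raise ValueError("T0 must be in (0, 1]")
        if not 0 <= self.T1 <= 1:
            raise ValueError("T1 must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


def estimate_diffusion(jumps: JumpDataset) -> float:
    """Diffusion coefficient D = <x^2> / (2 d dt) in um^2/s.

    ``<x^2>`` is the mean squared jump size over the dataset; for a d-dim
    Brownian path sampled at lag dt this is an unbiased moment estimator.
    """
    if len(jumps.jump_sq_displacements) == 0:
        raise DegenerateDataError("cannot estimate diffusion from zero jumps")
    msd = float(np.mean(jumps.jump_sq_displacements))
    return msd / (2.0 * jumps.d * jumps.dt)


def freedman_diaconis_width(values: Sequence[float]) -> float:
    """Freedman-Diaconis histogram bin width, 2 IQR n^(-1/3).

    The IQR uses linearly interpolated quantiles (numpy's default), a
    convention that matters for small samples.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("need >= 4 values for a Freedman-Diaconis width")
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = q3 - q1
    if iqr <= 0:
        raise DegenerateDataError("IQR is zero; data too degenerate to bin")
    return 2.0 * iqr * arr.size ** (-1.0 / 3.0)


def mitotic_stability(selective_count: int, nonselective_count: int) -> float:
    """Fraction of plated cells retaining the plasmid: colonies on selective
    media divided by colonies on non-selective media.

    Ratios above 1 can occur through counting noise; they are returned
    as-is with a warning rather than rejected.
    """
    if nonselective_count <= 0:
        raise ValueError("nonselective colony count must be positive")
    if selective_count < 0:
        raise ValueError("selective colony count must be nonnegative")
    ratio = selective_count / nonselective_count
    if ratio > 1.0:
        warnings.warn(
            f"mitotic stability {ratio:.3f} exceeds 1 (counting noise)",
            stacklevel=2,
        )
    return ratio


def plasmid_loss_rate(inp: LossRateInput) -> float:
    """Per-generation plasmid loss rate 1 - (T1/T0)^(1/n).

    The per-generation retention (1 - rate) compounded over n generations
    returns T1/T0 exactly.
    """
    return 1.0 - (inp.T1 / inp.T0) ** (1.0 / inp.n_generations)


def binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation binomial confidence interval, clipped to [0, 1].

    p_hat +/- z sqrt(p_hat (1 - p_hat) / trials).  Degenerate at p_hat in
    {0, 1}, where the interval collapses to a point (documented behaviour of
    the Wald interval).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    p = successes / trials
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(p * (1.0 - p) / trials)
    return (max(0.0, p - half), min(1.0, p + half))


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Plain two-sided two-sample t-test helper; returns (statistic, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
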