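# Methods

## Model

A single plasmid is represented as a hard sphere of radius *r* (point
particle when *r* = 0) performing Brownian motion with free diffusion
constant *D* inside the dividing yeast nucleus. The nucleus at any instant
is the union of three primitives on a common division axis (x):

* a **mother** prolate spheroid at negative x,
* a **daughter** prolate spheroid at positive x,
* a **bridge** cylinder spanning the gap, whose midpoint (x = 0) defines the
  mother/daughter boundary.

Spheroid tips touch the cylinder ends (tip-contact constraint), so lobe
centres are fully determined by the semi-axes and the bridge half-length.
Measured inputs are full extents (lengths, widths) in µm, as read off
microscopy images, and are halved into semi-axes on load. Geometry
parameters are piecewise-linearly interpolated in time between measured
frames (native spacing 30 s), giving a smoothly moving boundary. The
simulation ends at the last frame (karyofission); the readout is the
compartment of the particle at that instant.

Assumptions inherited from the model class: plasmid–chromosome and other
crowding interactions are folded into the *effective* measured *D*; there is
no active transport, tethering or pore-mediated barrier; a single plasmid is
simulated per run (no copy-number dynamics); the plasmid is a rigid sphere
rather than a flexible polymer, which brackets the behaviour of a real
polymer between the point-particle and large-sphere limits.

## Geometry numerics

**Signed clearance.** The clearance of a point is the maximum over
primitives of the per-primitive inside-clearance (distance to that
primitive's surface when inside it, minus the distance to the primitive when
outside). Spheroid distances reduce, by rotational symmetry, to a 2D
point-to-ellipse distance, solved as the root of
F(w) = (e₀y₀/(w+e₀²−e₁²))² + (e₁y₁/w)² − 1 with a safeguarded Newton
iteration. F is convex and decreasing, so iterates converge monotonically
after the first step; the substitution w = t + e₁² avoids catastrophic
cancellation for near-axis queries, and queries within 10⁻¹² µm of the axis
use the closed-form evolute case. Accuracy is ≤ 10⁻⁹ µm (verified against a
dense parametric oracle in the tests).

**Volume exclusion.** A sphere of radius r is admissible when it fits
entirely inside at least one primitive. Exact erosion of a non-convex union
has no closed form; the per-primitive convention is cheap and conservative
in the lobes. At the lobe/bridge junctions, however, the tangent tip contact
makes naive per-primitive erosion disconnect: the eroded cylinder and eroded
spheroid share no point for any realistic r, which would forbid *all*
finite-size passage — contradicting the behaviour of the true eroded union,
which a sphere straddling the junction can occupy whenever the bridge admits
it radially. The containment test therefore extends the bridge cylinder
axially into each lobe by 2r (beyond the fixed 1% connectivity overlap used
at r = 0). With this extension the eroded cylinder overlaps the eroded
spheroids, and junction passage occurs exactly when bridge radius > r, the
same threshold as the true eroded union. The price is a thin collar of
admissible centres near the junction where the sphere can marginally
protrude into the cusp region between primitives; the collar is of order r
in extent and negligible in volume for the r ≤ 0.1 µm regime the package
targets. r = 0 behaviour (membership, sampling, Monte-Carlo volumes) is
unaffected.

**Closest-point remapping.** Projection onto the admissible set takes the
best candidate over per-primitive projections. Cylinder projection is a
clamp. Spheroid projection uses the parallel-surface property — the nearest
point of the eroded spheroid shares its ellipse foot point with the query —
refined by a secant iteration along the surface normal to absorb curvature;
where the inner parallel surface self-intersects (foot near a tip with
r exceeding the tip curvature radius b²/a) it falls back to a bisection
toward the spheroid centre, which always has maximal clearance min(a, b).
Projected points overshoot the constraint by 10⁻⁹ µm so they strictly
satisfy containment, making projection idempotent to machine precision.
Agreement with a 0.005 µm lattice brute-force argmin is verified in tests.

**Sampling and volumes.** Initial positions are rejection-sampled uniformly
from the bounding box, accepting admissible points; an acceptance rate below
10⁻⁴ raises a degenerate-geometry error. Lobe volumes and volume fractions
are Monte-Carlo estimates over uniform point samples classified by the
bridge-midpoint rule (x = 0 ties go to the mother, a documented measure-zero
tie-break), with binomial standard errors reported. Monte-Carlo volume
estimation uses RNG streams independent of the simulation streams.

## Time stepping

The nominal step is δt = s²ᵣₑₛ/(mD), tying spatial resolution s_res to the
per-axis RMS displacement; defaults s_res = 0.025 µm and m = 4 (per-axis RMS
of s_res/2 per step). The step actually used is rounded *down* to
record_interval / ⌈record_interval/δt⌉ so that steps land exactly on the
recorded occupancy times; recorded labels therefore always refer to the
geometry at the recorded time, never up to one step later. Rounding down
preserves the resolution bound. Boundary motion per step is O(δt) (linear
interpolation between frames), subordinate to the O(√δt) diffusive motion.

Per-step order: (1) advance the clock and re-interpolate the geometry,
projecting the particle back inside if the moving boundary passed over it;
(2) apply the Gaussian displacement; (3) project again if the displacement
left the admissible set. A final partial step lands exactly on the last
frame time.

## Randomness

Each ensemble derives per-repeat substreams from one root seed via
`numpy.random.SeedSequence.spawn` with Philox counters, so repeats are
independent, order-invariant and reproducible bit-for-bit under a fixed
(seed, config, geometry) triple. Parameter sweeps and the time-step study
derive independent per-combination seeds the same way. Daughter-fraction
confidence bounds are normal-approximation (Wald) binomial intervals,
p̂ ± 1.959964·√(p̂(1−p̂)/n), clipped to [0, 1]; the interval degenerates to a
point at p̂ ∈ {0, 1}, a documented property of this interval rather than a
claim of certainty.

## Estimators

* Diffusion: D = ⟨x²⟩/(2dΔt) from squared jump magnitudes at fixed lag;
  d is the tracking dimensionality (2 for single-plane tracking; isotropy
  makes dropping the out-of-plane axis unbiased when d is set accordingly).
  Jumps near the nuclear membrane are assumed excluded upstream so the
  estimate is a free diffusion coefficient.
* Freedman–Diaconis bin width 2·IQR·n^(−1/3), IQR by linearly interpolated
  quantiles (numpy's default convention; the method is convention-sensitive
  at small n, so the choice is pinned here).
* Mitotic stability: selective/non-selective colony ratio; ratios above 1
  (counting noise) warn but are returned unchanged.
* Loss rate: 1 − (T1/T0)^(1/n); compounding the per-generation retention n
  times recovers T1/T0 identically.
* A plain two-sided two-sample t-test helper is provided for between-strain
  comparisons; no claim is made that it reproduces any particular published
  P value, since such tests are rarely fully specified.

## Synthetic data generator

The generator emulates measured anaphase morphology at the level of summary
metrics, not as a fitted model: endpoint dimensions are drawn uniformly from
configured ranges, the daughter grows from near zero via a monotone
smoothstep ramp, the bridge elongates the same way while its width
interpolates linearly, and the mother shrinks linearly by 10%. Draws are
rejected until the closed-form final daughter volume fraction (spheroid
volumes plus half the bridge each) lies in the target interval, 0.33–0.48 by
default — the measured range for dividing yeast nuclei, whose measured mean
(42%) the generator reproduces. Defaults (mother 2.0–2.6 × 1.4–1.9 µm,
daughter 1.5–2.2 × 1.1–1.7 µm, bridge elongating 0.4–0.8 → 2.0–3.2 µm,
anaphase 480–1200 s, 30 s frames) are fixed study conditions chosen to be
biologically plausible for budding yeast. Two presets reproduce the
geometry-specific contrasts seen across real cells: `narrow_bridge`
(persistently narrow bridge, 0.12–0.22 µm width — strong size exclusion,
weak D sensitivity) and `wide_bridge` (0.45–0.7 µm — transmission governed
by D instead).

What the generator does **not** emulate: correlations among morphology
metrics (only ranges are matched), membrane fluctuations, bent or curved
bridges, or cell-to-cell correlation structure of real populations. Passing
tests therefore demonstrate correctness of the simulator and estimators
under the assumed geometry class, not fidelity of any particular synthetic
cell to a particular real one. The loss-rate assay generator uses n = 8
generations and 10⁵ plated cells so the post-outgrowth colony count is far
from the degenerate zero-count regime.

## Numerical and design choices

| Parameter | Default | Why |
| --- | --- | --- |
| D | 0.0027 µm²/s | mean measured plasmid diffusion constant |
| particle radius | 0 / 0.05 µm | point particle and 50 nm sphere representations |
| s_res | 0.025 µm | ~6× finer than the 0.16 µm imaging resolution |
| m | 4 | conservative margin for moving boundaries; final fractions are insensitive across m = 1–8 |
| record_interval | 30 s | native frame spacing of measured geometries |
| repeats | 300 (traces), 1000 (sweeps), 5000 (validation) | binomial SE of ~3%, ~1.6%, ~0.7% |
| ellipse solver tolerance | 10⁻¹⁵ relative | distance accuracy ≤ 10⁻⁹ µm |
| projection overshoot | 10⁻⁹ µm | strict containment, idempotent remap |
| bridge overlap | 1% of half-length (+2r for fit tests) | connected union; junction passage threshold matches true erosion |

Degenerate inputs: geometries whose primitives all shrink below the particle
radius raise a simulation error naming the failing time; hair-thin sampling
targets raise a degenerate-geometry error; zero IQR raises a degenerate-data
error rather than returning an unusable bin width.

## Limitations

* The composite-primitive geometry cannot represent bent bridges, membrane
  fluctuations or arbitrary meshes.
* The junction collar introduced by the adaptive bridge extension slightly
  over-permits sphere centres within ~r of the tip-contact circle; exact
  union erosion would require a numerical offset-surface construction out of
  scope here.
* Wald intervals undercover near p = 0 or 1; traces at the extremes should
  be read with that in mind.
* Reported transmission percentages on synthetic geometries characterise the
  synthetic study conditions; they are not estimates for any measured cell.
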