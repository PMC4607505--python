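# karyosim

Stochastic spatial simulation of plasmid segregation during budding-yeast
nuclear division.

In *Saccharomyces cerevisiae*, autonomously replicating plasmids (ARS
plasmids, ERCs) are inherited asymmetrically: daughters receive fewer copies
than simple volume sharing would predict, a bias implicated in replicative
aging. One candidate explanation needs no active diffusion barrier at all —
during anaphase the nucleus elongates into two lobes joined by a narrow
bridge, and a passively diffusing plasmid simply fails to equilibrate across
the moving, constricting geometry before karyofission. `karyosim` implements
that morpho-kinetic model for anyone who wants to test it quantitatively:
a Brownian particle of radius *r* diffusing inside a time-varying nuclear
geometry built from two prolate spheroids connected by a cylindrical
bridge, with the bridge midpoint defining the mother/daughter boundary.

## Model

* **Geometry.** Each time point is a mother spheroid, a daughter spheroid
  and a bridge cylinder on a common division axis, parameterised by measured
  lengths and widths (µm); parameters are linearly interpolated between
  frames so the boundary moves smoothly.
* **Dynamics.** Time step δt = s²ᵣₑₛ/(mD) (defaults s_res = 0.025 µm,
  m = 4). Each step applies an isotropic Gaussian displacement with
  per-axis variance 2Dδt; excursions beyond the boundary are remapped to the
  closest admissible point, and the moving boundary itself pushes particles
  back inside. Volume exclusion treats the plasmid as a hard sphere that
  must fit within the (locally eroded) geometry, which can block passage
  through bridges narrower than the particle.
* **Readouts.** Transmission traces (fraction of an ensemble in the
  daughter lobe over time, with 95% binomial confidence intervals), final
  transmission versus diffusion constant D and particle radius r, and
  Monte-Carlo lobe volume fractions for comparison.
* **Estimators.** Diffusion coefficient from tracked jumps,
  D = ⟨x²⟩/(2dΔt); Freedman–Diaconis histogram widths 2·IQR·n^(−1/3);
  mitotic stability (selective/non-selective colony ratio); per-generation
  plasmid loss rate 1 − (T1/T0)^(1/n).
* **Synthetic data.** A geometry generator emulating measured anaphase
  morphologies (final daughter volume fraction in 33–48% by default), plus
  Brownian-track and colony-count generators with known ground truth, so
  the whole pipeline is testable without microscopy data.

## Worked example

```python
import numpy as np
import karyosim as ks
from karyosim import synthetic_data as sd

rng = np.random.default_rng(7)
series = sd.generate_geometry_series(
    sd.preset_params("wide_bridge"), rng, cell_id="demo"
)
print("frames:", len(series.frames), " anaphase duration:", series.duration, "s")

vf = ks.lobe_volume_fractions(series.frames[-1], 100_000, np.random.default_rng(1))
print(f"final daughter volume fraction: {vf.daughter:.3f} +/- {vf.se:.3f}")

for r in (0.0, 0.05):
    cfg = ks.SimulationConfig(D=0.0027, particle_radius=r, n_repeats=300, seed=42)
    tr = ks.run_ensemble(series, cfg)
    print(f"r = {r*1000:3.0f} nm: final transmission "
          f"{tr.final_daughter_fraction:.3f} "
          f"(95% CI {tr.ci_low[-1]:.3f}-{tr.ci_high[-1]:.3f})")
```

Output:

```
frames: 20  anaphase duration: 570.0 s
final daughter volume fraction: 0.373 +/- 0.002
r =   0 nm: final transmission 0.077 (95% CI 0.047-0.107)
r =  50 nm: final transmission 0.063 (95% CI 0.036-0.091)
```

Although the daughter lobe ends up holding 37% of the nuclear volume, only
~8% of point particles (and fewer 50 nm spheres) end up there: the moving,
constricting geometry alone retains plasmids in the mother — no diffusion
barrier is involved.

The same workflows are available from the shell:

```sh
karyosim synth-geometry --preset wide_bridge --n-cells 3 --seed 7 -o cells.csv
karyosim simulate cells.csv --repeats 300 --diffusion 0.0027 -o trace.csv
karyosim sweep cells.csv -D 0.001 -D 0.005 -D 0.009 -r 0 -r 0.05 -o sweep.csv
karyosim geometry-metrics cells.csv
```

Each command writes a JSON manifest (config, seed, input hashes, version)
next to its output so runs can be replayed bit-identically.

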