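# nemalign

Stress–shape misalignment in confluent cell monolayers: a two-field
active-nematic continuum model with a hybrid lattice-Boltzmann solver,
and the tissue-analysis pipeline that measures misalignment statistics
identically in simulations and in experiment-like data.

## The problem

Epithelial monolayers behave as active nematics: elongated cells define a
shape director **n**, and the contractile forces each cell generates
define a stress director **m** (the principal axis of the measured
in-plane stress tensor). Most continuum theories assume **n** and **m**
coincide. Measurements on MDCK islands show instead dynamic, correlated
domains where the two axes are systematically misaligned: defining
θ = cos⁻¹(**n**·**m**) ∈ [0°, 90°], a substantial area fraction of tissue
is *extensile* (θ > 45°, pulling along the short cell axis) inside a
mostly *contractile* (θ < 45°) background, with topological ±1/2 defects
of the shape field concentrated at the extensile/contractile interfaces.

`nemalign` is for modellers and image/stress-data analysts who want to
simulate this decoupled-director mechanism and to quantify misalignment,
interface domains, defects and correlation functions in gridded or
per-cell data.

## The model

Both orientations are symmetric traceless order parameters
Qⁿ = Sⁿ(**nn** − I/2), Qᵐ = Sᵐ(**mm** − I/2) governed by the free energy
density

    f = (C/2)(1 − 3Qⁿ:Qⁿ)² + (C/2)(1 − 3Qᵐ:Qᵐ)²
      + (Kₙ/2)|∇Qⁿ|² + (Kₘ/2)|∇Qᵐ|²
      + (J/2)(1 − 3Qⁿ:Qᵐ)²

with Kₙ > Kₘ (shape orientations are stiffer, hence longer-ranged, than
stress orientations) and a weak coupling J that slowly realigns the two
axes. Both tensors follow co-rotational relaxational dynamics,

    (∂ₜ + u·∇) Qˣ = −Ω·Qˣ + Qˣ·Ω + γ Hˣ,   x ∈ {n, m},

where Ω is the fluid vorticity, γ the rotational diffusivity and
Hˣ = −(δf/δQˣ − (I/2)Tr δf/δQˣ) the molecular field. The flow obeys
ρ(∂ₜ + u·∇)u = ∇·Π with active stress Π_act = −ζQᵐ (ζ < 0: contractile,
generated along the stress fibres) plus the passive viscous,
torque (QH − HQ) and Ericksen stresses. The momentum equation is solved
with a D2Q9 lattice-Boltzmann method (BGK collision, Guo forcing); the
order-parameter dynamics with second-order finite differences. Because
the two directors respond differently to the same active flow, vorticity
continuously regenerates misalignment that J slowly relaxes — extensile
patches emerge, and defects ride their boundaries.

Unit calibration: 1 lattice unit = 3 μm, 100 lattice time units = 10 min.

Two scenarios are built in:

* **mdck** — 200×200 periodic box, random initial directors, 120,000
  steps (active turbulence; a 128×128 / 40,200-step reduction is used for
  desk-scale checks), parameters γ=0.4, Kₙ=0.065, Kₘ=0.005, J=0.0008,
  ζ=−0.03, ρ=40, η=20/3, C=1/30.
* **lp9** — passive island (ζ=0) of radius R=80 with a pinned +1/2 defect
  in the shape field; the stress field relaxes into metastable states
  carrying a persistent extensile patch adjacent to the defect
  (Kₘ=0.02, Kₙ=0.01, exterior bulk scale C′=0.003).

## Worked example

Generate one synthetic MDCK-like island (1 mm diameter, 2500 cells per
frame, shape/stress correlation lengths 100/50 μm, target extensile
fraction 0.27) and push it through the full measurement stack:

```python
import numpy as np
from nemalign.synth import SynthConfig, generate_frames
from nemalign.analysis import analyze_cells, misalignment_histogram

cfg = SynthConfig(n_frames=4, extensile_target=0.27, seed=42)
tables, grids = generate_frames(cfg)

reports = [analyze_cells(t, cfg.diameter_um) for t in tables]
theta = np.concatenate([r.theta_deg[r.disc] for r in reports])
centres, density, extensile = misalignment_histogram(theta, n_bins=9)

print(f"extensile fraction:     {np.mean([r.extensile_fraction for r in reports]):.3f}")
print(f"interface fraction:     {np.mean([r.interface_fraction for r in reports]):.3f}")
print(f"defects per frame:      {np.mean([r.n_defects for r in reports]):.1f}")
print(f"mean misalignment:      {theta.mean():.1f} deg")
```

prints

```
extensile fraction:     0.250
interface fraction:     0.090
defects per frame:      16.0
mean misalignment:      30.5 deg
```

The extensile fraction recovered by the pipeline (0.250 over four
correlated frames) fluctuates around the configured target 0.27; the
interface fraction is the area within 5.2 μm (the stress-measurement
resolution) of an extensile/contractile boundary; defects are ±1/2
disclinations of the gridded shape-director field.

The same measurements run on simulation output:

```python
from nemalign import RunConfig, mdck_params, run
from nemalign.analysis import simulation_frame_stats

traj = run(RunConfig(nx=128, ny=128, steps=40_200, frame_every=300, seed=1),
           mdck_params())
stats = [simulation_frame_stats(traj.qn(i), traj.qm(i))
         for i in range(traj.n_frames - 50, traj.n_frames)]
```

A command-line interface mirrors the library:
`nemalign simulate|synth|analyze|lp9|report` (see `nemalign --help`);
every output directory carries a manifest (config hash, seeds, unit
calibration) making runs bit-reproducible.

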