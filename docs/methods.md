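# Methods

## Model

The tissue is described by two symmetric traceless 2×2 order parameters
on a shared grid: Qⁿ (cell-shape orientation, director **n**, magnitude
Sⁿ) and Qᵐ (contractile-stress orientation, director **m**, magnitude
Sᵐ). The free-energy density

f = (C/2)(1 − 3Qⁿ:Qⁿ)² + (C/2)(1 − 3Qᵐ:Qᵐ)²
  + (Kₙ/2)|∇Qⁿ|² + (Kₘ/2)|∇Qᵐ|² + (J/2)(1 − 3Qⁿ:Qᵐ)²

has its bulk minimum at S = √(2/3) for both tensors (Q:Q = 1/3, full
double contraction). The homogeneous aligned state Sⁿ = Sᵐ = √(2/3),
**n** = **m** is an exact stationary point of the molecular fields and is
dynamically stable; this is verified to 1e−10 in the tests.

Dynamics: (∂ₜ + u·∇)Qˣ = −Ω·Qˣ + Qˣ·Ω + γHˣ with
Hˣ = −(δf/δQˣ − (I/2)Tr δf/δQˣ) and the flow-tumbling parameter zero, so
only vorticity rotates the directors. The expanded molecular fields are

Hⁿ = 6C(1 − 3Qⁿ:Qⁿ)Qⁿ + Kₙ∇²Qⁿ + 3J(1 − 3Qⁿ:Qᵐ)Qᵐ

(roles swapped for Hᵐ); they are validated against a central-difference
functional derivative of the discrete total free energy (relative error
< 1e−5 on random states) rather than assumed. The momentum balance
ρ(∂ₜ + u·∇)u = ∇·Π carries Π = Π_active + Π_passive with
Π_active = −ζQᵐ; Π_passive is the lattice-Boltzmann ideal pressure and
viscous stress plus, for each order parameter, the antisymmetric torque
stress Q·H − H·Q and the Ericksen stress −K ∂αQᵢⱼ ∂βQᵢⱼ. The sign of the
torque stress is fixed by power balance: the kinetic-energy input
2ωτ exactly cancels the co-rotation term's free-energy rate, so with
ζ = 0 the total (free + kinetic) energy is non-increasing (verified
numerically).

## Numerics

* **Fluid**: D2Q9 lattice Boltzmann, BGK collision, Guo forcing for the
  body force ∇·(Π_active + Π_torque + Π_Ericksen); velocity includes the
  half-force correction. ν = c_s²(τ − ½), c_s² = 1/3; the MDCK values
  ρ = 40, η = 20/3 give τ = 1 exactly. Streaming conserves mass to
  machine precision; the measured decay rate of a sinusoidal shear wave
  reproduces η/ρ to better than 0.1%.
* **Order parameters**: explicit Euler, dt = 1 LB step; advection,
  vorticity and stress divergences use second-order central differences
  on the periodic grid. The elastic energy density uses forward
  differences, whose discrete adjoint is exactly the five-point Laplacian
  in H — relaxation is then an exact gradient descent of the discrete
  free energy (monotone to round-off), which the central-difference
  energy stencil would violate.
* **Storage**: only (Qxx, Qxy) are stored; tracelessness and symmetry are
  structural. Angles are radians in [0, π) internally, degrees at user
  interfaces.
* **Vorticity sign**: fixed once so that rigid-body flow u = ω(−y, x)
  co-rotates both directors at rate ω (the physically consistent choice;
  the torque-stress sign follows from it via the power balance above).
* **Stability**: γKₙ = 0.026 is far below the diffusive limit; the
  advection CFL number |u|dt stays below 0.02 in practice and is checked
  every step.

## Parameters

MDCK (active turbulence): γ = 0.4, Kₙ = 0.065, Kₘ = 0.005, J = 0.0008,
ζ = −0.03 (contractile), ρ = 40, η = 20/3, C = 1/30 (all LB units).
LP-9 (passive island): Kₘ = 0.02, Kₙ = 0.01, ζ = 0, C′ = 0.003, R = 80,
other values as MDCK. Physical calibration: 1 lattice unit = 3 μm,
100 time units = 10 min, so the standard frame interval of 300 steps is
30 min and the 5.2 μm stress resolution is ≈1.73 lattice units.

The bulk scale C deserves comment. The extensile area fraction and the
LP-9 metastability are governed almost entirely by how strongly the bulk
term regularises the order magnitude: for C ≲ 3e−3 the order is
effectively unconstrained (S̄ drifts to ≈0.55, defect cores are nearly
free), the steady extensile fraction collapses to ~3%, and the LP-9
stress field always anneals to full alignment. For C ≳ 0.03 the order is
pinned near √(2/3) and both phenomena appear robustly; the statistics are
then insensitive to the exact value (C = 1/30 and C = 0.1 are
indistinguishable). The default C = 1/30 sits in this saturated regime.
At these conditions the desk-scale MDCK run yields a steady extensile
fraction of ≈12%, an interface fraction of ≈20% and a defect–interface
colocalization of ≈87% (means over the last 50 frames; the tests state
the reference bands they check against). The extensile fraction also
falls steeply with the realignment coupling J (≈39% at J/4, ≈13.5% at
J = 8e−4, ≈0 at 4J at fixed C), so quantitative misalignment levels
should be read as J-and-C-conditional.

## Scenarios and protocols

* **MDCK**: random i.i.d. director angles with S = 1, fluid at rest;
  200×200 periodic box, 120,000 steps, a frame every 300 steps. Steady
  state is declared when Mann–Kendall trend tests on the defect count and
  the extensile fraction are both insignificant (α = 0.05) over the
  remaining tail; measurements average the final 150 frames. Desk-scale
  work (tests and the acceptance script) uses 128×128 over 40,200 steps
  with the final 50 frames, which reaches the same plateau — these sizes
  are the package's standard reduced protocol.
* **Activity ablation**: ζ = 0 relaxes the same initial condition to the
  aligned state — extensile fraction < 1%, defect count ~0, flows decay —
  demonstrating that activity drives the misalignment.
* **LP-9**: Qⁿ is imprinted with director angle φ/2 (φ the polar angle),
  core regularised as S = S_bulk·tanh(r/2), tapered to zero at the island
  edge, and held fixed; the defect centre sits between lattice sites so
  the angle is defined everywhere. Qᵐ starts from a smooth random nematic
  texture (correlation length R) and relaxes by ∂ₜQᵐ = γHᵐ alone, with
  the exterior bulk term (C′/2)(Q:Q)² suppressing order outside R.
  Site-independent random initial angles were rejected: they imprint the
  pinned winding locally everywhere and always anneal to the fully
  aligned minimum, whereas a smooth texture — the physically sensible
  state for an ordered, low-defect tissue — reaches the metastable
  branch. Relaxation stops at max|γHᵐ| < 1e−7 or a step cap; states
  hitting the cap are flagged metastable-drift. Across seeds the system
  settles either into full alignment or into a persistent extensile
  patch (stable over 200k steps) whose inner edge touches the defect core
  and whose area centroid sits at ≈0.51–0.56 R at a seed-dependent
  angular position; the island interior then carries no stress-field
  defect (the displaced charge lives in the disordered exterior).

## Analysis pipeline

Per-cell tables (centroid, shape angle, aspect ratio, stress tensor) are
gridded with lattice constant dl = L/√N: each cell to its closest site,
collisions resolved closest-first (ties by input order), empty sites
filled from the nearest occupied site. All interpolation (grid
refinement) acts on (cos 2ψ, sin 2ψ) — never on raw angles — so the
nematic π-periodicity is respected. The contractile-stress axis is the
positive-eigenvalue direction of the trace-removed stress tensor, with
magnitude √(((σxx−σyy)/2)² + σxy²); isotropic tensors are flagged and
excluded. θ is the nematic angular distance in [0°, 90°]; θ = 45° counts
as contractile (strict inequality for extensile). Defects are found by
plaquette winding with successive differences wrapped to (−π/2, π/2];
adjacent same-charge plaquettes merge to their centroid; +1/2
orientations come from a ring average of exp(2i(ψ − kφ)) — any
rotation-equivariant convention is acceptable and this one is verified
equivariant. Interface domains are sites whose Euclidean distance to the
opposite misalignment class is at most 5.2 μm; interface sites are
removed from the extensile/contractile tallies so the three fractions
partition the tissue. Correlation functions implement
C(r) = ⟨cos 2(ψ(r+r₀) − ψ(r₀))⟩ (FFT autocorrelation on periodic grids,
direct pair sums on masked island data restricted to a central 312 μm
disc) and the normalised velocity correlation; correlation lengths are
the interpolated 1/e crossings. Experimental-resolution statistics
(interface, defects) on cell-gridded data are computed after refining the
director grid to ≈5.2 μm mesh, since the cell-grid spacing (~20 μm)
exceeds the interface band width.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, with every
scale calibrated in closed form. Orientation fields are Gaussian-smoothed
white noise on the nematic components; for component correlation ρ(r)
the measured orientation correlation is C(r) = (π/4)ρ·₂F₁(½,½;2;ρ²), so
the filter width follows analytically from the requested 1/e length
(round-trip accurate to a few percent). The stress orientation is the
shape orientation rotated by σ·z(x) where z is a unit-variance Gaussian
field: σ is solved (with wrapping) from the target extensile fraction,
and z's correlation length from the requested stress-orientation length
ℓₘ via C_m(r) = C_n(r)·exp(−4σ²(1−ρ_z(r))). z is rank-mapped to exact
normal quantiles each frame so the realised fraction matches its
calibration without per-realisation drift. Temporal evolution is AR(1)
mixing of the underlying components with coefficient chosen so the
measured angular decorrelation crosses 1/e at the configured persistence.
Stress tensors are rebuilt from (angle, magnitude, isotropic part) with a
fixture decline law mag ∝ 0.35 + 0.65cos²θ (the qualitative weakening of
contraction with misalignment); aspect ratios are shifted log-normal with
mode ≈1.5 (a fixture choice). What the generator does **not** emulate:
mechanical force balance of the stress grids, cell packing geometry,
boundary effects at the island rim, or defect-mediated dynamics — passing
round-trip tests therefore validates the measurement stack and the
calibrations, not any biological mechanism.

## Problem sizes

Defaults used by the test suite and the acceptance script: MDCK 128×128
over 40,200 steps (last 50 frames), ablation 96×96 over 21,000 steps,
LP-9 96×96 with R = 38 over 40,000 steps (two seeds), synthetic islands
of 2500 cells over 32 frames. These sizes reach the statistical plateaus
of their full-size counterparts.

## Known limitations

* The quantitative extensile fraction is strongly parameter-conditional
  (see the C and J sensitivities above); the desk-scale default yields
  ≈12%, below the ≈28% experimental scale, while interface fraction and
  defect colocalization land on their expected values.
* Defect clusters spanning the periodic seam can occasionally be counted
  twice during merging (labeling is non-periodic); at observed defect
  densities this is negligible.
* The LP-9 relaxation at the full island radius does not reach the
  stationarity tolerance within practical step budgets; the patch
  geometry is stable long before (flagged metastable-drift, fraction
  changes < 0.1 points over 100k steps).
* Correlation lengths measured through the cell-gridding pipeline carry a
  +10–20% bias from nearest-cell assignment jitter; the FFT route on
  gridded fields is unbiased.
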