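"""Model parameters, run configuration, and unit calibration.

All simulation quantities are in lattice-Boltzmann (LB) units. The
calibration to physical units is fixed by matching the decay of the
orientation correlation functions between simulation and experiment:
10 LB length units correspond to ~30 um of tissue, and 100 LB time
units to ~10 min.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

# LB -> physical unit calibration (see module docstring).
MICRONS_PER_LU = 3.0
MINUTES_PER_STEP = 0.1

#: Spatial resolution of the monolayer stress measurement (um). Sites closer
#: than this to an extensile/contractile boundary form the interface domain.
STRESS_RESOLUTION_UM = 5.2


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-tensor free energy and hydrodynamics.

    Defaults are the MDCK parameter set. ``zeta < 0`` corresponds to
    contractile activity (cells pull inward along the stress director m).

    Attributes
    ----------
    C : bulk free-energy scale for both order parameters. Values well
        below ~0.03 leave the order magnitude essentially unregulated
        (defect cores become free and neither misalignment patches nor
        island metastability survive); the default keeps S pinned near
        its equilibrium sqrt(2/3).
    K_n, K_m : elastic constants penalising gradients of the shape (n)
        and stress (m) orientations. ``K_n > K_m`` gives the shape
        director the longer correlation length seen in experiments.
    J : shape-stress coupling; relaxes the misalignment angle.
    gamma : rotational diffusivity of both directors.
    zeta : activity; the active stress is ``-zeta * Q^m``.
    rho, eta : fluid mass density and dynamic viscosity.
    C_prime : exterior bulk scale for island geometries (LP-9 only).
    R : island radius in lattice units (LP-9 only).
    """

    C: float = 1e-1 / 3
    K_n: float = 0.065
    K_m: float = 0.005
    J: float = 0.0008
    gamma: float = 0.4
    zeta: float = -0.03
    rho: float = 40.0
    eta: float = 20.0 / 3.0
    C_prime: float | None = None
    R: float | None = None

    def __post_init__(self) -> None:
        for name in ("C", "K_n", "K_m", "J", "gamma", "rho", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.zeta > 0:
            import warnings

            warnings.warn(
                f"zeta = {self.zeta} > 0 is extensile activity, outside the "
                "contractile regime the model was calibrated in",
                stacklevel=2,
            )
        if self.C_prime is not None and self.C_prime <= 0:
            raise ValueError("C_prime must be positive when set")
        if self.R is not None and self.R <= 0:
            raise ValueError("R must be positive when set")

    @property
    def nu(self) -> float:
        """Kinematic viscosity eta/rho (LB units)."""
        return self.eta / self.rho

    def to_dict(self) -> dict:
        return asdict(self)


def mdck_params(**overrides) -> ModelParams:
    """The MDCK (active turbulence) parameter set."""
    return ModelParams(**overrides)


def lp9_params(**overrides) -> ModelParams:
    """The LP-9 (passive island, pinned defect) parameter set.

    Same as MDCK except K_m=0.02, K_n=0.01, zeta=0, C'=0.003, R=80.
    """
    defaults = dict(K_m=0.02, K_n=0.01, zeta=0.0, C_prime=0.003, R=80.0)
    defaults.update(overrides)
    return ModelParams(**defaults)


@dataclass
class RunConfig:
    """Schedule and initial conditions for a simulation run."""

    nx: int = 200
    ny: int = 200
    steps: int = 120_000
    frame_every: int = 300
    seed: int = 0
    s_init: float = 1.0
    scenario: str = "mdck"  # "mdck" | "lp9"
    microns_per_lu: float = MICRONS_PER_LU
    minutes_per_step: float = MINUTES_PER_STEP
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if self.steps % self.frame_every != 0:
            raise ValueError("frame_every must divide steps")
        if self.scenario not in ("mdck", "lp9"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def n_frames(self) -> int:
        return self.steps // self.frame_every

    def to_dict(self) -> dict:
        return asdict(self)
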