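"""LP-9 scenario: a pinned +1/2 shape defect in a passive circular island.

The shape director n is imprinted with a +1/2 disclination at the island
centre (angle = polar angle / 2) and held fixed; the stress tensor Q^m
relaxes towards the free-energy minimum with no flow and no activity
(zeta = 0). Outside the island radius R an exterior bulk term
(C'/2)(Q:Q)^2 drives the order to zero. The relaxed state is metastable:
an extensile patch forms next to the defect and its position and size
depend on the initial condition for m.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import energy
from .analysis import find_defects, interface_domains
from .params import ModelParams, lp9_params
from .qtensor import QTensorField, director_from_q, nematic_distance, q_from_director

S_BULK = np.sqrt(2.0 / 3.0)  # order magnitude minimising the interior bulk term


@dataclass
class LP9Config:
    """Geometry, parameters and stopping rule for the LP-9 relaxation."""

    nx: int = 200
    ny: int = 200
    R: float = 80.0
    centre: tuple[float, float] | None = None  # (x, y); defaults to box centre
    seed: int = 0
    s_init: float = 1.0
    max_steps: int = 500_000
    tol: float = 1e-7  # convergence: max |gamma H^m| per step
    check_every: int = 250
    params: ModelParams = field(default_factory=lp9_params)

    def __post_init__(self) -> None:
        if self.R >= min(self.nx, self.ny) / 2:
            raise ValueError("island radius must be smaller than half the box")
        if self.params.zeta != 0.0:
            raise ValueError("the LP-9 scenario is passive: zeta must be 0")
        if self.params.C_prime is None:
            raise ValueError("LP-9 requires the exterior bulk scale C_prime")
        if self.centre is None:
            # keep the core off lattice sites so the director angle is
            # defined everywhere (S > 0 except at the exact core point)
            self.centre = (self.nx / 2.0 - 0.5, self.ny / 2.0 - 0.5)


def _radius_grid(shape, centre):
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.hypot(xx - centre[0], yy - centre[1])


def imprint_defect(
    shape: tuple[int, int],
    centre: tuple[float, float],
    R: float,
    s_bulk: float = S_BULK,
) -> QTensorField:
    """Fixed Q^n with a +1/2 defect: director angle = polar angle / 2.

    The order magnitude ramps from zero at the core as tanh(r/2) and
    tapers to zero at the island edge, matching the exterior condition
    that no nematic order forms outside radius R.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx_, dy_ = xx - centre[0], yy - centre[1]
    phi = np.arctan2(dy_, dx_)
    r = np.hypot(dx_, dy_)
    S = s_bulk * np.tanh(r / 2.0) * np.clip(np.tanh((R - r) / 2.0), 0.0, None)
    return q_from_director(S, phi / 2.0)


def relax_stress(config: LP9Config, qn: QTensorField | None = None):
    """Relax Q^m at fixed Q^n: dQ^m/dt = gamma H^m (no advection, no flow).

    Runs until max|gamma H^m| < tol or the step cap; the total free energy
    is monotonically non-increasing along the path. Returns
    ``(qm, info)`` where info records convergence, the step count, the
    free-energy trace, the pinned qn and the island mask. A run hitting
    the cap is flagged ``metastable_drift`` rather than converged.
    """
    p = config.params
    shape = (config.ny, config.nx)
    if qn is None:
        qn = imprint_defect(shape, config.centre, config.R)
    interior = _radius_grid(shape, config.centre) <= config.R

    # random but spatially correlated initial stress orientations (a
    # confluent tissue has smooth stress textures; site-independent angles
    # would imprint the pinned defect's winding locally everywhere and
    # always anneal straight to the fully aligned minimum)
    from .synth import smooth_nematic_field

    n_side = max(config.nx, config.ny)
    psi0 = smooth_nematic_field(
        float(n_side), config.R, seed=config.seed, n=n_side
    )[: config.ny, : config.nx]
    s0 = np.where(interior, config.s_init, 0.0)
    qm = q_from_director(s0, psi0)

    f_trace = [energy.total_free_energy(qn, qm, p, interior)]
    steps_done = config.max_steps
    converged = False
    for step in range(1, config.max_steps + 1):
        h = energy.molecular_field("m", qn, qm, p, interior)
        qm.qxx += p.gamma * h.qxx
        qm.qxy += p.gamma * h.qxy
        if step % config.check_every == 0 or step == config.max_steps:
            rate = p.gamma * max(np.abs(h.qxx).max(), np.abs(h.qxy).max())
            f_trace.append(energy.total_free_energy(qn, qm, p, interior))
            if not np.isfinite(rate):
                raise FloatingPointError(f"relaxation diverged at step {step}")
            if rate < config.tol:
                converged = True
                steps_done = step
                break
    info = {
        "converged": converged,
        "metastable_drift": not converged,
        "steps": steps_done,
        "free_energy": np.array(f_trace),
        "qn": qn,
        "interior": interior,
    }
    return qm, info


def measure_patch(
    qm: QTensorField,
    qn: QTensorField,
    island: np.ndarray,
    defect_centre: tuple[float, float],
):
    """Extensile-patch geometry of a relaxed LP-9 state.

    Restricts the misalignment map to the island, finds connected
    extensile components, and reports the total extensile area fraction
    of the island, the largest patch's area fraction, and the offset of
    its centroid from the pinned shape defect (lattice units). A state
    with no extensile sites reports zero fraction and NaN offset.
    """
    _, psi_n, iso_n = director_from_q(qn, iso_tol=1e-3)
    _, psi_m, iso_m = director_from_q(qm, iso_tol=1e-3)
    theta = nematic_distance(psi_n, psi_m, degrees=True)
    valid = island & ~(iso_n | iso_m)
    extensile = (theta > 45.0) & valid

    n_island = int(valid.sum())
    fraction = float(extensile.sum() / n_island)
    if not extensile.any():
        return {
            "extensile_fraction": 0.0,
            "largest_patch_fraction": 0.0,
            "patch_offset": float("nan"),
            "patch_gap": float("nan"),
            "patch_centroid": (float("nan"), float("nan")),
            "n_patches": 0,
        }
    labels, n_lab = ndimage.label(extensile)
    sizes = ndimage.sum_labels(extensile, labels, range(1, n_lab + 1))
    biggest = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(extensile, labels, biggest)
    offset = float(np.hypot(cx - defect_centre[0], cy - defect_centre[1]))
    yy, xx = np.nonzero(labels == biggest)
    gap = float(
        np.hypot(xx - defect_centre[0], yy - defect_centre[1]).min()
    )  # distance from the defect to the patch's nearest site (adjacency)
    return {
        "extensile_fraction": fraction,
        "largest_patch_fraction": float(sizes[biggest - 1] / n_island),
        "patch_offset": offset,
        "patch_gap": gap,
        "patch_centroid": (float(cx), float(cy)),
        "n_patches": int(n_lab),
    }


def run_lp9(config: LP9Config):
    """Imprint, relax, measure: the full LP-9 experiment in silico."""
    qm, info = relax_stress(config)
    patch = measure_patch(qm, info["qn"], info["interior"], config.centre)
    patch["converged"] = info["converged"]
    patch["steps"] = info["steps"]
    return qm, info, patch
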