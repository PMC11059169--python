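"""D2Q9 lattice-Boltzmann fluid with BGK collision and Guo forcing.

The momentum balance rho (d_t + u.grad) u = div(Pi) is recovered in the
macroscopic limit, with the passive stress realised as the LB ideal
pressure plus viscous stress and the active stress entering as the body
force f = div(Pi_act). The kinematic viscosity is nu = c_s^2 (tau - 1/2)
with c_s^2 = 1/3; streaming conserves mass exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qtensor import QTensorField, ddx, ddy

# D2Q9 velocities (cx, cy) and weights.
CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=float)
CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=float)
W = np.array(
    [4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36]
)
CS2 = 1.0 / 3.0


def tau_from_viscosity(nu: float) -> float:
    """Relaxation time from kinematic viscosity: nu = c_s^2 (tau - 1/2)."""
    return nu / CS2 + 0.5


def equilibrium(rho: np.ndarray, ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
    """Second-order D2Q9 equilibrium populations, shape (9, ny, nx)."""
    usq = ux * ux + uy * uy
    feq = np.empty((9,) + rho.shape)
    for i in range(9):
        cu = CX[i] * ux + CY[i] * uy
        feq[i] = W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
    return feq


@dataclass
class FlowState:
    """Fluid populations plus cached macroscopic fields."""

    f: np.ndarray  # (9, ny, nx)
    tau: float

    rho: np.ndarray = field(init=False)
    ux: np.ndarray = field(init=False)
    uy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.update_macroscopic()

    @classmethod
    def at_rest(cls, shape: tuple[int, int], rho0: float, tau: float) -> "FlowState":
        rho = np.full(shape, float(rho0))
        zeros = np.zeros(shape)
        return cls(equilibrium(rho, zeros, zeros), tau)

    def update_macroscopic(self, fx: np.ndarray | float = 0.0, fy: np.ndarray | float = 0.0) -> None:
        """Recompute rho and u (with half-force correction) from populations."""
        self.rho = self.f.sum(axis=0)
        if np.any(self.rho <= 0):
            raise FloatingPointError("negative or zero fluid density")
        self.ux = (np.tensordot(CX, self.f, axes=(0, 0)) + 0.5 * fx) / self.rho
        self.uy = (np.tensordot(CY, self.f, axes=(0, 0)) + 0.5 * fy) / self.rho

    def total_mass(self) -> float:
        return float(self.f.sum())

    def total_momentum(self) -> tuple[float, float]:
        return (
            float(np.tensordot(CX, self.f, axes=(0, 0)).sum()),
            float(np.tensordot(CY, self.f, axes=(0, 0)).sum()),
        )


def lb_step(flow: FlowState, fx, fy) -> None:
    """One BGK collision + streaming cycle with Guo forcing, in place.

    ``fx``/``fy`` is the body force (array or scalar). Updates the cached
    macroscopic fields to the post-stream values.
    """
    tau = flow.tau
    flow.update_macroscopic(fx, fy)
    rho, ux, uy = flow.rho, flow.ux, flow.uy
    if not np.all(np.isfinite(ux)) or not np.all(np.isfinite(uy)):
        raise FloatingPointError("non-finite velocity in LB step")

    feq = equilibrium(rho, ux, uy)
    pref = 1.0 - 0.5 / tau
    f = flow.f
    for i in range(9):
        cu = CX[i] * ux + CY[i] * uy
        # Guo forcing term: w_i [3(c_i - u) + 9(c_i.u) c_i] . F
        sx = 3.0 * (CX[i] - ux) + 9.0 * cu * CX[i]
        sy = 3.0 * (CY[i] - uy) + 9.0 * cu * CY[i]
        src = pref * W[i] * (sx * fx + sy * fy)
        f[i] += -(f[i] - feq[i]) / tau + src
        # streaming: population i moves by (cx, cy)
        f[i] = np.roll(f[i], (int(CY[i]), int(CX[i])), axis=(0, 1))
    flow.update_macroscopic(fx, fy)


def active_stress(qm: QTensorField, zeta: float) -> tuple[np.ndarray, np.ndarray]:
    """Active stress Pi_act = -zeta Q^m; returns (Pi_xx, Pi_xy).

    Pi_yy = -Pi_xx is implied. With zeta < 0 this is tension along the
    stress director m (contractile cells pulling inward along m).
    """
    return -zeta * qm.qxx, -zeta * qm.qxy


def active_force(qm: QTensorField, zeta: float) -> tuple[np.ndarray, np.ndarray]:
    """Body force f = div(Pi_act) by central differences on the periodic grid."""
    pxx, pxy = active_stress(qm, zeta)
    fx = ddx(pxx) + ddy(pxy)
    fy = ddx(pxy) - ddy(pxx)
    return fx, fy


def passive_force(
    qn: QTensorField,
    hn: QTensorField,
    qm: QTensorField,
    hm: QTensorField,
    K_n: float,
    K_m: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Divergence of the passive liquid-crystal stresses of both tensors.

    With the flow-tumbling parameter zero the passive stress (beyond the
    LB ideal pressure and viscous stress) reduces to the antisymmetric
    torque stress Q.H - H.Q plus the Ericksen elastic stress
    -K d_a Q_ij d_b Q_ij for each order parameter. The antisymmetric
    part returns the directors' relaxation torque to the fluid; its sign
    is fixed so that the power it injects, +2*omega*tau, exactly cancels
    the co-rotation term's free-energy rate (isotropic parts are absorbed
    into the pressure).
    """
    # antisymmetric: sigma_xy = -sigma_yx = 2(q1 h2 - q2 h1), summed over fields
    tau = 2.0 * (
        qn.qxx * hn.qxy - qn.qxy * hn.qxx + qm.qxx * hm.qxy - qm.qxy * hm.qxx
    )
    # Ericksen: sigma_ab = -2K (d_a q1 d_b q1 + d_a q2 d_b q2) per field
    exx = np.zeros_like(tau)
    exy = np.zeros_like(tau)
    eyy = np.zeros_like(tau)
    for q, K in ((qn, K_n), (qm, K_m)):
        for comp in (q.qxx, q.qxy):
            gx, gy = ddx(comp), ddy(comp)
            exx -= 2.0 * K * gx * gx
            exy -= 2.0 * K * gx * gy
            eyy -= 2.0 * K * gy * gy
    fx = ddx(exx) + ddy(exy + tau)
    fy = ddx(exy - tau) + ddy(eyy)
    return fx, fy


def vorticity(ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
    """Scalar vorticity Omega_xy = (d_x u_y - d_y u_x)/2 on the periodic grid.

    Sign fixed so that rigid-body rotation u = omega(-y, x) co-rotates the
    directors at rate omega under the co-rotation terms of the Q dynamics.
    """
    return 0.5 * (ddx(uy) - ddy(ux))
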