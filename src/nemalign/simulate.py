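"""Hybrid time stepper: finite-difference Q dynamics + lattice-Boltzmann flow.

Each step advances both nematic tensors by explicit Euler (dt = 1 LB step)

    (d_t + u.grad) Q = -Omega.Q + Q.Omega + gamma H

and the fluid by one D2Q9 collision-streaming cycle forced by the
divergence of the active stress Pi_act = -zeta Q^m. The flow-tumbling
parameter is zero: only vorticity rotates the directors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import energy
from .lb import (
    FlowState,
    active_force,
    lb_step,
    passive_force,
    tau_from_viscosity,
    vorticity,
)
from .params import ModelParams, RunConfig
from .qtensor import QTensorField, ddx, ddy, q_from_director

log = logging.getLogger(__name__)


@dataclass
class TissueState:
    """Shape tensor, stress tensor, and flow on one shared grid."""

    qn: QTensorField
    qm: QTensorField
    flow: FlowState
    time: int = 0

    def __post_init__(self) -> None:
        if not (self.qn.shape == self.qm.shape == self.flow.rho.shape):
            raise ValueError("all fields must share one grid")
        if self.time < 0:
            raise ValueError("time must be >= 0")


def random_state(config: RunConfig, params: ModelParams) -> TissueState:
    """Random initial condition: i.i.d. uniform director angles, S = s_init."""
    rng = np.random.default_rng(config.seed)
    shape = (config.ny, config.nx)
    qn = q_from_director(config.s_init, rng.uniform(0.0, np.pi, shape))
    qm = q_from_director(config.s_init, rng.uniform(0.0, np.pi, shape))
    flow = FlowState.at_rest(shape, params.rho, tau_from_viscosity(params.nu))
    return TissueState(qn, qm, flow)


def update_q(
    state: TissueState,
    params: ModelParams,
    ux: np.ndarray | None = None,
    uy: np.ndarray | None = None,
    omega: np.ndarray | None = None,
    dt: float = 1.0,
    interior: np.ndarray | None = None,
    pin_n: bool = False,
    fields: tuple[QTensorField, QTensorField] | None = None,
) -> None:
    """Advance both Q tensors one explicit-Euler step, in place.

    ``ux``/``uy`` default to the flow state's velocity; ``omega`` defaults
    to the vorticity of that velocity. ``pin_n`` freezes Q^n (LP-9);
    ``fields`` allows reusing precomputed molecular fields (H^n, H^m).
    Raises if the advection CFL condition |u| dt > 0.5 is violated.
    """
    if ux is None or uy is None:
        ux, uy = state.flow.ux, state.flow.uy
    if omega is None:
        omega = vorticity(ux, uy)
    umax = max(np.max(np.abs(ux)), np.max(np.abs(uy)))
    if umax * dt > 0.5:
        raise FloatingPointError(
            f"advection CFL violated: max|u| dt = {umax * dt:.3f} > 0.5"
        )

    qn, qm = state.qn, state.qm
    if fields is None:
        hn = energy.molecular_field("n", qn, qm, params, interior)
        hm = energy.molecular_field("m", qn, qm, params, interior)
    else:
        hn, hm = fields

    def rhs(q: QTensorField, h: QTensorField):
        adv_xx = ux * ddx(q.qxx) + uy * ddy(q.qxx)
        adv_xy = ux * ddx(q.qxy) + uy * ddy(q.qxy)
        # -Omega.Q + Q.Omega rotates the director at the local vorticity rate
        rot_xx = -2.0 * omega * q.qxy
        rot_xy = 2.0 * omega * q.qxx
        return (
            -adv_xx + rot_xx + params.gamma * h.qxx,
            -adv_xy + rot_xy + params.gamma * h.qxy,
        )

    dm_xx, dm_xy = rhs(qm, hm)
    if not pin_n:
        dn_xx, dn_xy = rhs(qn, hn)
        qn.qxx += dt * dn_xx
        qn.qxy += dt * dn_xy
    qm.qxx += dt * dm_xx
    qm.qxy += dt * dm_xy


def step_mdck(state: TissueState, params: ModelParams) -> None:
    """One full hybrid step: total-stress forcing, LB update, Q update.

    The body force is the divergence of the active stress -zeta Q^m plus
    the passive torque and Ericksen stresses of both order parameters.
    """
    hn = energy.molecular_field("n", state.qn, state.qm, params)
    hm = energy.molecular_field("m", state.qn, state.qm, params)
    fx, fy = active_force(state.qm, params.zeta)
    px, py = passive_force(state.qn, hn, state.qm, hm, params.K_n, params.K_m)
    lb_step(state.flow, fx + px, fy + py)
    update_q(state, params, fields=(hn, hm))
    state.time += 1


@dataclass
class Trajectory:
    """Frames collected from a run, stacked as (n_frames, ny, nx) arrays."""

    steps: np.ndarray
    qn_xx: np.ndarray
    qn_xy: np.ndarray
    qm_xx: np.ndarray
    qm_xy: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    rho: np.ndarray
    config: RunConfig | None = None
    params: ModelParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    def qn(self, i: int) -> QTensorField:
        return QTensorField(
            self.qn_xx[i].astype(float), self.qn_xy[i].astype(float)
        )

    def qm(self, i: int) -> QTensorField:
        return QTensorField(
            self.qm_xx[i].astype(float), self.qm_xy[i].astype(float)
        )


def run(config: RunConfig, params: ModelParams, state: TissueState | None = None) -> Trajectory:
    """Run the MDCK scenario, collecting a frame every ``frame_every`` steps.

    Deterministic given ``config.seed``. Aborts with the offending step
    index if any field goes non-finite. For the LP-9 scenario use
    :mod:`nemalign.lp9`, which reuses this machinery with flow disabled.
    """
    if config.scenario != "mdck":
        raise ValueError("run() drives the MDCK scenario; use nemalign.lp9 for lp9")
    if state is None:
        state = random_state(config, params)
    nf = config.n_frames
    shape = (nf,) + state.qn.shape

    def alloc():
        return np.empty(shape, dtype=np.float32)

    traj = Trajectory(
        steps=np.arange(1, nf + 1) * config.frame_every,
        qn_xx=alloc(), qn_xy=alloc(), qm_xx=alloc(), qm_xy=alloc(),
        ux=alloc(), uy=alloc(), rho=alloc(),
        config=config, params=params,
        meta={"seed": config.seed, "scenario": config.scenario},
    )

    frame = 0
    for step in range(1, config.steps + 1):
        try:
            step_mdck(state, params)
        except FloatingPointError as exc:
            raise FloatingPointError(f"step {step}: {exc}") from exc
        if step % config.frame_every == 0:
            for name, arr in (
                ("qn_xx", state.qn.qxx), ("qn_xy", state.qn.qxy),
                ("qm_xx", state.qm.qxx), ("qm_xy", state.qm.qxy),
                ("ux", state.flow.ux), ("uy", state.flow.uy),
                ("rho", state.flow.rho),
            ):
                if not np.all(np.isfinite(arr)):
                    raise FloatingPointError(f"non-finite {name} at step {step}")
                getattr(traj, name)[frame] = arr
            frame += 1
        if step % 1000 == 0:
            f_tot = energy.total_free_energy(state.qn, state.qm, params)
            log.info(
                "step %d  F=%.6g  max|u|=%.3g",
                step, f_tot, max(np.max(np.abs(state.flow.ux)), np.max(np.abs(state.flow.uy))),
            )
    return traj


def detect_steady_state(
    defect_counts: np.ndarray,
    extensile_fractions: np.ndarray,
    window: int = 50,
    alpha: float = 0.05,
):
    """Earliest frame after which both series are trend-free.

    Applies a Mann-Kendall (Kendall tau) two-sided trend test to the tail
    of both series starting at each candidate frame; returns the first
    start index at which neither series shows a significant trend
    (p >= alpha) over at least ``window`` frames. Returns
    ``(index, flagged)``; if no steady window is found the fallback is the
    final ``window`` frames with ``flagged=True``.
    """
    from scipy import stats

    a = np.asarray(defect_counts, dtype=float)
    b = np.asarray(extensile_fractions, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1D and equally long")
    n = len(a)
    if n < window + 1:
        raise ValueError(f"need more than {window} frames, got {n}")

    def trend_free(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return True
        tau, p = stats.kendalltau(np.arange(len(x)), x)
        return bool(np.isnan(p) or p >= alpha)

    for start in range(0, n - window + 1):
        if trend_free(a[start:]) and trend_free(b[start:]):
            return start, False
    return n - window, True
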