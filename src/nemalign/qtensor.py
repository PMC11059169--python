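"""Symmetric-traceless Q-tensor fields on a 2D grid.

A 2D nematic order parameter Q = S (d x d - I/2) has only two independent
components; we store (Qxx, Qxy) and imply Qyy = -Qxx, Qyx = Qxy, which
enforces the traceless-symmetric invariant structurally.

Arrays are indexed [y, x]; x is axis 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def ddx(a: np.ndarray) -> np.ndarray:
    """Second-order central x-derivative on a periodic grid (spacing 1)."""
    return 0.5 * (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1))


def ddy(a: np.ndarray) -> np.ndarray:
    """Second-order central y-derivative on a periodic grid (spacing 1)."""
    return 0.5 * (np.roll(a, -1, axis=0) - np.roll(a, 1, axis=0))


def laplacian(a: np.ndarray) -> np.ndarray:
    """Five-point periodic Laplacian (spacing 1)."""
    return (
        np.roll(a, -1, axis=0)
        + np.roll(a, 1, axis=0)
        + np.roll(a, -1, axis=1)
        + np.roll(a, 1, axis=1)
        - 4.0 * a
    )


@dataclass
class QTensorField:
    """Two independent components of a symmetric traceless 2x2 tensor field."""

    qxx: np.ndarray
    qxy: np.ndarray
    periodic: bool = True

    def __post_init__(self) -> None:
        self.qxx = np.asarray(self.qxx, dtype=float)
        self.qxy = np.asarray(self.qxy, dtype=float)
        if self.qxx.shape != self.qxy.shape:
            raise ValueError("qxx and qxy must have the same shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.qxx.shape

    @property
    def qyy(self) -> np.ndarray:
        return -self.qxx

    def copy(self) -> "QTensorField":
        return QTensorField(self.qxx.copy(), self.qxy.copy(), self.periodic)

    def contract(self, other: "QTensorField") -> np.ndarray:
        """Full tensor contraction Q:P = Q_ij P_ij (counts all four entries)."""
        return 2.0 * (self.qxx * other.qxx + self.qxy * other.qxy)

    def norm_sq(self) -> np.ndarray:
        """Q:Q = S^2/2 at every site."""
        return self.contract(self)

    @classmethod
    def zeros(cls, shape: tuple[int, int], periodic: bool = True) -> "QTensorField":
        return cls(np.zeros(shape), np.zeros(shape), periodic)


def q_from_director(S, angle, periodic: bool = True) -> QTensorField:
    """Build Q = S (d x d - I/2) from order magnitude and director angle.

    Qxx = (S/2) cos 2*angle, Qxy = (S/2) sin 2*angle. ``S`` and ``angle``
    broadcast together; angles are in radians.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("order magnitude S must be non-negative")
    angle = np.asarray(angle, dtype=float)
    S, angle = np.broadcast_arrays(S, angle)
    return QTensorField(
        0.5 * S * np.cos(2.0 * angle), 0.5 * S * np.sin(2.0 * angle), periodic
    )


def director_from_q(q: QTensorField, iso_tol: float = 0.0):
    """Recover (S, angle, isotropic mask) from a Q-tensor field.

    S = 2 sqrt(Qxx^2 + Qxy^2); the angle is mapped into [0, pi). Sites with
    S <= iso_tol are isotropic: their angle is 0 by convention and they are
    flagged in the returned boolean mask.
    """
    S = 2.0 * np.hypot(q.qxx, q.qxy)
    angle = np.mod(0.5 * np.arctan2(q.qxy, q.qxx), np.pi)
    isotropic = S <= iso_tol
    angle = np.where(isotropic, 0.0, angle)
    return S, angle, isotropic


def wrap_angle_pi(angle: np.ndarray) -> np.ndarray:
    """Wrap nematic angles into [0, pi)."""
    return np.mod(angle, np.pi)


def nematic_distance(a, b, degrees: bool = False):
    """Minimum angular distance between two directors, in [0, pi/2].

    Respects the head-tail symmetry (a and a+pi are the same director).
    """
    d = np.mod(np.asarray(a) - np.asarray(b), np.pi)
    d = np.minimum(d, np.pi - d)
    return np.degrees(d) if degrees else d
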