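"""Two-tensor free energy and molecular fields.

The free-energy density couples a cell-shape order parameter Q^n and a
contractile-stress order parameter Q^m:

    f = (C/2)(1 - 3 Q^n:Q^n)^2 + (C/2)(1 - 3 Q^m:Q^m)^2
        + (K_n/2)|grad Q^n|^2 + (K_m/2)|grad Q^m|^2
        + (J/2)(1 - 3 Q^n:Q^m)^2

The bulk terms select S = sqrt(2/3) (Q:Q = 1/3); the elastic terms
penalise gradients with different stiffnesses for shape and stress; the
J term relaxes the misalignment between the two directors.

For island geometries the C and J terms act only inside the island and
the exterior bulk term (C'/2)(Q:Q)^2 per tensor, which is minimised by
S = 0, acts outside. Elastic terms act everywhere.

The molecular field is the negative traceless functional derivative,
H^x = -(df/dQ^x - (I/2) Tr df/dQ^x), so relaxational dynamics
dQ/dt = gamma*H descends the total free energy. Gradients use
second-order central differences on the periodic grid.
"""
from __future__ import annotations

import numpy as np

from .params import ModelParams
from .qtensor import QTensorField, laplacian


def _grad_sq(q: QTensorField) -> np.ndarray:
    """|grad Q|^2 = sum_ijk (d_k Q_ij)^2, counting all four tensor entries.

    Uses forward differences: their discrete adjoint is exactly the
    five-point Laplacian used in the molecular field, so relaxational
    dynamics is an exact gradient descent of the discrete free energy.
    """
    out = np.zeros_like(q.qxx)
    for a in (q.qxx, q.qxy):
        out += (np.roll(a, -1, axis=1) - a) ** 2 + (np.roll(a, -1, axis=0) - a) ** 2
    return 2.0 * out


def bulk_energy_density(
    qn: QTensorField, qm: QTensorField, params: ModelParams
) -> np.ndarray:
    """Interior bulk + coupling energy density per site."""
    if qn.shape != qm.shape:
        raise ValueError("Q^n and Q^m must share a grid")
    un = 1.0 - 3.0 * qn.norm_sq()
    um = 1.0 - 3.0 * qm.norm_sq()
    unm = 1.0 - 3.0 * qn.contract(qm)
    return 0.5 * params.C * (un**2 + um**2) + 0.5 * params.J * unm**2


def elastic_energy_density(
    qn: QTensorField, qm: QTensorField, params: ModelParams
) -> np.ndarray:
    """(K_n/2)|grad Q^n|^2 + (K_m/2)|grad Q^m|^2 per site."""
    return 0.5 * params.K_n * _grad_sq(qn) + 0.5 * params.K_m * _grad_sq(qm)


def exterior_bulk_energy_density(
    qn: QTensorField, qm: QTensorField, c_prime: float
) -> np.ndarray:
    """Exterior bulk density (C'/2)[(Q^n:Q^n)^2 + (Q^m:Q^m)^2]; minimum at S=0."""
    if c_prime is None:
        raise ValueError("exterior bulk energy requires C_prime")
    return 0.5 * c_prime * (qn.norm_sq() ** 2 + qm.norm_sq() ** 2)


def total_free_energy(
    qn: QTensorField,
    qm: QTensorField,
    params: ModelParams,
    interior: np.ndarray | None = None,
) -> float:
    """Free energy integrated over the domain (unit cell area).

    ``interior`` is an optional boolean mask for island geometries: the
    C/J bulk terms apply where it is True and the C' exterior term where
    it is False. With no mask the whole domain is interior.
    """
    elastic = elastic_energy_density(qn, qm, params)
    bulk = bulk_energy_density(qn, qm, params)
    if interior is None:
        return float(np.sum(bulk + elastic))
    ext = exterior_bulk_energy_density(qn, qm, params.C_prime)
    return float(np.sum(np.where(interior, bulk, ext) + elastic))


def molecular_field(
    which: str,
    qn: QTensorField,
    qm: QTensorField,
    params: ModelParams,
    interior: np.ndarray | None = None,
) -> QTensorField:
    """Molecular field H^n or H^m (symmetric traceless by construction).

    H^n = 6C(1 - 3Q^n:Q^n) Q^n + K_n lap(Q^n) + 3J(1 - 3Q^n:Q^m) Q^m
    (roles of n and m swapped for H^m). In the exterior of an island the
    bulk part is replaced by -2C'(Q:Q) Q. Trace removal is automatic
    because every term is proportional to a traceless tensor.
    """
    if which == "n":
        q, other, K = qn, qm, params.K_n
    elif which == "m":
        q, other, K = qm, qn, params.K_m
    else:
        raise ValueError("which must be 'n' or 'm'")

    u = 1.0 - 3.0 * q.norm_sq()
    unm = 1.0 - 3.0 * qn.contract(qm)
    bulk_xx = 6.0 * params.C * u * q.qxx + 3.0 * params.J * unm * other.qxx
    bulk_xy = 6.0 * params.C * u * q.qxy + 3.0 * params.J * unm * other.qxy
    if interior is not None:
        if params.C_prime is None:
            raise ValueError("island geometry requires C_prime")
        w = q.norm_sq()
        ext_xx = -2.0 * params.C_prime * w * q.qxx
        ext_xy = -2.0 * params.C_prime * w * q.qxy
        bulk_xx = np.where(interior, bulk_xx, ext_xx)
        bulk_xy = np.where(interior, bulk_xy, ext_xy)
    hxx = bulk_xx + K * laplacian(q.qxx)
    hxy = bulk_xy + K * laplacian(q.qxy)
    return QTensorField(hxx, hxy, q.periodic)
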