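"""Tissue measurement stack.

Applied identically to experiment-like per-cell tables and to simulation
frames: director-grid construction, principal-stress axes, misalignment
maps, topological defect detection, interface domains, and correlation
functions.

Angles are radians in [0, pi) internally; user-facing misalignment values
are degrees in [0, 90].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .params import MICRONS_PER_LU, STRESS_RESOLUTION_UM
from .qtensor import QTensorField, director_from_q, nematic_distance, wrap_angle_pi

#: Default interface half-width in lattice units of the simulation grid
#: (the stress-measurement resolution, 5.2 um, at 3 um per lattice unit).
INTERFACE_RMAX_LU = STRESS_RESOLUTION_UM / MICRONS_PER_LU


# ---------------------------------------------------------------------------
# director grids

@dataclass
class DirectorGrid:
    """Nematic angle field on a regular lattice with magnitude weights."""

    angle: np.ndarray  # radians, wrapped to [0, pi)
    magnitude: np.ndarray
    dl: float = 1.0  # lattice constant (physical length per site)
    isotropic: np.ndarray | None = None  # sites with undefined angle

    def __post_init__(self) -> None:
        self.angle = wrap_angle_pi(np.asarray(self.angle, dtype=float))
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.isotropic is None:
            self.isotropic = np.zeros(self.angle.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.angle.shape


def cells_to_grid(
    x: np.ndarray,
    y: np.ndarray,
    angle: np.ndarray,
    magnitude: np.ndarray,
    L: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DirectorGrid:
    """Map per-cell records to a square lattice with constant dl = L / sqrt(N).

    Each cell is assigned to the closest lattice site; when several cells
    land on one site the closest cell wins (ties broken by input order).
    Unoccupied sites are filled from their nearest occupied site.
    ``angle`` is in radians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_cells = len(x)
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    n = int(round(np.sqrt(n_cells)))
    dl = L / np.sqrt(n_cells)

    ix = np.clip(np.floor((x - origin[0]) / dl).astype(int), 0, n - 1)
    iy = np.clip(np.floor((y - origin[1]) / dl).astype(int), 0, n - 1)
    cx = origin[0] + (ix + 0.5) * dl
    cy = origin[1] + (iy + 0.5) * dl
    dist = np.hypot(x - cx, y - cy)

    flat = iy * n + ix
    order = np.lexsort((np.arange(n_cells), dist))  # closest first, then index
    sites, first = np.unique(flat[order], return_index=True)
    winners = order[first]

    ang = np.full((n, n), np.nan)
    mag = np.full((n, n), np.nan)
    ang.flat[sites] = np.asarray(angle, dtype=float)[winners]
    mag.flat[sites] = np.asarray(magnitude, dtype=float)[winners]

    empty = np.isnan(ang)
    if empty.any():
        _, (ny_idx, nx_idx) = ndimage.distance_transform_edt(
            empty, return_indices=True
        )
        ang = ang[ny_idx, nx_idx]
        mag = mag[ny_idx, nx_idx]
    return DirectorGrid(ang, mag, dl=dl)


def refine_grid(grid: DirectorGrid, factor: int) -> DirectorGrid:
    """Linearly interpolate a director grid onto a ``factor``-times finer mesh.

    Interpolation acts on the Q-tensor components (cos 2 psi, sin 2 psi),
    never on raw angles, so it respects the nematic pi-periodicity: the
    midpoint of 10 deg and 170 deg is 0 deg, not 90 deg. ``factor = 1``
    is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return DirectorGrid(
            grid.angle.copy(), grid.magnitude.copy(), grid.dl, grid.isotropic.copy()
        )
    c = np.cos(2.0 * grid.angle)
    s = np.sin(2.0 * grid.angle)
    zoom = lambda a: ndimage.zoom(a, factor, order=1, mode="nearest", grid_mode=True)
    cf, sf = zoom(c), zoom(s)
    mf = np.maximum(zoom(grid.magnitude), 0.0)
    return DirectorGrid(0.5 * np.arctan2(sf, cf), mf, dl=grid.dl / factor)


# ---------------------------------------------------------------------------
# defects

@dataclass
class DefectSet:
    """Positions (grid coordinates), charges (+-1/2) and orientations."""

    x: np.ndarray
    y: np.ndarray
    charge: np.ndarray
    orientation: np.ndarray
    dl: float = 1.0

    def __len__(self) -> int:
        return len(self.x)

    @property
    def total_charge(self) -> float:
        return float(self.charge.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "charge": self.charge,
                "orientation": self.orientation,
            }
        )


def _wrap_half_pi(d: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-pi/2, pi/2]."""
    return 0.5 * np.pi - np.mod(0.5 * np.pi - d, np.pi)


def plaquette_winding(angle: np.ndarray, periodic: bool = True) -> np.ndarray:
    """Winding number (in units of 2 pi) around each unit plaquette.

    Successive director-angle differences around the loop are wrapped to
    (-pi/2, pi/2]; a total of +-pi marks a +-1/2 defect. On a periodic
    grid the output has the same shape as the input and the windings sum
    to zero (topological charge neutrality); otherwise only interior
    plaquettes are returned.
    """
    a = np.asarray(angle, dtype=float)
    b = np.roll(a, -1, axis=1)  # x+1
    c = np.roll(b, -1, axis=0)  # x+1, y+1
    d = np.roll(a, -1, axis=0)  # y+1
    w = (
        _wrap_half_pi(b - a)
        + _wrap_half_pi(c - b)
        + _wrap_half_pi(d - c)
        + _wrap_half_pi(a - d)
    )
    winding = w / (2.0 * np.pi)
    if not periodic:
        winding = winding[:-1, :-1]
    return winding


def _defect_orientation(angle: np.ndarray, yc: int, xc: int, k: float) -> float:
    """Orientation of a defect of charge k from a ring of director samples.

    Uses a = <exp(2i(psi - k*phi))> on a radius-2 ring around the core and
    returns arg(a) / (2(1-k)); this convention rotates with the texture
    (equivariant under global rotation), which is all downstream
    statistics require.
    """
    ny, nx = angle.shape
    phis = np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False)
    ys = np.mod(np.round(yc + 2.0 * np.sin(phis)).astype(int), ny)
    xs = np.mod(np.round(xc + 2.0 * np.cos(phis)).astype(int), nx)
    a = np.mean(np.exp(2j * (angle[ys, xs] - k * phis)))
    return float(np.angle(a) / (2.0 * (1.0 - k)))


def find_defects(
    grid: DirectorGrid | np.ndarray, periodic: bool = True
) -> DefectSet:
    """Locate +-1/2 disclinations of a director field by plaquette winding.

    Adjacent plaquettes carrying the same charge are merged into a single
    defect at their centroid. Positions are in lattice-index units of the
    input grid (plaquette centres sit at half-integer coordinates).
    """
    if isinstance(grid, DirectorGrid):
        angle, dl = grid.angle, grid.dl
    else:
        angle, dl = np.asarray(grid, dtype=float), 1.0
    winding = plaquette_winding(angle, periodic=periodic)

    xs, ys, charges, orients = [], [], [], []
    for sign in (+1.0, -1.0):
        mask = sign * winding > 0.25
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask)
        for com in ndimage.center_of_mass(mask, labels, range(1, n_lab + 1)):
            yc, xc = com[0] + 0.5, com[1] + 0.5
            xs.append(xc)
            ys.append(yc)
            charges.append(0.5 * sign)
            orients.append(
                _defect_orientation(
                    angle, int(round(yc)) % angle.shape[0],
                    int(round(xc)) % angle.shape[1], 0.5 * sign,
                )
            )
    return DefectSet(
        np.array(xs), np.array(ys), np.array(charges), np.array(orients), dl=dl
    )


# ---------------------------------------------------------------------------
# stress axes and misalignment

def principal_stress_axis(sxx, sxy, syy, iso_tol: float = 0.0):
    """Contractile-stress direction and magnitude from a 2D stress tensor.

    The tensor is first made traceless by adding c = -(sxx+syy)/2 to the
    diagonal; the contractile axis m is the eigendirection with positive
    eigenvalue ("positive stress pointing outwards") and the magnitude is
    that eigenvalue, sqrt(((sxx-syy)/2)^2 + sxy^2). Isotropic tensors
    (magnitude <= iso_tol) have undefined angle and are flagged.

    Returns (angle in [0, pi), magnitude, isotropic mask); works on
    scalars or arrays.
    """
    sxx = np.asarray(sxx, dtype=float)
    sxy = np.asarray(sxy, dtype=float)
    syy = np.asarray(syy, dtype=float)
    mag = np.hypot(0.5 * (sxx - syy), sxy)
    angle = wrap_angle_pi(0.5 * np.arctan2(2.0 * sxy, sxx - syy))
    isotropic = mag <= iso_tol
    angle = np.where(isotropic, 0.0, angle)
    return angle, mag, isotropic


@dataclass
class MisalignmentMap:
    """Misalignment angle field theta (degrees in [0, 90]) with masks."""

    theta_deg: np.ndarray
    valid: np.ndarray
    frame_id: int | None = None

    @property
    def extensile(self) -> np.ndarray:
        """Sites with theta strictly greater than 45 deg (ties contractile)."""
        return (self.theta_deg > 45.0) & self.valid

    def extensile_fraction(self) -> float:
        n_valid = int(self.valid.sum())
        if n_valid == 0:
            raise ValueError("no valid sites")
        return float(self.extensile.sum() / n_valid)


def misalignment(
    n_grid: DirectorGrid, m_grid: DirectorGrid, frame_id: int | None = None
) -> MisalignmentMap:
    """Misalignment angle theta between shape and stress directors.

    theta is the minimum angular distance between the two headless
    directors, in [0, 90] degrees. Sites flagged isotropic in either grid
    are excluded from statistics via the validity mask.
    """
    if n_grid.shape != m_grid.shape:
        raise ValueError("grids must be co-registered")
    theta = nematic_distance(n_grid.angle, m_grid.angle, degrees=True)
    valid = ~(n_grid.isotropic | m_grid.isotropic)
    return MisalignmentMap(theta, valid, frame_id)


def interface_domains(
    extensile: np.ndarray,
    r_max: float = INTERFACE_RMAX_LU,
    periodic: bool = False,
    valid: np.ndarray | None = None,
):
    """Interface band around extensile/contractile boundaries.

    A site belongs to the interface domain when its Euclidean distance to
    the nearest site of the opposite class is at most ``r_max`` (lattice
    units). Returns ``(interface mask, fractions)`` where the fractions
    dict partitions the (valid) tissue into interface / extensile /
    contractile, interface sites being removed from the bulk tallies so
    the three fractions sum to one.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    mask = np.asarray(extensile, dtype=bool)
    if mask.all() or not mask.any():
        interface = np.zeros(mask.shape, dtype=bool)
    else:
        pad = int(np.ceil(r_max)) + 1
        if periodic:
            m = np.pad(mask, pad, mode="wrap")
        else:
            m = np.pad(mask, pad, mode="edge")
        d_ext = ndimage.distance_transform_edt(m)  # distance to contractile
        d_con = ndimage.distance_transform_edt(~m)  # distance to extensile
        near = np.where(m, d_ext, d_con) <= r_max
        interface = near[pad:-pad, pad:-pad]

    if valid is None:
        valid = np.ones(mask.shape, dtype=bool)
    n = int(valid.sum())
    fi = float((interface & valid).sum() / n)
    fe = float((mask & ~interface & valid).sum() / n)
    fractions = {
        "interface": fi,
        "extensile": fe,
        "contractile": 1.0 - fi - fe,
    }
    return interface, fractions


def defect_interface_colocalization(
    defects: DefectSet, interface: np.ndarray
) -> float | None:
    """Fraction of defects whose positions fall on interface sites.

    Returns ``None`` (undefined, flagged) when the defect set is empty.
    """
    if len(defects) == 0:
        return None
    ny, nx = interface.shape
    iy = np.mod(np.round(defects.y - 0.5).astype(int), ny)
    ix = np.mod(np.round(defects.x - 0.5).astype(int), nx)
    return float(interface[iy, ix].mean())


# ---------------------------------------------------------------------------
# correlation functions

def _radial_bin(values2d: np.ndarray, dl: float, max_r: float | None):
    """Bin a periodic 2D correlation map by minimum-image radius."""
    ny, nx = values2d.shape
    fy = np.minimum(np.arange(ny), ny - np.arange(ny))
    fx = np.minimum(np.arange(nx), nx - np.arange(nx))
    r = np.hypot(fy[:, None], fx[None, :])
    rmax = max_r if max_r is not None else min(ny, nx) / 2.0
    bins = np.arange(0.0, rmax + 1.0)
    idx = np.digitize(r.ravel(), bins) - 1
    keep = (idx >= 0) & (idx < len(bins) - 1)
    sums = np.bincount(idx[keep], weights=values2d.ravel()[keep], minlength=len(bins) - 1)
    counts = np.bincount(idx[keep], minlength=len(bins) - 1)
    centres = 0.5 * (bins[:-1] + bins[1:])
    centres[0] = 0.0  # the r=0 bin is exactly the origin
    with np.errstate(invalid="ignore"):
        return centres * dl, sums / counts, counts


def _fft_autocorr(components: list[np.ndarray]) -> np.ndarray:
    """Mean over r0 of sum_k a_k(r0) a_k(r0+r) for a periodic field."""
    n = components[0].size
    acc = np.zeros_like(components[0])
    for a in components:
        fa = np.fft.fft2(a)
        acc += np.fft.ifft2(fa * np.conj(fa)).real
    return acc / n


def orientation_correlation(
    angles: np.ndarray,
    mode: str = "spatial",
    dl: float = 1.0,
    dt: float = 1.0,
    mask: np.ndarray | None = None,
    max_r: float | None = None,
):
    """Nematic orientation correlation C(r) = <cos 2(psi(r0+r) - psi(r0))>.

    ``angles`` is one frame (ny, nx) or a stack (T, ny, nx) in radians;
    the angle may be a shape director, a stress director, or the
    misalignment field itself. C(0) = 1 exactly.

    spatial mode: averaged over frames and reference points; periodic
    FFT autocorrelation when no mask is given, otherwise a direct pair
    sum restricted to the masked sites (e.g. a central disc of island
    data). Returns (r, C) with r in units of ``dl``.

    temporal mode: C(t) = <cos 2(psi(r0, t0+t) - psi(r0, t0))> averaged
    over sites (within ``mask``) and time origins; needs >= 2 frames.
    Returns (t, C) with t in units of ``dt``.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim == 2:
        a = a[None]
    c, s = np.cos(2.0 * a), np.sin(2.0 * a)

    if mode == "spatial":
        if mask is None:
            acc = None
            for t in range(a.shape[0]):
                m = _fft_autocorr([c[t], s[t]])
                acc = m if acc is None else acc + m
            r, C, counts = _radial_bin(acc / a.shape[0], dl, max_r)
            good = counts > 0
            return r[good], C[good]
        return _masked_pair_correlation(c, s, mask, dl, max_r)

    if mode == "temporal":
        if a.shape[0] < 2:
            raise ValueError("temporal mode needs at least 2 frames")
        m = np.ones(a.shape[1:], dtype=bool) if mask is None else mask
        T = a.shape[0]
        cm, sm = c[:, m], s[:, m]
        out = np.empty(T)
        for lag in range(T):
            out[lag] = np.mean(
                cm[: T - lag] * cm[lag:] + sm[: T - lag] * sm[lag:]
            )
        return np.arange(T) * dt, out

    raise ValueError("mode must be 'spatial' or 'temporal'")


def _masked_pair_correlation(c, s, mask, dl, max_r, max_sites: int = 2500):
    """Direct pair-sum correlation over masked sites (non-periodic)."""
    ys, xs = np.nonzero(mask)
    if len(ys) < 2:
        raise ValueError("mask selects too few sites")
    if len(ys) > max_sites:  # deterministic thinning for tractable pair counts
        sel = np.linspace(0, len(ys) - 1, max_sites).astype(int)
        ys, xs = ys[sel], xs[sel]
    r_pair = np.hypot(
        ys[:, None] - ys[None, :], xs[:, None] - xs[None, :]
    ).ravel()
    rmax = max_r if max_r is not None else r_pair.max()
    bins = np.arange(0.0, rmax + 1.0)
    idx = np.digitize(r_pair, bins) - 1
    keep = (idx >= 0) & (idx < len(bins) - 1)
    sums = np.zeros(len(bins) - 1)
    counts = np.zeros(len(bins) - 1)
    for t in range(c.shape[0]):
        ct, st = c[t][ys, xs], s[t][ys, xs]
        v = (ct[:, None] * ct[None, :] + st[:, None] * st[None, :]).ravel()
        sums += np.bincount(idx[keep], weights=v[keep], minlength=len(bins) - 1)
        counts += np.bincount(idx[keep], minlength=len(bins) - 1)
    centres = 0.5 * (bins[:-1] + bins[1:])
    centres[0] = 0.0
    good = counts > 0
    return centres[good] * dl, sums[good] / counts[good]


def velocity_correlation(
    ux: np.ndarray,
    uy: np.ndarray,
    dl: float = 1.0,
    max_r: float | None = None,
):
    """Normalised velocity correlation C(r) = <u(r0+r).u(r0)> / <u.u>.

    ``ux``/``uy`` are single frames or (T, ny, nx) stacks on a periodic
    grid. Raises if the velocity is zero everywhere (undefined).
    """
    ux = np.asarray(ux, dtype=float)
    uy = np.asarray(uy, dtype=float)
    if ux.ndim == 2:
        ux, uy = ux[None], uy[None]
    acc = None
    for t in range(ux.shape[0]):
        m = _fft_autocorr([ux[t], uy[t]])
        acc = m if acc is None else acc + m
    r, C, counts = _radial_bin(acc / ux.shape[0], dl, max_r)
    good = counts > 0
    r, C = r[good], C[good]
    if C[0] <= 0:
        raise ValueError("zero velocity everywhere: correlation undefined")
    return r, C / C[0]


def correlation_length(r: np.ndarray, C: np.ndarray, level: float = np.exp(-1.0)) -> float:
    """First crossing of C(r) below ``level``, linearly interpolated.

    Returns NaN (flagged) if the curve never crosses.
    """
    below = np.nonzero(C < level)[0]
    if len(below) == 0 or below[0] == 0:
        return float("nan")
    i = below[0]
    r0, r1, c0, c1 = r[i - 1], r[i], C[i - 1], C[i]
    return float(r0 + (c0 - level) * (r1 - r0) / (c0 - c1))


# ---------------------------------------------------------------------------
# binned statistics

def stress_vs_misalignment(samples, n_bins: int = 9) -> pd.DataFrame:
    """Stress magnitude binned by misalignment angle.

    ``samples`` is a sequence of (magnitude, theta_deg) array pairs, one
    per experiment or frame. Each sample's magnitudes are rescaled by
    their maximum before pooling, making the curve invariant to global
    magnitude scaling. Returns bin centres, means, standard deviations
    and counts over theta bins spanning [0, 90] degrees; empty bins are
    flagged with NaN means.
    """
    if isinstance(samples, tuple) and len(samples) == 2:
        samples = [samples]
    mags, thetas = [], []
    for mag, theta in samples:
        mag = np.asarray(mag, dtype=float).ravel()
        mx = mag.max()
        if mx <= 0:
            raise ValueError("sample has no positive stress magnitudes")
        mags.append(mag / mx)
        thetas.append(np.asarray(theta, dtype=float).ravel())
    mag = np.concatenate(mags)
    theta = np.concatenate(thetas)
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    idx = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    std = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if count[b]:
            mean[b] = mag[idx == b].mean()
            std[b] = mag[idx == b].std()
    return pd.DataFrame(
        {
            "theta_deg": 0.5 * (edges[:-1] + edges[1:]),
            "mean": mean,
            "std": std,
            "count": count,
        }
    )


def misalignment_histogram(theta_deg: np.ndarray, n_bins: int = 18):
    """Normalised histogram of theta plus the extensile fraction.

    Returns (bin centres, density, extensile fraction); the extensile
    fraction counts theta strictly greater than 45 degrees.
    """
    theta = np.asarray(theta_deg, dtype=float).ravel()
    if np.any((theta < 0) | (theta > 90)):
        raise ValueError("theta samples must lie in [0, 90] degrees")
    density, edges = np.histogram(theta, bins=n_bins, range=(0.0, 90.0), density=True)
    fraction = float((theta > 45.0).mean())
    return 0.5 * (edges[:-1] + edges[1:]), density, fraction


# ---------------------------------------------------------------------------
# island (cell-table) pipeline

@dataclass
class IslandFrameReport:
    """Per-frame analysis products for one island cell table."""

    n_grid: DirectorGrid
    m_grid: DirectorGrid
    theta_deg: np.ndarray
    disc: np.ndarray  # sites inside the island
    extensile_fraction: float
    interface_fraction: float
    colocalization: float | None
    n_defects: int
    defects: DefectSet


def analyze_cells(
    table: pd.DataFrame,
    L_um: float,
    r_max_um: float = STRESS_RESOLUTION_UM,
    refine_target_um: float = STRESS_RESOLUTION_UM,
) -> IslandFrameReport:
    """Full measurement stack for one frame of per-cell island data.

    Expects columns ``x_um, y_um, angle_deg, aspect_ratio, sxx, sxy, syy``.
    Builds co-registered shape and stress director grids (dl = L/sqrt(N)),
    computes the misalignment map and its extensile fraction over the
    island disc at cell resolution, then refines both grids to roughly the
    stress-measurement resolution for the interface band and defect
    detection (the 5.2 um criterion is below the cell-grid spacing, so
    interface geometry needs the finer mesh).
    """
    x = table["x_um"].to_numpy()
    y = table["y_um"].to_numpy()
    psi_n = np.radians(table["angle_deg"].to_numpy())
    mag_n = np.maximum(table["aspect_ratio"].to_numpy() - 1.0, 0.0)
    n_grid = cells_to_grid(x, y, psi_n, mag_n, L_um)

    psi_m, mag_m, iso = principal_stress_axis(
        table["sxx"].to_numpy(), table["sxy"].to_numpy(), table["syy"].to_numpy()
    )
    m_grid = cells_to_grid(x, y, psi_m, mag_m, L_um)
    m_grid.isotropic = cells_to_grid(x, y, iso.astype(float), np.ones_like(
        psi_m), L_um).angle > 0.5  # carry the isotropic flags through gridding

    mm = misalignment(n_grid, m_grid)
    disc = _disc_mask(n_grid.shape, n_grid.dl, L_um)
    valid = mm.valid & disc
    extensile_fraction = float((mm.extensile & valid).sum() / valid.sum())

    factor = max(1, int(round(n_grid.dl / refine_target_um)))
    n_fine = refine_grid(n_grid, factor)
    m_fine = refine_grid(m_grid, factor)
    mm_fine = misalignment(n_fine, m_fine)
    disc_fine = _disc_mask(n_fine.shape, n_fine.dl, L_um)
    interface, fractions = interface_domains(
        mm_fine.extensile, r_max_um / n_fine.dl, periodic=False, valid=disc_fine
    )
    defects = find_defects(n_fine, periodic=False)
    inside = _defects_in_disc(defects, n_fine.dl, L_um)
    defects = DefectSet(
        defects.x[inside], defects.y[inside], defects.charge[inside],
        defects.orientation[inside], dl=defects.dl,
    )
    coloc = defect_interface_colocalization(defects, interface)
    return IslandFrameReport(
        n_grid=n_grid,
        m_grid=m_grid,
        theta_deg=mm.theta_deg,
        disc=disc,
        extensile_fraction=extensile_fraction,
        interface_fraction=fractions["interface"],
        colocalization=coloc,
        n_defects=len(defects),
        defects=defects,
    )


def _disc_mask(shape: tuple[int, int], dl: float, L: float) -> np.ndarray:
    """Sites whose centres lie inside the inscribed island disc."""
    ny, nx = shape
    cy = (np.arange(ny) + 0.5) * dl - 0.5 * L
    cx = (np.arange(nx) + 0.5) * dl - 0.5 * L
    return np.hypot(cy[:, None], cx[None, :]) <= 0.5 * L


def _defects_in_disc(defects: DefectSet, dl: float, L: float) -> np.ndarray:
    if len(defects) == 0:
        return np.zeros(0, dtype=bool)
    return (
        np.hypot(defects.x * dl - 0.5 * L, defects.y * dl - 0.5 * L) <= 0.5 * L
    )


def central_disc_mask(
    shape: tuple[int, int], dl: float, L: float, diameter_um: float = 312.0
) -> np.ndarray:
    """Central averaging disc used for island correlation functions.

    Restricting the spatial averages to a small central disc (default
    diameter 312 um) avoids edge effects of the island boundary.
    """
    ny, nx = shape
    cy = (np.arange(ny) + 0.5) * dl - 0.5 * L
    cx = (np.arange(nx) + 0.5) * dl - 0.5 * L
    return np.hypot(cy[:, None], cx[None, :]) <= 0.5 * diameter_um


# ---------------------------------------------------------------------------
# simulation-frame summary

@dataclass
class FrameStats:
    extensile_fraction: float
    interface_fraction: float
    colocalization: float | None
    n_defects: int
    theta_deg: np.ndarray = field(repr=False)
    interface: np.ndarray = field(repr=False)
    defects: DefectSet = field(repr=False)


def simulation_frame_stats(
    qn: QTensorField,
    qm: QTensorField,
    r_max: float = INTERFACE_RMAX_LU,
) -> FrameStats:
    """Misalignment, interface and defect statistics for one periodic frame."""
    _, psi_n, iso_n = director_from_q(qn)
    _, psi_m, iso_m = director_from_q(qm)
    gn = DirectorGrid(psi_n, np.ones_like(psi_n), isotropic=iso_n)
    gm = DirectorGrid(psi_m, np.ones_like(psi_m), isotropic=iso_m)
    mm = misalignment(gn, gm)
    interface, fractions = interface_domains(mm.extensile, r_max, periodic=True)
    defects = find_defects(gn, periodic=True)
    coloc = defect_interface_colocalization(defects, interface)
    return FrameStats(
        extensile_fraction=mm.extensile_fraction(),
        interface_fraction=fractions["interface"],
        colocalization=coloc,
        n_defects=len(defects),
        theta_deg=mm.theta_deg,
        interface=interface,
        defects=defects,
    )
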