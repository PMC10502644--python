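"""Desk-scale 2D Helmholtz wave simulation and multifrequency inversion.

Forward: finite-difference solution of the scalar heterogeneous Helmholtz
equation  laplacian(u) + rho * (2 pi f)^2 / G*(x, y) * u = 0  with a unit
Dirichlet drive on one edge and absorbing sponge layers on the others.

Inverse: magnitude-based multifrequency estimator over fields u_f,

    |G*| = rho * sum_f (2 pi f)^2 |u_f|  /  sum_f |lap u_f|
    phi  = arccos( - sum_f Re(lap u_f * conj u_f) / sum_f |lap u_f| |u_f| )

with a 5-point spacing-aware Laplacian on Gaussian-presmoothed fields, plus
a simpler phase-gradient wave-speed surrogate map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import gaussian_filter

from .errors import DomainError, InversionError, SolverError
from .rheology import (
    DEFAULT_DENSITY,
    fluidity_from_phase,
    speed_from_modulus,
)

__all__ = [
    "WaveFieldSet",
    "ParameterMaps",
    "helmholtz_forward",
    "mdev_invert",
    "gradient_speed_map",
]

# a sponge much thinner than a wavelength reflects; 24 px covers the
# slowest waves the desk-scale phantoms use (~20 px per wavelength)
SPONGE_WIDTH = 24  # pixels
SPONGE_STRENGTH = 2.0  # max imaginary fraction added to k^2
EDGE_MARGIN = 2  # pixels masked around the border after inversion
VALIDITY_REL_THRESHOLD = 1e-9


@dataclass
class WaveFieldSet:
    """Complex scalar displacement grids, one per drive frequency."""

    frequencies: np.ndarray  # Hz
    fields: list  # list of complex 2D arrays, shared shape
    spacing: float  # m per pixel

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.fields = [np.asarray(f, dtype=complex) for f in self.fields]
        if len(self.frequencies) != len(self.fields):
            raise DomainError("one field per frequency required")
        shapes = {f.shape for f in self.fields}
        if len(shapes) > 1:
            raise DomainError("all fields must share the grid")
        if self.spacing <= 0:
            raise DomainError("pixel spacing must be positive")

    @property
    def shape(self):
        return self.fields[0].shape


@dataclass
class ParameterMaps:
    """Co-registered 2D viscoelastic parameter maps."""

    magnitude: np.ndarray  # |G*|, Pa
    phase: np.ndarray  # phi, rad
    fluidity: np.ndarray  # dimensionless
    speed: np.ndarray  # c, m/s
    spacing: float  # m per pixel
    valid: Optional[np.ndarray] = None  # bool mask of trustworthy pixels
    density: float = DEFAULT_DENSITY
    masks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.fluidity = np.asarray(self.fluidity, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.magnitude.shape, dtype=bool)
        if not (
            self.magnitude.shape
            == self.phase.shape
            == self.fluidity.shape
            == self.speed.shape
        ):
            raise DomainError("parameter maps must share the grid")

    @classmethod
    def from_magnitude_phase(
        cls,
        magnitude,
        phase,
        spacing,
        rho: float = DEFAULT_DENSITY,
        valid=None,
        masks=None,
    ) -> "ParameterMaps":
        """Derive the fluidity and speed grids pointwise."""
        magnitude = np.asarray(magnitude, dtype=float)
        phase = np.asarray(phase, dtype=float)
        return cls(
            magnitude=magnitude,
            phase=phase,
            fluidity=fluidity_from_phase(phase),
            speed=speed_from_modulus(magnitude, phase, rho),
            spacing=spacing,
            valid=valid,
            density=rho,
            masks=masks or {},
        )

    @property
    def complex_modulus(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


def _sponge_sigma(shape, width, drive, lateral):
    """Quadratic damping ramps on the absorbing edges.

    The edge opposite the drive always absorbs; the two lateral edges
    absorb only when ``lateral == 'sponge'``.
    """
    ny, nx = shape
    ramp_lo = {
        "y": (((np.arange(width, 0, -1)) / width) ** 2)[:, None] * np.ones((1, nx)),
        "x": (((np.arange(width, 0, -1)) / width) ** 2)[None, :] * np.ones((ny, 1)),
    }
    sigma = np.zeros(shape)
    opposite = {"left": "right", "right": "left", "top": "bottom", "bottom": "top"}
    edges = [opposite[drive]]
    if lateral == "sponge":
        edges += ["top", "bottom"] if drive in ("left", "right") else ["left", "right"]
    for edge in edges:
        if edge == "top":
            sigma[:width, :] = np.maximum(sigma[:width, :], ramp_lo["y"])
        elif edge == "bottom":
            sigma[-width:, :] = np.maximum(sigma[-width:, :], ramp_lo["y"][::-1, :])
        elif edge == "left":
            sigma[:, :width] = np.maximum(sigma[:, :width], ramp_lo["x"])
        elif edge == "right":
            sigma[:, -width:] = np.maximum(sigma[:, -width:], ramp_lo["x"][:, ::-1])
    return sigma


def helmholtz_forward(
    truth: ParameterMaps,
    rho: float,
    f: float,
    drive: str = "left",
    sponge_width: int = SPONGE_WIDTH,
    sponge_strength: float = SPONGE_STRENGTH,
    lateral: str = "mirror",
) -> np.ndarray:
    """Solve the heterogeneous scalar Helmholtz equation on the truth maps.

    ``drive`` in {'left', 'right', 'top', 'bottom'} selects the unit
    Dirichlet edge. The opposite edge always carries a quadratically ramped
    sponge. The two lateral edges are mirror (zero normal derivative)
    boundaries by default — sponges absorb poorly at grazing incidence —
    or sponges when ``lateral='sponge'``.
    """
    if f <= 0:
        raise DomainError("frequency must be positive")
    ny, nx = truth.magnitude.shape
    if ny < 32 or nx < 32:
        raise DomainError("grid must be at least 32x32")
    if np.any(truth.magnitude <= 0):
        raise SolverError("truth |G*| must be strictly positive")
    h = truth.spacing
    omega = 2.0 * np.pi * f
    gstar = truth.complex_modulus
    ksq = rho * omega**2 / gstar  # complex k^2 field

    if lateral not in ("mirror", "sponge"):
        raise DomainError(f"unknown lateral boundary {lateral!r}")
    if drive not in ("left", "right", "top", "bottom"):
        raise DomainError(f"unknown drive edge {drive!r}")
    # sponge: add positive imaginary part to k^2 near absorbing edges
    sigma = _sponge_sigma((ny, nx), sponge_width, drive, lateral) * sponge_strength
    ksq_eff = ksq * (1.0 + 1j * sigma)

    idx = np.arange(ny * nx).reshape(ny, nx)
    interior = np.ones((ny, nx), dtype=bool)
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False

    drive_mask = np.zeros((ny, nx), dtype=bool)
    if drive == "left":
        drive_mask[:, 0] = True
    elif drive == "right":
        drive_mask[:, -1] = True
    elif drive == "top":
        drive_mask[0, :] = True
    else:
        drive_mask[-1, :] = True

    # lateral border pixels and the inward neighbor they mirror
    mirror_src = np.array([], dtype=int)
    mirror_dst = np.array([], dtype=int)
    if lateral == "mirror":
        if drive in ("left", "right"):
            cols_span = np.arange(1, nx - 1)
            mirror_src = np.concatenate([idx[0, cols_span], idx[-1, cols_span]])
            mirror_dst = np.concatenate([idx[1, cols_span], idx[-2, cols_span]])
        else:
            rows_span = np.arange(1, ny - 1)
            mirror_src = np.concatenate([idx[rows_span, 0], idx[rows_span, -1]])
            mirror_dst = np.concatenate([idx[rows_span, 1], idx[rows_span, -2]])

    n = ny * nx
    main = np.where(
        interior.ravel(), (ksq_eff - 4.0 / h**2).ravel(), 1.0 + 0.0j
    )
    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [main]
    ii, jj = np.nonzero(interior)
    flat = idx[ii, jj]
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rows.append(flat)
        cols.append(idx[ii + di, jj + dj])
        vals.append(np.full(len(flat), 1.0 / h**2, dtype=complex))
    if len(mirror_src):  # u_border - u_inward = 0 (diagonal already 1)
        rows.append(mirror_src)
        cols.append(mirror_dst)
        vals.append(np.full(len(mirror_src), -1.0, dtype=complex))
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    b = np.where(drive_mask.ravel(), 1.0 + 0.0j, 0.0 + 0.0j)
    try:
        u = spla.spsolve(A, b)
    except Exception as exc:  # pragma: no cover - singular systems
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise SolverError("solver returned non-finite field")
    residual = np.linalg.norm(A @ u - b) / np.linalg.norm(b)
    if residual > 1e-8:
        raise SolverError(f"discrete residual {residual:.2e} exceeds 1e-8")
    return u.reshape(ny, nx)


def _laplacian(u: np.ndarray, h: float) -> np.ndarray:
    """Spacing-aware 5-point Laplacian; edges are garbage and masked later."""
    lap = np.zeros_like(u)
    lap[1:-1, 1:-1] = (
        u[:-2, 1:-1] + u[2:, 1:-1] + u[1:-1, :-2] + u[1:-1, 2:]
        - 4.0 * u[1:-1, 1:-1]
    ) / h**2
    return lap


def _smooth_complex(u: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return u
    return gaussian_filter(u.real, sigma) + 1j * gaussian_filter(u.imag, sigma)


def mdev_invert(
    w: WaveFieldSet,
    rho: float = DEFAULT_DENSITY,
    smoothing_sigma: float = 1.0,
) -> ParameterMaps:
    """Multifrequency magnitude inversion of a wave-field set.

    Pixels where the summed Laplacian magnitude falls below a relative floor,
    and a 2-pixel border margin, are flagged invalid.
    """
    h = w.spacing
    num_mag = np.zeros(w.shape)
    den_mag = np.zeros(w.shape)
    num_phi = np.zeros(w.shape)
    den_phi = np.zeros(w.shape)
    for f, u in zip(w.frequencies, w.fields):
        us = _smooth_complex(u, smoothing_sigma)
        lap = _laplacian(us, h)
        omega = 2.0 * np.pi * f
        num_mag += omega**2 * np.abs(us)
        den_mag += np.abs(lap)
        num_phi += np.real(lap * np.conj(us))
        den_phi += np.abs(lap) * np.abs(us)

    valid = den_mag > VALIDITY_REL_THRESHOLD * max(den_mag.max(), 1e-300)
    valid &= den_phi > 0
    margin = np.zeros(w.shape, dtype=bool)
    margin[EDGE_MARGIN:-EDGE_MARGIN, EDGE_MARGIN:-EDGE_MARGIN] = True
    valid &= margin
    if not np.any(valid):
        raise InversionError("all pixels invalid")

    with np.errstate(divide="ignore", invalid="ignore"):
        magnitude = np.where(valid, rho * num_mag / den_mag, 0.0)
        cosphi = np.where(valid, -num_phi / np.where(valid, den_phi, 1.0), 1.0)
    # arccos range is [0, pi]; clip into the physical [0, pi/2] band for the
    # derived fluidity and speed grids
    phase = np.clip(np.arccos(np.clip(cosphi, -1.0, 1.0)), 0.0, np.pi / 2)
    return ParameterMaps.from_magnitude_phase(
        magnitude, phase, h, rho, valid=valid
    )


def gradient_speed_map(
    w: WaveFieldSet, k_floor: float = 1e-6
) -> np.ndarray:
    """Frequency-compounded phase-gradient wave-speed surrogate map.

    Per frequency the local wavenumber is the magnitude of the gradient of
    the field phase (computed wrap-free from phase increments of neighboring
    pixels); c_f = 2 pi f / |grad phase|. Compounding is amplitude-weighted.
    Pixels with phase-gradient magnitude below ``k_floor`` (rad/m) at every
    frequency come back as NaN.
    """
    h = w.spacing
    num = np.zeros(w.shape)
    den = np.zeros(w.shape)
    for f, u in zip(w.frequencies, w.fields):
        # wrap-free phase increments via products of neighboring samples
        dphase_y = np.zeros(w.shape)
        dphase_x = np.zeros(w.shape)
        dphase_y[1:-1, :] = np.angle(u[2:, :] * np.conj(u[:-2, :])) / (2 * h)
        dphase_x[:, 1:-1] = np.angle(u[:, 2:] * np.conj(u[:, :-2])) / (2 * h)
        dphase_y[0, :] = np.angle(u[1, :] * np.conj(u[0, :])) / h
        dphase_y[-1, :] = np.angle(u[-1, :] * np.conj(u[-2, :])) / h
        dphase_x[:, 0] = np.angle(u[:, 1] * np.conj(u[:, 0])) / h
        dphase_x[:, -1] = np.angle(u[:, -1] * np.conj(u[:, -2])) / h
        kmag = np.hypot(dphase_y, dphase_x)
        amp = np.abs(u)
        ok = kmag > k_floor
        c_f = np.where(ok, 2.0 * np.pi * f / np.where(ok, kmag, 1.0), 0.0)
        num += np.where(ok, amp * c_f, 0.0)
        den += np.where(ok, amp, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return c
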