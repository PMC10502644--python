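"""Scalar viscoelastic algebra and springpot dispersion fitting.

The quantities handled here are the complex shear modulus ``G* = G' + iG''``,
its phase angle ``phi = arctan(G''/G')``, the normalized fluidity
``(phi - pi/4)/(pi/4)`` spanning -1 (pure solid) to +1 (pure fluid), the
shear-wave speed / magnitude conversion
``|G*| = c^2 * rho * (1 + cos(phi)) / 2``, and the two-parameter springpot
model ``G* = mu^(1-alpha) * eta^alpha * (i*2*pi*f)^alpha`` with ``eta``
conventionally fixed to 1 Pa s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DomainError,
    FitFailureError,
    InvalidWavenumberError,
    UnderdeterminedError,
    UndefinedPhaseError,
)

__all__ = [
    "PHI_TRANSITION",
    "DEFAULT_DENSITY",
    "ComplexShearModulus",
    "ViscoelasticSummary",
    "SpringpotParams",
    "DispersionTable",
    "phase_angle",
    "fluidity_from_phase",
    "phase_from_fluidity",
    "modulus_from_speed",
    "speed_from_modulus",
    "springpot_modulus",
    "wavenumber_from_modulus",
    "wavenumber_to_speed_attenuation",
    "speed_attenuation_to_wavenumber",
    "fit_springpot",
]

#: Solid-fluid transition phase angle phi_0 (rad).
PHI_TRANSITION = math.pi / 4.0

#: Unit tissue density 1 kg/l expressed in SI (kg/m^3).
DEFAULT_DENSITY = 1000.0


@dataclass(frozen=True)
class ComplexShearModulus:
    """Storage/loss modulus pair in Pa."""

    storage: float
    loss: float

    def __post_init__(self):
        if self.storage < 0 or self.loss < 0:
            raise DomainError(
                f"moduli must be non-negative, got G'={self.storage}, G''={self.loss}"
            )

    @property
    def magnitude(self) -> float:
        return math.hypot(self.storage, self.loss)

    @property
    def as_complex(self) -> complex:
        return complex(self.storage, self.loss)


@dataclass(frozen=True)
class ViscoelasticSummary:
    """Point summary of a viscoelastic state at one frequency.

    ``penetration`` is ``+inf`` (with ``lossless=True``) in the elastic limit.
    """

    speed: float  # c, m/s
    penetration: float  # a, m/s
    phase: float  # phi, rad
    fluidity: float  # dimensionless, in [-1, 1]
    magnitude: float  # |G*|, Pa
    density: float = DEFAULT_DENSITY  # kg/m^3
    lossless: bool = False

    def __post_init__(self):
        if not (0.0 <= self.phase <= math.pi / 2 + 1e-12):
            raise DomainError(f"phase {self.phase} outside [0, pi/2]")
        if self.speed < 0 or self.magnitude < 0:
            raise DomainError("speed and magnitude must be non-negative")
        expected = fluidity_from_phase(self.phase)
        if abs(self.fluidity - expected) > 1e-12:
            raise DomainError(
                f"fluidity {self.fluidity} inconsistent with phase {self.phase}"
            )


@dataclass(frozen=True)
class SpringpotParams:
    """Two-parameter springpot: spring constant mu (Pa), power-law exponent
    alpha in [0, 1]; dashpot parameter eta fixed to 1 Pa s by convention."""

    mu: float
    alpha: float
    eta: float = 1.0

    def __post_init__(self):
        if self.mu <= 0:
            raise DomainError(f"mu must be positive, got {self.mu}")
        if not (0.0 <= self.alpha <= 1.0):
            raise DomainError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.eta <= 0:
            raise DomainError(f"eta must be positive, got {self.eta}")

    @property
    def phase(self) -> float:
        """Frequency-independent phase angle alpha * pi/2."""
        return self.alpha * math.pi / 2.0

    @property
    def fluidity(self) -> float:
        return fluidity_from_phase(self.phase)


@dataclass
class DispersionTable:
    """Per-frequency complex wavenumbers, or equivalently (c, a) pairs.

    Internally stores frequencies (Hz), speeds c (m/s) and penetration rates
    a (m/s, ``inf`` where lossless). Complex wavenumbers are available via
    :attr:`wavenumbers`.
    """

    frequencies: np.ndarray
    speeds: np.ndarray
    penetrations: np.ndarray
    lossless: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.penetrations = np.asarray(self.penetrations, dtype=float)
        if self.lossless is None:
            self.lossless = ~np.isfinite(self.penetrations)
        self.lossless = np.asarray(self.lossless, dtype=bool)
        if not (
            len(self.frequencies) == len(self.speeds) == len(self.penetrations)
        ):
            raise DomainError("column lengths differ")
        if np.any(self.frequencies <= 0) or np.any(
            np.diff(self.frequencies) <= 0
        ):
            raise DomainError("frequencies must be positive, strictly increasing")
        if np.any(self.speeds <= 0):
            raise DomainError("speeds must be positive (k' > 0)")
        if np.any(self.penetrations[~self.lossless] <= 0):
            raise DomainError("penetration rates must be positive (k'' >= 0)")

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def wavenumbers(self) -> np.ndarray:
        """Complex k* = k' + i k'' (rad/m); k'' = 0 where lossless."""
        k_re = 2.0 * np.pi * self.frequencies / self.speeds
        k_im = np.where(
            self.lossless, 0.0, self.frequencies / self.penetrations
        )
        return k_re + 1j * k_im

    @classmethod
    def from_wavenumbers(
        cls, frequencies, wavenumbers
    ) -> "DispersionTable":
        frequencies = np.asarray(frequencies, dtype=float)
        k = np.asarray(wavenumbers, dtype=complex)
        if np.any(k.real <= 0) or np.any(k.imag < 0):
            raise InvalidWavenumberError("require k' > 0 and k'' >= 0")
        c = 2.0 * np.pi * frequencies / k.real
        with np.errstate(divide="ignore"):
            a = np.where(k.imag > 0, frequencies / np.where(k.imag > 0, k.imag, 1.0), np.inf)
        return cls(frequencies, c, a, lossless=(k.imag == 0))

    def restrict(self, f_min: float, f_max: float) -> "DispersionTable":
        sel = (self.frequencies >= f_min) & (self.frequencies <= f_max)
        return DispersionTable(
            self.frequencies[sel],
            self.speeds[sel],
            self.penetrations[sel],
            lossless=self.lossless[sel],
        )

    def to_frame(self) -> pd.DataFrame:
        k = self.wavenumbers
        return pd.DataFrame(
            {
                "freq_hz": self.frequencies,
                "c_mps": self.speeds,
                "a_mps": self.penetrations,
                "k_re": k.real,
                "k_im": k.imag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DispersionTable":
        df = pd.read_csv(path)
        if {"freq_hz", "k_re", "k_im"} <= set(df.columns):
            return cls.from_wavenumbers(
                df["freq_hz"].to_numpy(), df["k_re"].to_numpy() + 1j * df["k_im"].to_numpy()
            )
        if {"freq_hz", "c_mps", "a_mps"} <= set(df.columns):
            return cls(
                df["freq_hz"].to_numpy(),
                df["c_mps"].to_numpy(),
                df["a_mps"].to_numpy(),
            )
        raise DomainError(
            "CSV must have columns freq_hz,k_re,k_im or freq_hz,c_mps,a_mps"
        )


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def phase_angle(g: ComplexShearModulus) -> float:
    """Phase angle arctan(G''/G') of the complex shear modulus, in [0, pi/2]."""
    if g.storage == 0 and g.loss == 0:
        raise UndefinedPhaseError("phase undefined for G' = G'' = 0")
    return math.atan2(g.loss, g.storage)


def fluidity_from_phase(phi):
    """Normalized fluidity (phi - pi/4) / (pi/4); -1 solid, +1 fluid."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < -1e-15) or np.any(phi > math.pi / 2 + 1e-12):
        raise DomainError("phase must lie in [0, pi/2]")
    out = (phi - PHI_TRANSITION) / PHI_TRANSITION
    return float(out) if out.ndim == 0 else out


def phase_from_fluidity(fluidity):
    """Inverse of :func:`fluidity_from_phase`."""
    fluidity = np.asarray(fluidity, dtype=float)
    if np.any(fluidity < -1 - 1e-12) or np.any(fluidity > 1 + 1e-12):
        raise DomainError("fluidity must lie in [-1, 1]")
    out = PHI_TRANSITION * (1.0 + fluidity)
    return float(out) if out.ndim == 0 else out


def modulus_from_speed(c, phi, rho: float = DEFAULT_DENSITY):
    """|G*| = c^2 * rho * (1 + cos(phi)) / 2."""
    c = np.asarray(c, dtype=float)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(c < 0):
        raise DomainError("speed must be non-negative")
    if np.any(phi_arr < -1e-15) or np.any(phi_arr > math.pi / 2 + 1e-12):
        raise DomainError("phase must lie in [0, pi/2]")
    if rho <= 0:
        raise DomainError("density must be positive")
    out = c**2 * rho * (1.0 + np.cos(phi_arr)) / 2.0
    return float(out) if out.ndim == 0 else out


def speed_from_modulus(magnitude, phi, rho: float = DEFAULT_DENSITY):
    """Inverse of :func:`modulus_from_speed`."""
    magnitude = np.asarray(magnitude, dtype=float)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(magnitude < 0):
        raise DomainError("modulus magnitude must be non-negative")
    if rho <= 0:
        raise DomainError("density must be positive")
    out = np.sqrt(2.0 * magnitude / (rho * (1.0 + np.cos(phi_arr))))
    return float(out) if out.ndim == 0 else out


def springpot_modulus(p: SpringpotParams, f):
    """G*(f) = mu^(1-alpha) * eta^alpha * (i 2 pi f)^alpha; arg = alpha*pi/2."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be positive")
    omega = 2.0 * np.pi * f
    mag = p.mu ** (1.0 - p.alpha) * p.eta**p.alpha * omega**p.alpha
    out = mag * np.exp(1j * p.alpha * np.pi / 2.0)
    return complex(out) if out.ndim == 0 else out


def wavenumber_from_modulus(gstar, f, rho: float = DEFAULT_DENSITY):
    """Complex k* = 2 pi f sqrt(rho / G*) with the sign fixed so k'' >= 0."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(gstar, dtype=complex)
    k = 2.0 * np.pi * f * np.sqrt(rho / g)
    k = np.where(k.imag < 0, np.conj(k), k)
    return complex(k) if k.ndim == 0 else k


def wavenumber_to_speed_attenuation(k, f):
    """(c, a) = (2 pi f / k', f / k''); a = +inf when k'' = 0 (lossless)."""
    k = complex(k)
    if k.real <= 0:
        raise InvalidWavenumberError(f"k' must be positive, got {k.real}")
    if k.imag < 0:
        raise InvalidWavenumberError(f"k'' must be non-negative, got {k.imag}")
    if f <= 0:
        raise DomainError("frequency must be positive")
    c = 2.0 * math.pi * f / k.real
    a = math.inf if k.imag == 0 else f / k.imag
    return c, a


def speed_attenuation_to_wavenumber(c, a, f) -> complex:
    """Inverse of :func:`wavenumber_to_speed_attenuation`."""
    if c <= 0 or f <= 0:
        raise DomainError("speed and frequency must be positive")
    k_im = 0.0 if math.isinf(a) else f / a
    return complex(2.0 * math.pi * f / c, k_im)


# ---------------------------------------------------------------------------
# springpot fitting
# ---------------------------------------------------------------------------

def _model_speed_attenuation(mu, alpha, f, rho):
    """Model c(f), a(f) for a springpot via the shear dispersion relation."""
    p = SpringpotParams(mu=mu, alpha=alpha)
    k = wavenumber_from_modulus(springpot_modulus(p, f), f, rho)
    k = np.atleast_1d(k)
    c = 2.0 * np.pi * np.asarray(f, dtype=float) / k.real
    with np.errstate(divide="ignore"):
        a = np.where(k.imag > 0, np.asarray(f, dtype=float) / np.where(k.imag > 0, k.imag, 1.0), np.inf)
    return c, a


def summary_at_frequency(
    p: SpringpotParams, f: float, rho: float = DEFAULT_DENSITY
) -> ViscoelasticSummary:
    """Evaluate a springpot state at one frequency as a point summary."""
    g = springpot_modulus(p, f)
    phi = p.phase
    mag = abs(g)
    c = speed_from_modulus(mag, phi, rho)
    k = wavenumber_from_modulus(g, f, rho)
    lossless = k.imag <= 0 or p.alpha == 0
    a = math.inf if lossless else f / k.imag
    return ViscoelasticSummary(
        speed=c,
        penetration=a,
        phase=phi,
        fluidity=fluidity_from_phase(phi),
        magnitude=mag,
        density=rho,
        lossless=lossless,
    )


def _warm_start(d: DispersionTable, rho: float):
    """Closed-form initial guess from per-frequency implied phase.

    From k''/k' = tan(phi/2) and (c, a): tan(phi/2) = c / (2 pi a).
    """
    with np.errstate(divide="ignore"):
        ratio = np.where(
            d.lossless, 0.0, d.speeds / (2.0 * np.pi * d.penetrations)
        )
    phi_i = 2.0 * np.arctan(ratio)
    phi0 = float(np.median(phi_i))
    alpha0 = min(max(phi0 * 2.0 / np.pi, 1e-6), 1.0 - 1e-6)
    i_med = len(d) // 2
    f_med = d.frequencies[i_med]
    mag = modulus_from_speed(d.speeds[i_med], phi_i[i_med], rho)
    omega = 2.0 * np.pi * f_med
    mu0 = (mag / omega**alpha0) ** (1.0 / (1.0 - alpha0))
    if not np.isfinite(mu0) or mu0 <= 0:
        mu0 = mag
    return mu0, alpha0


def fit_springpot(
    d: DispersionTable,
    rho: float = DEFAULT_DENSITY,
    report_freq: float = 500.0,
):
    """Fit (mu, alpha) to a dispersion table by joint relative least squares
    on c(f) and a(f); return the parameters and a summary at ``report_freq``.

    Penetration residuals are skipped at lossless rows (a = inf).
    """
    if len(d) < 3:
        raise UnderdeterminedError(
            f"need at least 3 frequencies, got {len(d)}"
        )
    f = d.frequencies
    use_a = ~d.lossless

    def residuals(theta):
        log_mu, alpha = theta
        c_m, a_m = _model_speed_attenuation(np.exp(log_mu), alpha, f, rho)
        res_c = (c_m - d.speeds) / d.speeds
        if not np.any(use_a):
            return res_c
        with np.errstate(invalid="ignore"):
            res_a = np.where(
                use_a & np.isfinite(a_m),
                (a_m - d.penetrations) / np.where(use_a, d.penetrations, 1.0),
                np.where(use_a, 1e3, 0.0),  # model lossless vs lossy data
            )
        return np.concatenate([res_c, res_a[use_a]])

    mu0, alpha0 = _warm_start(d, rho)
    result = least_squares(
        residuals,
        x0=[np.log(mu0), alpha0],
        bounds=([-np.inf, 0.0], [np.inf, 1.0]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not result.success:
        raise FitFailureError(
            "springpot fit did not converge",
            diagnostics={"status": result.status, "message": result.message},
        )
    mu_hat = float(np.exp(result.x[0]))
    alpha_hat = float(np.clip(result.x[1], 0.0, 1.0))
    params = SpringpotParams(mu=mu_hat, alpha=alpha_hat)
    return params, summary_at_frequency(params, report_freq, rho)
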