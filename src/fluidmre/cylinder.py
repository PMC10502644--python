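"""Axial shear-wave profiles in a z-infinite cylinder and their inversion.

The forward model for the complex axial displacement at radius ``r`` inside a
cylinder of radius ``R`` driven harmonically at its wall is

    u(r) = U0 * J0(k* r) / J0(k* R)

with ``J0`` the order-zero Bessel function of the first kind at complex
argument and ``k* = k' + i k''`` the complex shear wavenumber. Fitting a
measured radial profile recovers ``k*`` per drive frequency; a sweep of
frequencies yields a dispersion table that feeds the springpot fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import jv

from .errors import (
    DomainError,
    FitFailureError,
    ResonanceError,
    UnderdeterminedError,
)
from .rheology import (
    DEFAULT_DENSITY,
    DispersionTable,
    fit_springpot,
)

__all__ = [
    "CylinderProfile",
    "cylinder_profile_forward",
    "fit_cylinder_profile",
    "tabletop_pipeline",
]

#: Relative |J0(k R)| floor below which the forward model is rejected.
RESONANCE_TOL = 1e-6

#: Default springpot fitting band in Hz.
FIT_BAND = (200.0, 800.0)


@dataclass
class CylinderProfile:
    """One radial displacement profile at a single drive frequency."""

    radius: float  # R, m
    positions: np.ndarray  # r_i, m, sorted, in [0, R]
    displacements: np.ndarray  # complex u_i, arbitrary units
    frequency: float  # Hz

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=complex)
        if self.radius <= 0:
            raise DomainError("radius must be positive")
        if self.frequency <= 0:
            raise DomainError("frequency must be positive")
        if len(self.positions) != len(self.displacements):
            raise DomainError("positions/displacements length mismatch")
        if len(self.positions) < 8:
            raise DomainError("need at least 8 radial samples")
        if np.any(np.diff(self.positions) < 0):
            raise DomainError("positions must be sorted")
        if self.positions[0] < 0 or self.positions[-1] > self.radius * (1 + 1e-9):
            raise DomainError("positions must lie in [0, R]")

    def to_csv(self, path, sidecar_path=None) -> None:
        pd.DataFrame(
            {
                "r_m": self.positions,
                "u_re": self.displacements.real,
                "u_im": self.displacements.imag,
            }
        ).to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"radius_m": self.radius, "freq_hz": self.frequency}, fh
                )

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "CylinderProfile":
        df = pd.read_csv(path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            radius=meta["radius_m"],
            positions=df["r_m"].to_numpy(),
            displacements=df["u_re"].to_numpy() + 1j * df["u_im"].to_numpy(),
            frequency=meta["freq_hz"],
        )


def cylinder_profile_forward(k, R, r, U0=1.0 + 0.0j):
    """Forward Bessel profile U0 * J0(k r) / J0(k R); u(R) = U0 exactly."""
    if R <= 0:
        raise DomainError("radius must be positive")
    k = complex(k)
    r = np.asarray(r, dtype=float)
    denom = jv(0, k * R)
    if abs(denom) < RESONANCE_TOL:  # |J0(0)| = 1
        raise ResonanceError(
            f"J0(k R) = {denom:.3e} is within tolerance of a resonance zero"
        )
    return U0 * jv(0, k * r) / denom


def _projected_residual(k_re, k_im, profile: CylinderProfile):
    """Residual after solving the complex amplitude U0 in closed form."""
    k = complex(k_re, k_im)
    denom = jv(0, k * profile.radius)
    if abs(denom) < RESONANCE_TOL:
        return None, None, np.inf
    model = jv(0, k * profile.positions) / denom
    mm = np.vdot(model, model).real
    if mm == 0:
        return None, None, np.inf
    amp = np.vdot(model, profile.displacements) / mm
    resid = profile.displacements - amp * model
    return amp, resid, float(np.sum(np.abs(resid) ** 2))


def fit_cylinder_profile(profile: CylinderProfile):
    """Fit (k', k'', U0) to a measured radial profile.

    Returns ``(k, U0)`` with ``k = k' + i k''`` (``k' > 0``, ``k'' >= 0``).
    The complex drive amplitude is a nuisance parameter solved in closed form
    at each trial wavenumber (variable projection); the nonlinear search runs
    over ``(k', k'')`` only, seeded by a coarse grid because the Bessel
    objective is multimodal.
    """
    R = profile.radius
    # grid seed: k' in [pi/(2R), 20 pi/R], three damping ratios
    k_re_grid = np.linspace(np.pi / (2 * R), 20 * np.pi / R, 80)
    best = (np.inf, None)
    for k_re in k_re_grid:
        for ratio in (0.01, 0.05, 0.2, 0.5):
            _, _, cost = _projected_residual(k_re, ratio * k_re, profile)
            if cost < best[0]:
                best = (cost, (k_re, ratio * k_re))
    if best[1] is None:
        raise FitFailureError("grid search found no admissible wavenumber")

    def residuals(theta):
        _, resid, cost = _projected_residual(theta[0], theta[1], profile)
        if resid is None:
            return np.full(2 * len(profile.positions), 1e6)
        return np.concatenate([resid.real, resid.imag])

    bounds = ([1e-12, 0.0], [np.inf, np.inf])
    result = least_squares(
        residuals,
        x0=list(best[1]),
        bounds=bounds,
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    # the lossless limit sits on the k'' = 0 bound where the trust-region
    # solver can stall a shade above it; accept the bound if it is no worse
    _, _, cost_hat = _projected_residual(result.x[0], result.x[1], profile)
    _, _, cost_bound = _projected_residual(result.x[0], 0.0, profile)
    if cost_bound <= cost_hat:
        result.x[1] = 0.0
    if not result.success:
        raise FitFailureError(
            "cylinder profile fit did not converge",
            diagnostics={"status": result.status, "message": result.message},
        )
    k = complex(result.x[0], max(result.x[1], 0.0))
    if abs(jv(0, k * R)) < RESONANCE_TOL:
        raise ResonanceError("fit converged onto a J0 resonance")
    amp, _, _ = _projected_residual(k.real, k.imag, profile)
    return k, complex(amp)


def tabletop_pipeline(
    profiles,
    rho: float = DEFAULT_DENSITY,
    fit_band=FIT_BAND,
    report_freq: float = 500.0,
):
    """Per-frequency wavenumber fits -> dispersion table -> springpot summary.

    Frequencies outside ``fit_band`` are kept in the returned table but
    excluded from the springpot fit. Per-frequency fit failures are skipped
    with a warning; the pipeline fails if fewer than 3 usable in-band
    frequencies remain.
    """
    freqs, ks = [], []
    for profile in sorted(profiles, key=lambda p: p.frequency):
        try:
            k, _ = fit_cylinder_profile(profile)
        except (FitFailureError, ResonanceError) as exc:
            warnings.warn(
                f"profile at {profile.frequency} Hz skipped: {exc}",
                stacklevel=2,
            )
            continue
        freqs.append(profile.frequency)
        ks.append(k)
    if not freqs:
        raise FitFailureError("no profile could be fitted")
    table = DispersionTable.from_wavenumbers(np.array(freqs), np.array(ks))
    band_table = table.restrict(*fit_band)
    if len(band_table) < 3:
        raise UnderdeterminedError(
            f"only {len(band_table)} usable frequencies in band {fit_band}"
        )
    params, summary = fit_springpot(band_table, rho, report_freq=report_freq)
    return table, params, summary
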