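"""Seeded generators for every input the analysis pipeline consumes:
springpot dispersion tables, cylinder wave profiles, heterogeneous 2D
viscoelastic phantoms with wave fields, jammed/unjammed cell-track
mixtures, and the packaged meta-analysis fixture.

All generators are deterministic under a fixed seed. Every generated
artifact carries enough ground truth to score downstream estimators.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import jv

from .classify import ControlSummary, TumorRecord
from .cylinder import RESONANCE_TOL, CylinderProfile, cylinder_profile_forward
from .errors import DomainError
from .inversion import ParameterMaps, WaveFieldSet, helmholtz_forward
from .rheology import (
    DEFAULT_DENSITY,
    DispersionTable,
    SpringpotParams,
    modulus_from_speed,
    phase_from_fluidity,
    springpot_modulus,
    wavenumber_from_modulus,
)
from .tracks import CellTrack

__all__ = [
    "SCENARIOS",
    "PhantomSpec",
    "springpot_for_target",
    "make_dispersion",
    "make_cylinder_profiles",
    "make_phantom",
    "make_tracks",
    "table2_fixture",
]

#: Named (speed m/s, fluidity) targets at 500 Hz for the measured gel and
#: tissue scenarios used throughout the tests.
SCENARIOS = {
    "rat-tail": (0.542, -0.176),
    "bovine-skin": (0.64, 0.350),
    "mix-uncrosslinked": (0.461, -0.240),
    "crosslinked-mix": (1.09, -0.754),
    "hcc-in-cirrhosis": (2.54, 0.53),
}


def springpot_for_target(
    speed: float,
    fluidity: float,
    f: float = 500.0,
    rho: float = DEFAULT_DENSITY,
) -> SpringpotParams:
    """Invert (c, fluidity) at one frequency into springpot parameters.

    alpha follows from the fluidity (phi = alpha * pi/2) and mu from the
    modulus magnitude at ``f``.
    """
    phi = phase_from_fluidity(fluidity)
    alpha = phi * 2.0 / math.pi
    mag = modulus_from_speed(speed, phi, rho)
    omega = 2.0 * math.pi * f
    if alpha >= 1.0:
        raise DomainError("pure dashpot target cannot fix mu")
    mu = (mag / omega**alpha) ** (1.0 / (1.0 - alpha))
    return SpringpotParams(mu=mu, alpha=alpha)


def make_dispersion(
    p: SpringpotParams,
    freqs,
    noise: float = 0.0,
    seed: int = 0,
    rho: float = DEFAULT_DENSITY,
) -> DispersionTable:
    """Dispersion table from the springpot model with multiplicative
    lognormal noise of relative sd ``noise`` on c and a."""
    freqs = np.asarray(freqs, dtype=float)
    if noise < 0:
        raise DomainError("noise must be non-negative")
    k = np.atleast_1d(
        wavenumber_from_modulus(springpot_modulus(p, freqs), freqs, rho)
    )
    c = 2.0 * np.pi * freqs / k.real
    lossless = k.imag == 0
    with np.errstate(divide="ignore"):
        a = np.where(lossless, np.inf, freqs / np.where(lossless, 1.0, k.imag))
    if noise > 0:
        rng = np.random.default_rng(seed)
        c = c * np.exp(noise * rng.standard_normal(len(freqs)))
        a = np.where(
            lossless, a, a * np.exp(noise * rng.standard_normal(len(freqs)))
        )
    return DispersionTable(freqs, c, a, lossless=lossless)


def make_cylinder_profiles(
    p: SpringpotParams,
    R: float = 0.004,
    n_radial: int = 64,
    freqs=None,
    noise: float = 0.0,
    seed: int = 0,
    rho: float = DEFAULT_DENSITY,
):
    """Forward Bessel profiles per frequency with additive complex Gaussian
    noise; frequencies at a J0 resonance are skipped with a warning.

    Returns ``(profiles, metadata)`` where metadata records the generating
    parameters and the 500 Hz ground-truth summary targets.
    """
    if R <= 0:
        raise DomainError("radius must be positive")
    if n_radial < 8:
        raise DomainError("need at least 8 radial samples")
    if freqs is None:
        freqs = np.arange(200.0, 2001.0, 100.0)
    rng = np.random.default_rng(seed)
    r = np.linspace(0.0, R, n_radial)
    profiles = []
    for f in np.asarray(freqs, dtype=float):
        k = wavenumber_from_modulus(springpot_modulus(p, f), f, rho)
        if abs(jv(0, k * R)) < RESONANCE_TOL:
            warnings.warn(
                f"frequency {f} Hz at a J0 resonance; skipped", stacklevel=2
            )
            continue
        u = cylinder_profile_forward(k, R, r)
        if noise > 0:
            scale = noise * float(np.sqrt(np.mean(np.abs(u) ** 2)))
            u = u + scale * (
                rng.standard_normal(n_radial)
                + 1j * rng.standard_normal(n_radial)
            ) / math.sqrt(2.0)
        profiles.append(
            CylinderProfile(
                radius=R, positions=r, displacements=u, frequency=f
            )
        )
    from .rheology import summary_at_frequency

    summary = summary_at_frequency(p, 500.0, rho)
    metadata = {
        "mu": p.mu,
        "alpha": p.alpha,
        "rho": rho,
        "radius_m": R,
        "target_c_500hz": summary.speed,
        "target_fluidity_500hz": summary.fluidity,
        "seed": seed,
        "noise": noise,
    }
    return profiles, metadata


@dataclass
class PhantomSpec:
    """Recipe for a heterogeneous 2D viscoelastic phantom."""

    shape: tuple = (96, 96)  # grid (ny, nx)
    spacing: float = 0.002  # m per pixel
    background: tuple = (2.0, -0.5)  # (c m/s, fluidity)
    inclusion: tuple = (3.0, 0.2)  # (c m/s, fluidity)
    inclusion_shape: str = "disk"  # 'disk' or 'star'
    inclusion_radius_frac: float = 0.25  # of min grid dimension
    n_fingers: int = 8
    finger_amplitude: float = 0.3
    boundary_blur: float = 0.0  # Gaussian sigma, pixels
    island_fraction: float = 0.0  # fluid-island fraction inside inclusion
    island_fluidity: float = 0.5
    noise: float = 0.0  # relative complex Gaussian noise on the fields
    frequencies: tuple = (40.0, 50.0, 60.0)
    rho: float = DEFAULT_DENSITY
    seed: int = 0
    drive: str = "left"

    def __post_init__(self):
        for c, fl in (self.background, self.inclusion):
            if c <= 0:
                raise DomainError("speeds must be positive")
            if not -1.0 <= fl <= 1.0:
                raise DomainError("fluidity must lie in [-1, 1]")
        if self.boundary_blur < 0 or not 0.0 <= self.island_fraction <= 1.0:
            raise DomainError("invalid blur or island fraction")
        ny, nx = self.shape
        if self.inclusion_radius_frac * (1 + self.finger_amplitude) > 0.5:
            raise DomainError("inclusion exceeds the grid")
        if min(ny, nx) < 32:
            raise DomainError("grid must be at least 32x32")


def _inclusion_mask(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r0 = spec.inclusion_radius_frac * min(ny, nx)
    if spec.inclusion_shape == "disk":
        return r <= r0
    if spec.inclusion_shape == "star":
        theta = np.arctan2(yy - cy, xx - cx)
        boundary = r0 * (
            1.0 + spec.finger_amplitude * np.cos(spec.n_fingers * theta)
        )
        return r <= boundary
    raise DomainError(f"unknown inclusion shape {spec.inclusion_shape!r}")


def make_phantom(spec: PhantomSpec):
    """Build truth maps, simulate multifrequency wave fields, return masks.

    Returns ``(truth, wavefields, masks)``; ``masks`` carries the crisp
    tumor mask plus ground-truth feature labels under ``'labels'``.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    mask = _inclusion_mask(spec)

    c_bg, fl_bg = spec.background
    c_in, fl_in = spec.inclusion
    fluidity = np.where(mask, fl_in, fl_bg).astype(float)
    speed = np.where(mask, c_in, c_bg).astype(float)

    island_mask = np.zeros_like(mask)
    if spec.island_fraction > 0:
        # thresholded smoothed noise gives the exact requested occupancy
        noise_field = gaussian_filter(rng.standard_normal(spec.shape), 2.0)
        vals = noise_field[mask]
        cut = np.quantile(vals, 1.0 - spec.island_fraction)
        island_mask = mask & (noise_field >= cut)
        fluidity[island_mask] = spec.island_fluidity

    if spec.boundary_blur > 0:
        fluidity = gaussian_filter(fluidity, spec.boundary_blur)
        speed = gaussian_filter(speed, spec.boundary_blur)
    fluidity = np.clip(fluidity, -1.0, 1.0)

    phase = phase_from_fluidity(fluidity)
    magnitude = modulus_from_speed(speed, phase, spec.rho)
    truth = ParameterMaps.from_magnitude_phase(
        magnitude,
        phase,
        spec.spacing,
        spec.rho,
        masks={"tumor": mask, "islands": island_mask},
    )

    fields = []
    for f in spec.frequencies:
        u = helmholtz_forward(truth, spec.rho, f, drive=spec.drive)
        if spec.noise > 0:
            scale = spec.noise * float(np.sqrt(np.mean(np.abs(u) ** 2)))
            u = u + scale * (
                rng.standard_normal(spec.shape)
                + 1j * rng.standard_normal(spec.shape)
            ) / math.sqrt(2.0)
        fields.append(u)
    wavefields = WaveFieldSet(
        frequencies=np.asarray(spec.frequencies, dtype=float),
        fields=fields,
        spacing=spec.spacing,
    )

    labels = {
        "heterogeneous": spec.island_fraction >= 0.1,
        "front": (
            "diffuse"
            if (spec.boundary_blur >= 2.5 or spec.inclusion_shape == "star")
            else "sharp"
        ),
        "island_fraction": spec.island_fraction,
    }
    masks = {"tumor": mask, "islands": island_mask, "labels": labels}
    return truth, wavefields, masks


def make_tracks(
    n: int = 50,
    unjammed_fraction: float = 0.3,
    cell_radius: float = 10.0,
    caged_sd: float = 3.0,
    speed: float = 0.5,
    duration: float = 720.0,
    dt: float = 10.0,
    seed: int = 0,
    relaxation_min: float = 120.0,
):
    """Mixture of caged (Ornstein-Uhlenbeck confined) and persistent
    migratory 3D tracks, all cluster-tagged.

    Jammed tracks have stationary 3D positional sd ``caged_sd`` (um);
    unjammed tracks move with mean speed ``speed`` (um/min) and slowly
    diffusing direction. Returns ``(tracks, truth_labels)``.
    """
    if not 0.0 <= unjammed_fraction <= 1.0:
        raise DomainError("fraction must lie in [0, 1]")
    if dt <= 0:
        raise DomainError("dt must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    n_steps = len(times)
    n_unjammed = int(round(n * unjammed_fraction))
    tracks, labels = [], []
    axis_sd = caged_sd / math.sqrt(3.0)
    decay = math.exp(-dt / relaxation_min)
    kick = axis_sd * math.sqrt(1.0 - decay**2)
    for i in range(n):
        origin = rng.uniform(0.0, 200.0, size=3)
        unjammed = i < n_unjammed
        if unjammed:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = np.zeros((n_steps, 3))
            for t in range(1, n_steps):
                direction = direction + 0.15 * rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                step = speed * dt * max(
                    0.0, 1.0 + 0.2 * rng.standard_normal()
                )
                pos[t] = pos[t - 1] + step * direction
        else:
            pos = np.zeros((n_steps, 3))
            x = axis_sd * rng.standard_normal(3)
            pos[0] = x
            for t in range(1, n_steps):
                x = decay * x + kick * rng.standard_normal(3)
                pos[t] = x
        tracks.append(
            CellTrack(
                cell_id=f"cell_{i:04d}",
                times=times,
                positions=origin + pos,
                region="cluster",
            )
        )
        labels.append("unjammed" if unjammed else "jammed")
    return tracks, labels


def table2_fixture():
    """The packaged per-entity stiffness/fluidity meta-analysis fixture."""
    ref = importlib.resources.files("fluidmre") / "data" / "table2.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False)
    records = []
    for entity in df["entity"].unique():
        sub = df[df["entity"] == entity]
        tumor = sub[sub["role"] == "tumor"].iloc[0]
        controls = tuple(
            ControlSummary(
                tag=row["control_tag"],
                subregion=row["subregion"],
                c_mean=float(row["c_mean"]),
                c_sd=float(row["c_sd"]),
                fluidity_mean=float(row["fluidity_mean"]),
                fluidity_sd=float(row["fluidity_sd"]),
                n=int(row["n"]),
            )
            for _, row in sub[sub["role"] == "control"].iterrows()
        )
        records.append(
            TumorRecord(
                entity=entity,
                study=tumor["study"],
                c_mean=float(tumor["c_mean"]),
                c_sd=float(tumor["c_sd"]),
                fluidity_mean=float(tumor["fluidity_mean"]),
                fluidity_sd=float(tumor["fluidity_sd"]),
                n=int(tumor["n"]),
                controls=controls,
            )
        )
    return records
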