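"""Fluidity-map features: regime labels, heterogeneity, front texture, and
the boundary-instability criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import perimeter_crofton

from .errors import DomainError, EmptyROIError, UndefinedCriterionError

__all__ = [
    "REGIMES",
    "RegimeThresholds",
    "FrontAssessment",
    "regime_classify",
    "regime_map",
    "heterogeneity_score",
    "front_texture",
    "saffman_taylor_unstable",
]

REGIMES = ("solid", "transitional", "fluid")


@dataclass(frozen=True)
class RegimeThresholds:
    """Fluidity cut points separating solid / transitional / fluid.

    The defaults reproduce the published retrospective labels; they are
    configuration, not constants, and may be refined (e.g. by ROC analysis)
    as more data accrues. ``borderline`` is the half-width within which a
    mean is annotated with a dual label.
    """

    low: float = -0.1
    high: float = 0.1
    borderline: float = 0.03

    def __post_init__(self):
        if not self.low < self.high:
            raise DomainError("require low < high")


@dataclass(frozen=True)
class FrontAssessment:
    """Texture of a tumor front: shape roughness plus profile width."""

    label: str  # 'sharp' or 'diffuse'
    roughness: float  # perimeter^2 / (4 pi area), >= 1 for a disk
    gradient_width: float  # m, mean 25->75% contrast traversal distance


def regime_classify(
    fluidity: float, thresholds: RegimeThresholds = RegimeThresholds()
) -> str:
    """Label a fluidity value solid / transitional / fluid."""
    if not (-1.0 - 1e-12 <= fluidity <= 1.0 + 1e-12):
        raise DomainError(f"fluidity {fluidity} outside [-1, 1]")
    if fluidity < thresholds.low:
        return "solid"
    if fluidity > thresholds.high:
        return "fluid"
    return "transitional"


def regime_dual_label(
    fluidity: float, thresholds: RegimeThresholds = RegimeThresholds()
) -> str:
    """Primary label, with an adjacent label appended near a cut point."""
    primary = regime_classify(fluidity, thresholds)
    b = thresholds.borderline
    if abs(fluidity - thresholds.low) <= b:
        return "solid/transitional"
    if abs(fluidity - thresholds.high) <= b:
        return "transitional/fluid"
    return primary


def regime_map(
    fluidity_map, thresholds: RegimeThresholds = RegimeThresholds()
) -> np.ndarray:
    """Integer regime grid: 0 solid, 1 transitional, 2 fluid."""
    fl = np.asarray(fluidity_map, dtype=float)
    out = np.ones(fl.shape, dtype=np.int8)
    out[fl < thresholds.low] = 0
    out[fl > thresholds.high] = 2
    return out


def heterogeneity_score(
    fluidity_map,
    roi_mask,
    thresholds: RegimeThresholds = RegimeThresholds(),
    min_fraction: float = 0.10,
):
    """Shannon entropy (nats) of regime occupancy within an ROI.

    Returns ``(score, heterogeneous, fractions)`` where ``heterogeneous`` is
    True when at least two regimes each occupy ``min_fraction`` of the ROI
    and ``fractions`` maps regime name to occupancy.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not np.any(roi):
        raise EmptyROIError("ROI selects no pixels")
    regimes = regime_map(fluidity_map, thresholds)[roi]
    fractions = {
        name: float(np.mean(regimes == code))
        for code, name in enumerate(REGIMES)
    }
    probs = np.array([v for v in fractions.values() if v > 0])
    score = float(-np.sum(probs * np.log(probs)))
    heterogeneous = int(np.sum(probs >= min_fraction)) >= 2
    return score, heterogeneous, fractions


def _roughness(mask: np.ndarray) -> float:
    """Isoperimetric compactness perimeter^2 / (4 pi area); 1 for a disk."""
    area = float(mask.sum())
    per = float(perimeter_crofton(mask, directions=4))
    return per**2 / (4.0 * math.pi * area)


def front_texture(
    fluidity_map,
    tumor_mask,
    spacing: float,
    roughness_threshold: float = 1.5,
    width_threshold_px: float = 3.0,
    band_px: int = 12,
) -> FrontAssessment:
    """Assess a tumor front as sharp or diffuse.

    Roughness is the isoperimetric compactness of the mask. The gradient
    width is estimated from the mean fluidity profile along boundary normals
    (binned by signed Euclidean distance from the boundary within
    ``band_px`` pixels): the distance over which the profile traverses from
    25% to 75% of the tumor-background contrast. The front is labeled
    diffuse when roughness exceeds ``roughness_threshold`` OR the gradient
    width exceeds ``width_threshold_px`` pixels.
    """
    mask = np.asarray(tumor_mask, dtype=bool)
    fl = np.asarray(fluidity_map, dtype=float)
    if not np.any(mask):
        raise EmptyROIError("tumor mask is empty")
    if np.all(mask):
        raise EmptyROIError("tumor mask complement is empty")
    edge_touch = (
        mask[0, :].any() or mask[-1, :].any()
        or mask[:, 0].any() or mask[:, -1].any()
    )
    if edge_touch:
        warnings.warn(
            "tumor mask touches the image edge; affected normals excluded",
            stacklevel=2,
        )

    rough = _roughness(mask)

    # signed distance: negative inside the tumor, positive outside (pixels)
    dist_out = distance_transform_edt(~mask)
    dist_in = distance_transform_edt(mask)
    signed = np.where(mask, -dist_in, dist_out)

    inner = fl[signed <= -band_px]
    outer = fl[signed >= band_px]
    tumor_level = float(np.mean(inner)) if inner.size else float(np.mean(fl[mask]))
    bg_level = float(np.mean(outer)) if outer.size else float(np.mean(fl[~mask]))
    contrast = tumor_level - bg_level

    if abs(contrast) < 1e-12:
        width_px = 0.0
    else:
        bins = np.arange(-band_px, band_px + 1)
        prof = np.full(len(bins) - 1, np.nan)
        for i in range(len(bins) - 1):
            sel = (signed >= bins[i]) & (signed < bins[i + 1])
            if np.any(sel):
                prof[i] = np.mean(fl[sel])
        centers = (bins[:-1] + bins[1:]) / 2.0
        ok = np.isfinite(prof)
        centers, prof = centers[ok], prof[ok]
        # normalize to 0 at background level, 1 at tumor level
        norm = (prof - bg_level) / contrast
        # profile decreases (in normalized units) from inside to outside;
        # find 75% and 25% crossings by interpolation on the monotone hull
        order = np.argsort(centers)
        centers, norm = centers[order], norm[order]
        d75 = _crossing(centers, norm, 0.75)
        d25 = _crossing(centers, norm, 0.25)
        width_px = abs(d25 - d75)

    label = (
        "diffuse"
        if (rough > roughness_threshold or width_px > width_threshold_px)
        else "sharp"
    )
    return FrontAssessment(
        label=label, roughness=rough, gradient_width=width_px * spacing
    )


def _crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """First downward crossing of ``level`` by linear interpolation."""
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return x[i] + (level - y0) / (y1 - y0) * (x[i + 1] - x[i])
    return x[int(np.argmin(np.abs(y - level)))]


def saffman_taylor_unstable(
    phi_tumor: float,
    phi_control: float,
    g_tumor: float,
    g_control: float,
) -> bool:
    """Boundary-instability criterion:
    unstable iff sin(phi_tumor) / sin(phi_control) < G_control / G_tumor.
    """
    for name, phi in (("tumor", phi_tumor), ("control", phi_control)):
        if not (0.0 <= phi <= math.pi / 2 + 1e-12):
            raise DomainError(f"phi_{name} outside [0, pi/2]")
    if g_tumor <= 0 or g_control <= 0:
        raise DomainError("moduli must be positive")
    if math.sin(phi_control) == 0.0:
        raise UndefinedCriterionError("sin(phi_control) = 0: criterion undefined")
    return math.sin(phi_tumor) / math.sin(phi_control) < g_control / g_tumor
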