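"""Displacement analysis of 3D cell trajectories with the one-cell-radius
unjamming threshold.

A cluster-resident cell whose maximum displacement from its starting
position exceeds one cell radius has escaped its cage and is labeled
``unjammed``; the criterion does not apply to single cells tracked in
stroma-like regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError, EmptyROIError

__all__ = [
    "DEFAULT_CELL_RADIUS_UM",
    "CellTrack",
    "displacement_series",
    "classify_track",
    "unjammed_fraction",
    "tracks_to_tsv",
    "tracks_from_tsv",
]

#: Default cell radius in micrometres (configurable; the threshold is
#: stated in units of cell radius).
DEFAULT_CELL_RADIUS_UM = 10.0

REGIONS = ("cluster", "stroma")


@dataclass
class CellTrack:
    """One tracked cell: times in minutes, positions in micrometres."""

    cell_id: str
    times: np.ndarray  # min
    positions: np.ndarray  # (n, 3) um
    region: str  # 'cluster' or 'stroma'

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.region not in REGIONS:
            raise DomainError(f"unknown region {self.region!r}")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise DomainError("positions must have shape (n, 3)")
        if len(self.times) != len(self.positions):
            raise DomainError("times/positions length mismatch")
        if len(self.times) < 2:
            raise DomainError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise DomainError("positions must be finite")


def displacement_series(track: CellTrack) -> np.ndarray:
    """Euclidean displacement from the first position, per time point (um)."""
    return np.linalg.norm(track.positions - track.positions[0], axis=1)


def classify_track(
    track: CellTrack, cell_radius: float = DEFAULT_CELL_RADIUS_UM
) -> str:
    """'unjammed' iff the maximum displacement exceeds one cell radius.

    Returns ``'not-applicable'`` for stroma-tagged tracks (the caged-motion
    criterion only holds inside dense cell clusters).
    """
    if track.region == "stroma":
        return "not-applicable"
    return (
        "unjammed"
        if float(displacement_series(track).max()) > cell_radius
        else "jammed"
    )


def unjammed_fraction(
    tracks, cell_radius: float = DEFAULT_CELL_RADIUS_UM, ci_level: float = 0.95
):
    """Fraction of cluster tracks classified unjammed, with a Wilson
    confidence interval. Returns ``(fraction, (low, high), n_applicable)``.
    """
    labels = [classify_track(t, cell_radius) for t in tracks]
    applicable = [lab for lab in labels if lab != "not-applicable"]
    if not applicable:
        raise EmptyROIError("no cluster-tagged tracks")
    n = len(applicable)
    k = sum(lab == "unjammed" for lab in applicable)
    low, high = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
    return k / n, (float(low), float(high)), n


def tracks_to_tsv(tracks, path) -> None:
    rows = []
    for t in tracks:
        for i in range(len(t.times)):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "t_min": t.times[i],
                    "x_um": t.positions[i, 0],
                    "y_um": t.positions[i, 1],
                    "z_um": t.positions[i, 2],
                    "region": t.region,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def tracks_from_tsv(path):
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_min")
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                times=grp["t_min"].to_numpy(),
                positions=grp[["x_um", "y_um", "z_um"]].to_numpy(),
                region=grp["region"].iloc[0],
            )
        )
    return tracks
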