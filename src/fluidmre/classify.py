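"""Growth-pattern decision scheme and retrospective meta-analysis fixtures.

A tumor is scored on five categorical inputs — stiffness ratio versus
control, tumor fluidity regime, control fluidity regime, spatial
heterogeneity, and front texture — yielding one of four growth patterns:

    type 1: neither displacing growth nor infiltrative cell spreading
    type 2: displacing growth only
    type 3: infiltrative cell spreading only
    type 4: both

so that type = 1 + displacing + 2 * infiltrative.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from scipy import stats

from .errors import (
    AmbiguousClassificationError,
    DomainError,
)
from .maps import REGIMES, saffman_taylor_unstable

__all__ = [
    "ClassifierInput",
    "GrowthPattern",
    "ControlSummary",
    "TumorRecord",
    "classify_growth",
    "enumerate_combinations",
    "stiffer_than_control",
    "reproduce_table3",
    "delta_table",
    "load_table3_annotations",
]

FRONT_STATES = ("sharp", "diffuse", "redundant")


@dataclass(frozen=True)
class ClassifierInput:
    """The five categorical classifier inputs.

    ``control_regime`` may be a primary regime, a dual label such as
    ``'solid/transitional'``, or ``'redundant'``; it is carried for
    reporting and the boundary-stability fallback but does not pivot the
    reconstructed tree. ``front`` may be ``'redundant'`` when unknown.
    """

    stiffer: bool
    tumor_regime: str
    control_regime: str = "redundant"
    heterogeneous: bool = False
    front: str = "sharp"

    def __post_init__(self):
        if self.tumor_regime not in REGIMES:
            raise DomainError(f"unknown tumor regime {self.tumor_regime!r}")
        primary = self.control_regime.split("/")[0]
        if primary not in REGIMES + ("redundant",):
            raise DomainError(f"unknown control regime {self.control_regime!r}")
        if self.front not in FRONT_STATES:
            raise DomainError(f"unknown front state {self.front!r}")


@dataclass(frozen=True)
class GrowthPattern:
    displacing: bool
    infiltrative: bool

    @property
    def type(self) -> int:
        return 1 + int(self.displacing) + 2 * int(self.infiltrative)


@dataclass(frozen=True)
class ControlSummary:
    tag: str  # DTT / HV / CLH / BPH
    subregion: str  # e.g. PZ / TZ, empty when not applicable
    c_mean: float
    c_sd: float
    fluidity_mean: float
    fluidity_sd: float
    n: int


@dataclass(frozen=True)
class TumorRecord:
    """One per-entity row of the meta-analysis fixture."""

    entity: str
    study: str
    c_mean: float
    c_sd: float
    fluidity_mean: float
    fluidity_sd: float
    n: int
    controls: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.c_sd < 0 or self.fluidity_sd < 0 or self.n < 1:
            raise DomainError("require sds >= 0 and N >= 1")


def _pattern_for_front(x: ClassifierInput, front: str) -> GrowthPattern:
    if not x.stiffer:
        # a softer tumor cannot push its surroundings aside
        displacing = False
        infiltrative = front == "diffuse"
    else:
        # activity (fluid or transitional regime, or heterogeneity implying
        # at least partial fluid-like behavior) enables displacing growth
        displacing = (
            x.tumor_regime in ("fluid", "transitional") or x.heterogeneous
        )
        infiltrative = front == "diffuse" or x.tumor_regime == "fluid"
    return GrowthPattern(displacing=displacing, infiltrative=infiltrative)


def classify_growth(
    x: ClassifierInput, moduli: Optional[dict] = None
) -> GrowthPattern:
    """Apply the decision tree to one classifier input.

    When ``front`` is redundant/unknown and the type depends on it, the
    boundary-stability criterion is used as fallback if ``moduli`` provides
    ``phi_tumor, phi_control, g_tumor, g_control``; otherwise an
    :class:`AmbiguousClassificationError` listing the possible types is
    raised.
    """
    if x.front != "redundant":
        return _pattern_for_front(x, x.front)
    sharp = _pattern_for_front(x, "sharp")
    diffuse = _pattern_for_front(x, "diffuse")
    if sharp.type == diffuse.type:
        return sharp
    if moduli is not None:
        unstable = saffman_taylor_unstable(
            moduli["phi_tumor"],
            moduli["phi_control"],
            moduli["g_tumor"],
            moduli["g_control"],
        )
        return diffuse if unstable else sharp
    raise AmbiguousClassificationError(
        "front texture unknown and decisive; possible types "
        f"{sorted({sharp.type, diffuse.type})}",
        possible_types={sharp.type, diffuse.type},
    )


def enumerate_combinations(thresholds=None) -> pd.DataFrame:
    """All 2 x 3 x 3 x 2 x 2 = 72 input combinations with their patterns."""
    rows = []
    for stiffer, t_reg, c_reg, het, front in itertools.product(
        (False, True), REGIMES, REGIMES, (False, True), ("sharp", "diffuse")
    ):
        x = ClassifierInput(
            stiffer=stiffer,
            tumor_regime=t_reg,
            control_regime=c_reg,
            heterogeneous=het,
            front=front,
        )
        p = classify_growth(x)
        rows.append(
            {
                "stiffer": stiffer,
                "tumor_regime": t_reg,
                "control_regime": c_reg,
                "heterogeneous": het,
                "front": front,
                "displacing": p.displacing,
                "infiltrative": p.infiltrative,
                "type": p.type,
            }
        )
    return pd.DataFrame(rows)


def stiffer_than_control(
    t_mean: float,
    t_sd: float,
    t_n: int,
    c_mean: float,
    c_sd: float,
    c_n: int,
    alpha: float = 0.05,
) -> bool:
    """True iff tumor mean exceeds control mean AND Welch's t-test (from
    summary statistics) rejects equality at ``alpha``.

    With N < 2 on either side the test is impossible; falls back to a plain
    mean comparison with a warning.
    """
    if t_n < 2 or c_n < 2:
        warnings.warn(
            "cannot run Welch's t-test with N < 2; falling back to mean "
            "comparison",
            stacklevel=2,
        )
        return t_mean > c_mean
    se2 = t_sd**2 / t_n + c_sd**2 / c_n
    if se2 == 0:
        return False
    t_stat = (t_mean - c_mean) / se2**0.5
    df = se2**2 / (
        (t_sd**2 / t_n) ** 2 / (t_n - 1) + (c_sd**2 / c_n) ** 2 / (c_n - 1)
    )
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return (t_mean > c_mean) and (p < alpha)


def load_table3_annotations() -> pd.DataFrame:
    """Packaged retrospective classification inputs, one row per entity."""
    ref = importlib.resources.files("fluidmre") / "data" / "table3_annotations.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"bracketed_type": "Int64"})
    return df


def reproduce_table3(annotations: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Run the classifier over the retrospective per-entity inputs.

    Returns the annotation table extended with ``computed_type`` and
    ``matches_printed``. Bracketed clinical-context corrections are carried
    through unchanged as ``bracketed_type`` — they are knowledge external to
    the scheme, never tree output.
    """
    if annotations is None:
        annotations = load_table3_annotations()
    out = annotations.copy()
    computed = []
    for _, row in annotations.iterrows():
        x = ClassifierInput(
            stiffer=bool(row["stiffer"]),
            tumor_regime=row["tumor_regime"],
            control_regime=row["control_regime"],
            heterogeneous=bool(row["heterogeneous"]),
            front=row["front"],
        )
        computed.append(classify_growth(x).type)
    out["computed_type"] = computed
    out["matches_printed"] = out["computed_type"] == out["printed_type"]
    return out


def delta_table(records) -> pd.DataFrame:
    """Per-study (delta c, delta fluidity) arrows, one per control group."""
    rows = []
    for rec in records:
        for ctrl in rec.controls:
            rows.append(
                {
                    "entity": rec.entity,
                    "study": rec.study,
                    "control_tag": ctrl.tag,
                    "subregion": ctrl.subregion,
                    "delta_c": rec.c_mean - ctrl.c_mean,
                    "delta_fluidity": rec.fluidity_mean - ctrl.fluidity_mean,
                }
            )
    return pd.DataFrame(rows)
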