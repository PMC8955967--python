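"""Closed-form quantitative formulas for the companion assays.

Implements the 2^-ddCt relative-expression calculation for qPCR, the
two-diameter ellipsoid estimate of multicellular tumour spheroid (MTS)
volume, and the derived relative-volume and percent-inhibition ratios.
Batch helpers read and write plain TSV tables via pandas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "SpheroidDiameters",
    "relative_expression",
    "spheroid_volume",
    "relative_volume",
    "percent_inhibition",
    "qpcr_table",
    "spheroid_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for target and reference genes in sample and calibrator."""

    ct_target: float
    ct_reference: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        cts = (
            self.ct_target,
            self.ct_reference,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        )
        if not all(math.isfinite(c) for c in cts):
            raise ValueError("all Ct values must be finite")
        if any(not (0 < c < 45) for c in cts):
            warnings.warn(
                "Ct value outside the usual 0-45 cycle range", stacklevel=2
            )

    @property
    def ddct(self) -> float:
        return (self.ct_target - self.ct_reference) - (
            self.ct_target_calibrator - self.ct_reference_calibrator
        )


def relative_expression(q: QpcrMeasurement) -> float:
    """Fold change by the 2^-ddCt method: 1.0 means no change vs calibrator."""
    return 2.0 ** (-q.ddct)


@dataclass(frozen=True)
class SpheroidDiameters:
    """Largest diameter a and largest perpendicular diameter b, in mm."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")


def spheroid_volume(d: SpheroidDiameters) -> float:
    """Ellipsoid volume estimate V = a * b^2 * pi / 6, in mm^3.

    Equals the sphere volume pi*d^3/6 when a == b == d.
    """
    return d.a * d.b**2 * math.pi / 6.0


def relative_volume(v_day_x: float, v_day0: float) -> float:
    """Growth ratio: volume at day x over volume at day 0."""
    if v_day0 <= 0:
        raise ValueError("day-0 volume must be positive")
    return v_day_x / v_day0


def percent_inhibition(treated: float, control: float) -> float:
    """(1 - treated/control) * 100, relative to the chosen baseline.

    The baseline may be an untreated control or a reporter-only control;
    both are meaningful, so the caller picks which value to pass.
    """
    if control <= 0:
        raise ValueError("control value must be positive")
    return (1.0 - treated / control) * 100.0


def qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Batch 2^-ddCt over a Ct table.

    Expects columns ct_target, ct_reference, ct_target_calibrator,
    ct_reference_calibrator; returns a copy with ddct and fold_change.
    """
    out = table.copy()
    rows = [
        QpcrMeasurement(
            r.ct_target,
            r.ct_reference,
            r.ct_target_calibrator,
            r.ct_reference_calibrator,
        )
        for r in table.itertuples(index=False)
    ]
    out["ddct"] = [q.ddct for q in rows]
    out["fold_change"] = [relative_expression(q) for q in rows]
    return out


def spheroid_table(table: pd.DataFrame) -> pd.DataFrame:
    """Batch spheroid volumes over a diameters table (columns a, b in mm)."""
    out = table.copy()
    out["volume_mm3"] = [
        spheroid_volume(SpheroidDiameters(r.a, r.b))
        for r in table.itertuples(index=False)
    ]
    return out
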