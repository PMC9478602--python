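"""Cumulative dose-volume-histogram engine and plan-evaluation statistics.

Implements the standard target metrics — Dmin/Dmax/Dmean, Dx% (minimum dose
to the hottest x% of the structure), Vx (percent of the structure receiving
at least x cGy) — plus the homogeneity index

    HI = (D2% - D98%) / D50%

and a coverage-style conformity index: the percent of PTV voxels inside the
reference isodose (a configurable fraction of prescription).  Dmin/Dmax are
raw voxel extremes; Dx% is a linear order-statistic quantile of the voxel
dose samples, so D100% = Dmin and Dx% -> Dmax as x -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BolusQAError,
    ConfigurationError,
    EmptyStructureError,
    ValidationError,
)
from .grids import DoseGrid, StructureMask, require_same_grid
from .util import round_half_up

__all__ = [
    "DVHResult",
    "OARConstraintSet",
    "DEFAULT_OAR_CONSTRAINTS",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "conformity_index",
    "oar_report",
]


@dataclass
class DVHResult:
    """Voxel dose samples of one structure plus cumulative-curve accessors."""

    structure_name: str
    dose_samples: np.ndarray  # cGy, one entry per mask voxel
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        self.dose_samples = np.asarray(self.dose_samples, dtype=float).ravel()
        if self.dose_samples.size == 0:
            raise EmptyStructureError(f"{self.structure_name}: no voxels in mask")

    @property
    def d_min(self) -> float:
        return float(self.dose_samples.min())

    @property
    def d_max(self) -> float:
        return float(self.dose_samples.max())

    @property
    def d_mean(self) -> float:
        return float(self.dose_samples.mean())

    @property
    def volume_mm3(self) -> float:
        return self.dose_samples.size * self.voxel_volume_mm3

    def cumulative(self, thresholds) -> np.ndarray:
        """Fractional volume receiving >= each threshold (non-increasing)."""
        t = np.atleast_1d(np.asarray(thresholds, dtype=float))
        return (self.dose_samples[None, :] >= t[:, None]).mean(axis=1)

    def curve(self, n_points: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """(dose, fractional volume) pairs of the cumulative DVH for plotting."""
        doses = np.linspace(0.0, self.d_max * 1.02, n_points)
        return doses, self.cumulative(doses)


def compute_dvh(dose: DoseGrid, mask: StructureMask) -> DVHResult:
    """Extract the dose samples of a structure.

    The dose grid and mask must share shape, spacing and origin; the mask
    must be non-empty.
    """
    require_same_grid(dose, mask, "dose grid and structure mask")
    if mask.is_empty():
        raise EmptyStructureError(f"{mask.name or 'structure'}: mask is empty")
    return DVHResult(
        structure_name=mask.name or "structure",
        dose_samples=dose.values[mask.mask],
        voxel_volume_mm3=dose.voxel_volume_mm3,
    )


def dose_at_volume(dvh: DVHResult, q: float) -> float:
    """Dx%: the dose covering q percent of the structure volume, in cGy.

    Linear interpolation on the order statistics of the voxel doses;
    D100% is the minimum dose, and Dx% tends to the maximum as x -> 0.
    """
    if not 0 < q <= 100:
        raise ValidationError(f"q: must be in (0, 100], got {q}")
    return float(np.percentile(dvh.dose_samples, 100.0 - q, method="linear"))


def volume_at_dose(dvh: DVHResult, x: float) -> float:
    """Vx: percent of the structure receiving at least x cGy."""
    if x < 0:
        raise ValidationError(f"x: dose threshold must be >= 0, got {x}")
    return float(100.0 * np.mean(dvh.dose_samples >= x))


def homogeneity_index(dvh: DVHResult, rounded: bool = True) -> float:
    """HI = (D2% - D98%) / D50%; 0 for a perfectly uniform dose.

    Reported rounded half-up to 2 decimals (pass ``rounded=False`` for the
    raw value).
    """
    d50 = dose_at_volume(dvh, 50.0)
    if d50 <= 0:
        raise BolusQAError(f"{dvh.structure_name}: degenerate dose, D50% = {d50}")
    hi = (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / d50
    return round_half_up(hi, 2) if rounded else hi


def conformity_index(
    dose: DoseGrid,
    ptv: StructureMask,
    prescription: float | None = None,
    iso_fraction: float = 0.95,
) -> float:
    """Percent of PTV voxels covered by the reference isodose.

    The reference isodose is ``iso_fraction * prescription`` (cGy, on the
    same per-fraction or total scale as the dose grid).
    """
    if prescription is None or prescription <= 0:
        raise ConfigurationError("conformity_index: prescription dose is undefined")
    require_same_grid(dose, ptv, "dose grid and PTV mask")
    if ptv.is_empty():
        raise EmptyStructureError("PTV: mask is empty")
    samples = dose.values[ptv.mask]
    return float(100.0 * np.mean(samples >= iso_fraction * prescription))


@dataclass
class OARConstraintSet:
    """Requested metrics per structure.

    ``requests`` maps structure name to metric strings: ``"Dmean"``,
    ``"Dmax"``, ``"Dmin"``, ``"D<q>%"`` (dose to the hottest q percent) or
    ``"V<x>"`` with x the dose threshold in cGy.
    """

    requests: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for structure, metrics in self.requests.items():
            for m in metrics:
                _parse_metric(m)  # raises on malformed/negative requests


def _parse_metric(metric: str):
    m = metric.strip()
    if m in ("Dmean", "Dmax", "Dmin"):
        return (m, None)
    if m.startswith("D") and m.endswith("%"):
        q = float(m[1:-1])
        if not 0 < q <= 100:
            raise ValidationError(f"metric {metric!r}: q must be in (0, 100]")
        return ("Dq", q)
    if m.startswith("V"):
        x = float(m[1:])
        if x < 0:
            raise ValidationError(f"metric {metric!r}: threshold must be >= 0")
        return ("Vx", x)
    raise ValidationError(f"metric {metric!r}: unrecognized request")


# The clinically reported organ-at-risk set: ipsilateral lung mean dose and
# V5/V20/V30 Gy, heart mean dose and V30/V40 Gy, spinal-cord PRV max dose.
DEFAULT_OAR_CONSTRAINTS = OARConstraintSet(
    {
        "ipsilateral_lung": ["Dmean", "V500", "V2000", "V3000"],
        "heart": ["Dmean", "V3000", "V4000"],
        "spinal_cord_PRV": ["Dmax"],
    }
)


def oar_report(
    dose: DoseGrid,
    masks: dict[str, StructureMask],
    constraints: OARConstraintSet | None = None,
) -> list[dict]:
    """One row per (structure, metric): doses in integer cGy, volumes in %.

    Rounding follows report precision: doses half-up to whole cGy, volume
    percents half-up to 2 decimals.
    """
    constraints = constraints or DEFAULT_OAR_CONSTRAINTS
    rows: list[dict] = []
    for structure, metrics in constraints.requests.items():
        if structure not in masks:
            raise KeyError(f"structure {structure!r} not among masks {sorted(masks)}")
        dvh = compute_dvh(dose, masks[structure])
        for metric in metrics:
            kind, arg = _parse_metric(metric)
            if kind == "Dmean":
                value, units = round_half_up(dvh.d_mean, 0), "cGy"
            elif kind == "Dmax":
                value, units = round_half_up(dvh.d_max, 0), "cGy"
            elif kind == "Dmin":
                value, units = round_half_up(dvh.d_min, 0), "cGy"
            elif kind == "Dq":
                value, units = round_half_up(dose_at_volume(dvh, arg), 0), "cGy"
            else:  # Vx
                value, units = round_half_up(volume_at_dose(dvh, arg), 2), "%"
            rows.append(
                {"structure": structure, "metric": metric, "value": value, "units": units}
            )
    return rows
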