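"""In-vivo skin-dose verification with radiochromic film.

Protocol implemented here: the PTV outline in the beam's-eye view (BEV) is
split into a 4-row x 2-column grid of sub-regions, one 3 x 2 cm^2 film piece
is taped at the center of each (a 2 x 1.5 cm^2 piece where the surface is
too uneven); scanned film responses are converted to dose through a
calibration curve rescaled per scan with two reference films (one
unexposed, one exposed to a known dose); the planned counterpart is the
mean dose of a thin ROI between bolus and skin averaged over the three CT
slices nearest the film center; agreement is the absolute percent
difference

    |%diff| = |100 * (D_fact - D_theory) / D_theory|

with per-patient doses taken as the mean over the eight sub-regions.

The calibration curve maps net optical density, netOD =
log10(response_unexposed / response), to dose via the standard
radiochromic-film parameterization D = a*netOD + b*netOD^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import BolusQAError, MeasurementError, ValidationError
from .grids import DoseGrid
from .util import round_half_up

__all__ = [
    "Subregion",
    "SubregionLayout",
    "FilmCalibration",
    "SkinDoseRecord",
    "layout_subregions",
    "calibrate_film",
    "film_dose",
    "tps_surface_dose",
    "percent_diff",
    "summarize_cohort",
]

FILM_W_MM, FILM_H_MM = 30.0, 20.0  # standard film piece, 3 x 2 cm^2
FILM_W_RED_MM, FILM_H_RED_MM = 20.0, 15.0  # reduced piece for uneven regions


@dataclass(frozen=True)
class Subregion:
    """One numbered film rectangle in BEV mm coordinates."""

    id: int  # 1..8, row-major
    center: tuple[float, float]
    width: float
    height: float
    reduced: bool = False


@dataclass
class SubregionLayout:
    """The eight film sub-regions tiling the PTV's BEV bounding box.

    The bbox is split into 4 rows (cranial-caudal) by 2 columns
    (left-right); one rectangle is centered in each cell, numbered 1..8
    row-major starting at the cranial-left cell.
    """

    ptv_bbox: tuple[float, float, float, float]  # x0, y0, width, height
    rectangles: list[Subregion] = field(default_factory=list)

    @property
    def cell_size(self) -> tuple[float, float]:
        _, _, w, h = self.ptv_bbox
        return w / 2.0, h / 4.0


def layout_subregions(ptv_bev_bbox: tuple[float, float, float, float]) -> SubregionLayout:
    """Place the 8 film rectangles on the PTV's BEV bounding box.

    ``ptv_bev_bbox`` is (x0, y0, width, height) in BEV mm, x toward patient
    left, y toward cranial.  Cells too small for the standard 3 x 2 cm^2
    piece get the reduced 2 x 1.5 cm^2 piece with ``reduced`` set.
    """
    x0, y0, w, h = ptv_bev_bbox
    if w <= 0 or h <= 0:
        raise ValidationError("ptv_bev_bbox: width and height must be > 0")
    cw, ch = w / 2.0, h / 4.0
    rects: list[Subregion] = []
    num = 1
    for row in range(4):  # cranial to caudal
        cy = y0 + h - (row + 0.5) * ch
        for col in range(2):  # left to right
            cx = x0 + (col + 0.5) * cw
            reduced = cw < FILM_W_MM or ch < FILM_H_MM
            rects.append(
                Subregion(
                    id=num,
                    center=(cx, cy),
                    width=FILM_W_RED_MM if reduced else FILM_W_MM,
                    height=FILM_H_RED_MM if reduced else FILM_H_MM,
                    reduced=reduced,
                )
            )
            num += 1
    return SubregionLayout(ptv_bbox=tuple(ptv_bev_bbox), rectangles=rects)


@dataclass(frozen=True)
class FilmCalibration:
    """Dose-response curve D(netOD) = rescale * (a*netOD + b*netOD^n).

    ``unexposed_response`` is the scanner reading of the unexposed reference
    of the scan this calibration applies to; netOD of a film reading r is
    log10(unexposed_response / r).
    """

    a: float = 600.0  # cGy per unit netOD, linear term
    b: float = 2200.0  # cGy, power term
    n: float = 2.5
    rescale: float = 1.0
    unexposed_response: float = 1.0

    def validate(self) -> None:
        if self.a <= 0 or self.b < 0 or self.n <= 1:
            raise ValidationError("calibration: require a > 0, b >= 0, n > 1")
        if self.rescale <= 0:
            raise ValidationError("rescale: must be > 0")
        if not 0 < self.unexposed_response <= 1:
            raise ValidationError("unexposed_response: must be in (0, 1]")

    def dose_from_netod(self, netod: float) -> float:
        if netod < 0:
            raise BolusQAError(f"negative netOD ({netod:.4f}): response exceeds unexposed reference")
        return self.rescale * (self.a * netod + self.b * netod**self.n)

    def netod_from_dose(self, dose: float) -> float:
        """Numerically invert the (monotone) curve."""
        if dose < 0:
            raise ValidationError("dose: must be >= 0")
        if dose == 0:
            return 0.0
        hi = 1.0
        while self.dose_from_netod(hi) < dose:
            hi *= 2.0
        return float(brentq(lambda x: self.dose_from_netod(x) - dose, 0.0, hi, xtol=1e-12))

    def response_from_dose(self, dose: float) -> float:
        """Forward model: scanner response a film exposed to ``dose`` would give."""
        return self.unexposed_response * 10.0 ** (-self.netod_from_dose(dose))


def calibrate_film(
    base: FilmCalibration,
    scan_unexposed: float,
    scan_exposed: float,
    known_dose: float,
) -> FilmCalibration:
    """Rescale the base curve to a specific scan using two reference films.

    The returned calibration maps the unexposed reference to 0 cGy (by the
    netOD definition) and the exposed reference's netOD exactly to
    ``known_dose``, absorbing scanner/session response drift into a single
    multiplicative dose factor.
    """
    base.validate()
    if known_dose <= 0:
        raise ValidationError("known_dose: must be > 0")
    for name, r in (("scan_unexposed", scan_unexposed), ("scan_exposed", scan_exposed)):
        if not 0 < r <= 1:
            raise ValidationError(f"{name}: response must be in (0, 1]")
    if scan_exposed >= scan_unexposed:
        raise MeasurementError(
            "exposed reference did not darken relative to the unexposed reference"
        )
    netod_ref = math.log10(scan_unexposed / scan_exposed)
    unscaled = base.a * netod_ref + base.b * netod_ref**base.n
    return replace(
        base,
        rescale=known_dose / unscaled,
        unexposed_response=float(scan_unexposed),
    )


def film_dose(roi_mean_response: float, cal: FilmCalibration) -> float:
    """Dose (cGy) of a film piece from its mean ROI response.

    The measurement ROI is the central 1 x 1 cm^2 of the piece; the reading
    passed in is its mean response in (0, 1].
    """
    if not 0 < roi_mean_response <= 1:
        raise ValidationError("roi_mean_response: must be in (0, 1]")
    if roi_mean_response > cal.unexposed_response:
        raise BolusQAError(
            "negative netOD: ROI response exceeds the unexposed reference"
        )
    netod = math.log10(cal.unexposed_response / roi_mean_response)
    return cal.dose_from_netod(netod)


def tps_surface_dose(
    dose: DoseGrid,
    roi_center: tuple[float, float, float],
    skin_normal: tuple[float, float, float],
    roi_length_mm: float = 10.0,
    roi_depth_mm: float = 1.0,
    n_slices: int = 3,
) -> float:
    """Planned skin-surface dose at a film position.

    Averages the dose over a thin ROI (default 10 x 1 mm) tangent to the
    skin at ``roi_center`` — long axis in the axial plane perpendicular to
    the outward ``skin_normal``, short axis along the normal — replicated on
    the ``n_slices`` axial slices nearest the center.  Nearest-voxel
    sampling; any sample outside the grid raises an error.
    """
    center = np.asarray(roi_center, dtype=float)
    normal = np.asarray(skin_normal, dtype=float)
    nrm = np.linalg.norm(normal)
    if nrm == 0:
        raise ValidationError("skin_normal: must be a nonzero vector")
    normal = normal / nrm
    ez = np.array([0.0, 0.0, 1.0])
    tangent = np.cross(normal, ez)
    tn = np.linalg.norm(tangent)
    if tn < 1e-9:  # normal along z: take any in-plane tangent
        tangent = np.array([1.0, 0.0, 0.0])
    else:
        tangent = tangent / tn

    # axial slice indices nearest the center
    kc = (center[2] - dose.origin[2]) / dose.spacing[2]
    k0 = int(np.clip(round(kc), 0, dose.shape[2] - 1))
    half = (n_slices - 1) // 2
    ks = np.arange(k0 - half, k0 - half + n_slices)
    if ks.min() < 0 or ks.max() >= dose.shape[2]:
        raise BolusQAError("ROI extends outside the dose grid (axial)")

    n_l = max(3, int(np.ceil(roi_length_mm / min(dose.spacing[:2]))) * 2 + 1)
    n_d = max(3, int(np.ceil(roi_depth_mm / min(dose.spacing[:2]))) * 2 + 1)
    ls = np.linspace(-roi_length_mm / 2.0, roi_length_mm / 2.0, n_l)
    ds = np.linspace(-roi_depth_mm / 2.0, roi_depth_mm / 2.0, n_d)

    samples = []
    for k in ks:
        for l in ls:
            for d in ds:
                p = center + l * tangent + d * normal
                i = round((p[0] - dose.origin[0]) / dose.spacing[0])
                j = round((p[1] - dose.origin[1]) / dose.spacing[1])
                if not (0 <= i < dose.shape[0] and 0 <= j < dose.shape[1]):
                    raise BolusQAError("ROI extends outside the dose grid (in-plane)")
                samples.append(dose.values[int(i), int(j), int(k)])
    return float(np.mean(samples))


def percent_diff(d_fact: float, d_theory: float, rounded: bool = True) -> float:
    """|%diff| = |100 (D_fact - D_theory) / D_theory|, half-up to 2 decimals."""
    if d_theory <= 0:
        raise ValidationError("d_theory: must be > 0")
    value = abs(100.0 * (d_fact - d_theory) / d_theory)
    return round_half_up(value, 2) if rounded else value


@dataclass
class SkinDoseRecord:
    """One patient's film (measured) and TPS (planned) skin doses.

    Per-subregion doses are keyed by sub-region id; the patient-level
    ``d_fact``/``d_theory`` are the means over the sub-regions present in
    both maps, and ``pct_diff`` is their absolute percent difference.
    """

    patient_id: str
    film_doses: dict[int, float]
    tps_doses: dict[int, float]

    def __post_init__(self) -> None:
        common = set(self.film_doses) & set(self.tps_doses)
        if not common:
            raise ValidationError(
                f"{self.patient_id}: no sub-region present in both film and TPS doses"
            )
        self._common = sorted(common)

    @property
    def d_fact(self) -> float:
        return float(np.mean([self.film_doses[k] for k in self._common]))

    @property
    def d_theory(self) -> float:
        return float(np.mean([self.tps_doses[k] for k in self._common]))

    @property
    def pct_diff(self) -> float:
        return percent_diff(self.d_fact, self.d_theory)


def summarize_cohort(records) -> dict[str, dict[str, float]]:
    """Median / min / max of D_fact, D_theory and |%diff| over the cohort.

    The median is the middle order statistic (mean of the two middle values
    for even cohorts); min/max are exact.
    """
    records = list(records)
    if not records:
        raise ValidationError("records: empty cohort")
    cols = {
        "d_fact": np.array([r.d_fact for r in records]),
        "d_theory": np.array([r.d_theory for r in records]),
        "pct_diff": np.array([r.pct_diff for r in records]),
    }
    return {
        name: {
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
        for name, v in cols.items()
    }
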