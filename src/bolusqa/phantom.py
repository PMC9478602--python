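"""Synthetic chest phantom, analytic beam model and toxicity-cohort simulator.

Everything downstream (bolus design, DVH statistics, in-vivo film
verification, toxicity tabulation) is testable against the objects produced
here, without any imaging downloads.

The phantom is an elliptic cylinder of soft tissue containing an ipsilateral
lung, a heart and a spinal-cord planning volume; the chest-wall clinical
target volume (CTV) is the anterior-lateral wall shell and the planning
target volume (PTV) is its isotropic expansion.  The beam model is a
one-dimensional megavoltage depth-dose curve

    D(z) = (1 - exp(-z / z_b)) * exp(-mu * max(0, z - z_b))

evaluated at the water-equivalent depth z of each voxel along the beam
direction, with z_b the depth of dose maximum (~15 mm for a 6 MV beam) and
mu an effective linear attenuation coefficient.  Bolus voxels count as
tissue, which is exactly the mechanism by which a 5 mm bolus lifts the skin
surface out of the build-up (skin-sparing) region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, ValidationError
from .grids import DoseGrid, ImageVolume, StructureMask
from .toxicity import FRACTION_BINS_DURING, ToxicityRecord

__all__ = [
    "PhantomSpec",
    "BeamSpec",
    "make_chest_phantom",
    "make_dose_grid",
    "make_toxicity_cohort",
    "TABLE_GRADE_PROBS",
    "TABLE_COMBO_PROBS",
    "TABLE_BIN_PROBS",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic chest phantom.

    All lengths are mm.  ``chest_half_axes`` are the (left-right,
    anterior-posterior) half axes of the elliptic cross-section;
    ``wall_thickness`` is the depth of the chest-wall shell that houses the
    CTV; ``ptv_margin`` is the isotropic CTV->PTV expansion (5 mm default,
    the standard setup margin).
    """

    chest_half_axes: tuple[float, float] = (120.0, 80.0)
    axial_length: float = 150.0
    wall_thickness: float = 15.0
    ptv_margin: float = 5.0
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    hu_tissue: float = 40.0
    hu_lung: float = -750.0
    hu_air: float = -1000.0
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel_spacing: all components must be > 0")
        if any(a <= 0 for a in self.chest_half_axes):
            raise ValidationError("chest_half_axes: must be > 0")
        if self.axial_length <= 0:
            raise ValidationError("axial_length: must be > 0")
        if not 0 < self.wall_thickness < min(self.chest_half_axes):
            raise ValidationError(
                "wall_thickness: must be positive and < min(chest_half_axes)"
            )
        if self.ptv_margin < 0:
            raise ValidationError("ptv_margin: must be >= 0")


@dataclass(frozen=True)
class BeamSpec:
    """Prescription and depth-dose parameters of the treatment beam.

    ``buildup_depth`` (z_b) is the depth of dose maximum in mm;
    ``attenuation_coeff`` (mu) the exponential falloff beyond z_b, per mm.
    ``field_margin`` and ``penumbra_sigma`` shape the transverse field:
    full dose inside the PTV projection dilated by ``field_margin``, then a
    Gaussian penumbra of width ``penumbra_sigma``.
    """

    energy_label: str = "6 MV"
    prescription_dose: float = 5000.0  # cGy
    n_fractions: int = 25
    buildup_depth: float = 15.0  # mm
    attenuation_coeff: float = 0.004  # per mm
    gantry_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    field_margin: float = 10.0  # mm
    penumbra_sigma: float = 5.0  # mm

    def validate(self) -> None:
        if self.prescription_dose <= 0:
            raise ValidationError("prescription_dose: must be > 0")
        if self.n_fractions < 1:
            raise ValidationError("n_fractions: must be >= 1")
        if self.buildup_depth <= 0:
            raise ValidationError("buildup_depth: must be > 0")
        if self.attenuation_coeff < 0:
            raise ValidationError("attenuation_coeff: must be >= 0")
        d = np.asarray(self.gantry_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValidationError("gantry_direction: must be a unit vector")

    @property
    def fraction_dose(self) -> float:
        """Per-fraction prescription in cGy."""
        return self.prescription_dose / self.n_fractions


def make_chest_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[ImageVolume, dict[str, StructureMask]]:
    """Build the CT-like phantom volume and its structure masks.

    Returns the volume (HU) and masks ``{body, chest_wall_CTV, PTV,
    ipsilateral_lung, heart, spinal_cord_PRV}``.  Guarantees
    CTV ⊆ PTV ⊆ body.
    """
    spec = spec or PhantomSpec()
    spec.validate()

    a, b = spec.chest_half_axes
    half_len = spec.axial_length / 2.0
    pad = 6.0 * max(spec.voxel_spacing)  # air margin so the bolus fits
    half_extent = np.array([a + pad, b + pad, half_len + pad])
    spacing = np.asarray(spec.voxel_spacing)
    shape = np.maximum(1, np.ceil(2 * half_extent / spacing).astype(int) + 1)
    origin = -(shape - 1) / 2.0 * spacing  # grid centered on (0, 0, 0)

    vol = ImageVolume(
        np.full(tuple(shape), spec.hu_air, dtype=float),
        tuple(spacing),
        tuple(origin),
    )
    x, y, z = vol.coordinate_grids()

    body = ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (np.abs(z) <= half_len)
    body = np.broadcast_to(body, tuple(shape)).copy()

    # depth from the body surface (mm); defines the chest-wall shell
    depth = ndimage.distance_transform_edt(body, sampling=spacing)

    # CTV: anterior (y < 0) left-sided (x > 0) wall shell, central axial band
    ctv = (
        body
        & (depth <= spec.wall_thickness)
        & (y < -0.1 * b)
        & (x > 0.1 * a)
        & (np.abs(z) <= 0.35 * spec.axial_length)
    )

    if spec.ptv_margin > 0:
        dist_to_ctv = ndimage.distance_transform_edt(~ctv, sampling=spacing)
        ptv = (dist_to_ctv <= spec.ptv_margin) & body
    else:
        ptv = ctv.copy()
    ptv |= ctv  # containment by construction

    # OARs, clipped to the body interior
    lung = (
        ((x - 0.45 * a) / (0.38 * a)) ** 2
        + ((y - 0.05 * b) / (0.55 * b)) ** 2
        + (z / (0.40 * spec.axial_length)) ** 2
    ) <= 1.0
    lung = np.broadcast_to(lung, tuple(shape)) & body & (depth > spec.wall_thickness)

    heart = (
        ((x - 0.15 * a) / (0.25 * a)) ** 2
        + ((y - 0.25 * b) / (0.30 * b)) ** 2
        + ((z + 0.15 * spec.axial_length) / (0.25 * spec.axial_length)) ** 2
    ) <= 1.0
    heart = np.broadcast_to(heart, tuple(shape)) & body & ~lung

    cord = (x**2 + (y - (b - 18.0)) ** 2) <= 8.0**2
    cord = np.broadcast_to(cord, tuple(shape)) & body

    vol.values[body] = spec.hu_tissue
    vol.values[lung] = spec.hu_lung

    masks = {
        "body": StructureMask(body, vol.spacing, vol.origin, "body"),
        "chest_wall_CTV": StructureMask(ctv, vol.spacing, vol.origin, "chest_wall_CTV"),
        "PTV": StructureMask(ptv, vol.spacing, vol.origin, "PTV"),
        "ipsilateral_lung": StructureMask(lung, vol.spacing, vol.origin, "ipsilateral_lung"),
        "heart": StructureMask(heart, vol.spacing, vol.origin, "heart"),
        "spinal_cord_PRV": StructureMask(cord, vol.spacing, vol.origin, "spinal_cord_PRV"),
    }
    return vol, masks


def _beam_axis(direction: tuple[float, float, float]) -> tuple[int, int]:
    """Map the gantry unit vector to (array axis, +1/-1 orientation)."""
    d = np.asarray(direction, dtype=float)
    axis = int(np.argmax(np.abs(d)))
    rest = np.delete(np.abs(d), axis)
    if not (np.isclose(np.abs(d[axis]), 1.0, atol=1e-6) and np.allclose(rest, 0, atol=1e-6)):
        raise ValidationError(
            "gantry_direction: only axis-aligned beams are supported "
            f"(got {tuple(d)})"
        )
    return axis, 1 if d[axis] > 0 else -1


def make_dose_grid(
    phantom: ImageVolume,
    masks: dict[str, StructureMask],
    beam: BeamSpec | None = None,
    bolus_mask: StructureMask | None = None,
    normalization: str = "mid_ctv",
    per_fraction: bool = True,
) -> DoseGrid:
    """Analytic dose grid with the megavoltage build-up effect.

    Water-equivalent depth is accumulated along the (axis-aligned) beam
    direction through body and bolus voxels alike, then the depth-dose curve
    is applied and weighted by the transverse field profile.

    normalization
        ``"mid_ctv"``: the CTV voxel nearest the CTV centroid receives
        exactly the per-fraction prescription.  ``"d95"``: the dose covering
        95% of the PTV equals the per-fraction prescription — i.e. the plan
        is normalized so at least 95% of the target meets prescription.
    per_fraction
        If False the grid is scaled by ``n_fractions`` (total course dose).
    """
    beam = beam or BeamSpec()
    beam.validate()
    body = masks["body"]
    ctv = masks["chest_wall_CTV"]
    ptv = masks["PTV"]
    for m in (body, ctv, ptv):
        if not phantom.same_grid(m):
            raise AlignmentError("phantom and structure masks are not on the same grid")
    medium = body.mask.copy()
    if bolus_mask is not None:
        if not phantom.same_grid(bolus_mask):
            raise AlignmentError("bolus mask is not on the phantom grid")
        medium |= bolus_mask.mask

    axis, orient = _beam_axis(beam.gantry_direction)
    step = phantom.spacing[axis]
    med = medium if orient > 0 else np.flip(medium, axis=axis)
    depth = (np.cumsum(med, axis=axis) - 0.5 * med) * step
    if orient < 0:
        depth = np.flip(depth, axis=axis)
    depth = np.where(medium, depth, 0.0)

    zb, mu = beam.buildup_depth, beam.attenuation_coeff
    raw = (1.0 - np.exp(-depth / zb)) * np.exp(-mu * np.maximum(0.0, depth - zb))
    raw[~medium] = 0.0

    # transverse field: PTV beam's-eye projection + margin, Gaussian penumbra
    field2d = ptv.mask.any(axis=axis)
    plane_spacing = tuple(np.delete(phantom.spacing, axis))
    dist_out = ndimage.distance_transform_edt(~field2d, sampling=plane_spacing)
    weight2d = np.where(
        dist_out <= beam.field_margin,
        1.0,
        np.exp(-((dist_out - beam.field_margin) ** 2) / (2.0 * beam.penumbra_sigma**2)),
    )
    raw *= np.expand_dims(weight2d, axis)

    if normalization == "mid_ctv":
        idx = np.argwhere(ctv.mask)
        if idx.size == 0:
            raise ValidationError("chest_wall_CTV: mask is empty")
        centroid = idx.mean(axis=0)
        mid = idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))]
        ref = raw[tuple(mid)]
    elif normalization == "d95":
        samples = raw[ptv.mask]
        if samples.size == 0:
            raise ValidationError("PTV: mask is empty")
        ref = float(np.percentile(samples, 5.0))
    else:
        raise ValidationError(f"normalization: unknown mode {normalization!r}")
    if ref <= 0:
        raise ValidationError("normalization reference dose is zero")

    values = raw * (beam.fraction_dose / ref)
    if not per_fraction:
        values = values * beam.n_fractions  # exact multiple of the per-fraction grid
    return DoseGrid(values, phantom.spacing, phantom.origin)


# ---------------------------------------------------------------------------
# Toxicity cohort simulator
# ---------------------------------------------------------------------------

# Empirical study conditions: acute-dermatitis grade mix, the presentation
# combinations seen within each grade, their onset fraction bins, and the
# interruption probability among grade-3 patients (4 of 7).
TABLE_GRADE_PROBS: tuple[float, ...] = (321 / 360, 32 / 360, 7 / 360, 0.0)

TABLE_COMBO_PROBS: dict[int, list[tuple[frozenset[str], float]]] = {
    1: [
        (frozenset({"FE"}), 229 / 321),
        (frozenset({"DD"}), 54 / 321),
        (frozenset({"FE", "DD"}), 38 / 321),
    ],
    2: [
        (frozenset({"PMD", "MER"}), 18 / 32),
        (frozenset({"MER", "MED"}), 9 / 32),
        (frozenset({"PMD", "MER", "MED"}), 5 / 32),
    ],
    3: [
        (frozenset({"PE"}), 2 / 7),
        (frozenset({"PE", "CMD"}), 5 / 7),
    ],
    4: [(frozenset({"NEC"}), 1.0)],
}

TABLE_BIN_PROBS: dict[int, tuple[float, ...]] = {
    1: (39 / 321, 59 / 321, 94 / 321, 129 / 321),
    2: (0.0, 0.0, 6 / 32, 26 / 32),
    3: (0.0, 0.0, 1 / 7, 6 / 7),
    4: (0.0, 0.0, 0.0, 1.0),
}

_INTERRUPT_PROB = {3: 4 / 7}


def _check_probs(name: str, probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name}: probabilities must be >= 0 and sum to 1")
    return p


def make_toxicity_cohort(
    n: int,
    grade_probs=None,
    bin_probs=None,
    seed: int = 0,
) -> list[ToxicityRecord]:
    """Simulate a during-radiotherapy acute skin-toxicity cohort.

    Draws a worst grade per patient from ``grade_probs`` (grades 1-4),
    then a presentation combination and an onset fraction bin conditional on
    the grade.  Defaults reproduce the observed cohort mix.  Deterministic
    for a fixed seed.
    """
    if n < 0:
        raise ValidationError("n: must be >= 0")
    gp = _check_probs("grade_probs", grade_probs if grade_probs is not None else TABLE_GRADE_PROBS)
    bp = dict(TABLE_BIN_PROBS)
    if bin_probs is not None:
        for g, probs in dict(bin_probs).items():
            bp[g] = tuple(probs)
    for g, probs in bp.items():
        _check_probs(f"bin_probs[{g}]", probs)

    rng = np.random.default_rng(seed)
    records: list[ToxicityRecord] = []
    grades = rng.choice(np.arange(1, len(gp) + 1), size=n, p=gp)
    for i, g in enumerate(grades):
        g = int(g)
        combos, weights = zip(*TABLE_COMBO_PROBS[g])
        combo = combos[rng.choice(len(combos), p=np.asarray(weights))]
        fbin = FRACTION_BINS_DURING[rng.choice(4, p=np.asarray(bp[g]))]
        interrupted = bool(rng.random() < _INTERRUPT_PROB.get(g, 0.0))
        records.append(
            ToxicityRecord(
                patient_id=f"S{i + 1:05d}",
                fraction_bin=fbin,
                presentations=frozenset(combo),
                interrupted=interrupted,
            )
        )
    return records
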