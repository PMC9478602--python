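"""Bolus-design geometry and bolus-skin fit analysis.

The design pipeline mirrors how a patient-specific bolus is modelled from a
CT scan: segment the body, offset its surface outward by the desired
thickness, subtract the body from the offset to leave a conformal shell over
the marked treatment area, and export the shell as an STL for printing.

The offset is computed on the voxel Euclidean distance field rather than by
inflating the surface mesh: distance-field offsets are immune to the
self-intersections mesh offsetting produces on concave chest walls.

Fit quality is quantified by the air gap: the distance from sampled skin
points, along the outward surface normal, to the bolus inner surface.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import (
    CoverageError,
    EmptyBodyError,
    EmptyBolusError,
    STLFormatError,
    ValidationError,
)
from .grids import ImageVolume, StructureMask, require_same_grid

__all__ = [
    "AreaMark",
    "BolusSpec",
    "SurfaceMesh",
    "GapReport",
    "extract_body_surface",
    "design_bolus",
    "export_stl",
    "import_stl",
    "air_gap_profile",
    "sample_skin_points",
]


@dataclass(frozen=True)
class AreaMark:
    """The treatment area marked on the skin, in phantom coordinates.

    ``theta`` is the angle around the cranio-caudal (z) axis measured from
    +x (patient left) toward +y (posterior), degrees in [0, 360]; the range
    may wrap through 0.  The axial range is world z in mm.
    """

    theta_start_deg: float = 200.0
    theta_end_deg: float = 340.0
    z_min_mm: float = -50.0
    z_max_mm: float = 50.0

    def validate(self) -> None:
        for name, v in (("theta_start_deg", self.theta_start_deg), ("theta_end_deg", self.theta_end_deg)):
            if not 0.0 <= v <= 360.0:
                raise ValidationError(f"{name}: must lie in [0, 360], got {v}")
        if self.z_min_mm >= self.z_max_mm:
            raise ValidationError("z range: z_min_mm must be < z_max_mm")

    def contains(self, theta_deg: np.ndarray, z_mm: np.ndarray) -> np.ndarray:
        t = np.mod(theta_deg, 360.0)
        if self.theta_start_deg <= self.theta_end_deg:
            in_theta = (t >= self.theta_start_deg) & (t <= self.theta_end_deg)
        else:  # wrapped range
            in_theta = (t >= self.theta_start_deg) | (t <= self.theta_end_deg)
        return in_theta & (z_mm >= self.z_min_mm) & (z_mm <= self.z_max_mm)


@dataclass(frozen=True)
class BolusSpec:
    """Bolus thickness (mm), marked area, and relative (electron) density."""

    thickness: float = 5.0
    area_mark: AreaMark | None = None  # None = full body coverage
    relative_density: float = 1.0

    def validate(self) -> None:
        if self.thickness <= 0:
            raise ValidationError("thickness: must be > 0")
        if self.relative_density <= 0:
            raise ValidationError("relative_density: must be > 0")
        if self.area_mark is not None:
            self.area_mark.validate()


@dataclass
class SurfaceMesh:
    """A triangulated surface in patient mm coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("faces: vertex index out of range")

    @classmethod
    def from_mask(cls, mask: StructureMask, level: float = 0.5) -> "SurfaceMesh":
        """Iso-surface of a binary mask at the given level, vertices in world mm.

        The mask is zero-padded by one voxel so surfaces touching the grid
        boundary still close.
        """
        padded = np.pad(mask.mask.astype(np.float32), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=level, spacing=mask.spacing)
        verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), closed=bool(tm.is_watertight))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        """V - E + F; 2 for a closed surface of genus 0."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + len(self.faces)


@dataclass
class GapReport:
    """Per-point bolus-skin air gaps (mm) and their summary.

    ``gaps`` are signed: positive means air between the skin and the bolus
    inner surface, negative means the discretized surfaces interpenetrate.
    ``mean_gap`` averages ``max(gap, 0)`` so interpenetration does not
    offset genuine gaps; ``n_missed`` counts sample rays with no bolus
    intersection (excluded from the statistics).
    """

    sample_points: np.ndarray
    gaps: np.ndarray
    n_missed: int = 0
    mean_gap: float = field(init=False)
    max_gap: float = field(init=False)

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, dtype=float).reshape(-1, 3)
        self.gaps = np.asarray(self.gaps, dtype=float).ravel()
        clipped = np.clip(self.gaps, 0.0, None)
        self.mean_gap = float(clipped.mean()) if clipped.size else 0.0
        self.max_gap = float(clipped.max()) if clipped.size else 0.0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("point_id,x_mm,y_mm,z_mm,gap_mm\n")
            for i, (p, g) in enumerate(zip(self.sample_points, self.gaps)):
                fh.write(f"{i},{p[0]:.3f},{p[1]:.3f},{p[2]:.3f},{g:.4f}\n")

    def summary(self) -> dict:
        return {
            "n_points": int(self.gaps.size),
            "n_missed": int(self.n_missed),
            "mean_gap_mm": self.mean_gap,
            "max_gap_mm": self.max_gap,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def extract_body_surface(
    ct: ImageVolume, threshold_hu: float = -300.0
) -> tuple[StructureMask, SurfaceMesh]:
    """Segment the body from a CT volume and triangulate its surface.

    Voxels above ``threshold_hu`` are closed with a 1-voxel ball (sealing
    skin holes), the largest 6-connected component is kept and internal
    cavities are filled; the surface is the 0.5 iso-level of that mask.
    """
    above = np.asarray(ct.values) > threshold_hu
    if not above.any():
        raise EmptyBodyError(f"no voxel above {threshold_hu} HU")
    closed = ndimage.binary_closing(above, structure=ndimage.generate_binary_structure(3, 1))
    closed |= above  # closing must not remove foreground
    labels, n = ndimage.label(closed, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        largest = np.argmax(ndimage.sum_labels(closed, labels, index=np.arange(1, n + 1))) + 1
        closed = labels == largest
    closed = ndimage.binary_fill_holes(closed)
    mask = StructureMask(closed, ct.spacing, ct.origin, "body")
    return mask, SurfaceMesh.from_mask(mask)


def design_bolus(
    body: StructureMask, spec: BolusSpec | None = None
) -> tuple[StructureMask, SurfaceMesh]:
    """Offset the body surface outward and subtract to form the bolus shell.

    The outward offset is the set of exterior voxels within ``thickness`` mm
    of the body (Euclidean distance transform); the shell is restricted to
    the marked area.  The returned mask is always disjoint from the body.
    """
    spec = spec or BolusSpec()
    spec.validate()
    if body.is_empty():
        raise EmptyBodyError("body mask is empty")

    dist_to_body = ndimage.distance_transform_edt(~body.mask, sampling=body.spacing)
    shell = (dist_to_body <= spec.thickness) & ~body.mask

    if spec.area_mark is not None:
        x, y, z = body.coordinate_grids()
        idx = np.argwhere(body.mask)
        cx, cy = body.index_to_world(idx)[:, :2].mean(axis=0)
        theta = np.degrees(np.arctan2(y - cy, x - cx))
        zz = np.broadcast_to(z, body.shape)
        shell &= spec.area_mark.contains(
            np.broadcast_to(theta, body.shape), zz
        )

    if not shell.any():
        raise EmptyBolusError("marked area does not intersect the body surface")
    bolus = body.like(shell, "bolus")
    return bolus, SurfaceMesh.from_mask(bolus)


# ---------------------------------------------------------------------------
# STL serialization (binary, little-endian: 80-byte header, uint32 facet
# count, then 50 bytes per facet)
# ---------------------------------------------------------------------------

def export_stl(mesh: SurfaceMesh, path) -> None:
    """Write a binary STL."""
    mesh.to_trimesh().export(str(path), file_type="stl")


_FACET_DTYPE = np.dtype(
    [("normal", "<f4", 3), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


def import_stl(path) -> SurfaceMesh:
    """Read a binary STL with strict structural validation.

    Truncated or size-inconsistent files raise :class:`STLFormatError`
    carrying the byte offset at which parsing failed.  Duplicate vertices
    are welded exactly (bitwise equality) so a round trip preserves the
    face count and the 32-bit vertex coordinates.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 84:
        raise STLFormatError("file too short for STL header", byte_offset=len(data))
    (n_facets,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * n_facets
    if len(data) < expected:
        raise STLFormatError(
            f"truncated STL: header declares {n_facets} facets ({expected} bytes)",
            byte_offset=len(data),
        )
    if len(data) > expected:
        raise STLFormatError(
            f"trailing bytes after {n_facets} declared facets", byte_offset=expected
        )
    facets = np.frombuffer(data, dtype=_FACET_DTYPE, count=n_facets, offset=84)
    tri_verts = facets["vertices"].reshape(-1, 3)
    uniq, inverse = np.unique(tri_verts, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    mesh = SurfaceMesh(uniq.astype(float), faces)
    tm = mesh.to_trimesh()
    mesh.closed = bool(tm.is_watertight)
    return mesh


# ---------------------------------------------------------------------------
# Air-gap fitness
# ---------------------------------------------------------------------------

def _outward_normals(skin: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Skin surface normals at the vertices nearest each point, oriented outward."""
    from scipy.spatial import cKDTree

    _, vid = cKDTree(skin.vertices).query(points)
    normals = np.array(skin.vertex_normals[vid], dtype=float)
    outward = points - skin.centroid
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


def _line_triangle_ts(
    v0: np.ndarray, e1: np.ndarray, e2: np.ndarray, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Signed line parameters t of all triangle intersections (Moller-Trumbore).

    ``v0``/``e1``/``e2`` are the triangle bases and edge vectors; the line is
    ``origin + t * direction`` with t unrestricted in sign.
    """
    eps = 1e-12
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("ij,ij->i", np.broadcast_to(direction, e1.shape), q)
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
    t = f * np.einsum("ij,ij->i", e2, q)
    return t[hit]


def air_gap_profile(
    skin: SurfaceMesh,
    bolus_inner: SurfaceMesh,
    points: np.ndarray,
    normals: np.ndarray | None = None,
) -> GapReport:
    """Signed bolus-skin gap at skin sample points.

    Casts a line through each point along the outward skin normal and takes
    the bolus-surface intersection closest to the point (signed: negative
    when the bolus surface lies behind the skin point, i.e. the discretized
    surfaces interpenetrate).  Points whose line misses the bolus entirely
    are excluded and counted in ``n_missed``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.size == 0:
        raise ValidationError("points: at least one sample point is required")
    if normals is None:
        normals = _outward_normals(skin.to_trimesh(), points)
    else:
        normals = np.asarray(normals, dtype=float).reshape(-1, 3)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)

    v0 = bolus_inner.vertices[bolus_inner.faces[:, 0]]
    e1 = bolus_inner.vertices[bolus_inner.faces[:, 1]] - v0
    e2 = bolus_inner.vertices[bolus_inner.faces[:, 2]] - v0

    kept_points, gaps = [], []
    n_missed = 0
    for p, nrm in zip(points, normals):
        ts = _line_triangle_ts(v0, e1, e2, p, nrm)
        if ts.size == 0:
            n_missed += 1
            continue
        gaps.append(float(ts[np.argmin(np.abs(ts))]))
        kept_points.append(p)
    if not kept_points:
        raise CoverageError("all sample rays missed the bolus surface")
    return GapReport(np.asarray(kept_points), np.asarray(gaps), n_missed=n_missed)


def sample_skin_points(
    skin: SurfaceMesh,
    n: int,
    area_mark: AreaMark | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Subsample skin-mesh vertices (optionally restricted to the marked area)."""
    verts = skin.vertices
    if area_mark is not None:
        cx, cy = verts[:, 0].mean(), verts[:, 1].mean()
        theta = np.degrees(np.arctan2(verts[:, 1] - cy, verts[:, 0] - cx))
        keep = area_mark.contains(theta, verts[:, 2])
        verts = verts[keep]
    if len(verts) == 0:
        raise CoverageError("no skin vertices inside the marked area")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(verts), size=min(n, len(verts)), replace=False)
    return verts[np.sort(idx)]
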