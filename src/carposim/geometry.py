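"""Parametric carpal articular geometry, mesh I/O and inertial properties.

The radio-carpal articulation is represented by three convex trochlear
facets on the distal radius (medial/radial, intermediate and ulnar facet)
articulating with three congruent concave facets on the proximal surfaces
of the radial (Cr), intermediate (Ci) and ulnar (Cu) carpal bones.  Each
facet is a circular-arc (part-cylinder) patch whose axis is the carpus
hinge axis (+y); the opposing concave patch is the exact outward offset of
the convex one by the total cartilage gap, so that at the reference
full-extension pose the minimum bone-surface separation equals the gap.

All quantities are strictly SI (meters, kilograms); mesh files are written
in meters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh

from .errors import MeshFormatError, ParameterError, TopologyError

__all__ = [
    "SEGMENT_IDS",
    "FACET_LABELS",
    "BodySegment",
    "MaterialParams",
    "CylindricalFacet",
    "ArticularSurfacePatch",
    "make_radiocarpal_geometry",
    "inertia_from_mesh",
    "read_mesh",
    "write_mesh",
]

SEGMENT_IDS = (
    "trunk",
    "humerus",
    "ulna",
    "radius",
    "Cr",
    "Ci",
    "Cu",
    "distal_row",  # fused C2 + C3 + C4
    "metacarpus",
    "phalanx_prox_mid",  # fused P1 + P2
    "phalanx_distal",
)

FACET_LABELS = (
    "radial_facet",
    "intermediate_facet",
    "ulnar_facet",
    "Cr_prox",
    "Ci_prox",
    "Cu_prox",
    "hoof_sole",
    "ground",
)


@dataclass
class BodySegment:
    """A rigid body segment: mass, inertia about the COM, and pose.

    ``inertia`` is expressed in the segment frame about the center of mass;
    ``com`` is the center of mass in the segment frame.
    """

    id: str
    mass: float
    inertia: np.ndarray
    com: np.ndarray
    pose: "object" = None  # rigid.Pose; imported lazily to avoid cycles

    def __post_init__(self):
        from .rigid import Pose

        if self.id not in SEGMENT_IDS:
            raise ParameterError(f"unknown segment id {self.id!r}")
        if not self.mass > 0:
            raise ParameterError(f"segment {self.id}: mass must be positive")
        self.inertia = np.asarray(self.inertia, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ParameterError(f"segment {self.id}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ParameterError(f"segment {self.id}: inertia must be positive-definite")
        if self.pose is None:
            self.pose = Pose.identity()
        if abs(np.linalg.norm(self.pose.q) - 1.0) > 1e-9:
            raise ParameterError(f"segment {self.id}: quaternion not unit-norm")


@dataclass
class MaterialParams:
    """Material constants of the model.

    bone_density : kg/m^3, default 1590 (literature value for equine bone).
    cartilage_modulus : Pa, aggregate compressive modulus used to calibrate
        the penalty-contact stiffness.
    ground_stiffness : N/m^e for the hoof-ground penalty contact.
    ground_damping : N·s/m maximal ground damping coefficient.
    """

    bone_density: float = 1590.0
    cartilage_modulus: float = 10e6
    ground_stiffness: float = 2.5e6
    ground_damping: float = 5e3

    def __post_init__(self):
        for name in ("bone_density", "cartilage_modulus", "ground_stiffness", "ground_damping"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CylindricalFacet:
    """Parametric description of a part-cylinder facet in its body frame.

    The facet surface is ``axis_point + radius*(sin(phi) x - cos(phi) z) + y ŷ``
    for ``phi`` in ``phi_range`` and ``y`` in ``y_range``; ``phi = 0`` is the
    distal-most (straight down) point, positive ``phi`` is dorsal (+x).
    ``convex`` facets bulge away from the axis (radius trochlea); concave
    facets (carpal bone cups) face the axis.
    """

    radius: float
    y_range: tuple
    phi_range: tuple
    convex: bool
    axis_point: tuple = (0.0, 0.0, 0.0)

    def points(self, phi: np.ndarray, y: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, float)
        y = np.asarray(y, float)
        x = self.radius * np.sin(phi) + self.axis_point[0]
        z = -self.radius * np.cos(phi) + self.axis_point[2]
        return np.column_stack([x, y + self.axis_point[1], z])


@dataclass
class ArticularSurfacePatch:
    """A triangle-mesh articular surface patch plus orientation metadata."""

    mesh: trimesh.Trimesh
    facet_label: str
    dorsal_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    cylinder: Optional[CylindricalFacet] = None
    landmark_mpr: Optional[np.ndarray] = None  # polyline along the medial parasagittal ridge

    def __post_init__(self):
        if self.facet_label not in FACET_LABELS:
            raise ParameterError(f"unknown facet label {self.facet_label!r}")
        self.dorsal_axis = np.asarray(self.dorsal_axis, float)
        n = np.linalg.norm(self.dorsal_axis)
        if n == 0:
            raise ParameterError("dorsal_axis must be non-zero")
        self.dorsal_axis = self.dorsal_axis / n
        areas = self.mesh.area_faces
        if np.any(areas <= 0):
            raise TopologyError("patch contains degenerate faces")

    @property
    def area(self) -> float:
        return float(self.mesh.area)


def _facet_patch(
    radius: float,
    y_lo: float,
    y_hi: float,
    phi_lo: float,
    phi_hi: float,
    n_phi: int,
    n_y: int,
    convex: bool,
    label: str,
) -> ArticularSurfacePatch:
    """Build one part-cylinder patch with normals facing the opposing surface."""
    phi = np.linspace(phi_lo, phi_hi, n_phi + 1)
    y = np.linspace(y_lo, y_hi, n_y + 1)
    P, Y = np.meshgrid(phi, y, indexing="ij")
    verts = np.column_stack(
        [
            radius * np.sin(P).ravel(),
            Y.ravel(),
            -radius * np.cos(P).ravel(),
        ]
    )
    faces = []
    for i in range(n_phi):
        for j in range(n_y):
            a = i * (n_y + 1) + j
            b = (i + 1) * (n_y + 1) + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    faces = np.asarray(faces, dtype=np.int64)
    # the natural winding above gives normals toward the axis (fits the
    # concave cup); the convex trochlea must face away from the axis
    if convex:
        faces = faces[:, ::-1]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    cyl = CylindricalFacet(
        radius=radius,
        y_range=(y_lo, y_hi),
        phi_range=(phi_lo, phi_hi),
        convex=convex,
    )
    return ArticularSurfacePatch(mesh=mesh, facet_label=label, cylinder=cyl)


def make_radiocarpal_geometry(
    facet_radii: Sequence[float] = (0.035, 0.035, 0.035),
    facet_widths: Sequence[float] = (0.030, 0.025, 0.015),
    cartilage_gap: float = 1.0e-3,
    resolution: int = 12,
    phi_span: float = np.deg2rad(120.0),
):
    """Build the three radius trochlear facets and their congruent carpal cups.

    Parameters
    ----------
    facet_radii : arc radius [m] of the (medial, intermediate, ulnar) facet.
    facet_widths : medio-lateral width [m] of each facet; the defaults put
        most of the candidate contact area on the medial facet, where the
        studied fracture initiated.
    cartilage_gap : total cartilage thickness [m] separating the bone
        surfaces at the reference (full-extension) pose.
    resolution : number of subdivisions per facet in each direction (>= 8).
    phi_span : angular extent of each facet arc [rad], centered on the
        distal-most point.

    Returns
    -------
    (radius_patches, carpal_patches) : each a list of 3 ArticularSurfacePatch
        ordered (medial, intermediate, ulnar) = (radial_facet/Cr, intermediate
        facet/Ci, ulnar facet/Cu).  Radius patches live in the radius body
        frame (trochlea axis = +y through the origin); each carpal patch
        lives in its carpal bone's body frame, which at the reference pose
        coincides with the radius frame.
    """
    facet_radii = tuple(float(r) for r in facet_radii)
    facet_widths = tuple(float(w) for w in facet_widths)
    if len(facet_radii) != 3 or len(facet_widths) != 3:
        raise ParameterError("facet_radii and facet_widths must have 3 entries")
    if any(r <= 0 for r in facet_radii) or any(w <= 0 for w in facet_widths):
        raise ParameterError("facet dimensions must be strictly positive")
    if not cartilage_gap > 0:
        raise ParameterError("cartilage_gap must be strictly positive")
    if resolution < 8:
        raise ParameterError("resolution must be >= 8 subdivisions per facet")

    total_w = sum(facet_widths)
    # medial facet occupies the +y end (medial = +y by package convention)
    edges = np.concatenate([[total_w / 2.0], total_w / 2.0 - np.cumsum(facet_widths)])
    radius_labels = ("radial_facet", "intermediate_facet", "ulnar_facet")
    carpal_labels = ("Cr_prox", "Ci_prox", "Cu_prox")

    radius_patches, carpal_patches = [], []
    half = phi_span / 2.0
    for k in range(3):
        y_hi, y_lo = float(edges[k]), float(edges[k + 1])
        radius_patches.append(
            _facet_patch(
                facet_radii[k], y_lo, y_hi, -half, half, resolution, resolution, True, radius_labels[k]
            )
        )
        carpal_patches.append(
            _facet_patch(
                facet_radii[k] + cartilage_gap,
                y_lo,
                y_hi,
                -half,
                half,
                resolution,
                resolution,
                False,
                carpal_labels[k],
            )
        )
    # mark the medial parasagittal ridge: boundary between medial and
    # intermediate facets on the radius, stored on the medial patch
    mpr_phi = np.linspace(-half, half, resolution + 1)
    ridge = CylindricalFacet(facet_radii[0], (0, 0), (-half, half), True).points(
        mpr_phi, np.full_like(mpr_phi, edges[1])
    )
    radius_patches[0].landmark_mpr = ridge
    return radius_patches, carpal_patches


def inertia_from_mesh(mesh: trimesh.Trimesh, density: float):
    """Mass, center of mass and inertia tensor (about the COM) of a closed mesh.

    Uses the divergence-theorem mass properties of the triangle mesh at the
    given homogeneous density.  Raises :class:`TopologyError` for open or
    inconsistently wound meshes.
    """
    if not density > 0:
        raise ParameterError("density must be strictly positive")
    if not mesh.is_watertight:
        raise TopologyError("mesh must be closed (watertight) for inertial properties")
    if not mesh.is_winding_consistent:
        raise TopologyError("mesh winding is inconsistent")
    m = mesh.copy()
    if m.volume < 0:
        m.invert()
    m.density = float(density)
    mass = float(m.mass)
    com = np.asarray(m.center_mass, dtype=float)
    inertia = np.asarray(m.moment_inertia, dtype=float)
    inertia = 0.5 * (inertia + inertia.T)  # symmetrize roundoff
    return mass, com, inertia


def read_mesh(path) -> trimesh.Trimesh:
    """Read an STL (ASCII or binary) or PLY mesh, preserving topology exactly."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise MeshFormatError(f"empty mesh file: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # parser failures from any backend
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in {path}")
        mesh = geoms[0]
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise MeshFormatError(f"no triangles in {path}")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    """Write a mesh as STL (set ``ascii=True`` for the text dialect) or PLY."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl" and ascii:
        from trimesh.exchange.stl import export_stl_ascii

        path.write_text(export_stl_ascii(mesh))
    elif suffix in (".stl", ".ply"):
        mesh.export(str(path))
    else:
        raise MeshFormatError(f"unsupported mesh format {suffix!r}")
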