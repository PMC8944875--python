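"""Penalty contact between articular surfaces and hoof-ground contact.

Contact onset between two articulating bones is defined at a bone-surface
separation equal to the local total cartilage thickness (C.Th): the two
cartilage half-layers are the compliant medium, so the interpenetration of
the contact model is delta = C.Th - separation, clamped at zero.  The
normal force follows the impact-style penalty law

    F = k_c * delta^e + step(delta; 0 -> c_max over d_ramp) * delta_rate

clamped to be non-negative (no adhesion).  Articular pairs are
frictionless; the hoof-ground pair adds velocity-regularised Coulomb
friction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import GeometryError, ParameterError
from .geometry import ArticularSurfacePatch, CylindricalFacet
from .rigid import Pose

__all__ = [
    "CONTACT_PAIR_IDS",
    "closest_points_on_mesh",
    "ContactPair",
    "ContactState",
    "GroundParams",
    "smooth_step",
    "contact_force",
    "detect_penetration",
    "center_of_contact",
    "ground_reaction",
    "calibrate_contact_stiffness",
    "cylinder_penetration",
]

CONTACT_PAIR_IDS = ("Ra_Cr", "Ra_Ci", "Ra_Cu", "hoof_ground")

_ARTICULAR_IDS = ("Ra_Cr", "Ra_Ci", "Ra_Cu")


def closest_points_on_mesh(points: np.ndarray, triangles: np.ndarray):
    """Closest points and distances from query points to a triangle soup.

    Fully vectorised point-triangle projection (all points against all
    triangles, then the per-point minimum); intended for the patch-sized
    meshes this package works with.

    Parameters
    ----------
    points : (n, 3) query points.
    triangles : (m, 3, 3) triangle vertex coordinates.

    Returns
    -------
    (closest, dist) : (n, 3) closest surface points and (n,) distances.
    """
    p = np.asarray(points, float)[:, None, :]  # (n, 1, 3)
    tri = np.asarray(triangles, float)
    a, b, c = tri[:, 0][None], tri[:, 1][None], tri[:, 2][None]  # (1, m, 3)
    ab, ac = b - a, c - a
    ap = p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
        w_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
        w_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    # region selection (Ericson, Real-Time Collision Detection)
    r_a = (d1 <= 0) & (d2 <= 0)
    r_b = (d3 >= 0) & (d4 <= d3)
    r_c = (d6 >= 0) & (d5 <= d6)
    r_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    r_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    r_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    q = a + np.nan_to_num(v_in)[..., None] * ab + np.nan_to_num(w_in)[..., None] * ac
    q = np.where(r_bc[..., None], b + w_bc[..., None] * (c - b), q)
    q = np.where(r_ac[..., None], a + w_ac[..., None] * ac, q)
    q = np.where(r_ab[..., None], a + v_ab[..., None] * ab, q)
    q = np.where(r_c[..., None], np.broadcast_to(c, q.shape), q)
    q = np.where(r_b[..., None], np.broadcast_to(b, q.shape), q)
    q = np.where(r_a[..., None], np.broadcast_to(a, q.shape), q)

    d2_all = ((p - q) ** 2).sum(-1)  # (n, m)
    k = np.argmin(d2_all, axis=1)
    idx = np.arange(len(k))
    return q[idx, k], np.sqrt(d2_all[idx, k])


def calibrate_contact_stiffness(
    cartilage_modulus: float, facet_area: float, mean_cth: float, exponent: float = 1.5
) -> float:
    """Penalty stiffness k_c [N/m^e] for one articular facet.

    Calibrated so the contact force at full cartilage compression
    (delta = C.Th) equals ``cartilage_modulus * facet_area``:
    k_c = E * A / C.Th^e.  At e = 1 this reduces to E * A / C.Th.
    """
    if min(cartilage_modulus, facet_area, mean_cth) <= 0:
        raise ParameterError("calibration inputs must be strictly positive")
    return cartilage_modulus * facet_area / mean_cth**exponent


@dataclass
class ContactPair:
    """One contact pair and its penalty parameters.

    ``cth`` is the total cartilage thickness: a scalar or a per-face map
    over ``surfA``'s faces [m].  ``friction_mu`` must be 0 for the three
    articular pairs (articular contact is frictionless).
    """

    id: str
    surfA: ArticularSurfacePatch
    surfB: ArticularSurfacePatch
    stiffness: float  # k_c [N/m^e]
    exponent: float = 1.5
    max_damping: float = 2.0e3  # c_max [N·s/m]
    damping_depth: float = 2.0e-4  # d_ramp [m]
    cth: object = 1.0e-3  # scalar or (n_faces,) array [m]
    friction_mu: float = 0.0

    def __post_init__(self):
        if self.id not in CONTACT_PAIR_IDS:
            raise ParameterError(f"unknown contact pair id {self.id!r}")
        if not self.stiffness > 0:
            raise ParameterError("contact stiffness must be positive")
        if self.exponent < 1:
            raise ParameterError("contact exponent must be >= 1")
        if not self.damping_depth > 0:
            raise ParameterError("damping_depth must be positive")
        if self.id in _ARTICULAR_IDS and self.friction_mu != 0.0:
            raise ParameterError("articular contact pairs are frictionless (mu = 0)")
        self.cth = np.asarray(self.cth, dtype=float)
        if np.any(self.cth <= 0):
            raise ParameterError("cartilage thickness must be positive")

    def cth_at_faces(self, n_faces: int) -> np.ndarray:
        if self.cth.ndim == 0:
            return np.full(n_faces, float(self.cth))
        if self.cth.shape != (n_faces,):
            raise ParameterError("per-face cth map does not match surfA face count")
        return self.cth


@dataclass
class ContactState:
    """Active contact regions of one pair at one instant."""

    pair_id: str
    faces: np.ndarray  # (n,) face indices on surfA
    penetration: np.ndarray  # delta > 0 [m]
    penetration_rate: np.ndarray  # [m/s]
    normals: np.ndarray  # (n, 3) unit, world frame (from surfA faces)
    points: np.ndarray  # (n, 3) world [m]
    normal_forces: np.ndarray  # (n,) >= 0 [N]
    # optional projection support for center_of_contact
    surfA: Optional[ArticularSurfacePatch] = None
    poseA: Optional[Pose] = None

    @property
    def total_force(self) -> np.ndarray:
        if len(self.faces) == 0:
            return np.zeros(3)
        return (self.normal_forces[:, None] * self.normals).sum(axis=0)

    @property
    def coc(self) -> Optional[np.ndarray]:
        return center_of_contact(self)


def smooth_step(x, x0: float, y0: float, x1: float, y1: float):
    """Cubic smooth step: y0 at x <= x0, y1 at x >= x1, C1 in between."""
    t = np.clip((np.asarray(x, float) - x0) / (x1 - x0), 0.0, 1.0)
    return y0 + (y1 - y0) * t * t * (3.0 - 2.0 * t)


def contact_force(delta, delta_rate, stiffness, exponent=1.5, max_damping=2.0e3, damping_depth=2.0e-4):
    """Normal penalty force [N]; vectorised over delta.

    F = k * delta^e + step(delta) * delta_rate, clamped at 0 (no adhesion).
    The damping coefficient ramps from 0 at delta = 0 to c_max at
    delta = d_ramp so the force is continuous at contact onset.
    """
    delta = np.maximum(np.asarray(delta, float), 0.0)
    c = smooth_step(delta, 0.0, 0.0, damping_depth, max_damping)
    f = stiffness * delta**exponent + c * np.asarray(delta_rate, float)
    return np.maximum(f, 0.0)


def detect_penetration(
    pair: ContactPair, poseA: Pose, poseB: Pose
) -> List[Tuple[int, float, np.ndarray, np.ndarray]]:
    """Mesh-general penetration query.

    For every face of ``surfA`` (posed by ``poseA``), the separation to
    ``surfB`` (posed by ``poseB``) is measured at the face centroid by a
    closest-point query; the cartilage interpenetration is
    delta = cth(face) - separation.  Only faces with delta > 0 are
    returned, as ``(face index, delta, world normal, world point)`` tuples.
    Assumes the bone surfaces themselves do not cross (the cartilage layer
    is the compliant medium).
    """
    meshA = pair.surfA.mesh
    meshB = pair.surfB.mesh
    if meshB.is_watertight and not meshB.is_winding_consistent:
        raise GeometryError("surfB mesh winding inconsistent")

    tri_b = poseB.transform(meshB.triangles.reshape(-1, 3)).reshape(-1, 3, 3)
    centroids = poseA.transform(meshA.triangles_center)
    normals = poseA.rotate(meshA.face_normals)
    _, dist = closest_points_on_mesh(centroids, tri_b)
    cth = pair.cth_at_faces(len(meshA.faces))
    delta = cth - dist
    out = []
    for i in np.flatnonzero(delta > 0):
        out.append((int(i), float(delta[i]), normals[i], centroids[i]))
    return out


def cylinder_penetration(
    facetA: CylindricalFacet,
    facetB: CylindricalFacet,
    points_A: np.ndarray,
    normals_A: np.ndarray,
    poseA: Pose,
    poseB: Pose,
    cth: np.ndarray,
):
    """Fast analytic penetration for a convex/concave cylinder facet pair.

    ``points_A``/``normals_A`` are surfA face centroids and outward normals
    in A's body frame.  The opposing concave facet is the cylinder of radius
    ``facetB.radius`` about B's facet axis; separation at a point p on A is
    R_B - |p - axis_B| (measured radially), masked to B's angular and
    medio-lateral extent.  Returns ``(delta, normals_world, points_world,
    active_mask)`` with delta unclamped (can be negative) for smooth
    rate estimation.
    """
    pw = poseA.transform(points_A)
    p_b = poseB.inverse_transform(pw)  # into B's body frame
    rel = p_b - np.asarray(facetB.axis_point, float)
    x, y, z = rel[:, 0], rel[:, 1], rel[:, 2]
    rho = np.hypot(x, z)
    separation = facetB.radius - rho
    delta = cth - separation
    phi = np.arctan2(x, -z)
    y_lo, y_hi = facetB.y_range
    phi_lo, phi_hi = facetB.phi_range
    active = (y >= y_lo) & (y <= y_hi) & (phi >= phi_lo) & (phi <= phi_hi)
    normals_world = poseA.rotate(normals_A)
    return delta, normals_world, pw, active


def center_of_contact(state: ContactState) -> Optional[np.ndarray]:
    """Force-weighted centroid of the active contact points, projected onto
    surfA along its local normal; ``None`` when no region is active."""
    if state.faces.size == 0 or state.normal_forces.sum() <= 0.0:
        return None
    w = state.normal_forces
    centroid = (w[:, None] * state.points).sum(axis=0) / w.sum()
    if state.surfA is None or state.poseA is None:
        return centroid
    cyl = state.surfA.cylinder
    if cyl is not None:
        # project radially onto the parametric facet surface
        p_local = state.poseA.inverse_transform(centroid) - np.asarray(cyl.axis_point, float)
        rho = np.hypot(p_local[0], p_local[2])
        if rho > 0:
            scale = cyl.radius / rho
            proj = np.array([p_local[0] * scale, p_local[1], p_local[2] * scale])
            return state.poseA.transform(proj + np.asarray(cyl.axis_point, float))
        return centroid
    tri = state.poseA.transform(state.surfA.mesh.triangles.reshape(-1, 3)).reshape(-1, 3, 3)
    closest, _ = closest_points_on_mesh(centroid[None, :], tri)
    return closest[0]


@dataclass
class GroundParams:
    """Hoof-ground contact parameters (ground is the plane z = 0)."""

    stiffness: float = 2.5e6  # N/m^e
    exponent: float = 1.0
    max_damping: float = 5.0e3
    damping_depth: float = 1.0e-3
    friction_mu: float = 0.55  # dirt track (tuff clay and sand)
    v_eps: float = 0.05  # m/s stick-slip regularisation velocity


def ground_reaction(hoof_pos, hoof_vel, params: GroundParams = None) -> np.ndarray:
    """Ground reaction force [N] on the hoof from the z = 0 plane.

    Normal component by the penalty law; tangential component is
    regularised Coulomb friction |F_t| <= mu * F_n with a smooth
    stick-slip transition over ``v_eps``.
    """
    if params is None:
        params = GroundParams()
    p = np.asarray(hoof_pos, float)
    v = np.asarray(hoof_vel, float)
    delta = -p[2]
    if delta <= 0.0:
        return np.zeros(3)
    fn = float(
        contact_force(
            delta, -v[2], params.stiffness, params.exponent, params.max_damping, params.damping_depth
        )
    )
    vt = v.copy()
    vt[2] = 0.0
    speed = np.linalg.norm(vt)
    ft = np.zeros(3)
    if speed > 0.0:
        mag = params.friction_mu * fn * np.tanh(speed / params.v_eps)
        ft = -mag * vt / speed
    return np.array([ft[0], ft[1], fn])
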